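"""Mixed-effects analysis of the observation table.

Each physiological measure is analysed separately with a linear mixed model
whose fixed effects are one affective dimension (three treatment-coded levels)
plus Task (two levels), and whose random part is crossed random intercepts of
item (musical piece) and interval (first/second half).  The three dimensions
are fitted in separate models because their ratings correlate.  Reference
levels: Valence = neutral, Energy = high, Tension = high, Task = felt.

Fitting is by REML (delegated to statsmodels MixedLM; the crossed intercepts
enter as variance components over a single trivial group).  On top of the fit
this module computes:

* Wald F-tests per factor with containment (between-within) denominator
  degrees of freedom: factors constant within item are tested against
  ``n_items - p_item`` (the item-level design rank), factors varying within
  item against ``N - n_items - n_intervals``;
* Wald 95% confidence intervals for the fixed effects;
* marginal and conditional R2 for mixed models (fixed-effects variance vs
  fixed plus random, each over the total including residual);
* the felt-intensity analyses: Pearson correlation of per-stimulus mean
  intensity with the dimension ratings, and mixed models with the z-scored
  intensity rating as a single continuous fixed effect.

No multiple-comparison correction is applied anywhere.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.formula.api as smf

from .errors import DomainError, MusicPhysError, SchemaError

DIMENSION_LEVEL_COLUMN = {
    "valence": "valence_level",
    "energy": "energy_level",
    "tension": "tension_level",
}

REFERENCE_LEVELS = {
    "valence": "neutral",
    "energy": "high",
    "tension": "high",
    "task": "felt",
}


@dataclass(frozen=True)
class ModelSpec:
    """One measure, one affective dimension, Task, crossed item/interval."""

    response: str  # measure name, e.g. "EMGZ"
    dimension: str  # "valence" | "energy" | "tension"
    reference_levels: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    def __post_init__(self):
        if self.dimension not in DIMENSION_LEVEL_COLUMN:
            raise DomainError(f"unknown dimension {self.dimension!r}")


@dataclass
class FixedEffectEstimate:
    term: str
    b: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class ModelFit:
    measure: str
    dimension: str | None  # None for intensity models
    estimates: list
    variance_components: dict  # name -> {"var": v, "sd": s}
    f_tests: dict  # factor -> {"F": f, "df_num": q, "df_den": d, "p": p}
    t_tests: dict  # term -> {"t": t, "df": d, "p": p}
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# R2 for mixed models


def r2_glmm(var_fixed: float, var_random_sum: float, var_residual: float):
    """Marginal and conditional R2 of a mixed model.

    marginal = var_fixed / total, conditional = (var_fixed + var_random) /
    total, with total = var_fixed + var_random_sum + var_residual.
    ``var_fixed`` is the variance of the fixed-effects linear predictor over
    the data.  Scale-invariant in its three inputs.
    """
    for name, v in (
        ("var_fixed", var_fixed),
        ("var_random_sum", var_random_sum),
        ("var_residual", var_residual),
    ):
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")
    total = var_fixed + var_random_sum + var_residual
    if total == 0:
        raise DomainError("all variance components are zero")
    return var_fixed / total, (var_fixed + var_random_sum) / total


# ---------------------------------------------------------------------------
# model fitting


def _pretty_term(name: str, dimension: str | None) -> str:
    if name == "Intercept":
        return "Intercept"
    if name == "intensity_z":
        return "Intensity (z)"
    m = re.search(r"\[T\.([^\]]+)\]", name)
    if m is None:
        return name
    level = m.group(1)
    if "task" in name:
        return f"Task ({level})"
    if dimension is not None:
        return f"{dimension.capitalize()} ({level})"
    return f"({level})"


def _fit_mixedlm(df: pd.DataFrame, fixed_formula: str):
    """REML fit with crossed random intercepts of item and interval.

    A random term with fewer than two observed levels is dropped with a
    warning (a single level is indistinguishable from the intercept).
    """
    df = df.reset_index(drop=True).copy()
    notes = []
    vc = {}
    if df["stimulus"].nunique() >= 2:
        vc["item"] = "0 + C(stimulus)"
    else:
        notes.append("degenerate random effect: single item; item intercept dropped")
    if df["interval"].nunique() >= 2:
        vc["interval"] = "0 + C(interval)"
    else:
        notes.append(
            "degenerate random effect: single interval; interval intercept dropped"
        )
    df["_group"] = 1
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            fixed_formula, df, groups="_group",
            vc_formula=vc or None, re_formula="0" if vc else None,
        )
        result = None
        # boundary variance components can defeat a single optimizer; walk a
        # ladder, prefer a converged fit, otherwise the best REML likelihood
        # among candidates with a finite fixed-effects covariance
        for method in (None, "powell", "nm", "cg"):
            kw = {"reml": True}
            if method is not None:
                kw["method"] = method
            try:
                candidate = model.fit(**kw)
            except (np.linalg.LinAlgError, ValueError):
                continue
            finite = bool(np.isfinite(np.asarray(candidate.bse_fe)).all())
            if not finite:
                continue
            if result is None or candidate.llf > result.llf + 1e-8:
                result = candidate
                if method is not None:
                    notes.append(f"optimizer fallback: {method}")
            if getattr(candidate, "converged", False):
                result = candidate
                break
        if result is None:
            raise MusicPhysError(f"mixed-model fit failed for {fixed_formula!r}")
    for w in caught:
        notes.append(f"{w.category.__name__}: {w.message}")
    return model, result, notes


def _variance_components(model, result) -> dict:
    comps = {}
    names = list(getattr(model.exog_vc, "names", []) or [])
    for name, var in zip(names, np.atleast_1d(result.vcomp)):
        v = float(max(var, 0.0))
        comps[name] = {"var": v, "sd": float(np.sqrt(v))}
    comps["residual"] = {
        "var": float(result.scale),
        "sd": float(np.sqrt(result.scale)),
    }
    return comps


def _wald_F(result, term_idx):
    """Wald chi2 / q for a joint test that the listed coefficients are zero."""
    fe = np.asarray(result.fe_params)
    k = fe.size
    cov = np.asarray(result.cov_params())[:k, :k]
    idx = np.asarray(term_idx)
    c = fe[idx]
    V = cov[np.ix_(idx, idx)]
    chi2 = float(c @ np.linalg.solve(V, c))
    return chi2 / idx.size


def _containment_df(df: pd.DataFrame, n_item_level_params: int) -> dict:
    """Between-within denominator df.

    Factors constant within item (the dimension levels) are tested against
    the item stratum: n_items minus the item-level fixed params (intercept +
    dimension coefficients).  Factors varying within item (Task, intensity)
    are tested against the observation stratum: N minus the random-intercept
    levels.
    """
    n_items = df["stimulus"].nunique()
    n_intervals = df["interval"].nunique()
    n = len(df)
    return {
        "item_level": max(n_items - n_item_level_params, 1),
        "obs_level": max(n - n_items - n_intervals, 1),
    }


def fit_measure_model(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one measure's mixed model for one affective dimension plus Task.

    Returns estimates with Wald 95% CIs, variance components, containment-df
    Wald F-tests per factor, and marginal/conditional R2.  A variance
    component estimated at the zero boundary attaches a singular-fit warning
    rather than raising.
    """
    needed = {"value", "task", "stimulus", "interval", DIMENSION_LEVEL_COLUMN[spec.dimension]}
    missing = needed - set(table.columns)
    if missing:
        raise SchemaError(f"observation table missing columns {sorted(missing)}")
    df = table[table["measure"] == spec.response].dropna(subset=["value"]).copy()
    if df.empty:
        raise DomainError(f"no rows for measure {spec.response!r}")
    level_col = DIMENSION_LEVEL_COLUMN[spec.dimension]
    if df[level_col].nunique() < 2 or df["task"].nunique() < 2:
        raise DomainError("need >= 2 observed levels per fixed factor")

    ref_dim = spec.reference_levels[spec.dimension]
    ref_task = spec.reference_levels["task"]
    formula = (
        f"value ~ C({level_col}, Treatment('{ref_dim}'))"
        f" + C(task, Treatment('{ref_task}'))"
    )
    model, result, notes = _fit_mixedlm(df, formula)

    names = list(model.exog_names)
    ci = result.conf_int()
    estimates = []
    for i, nm in enumerate(names):
        estimates.append(
            FixedEffectEstimate(
                term=_pretty_term(nm, spec.dimension),
                b=float(result.fe_params.iloc[i]),
                se=float(result.bse_fe.iloc[i]),
                ci_low=float(ci.iloc[i, 0]),
                ci_high=float(ci.iloc[i, 1]),
            )
        )

    comps = _variance_components(model, result)
    if any(c["var"] < 1e-10 for k, c in comps.items() if k != "residual"):
        notes.append("singular fit: variance component at zero boundary")

    dim_idx = [i for i, nm in enumerate(names) if level_col in nm]
    task_idx = [i for i, nm in enumerate(names) if "task" in nm]
    dfs = _containment_df(df, n_item_level_params=1 + len(dim_idx))
    f_tests = {}
    for factor, idx, df_den in (
        (spec.dimension.capitalize(), dim_idx, dfs["item_level"]),
        ("Task", task_idx, dfs["obs_level"]),
    ):
        F = _wald_F(result, idx)
        q = len(idx)
        f_tests[factor] = {
            "F": F,
            "df_num": q,
            "df_den": df_den,
            "p": float(sp_stats.f.sf(F, q, df_den)),
        }

    var_fixed = float(np.var(np.asarray(model.exog) @ np.asarray(result.fe_params), ddof=1))
    var_random = sum(c["var"] for k, c in comps.items() if k != "residual")
    r2m, r2c = r2_glmm(var_fixed, var_random, comps["residual"]["var"])

    return ModelFit(
        measure=spec.response,
        dimension=spec.dimension,
        estimates=estimates,
        variance_components=comps,
        f_tests=f_tests,
        t_tests={},
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(df),
        warnings=notes,
    )


def fit_intensity_model(table: pd.DataFrame, measure: str) -> ModelFit:
    """Mixed model of one measure on the z-scored felt-intensity rating.

    Felt-task rows only; same crossed random intercepts as the dimension
    models, a single continuous fixed effect.  Reports the slope with SE and
    a t-test at the observation-level containment df.
    """
    if "intensity_z" not in table.columns:
        raise SchemaError("observation table has no intensity_z column")
    df = table[
        (table["measure"] == measure) & (table["task"] == "felt")
    ].dropna(subset=["value", "intensity_z"]).copy()
    if df.empty:
        raise DomainError(f"no felt-task rows with intensity for {measure!r}")

    model, result, notes = _fit_mixedlm(df, "value ~ intensity_z")
    names = list(model.exog_names)
    ci = result.conf_int()
    estimates = [
        FixedEffectEstimate(
            term=_pretty_term(nm, None),
            b=float(result.fe_params.iloc[i]),
            se=float(result.bse_fe.iloc[i]),
            ci_low=float(ci.iloc[i, 0]),
            ci_high=float(ci.iloc[i, 1]),
        )
        for i, nm in enumerate(names)
    ]
    comps = _variance_components(model, result)
    dfs = _containment_df(df, n_item_level_params=1)
    i_slope = names.index("intensity_z")
    b = float(result.fe_params.iloc[i_slope])
    se = float(result.bse_fe.iloc[i_slope])
    tval = b / se
    df_den = dfs["obs_level"]
    t_tests = {
        "Intensity (z)": {
            "t": tval,
            "df": df_den,
            "p": float(2 * sp_stats.t.sf(abs(tval), df_den)),
        }
    }
    var_fixed = float(np.var(np.asarray(model.exog) @ np.asarray(result.fe_params), ddof=1))
    var_random = sum(c["var"] for k, c in comps.items() if k != "residual")
    r2m, r2c = r2_glmm(var_fixed, var_random, comps["residual"]["var"])
    return ModelFit(
        measure=measure,
        dimension=None,
        estimates=estimates,
        variance_components=comps,
        f_tests={},
        t_tests=t_tests,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(df),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# felt-intensity correlation


def intensity_by_stimulus(table: pd.DataFrame) -> pd.Series:
    """Per-stimulus mean of the z-scored felt-intensity rating."""
    felt = table[(table["task"] == "felt")].dropna(subset=["intensity_z"])
    if felt.empty:
        raise DomainError("no felt-task intensity ratings in the table")
    return felt.groupby("stimulus")["intensity_z"].mean()


def correlate_intensity(per_stim_intensity: pd.Series, stimuli, dimension: str):
    """Pearson correlation of mean felt intensity with a dimension rating.

    ``per_stim_intensity`` is indexed by stimulus id; ratings come from the
    stimulus table.  Returns (r, two-sided p at n-2 df).
    """
    if dimension not in DIMENSION_LEVEL_COLUMN:
        raise DomainError(f"unknown dimension {dimension!r}")
    ratings = {s.index_ref: s.rating(dimension) for s in stimuli}
    missing = [sid for sid in per_stim_intensity.index if sid not in ratings]
    if missing:
        raise DomainError(f"stimuli without ratings: {missing}")
    x = np.asarray(per_stim_intensity, dtype=float)
    y = np.array([ratings[sid] for sid in per_stim_intensity.index])
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance on one side of the correlation")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# reporting


def model_report(fits) -> dict:
    """Machine-readable report of one or more fits (layout mirrors the
    fixed-effects / random-components / R2 tables)."""
    fits = list(fits)
    if not fits:
        warnings.warn("model_report called with no fits")
        return {"models": []}
    models = []
    for f in fits:
        models.append(
            {
                "measure": f.measure,
                "dimension": f.dimension,
                "fixed_effects": [
                    {
                        "term": e.term,
                        "b": e.b,
                        "se": e.se,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                    }
                    for e in f.estimates
                ],
                "random_effects": f.variance_components,
                "f_tests": f.f_tests,
                "t_tests": f.t_tests,
                "r2_marginal": f.r2_marginal,
                "r2_conditional": f.r2_conditional,
                "n_obs": f.n_obs,
                "warnings": list(f.warnings),
            }
        )
    return {"models": models}


def report_to_fits(report: dict) -> list:
    """Inverse of :func:`model_report` (serialization round-trip)."""
    fits = []
    for m in report.get("models", []):
        fits.append(
            ModelFit(
                measure=m["measure"],
                dimension=m["dimension"],
                estimates=[
                    FixedEffectEstimate(
                        term=e["term"],
                        b=e["b"],
                        se=e["se"],
                        ci_low=e["ci_low"],
                        ci_high=e["ci_high"],
                    )
                    for e in m["fixed_effects"]
                ],
                variance_components=m["random_effects"],
                f_tests=m["f_tests"],
                t_tests=m["t_tests"],
                r2_marginal=m["r2_marginal"],
                r2_conditional=m["r2_conditional"],
                n_obs=m["n_obs"],
                warnings=list(m["warnings"]),
            )
        )
    return fits
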