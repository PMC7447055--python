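import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musicphys import stats as ms
from musicphys.errors import DomainError, SchemaError
from musicphys.synth import MEASURES, GeneratorConfig, simulate_observations


def _balanced_toy(n_rep=8, seed=0):
    """Balanced fully-crossed toy table: 6 items (2 per valence level),
    2 tasks, 2 intervals, n_rep replicate participants."""
    rng = np.random.default_rng(seed)
    levels = {1: "negative", 2: "negative", 3: "neutral",
              4: "neutral", 5: "positive", 6: "positive"}
    shift = {"negative": -0.4, "neutral": 0.0, "positive": 0.5}
    rows = []
    for p in range(n_rep):
        for item, lv in levels.items():
            for task in ("felt", "perceived"):
                for interval in (1, 2):
                    val = (
                        shift[lv]
                        + (0.3 if task == "perceived" else 0.0)
                        + rng.standard_normal()
                    )
                    rows.append(
                        {"participant": f"P{p}", "stimulus": item, "task": task,
                         "interval": interval, "measure": "HR", "value": val,
                         "valence_level": lv, "energy_level": "medium",
                         "tension_level": "medium"}
                    )
    return pd.DataFrame(rows)


class TestR2Glmm:
    def test_worked_example(self):
        assert ms.r2_glmm(1.0, 1.0, 2.0) == (0.25, 0.50)

    def test_no_random_variance_marginal_equals_conditional(self):
        r2m, r2c = ms.r2_glmm(1.5, 0.0, 0.5)
        assert r2m == r2c == 0.75

    def test_all_zero_rejected(self):
        with pytest.raises(DomainError):
            ms.r2_glmm(0.0, 0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            ms.r2_glmm(-1.0, 1.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        vf=st.floats(min_value=0.01, max_value=10),
        vr=st.floats(min_value=0.0, max_value=10),
        ve=st.floats(min_value=0.01, max_value=10),
        c=st.floats(min_value=0.01, max_value=100),
    )
    def test_scale_invariant(self, vf, vr, ve, c):
        a = ms.r2_glmm(vf, vr, ve)
        b = ms.r2_glmm(c * vf, c * vr, c * ve)
        assert a == pytest.approx(b, rel=1e-9)

    def test_recovers_generating_variances(self):
        """Plug-in truth vs estimate on a large synthetic fit.

        The plug-in truth uses the realized random offsets (the same latent
        draw backs both the observation table and the ground-truth object).
        """
        from musicphys.synth import simulate_cohort

        cfg = GeneratorConfig(n_participants=16, n_stimuli=16, seed=8)
        obs = simulate_observations(cfg)
        truth = simulate_cohort(cfg, render=False).truth
        fit = ms.fit_measure_model(obs, ms.ModelSpec("HR", "energy"))
        df = obs[obs["measure"] == "HR"]
        eff = {"low": -0.23, "medium": -0.07, "high": 0.0}
        pred = df["energy_level"].map(eff) + np.where(df["task"] == "perceived", 0.2, 0.0)
        vf = pred.var(ddof=1)
        vr = float(
            np.var(list(truth.item_offsets["HR"].values()), ddof=1)
            + np.var(list(truth.interval_offsets["HR"].values()), ddof=1)
        )
        ve = cfg.sd_residual**2
        r2m_true, r2c_true = ms.r2_glmm(vf, vr, ve)
        assert fit.r2_marginal == pytest.approx(r2m_true, abs=0.05)
        assert fit.r2_conditional == pytest.approx(r2c_true, abs=0.05)


class TestFitMeasureModel:
    def test_balanced_estimates_match_group_mean_oracle(self):
        """On a balanced crossed design, fixed effects equal marginal
        group-mean differences (brute-force oracle)."""
        df = _balanced_toy()
        fit = ms.fit_measure_model(df, ms.ModelSpec("HR", "valence"))
        by_level = df.groupby("valence_level")["value"].mean()
        by_task = df.groupby("task")["value"].mean()
        est = {e.term: e.b for e in fit.estimates}
        assert est["Valence (negative)"] == pytest.approx(
            by_level["negative"] - by_level["neutral"], abs=1e-8
        )
        assert est["Valence (positive)"] == pytest.approx(
            by_level["positive"] - by_level["neutral"], abs=1e-8
        )
        assert est["Task (perceived)"] == pytest.approx(
            by_task["perceived"] - by_task["felt"], abs=1e-8
        )

    def test_ci_brackets_estimate(self):
        df = _balanced_toy()
        fit = ms.fit_measure_model(df, ms.ModelSpec("HR", "valence"))
        for e in fit.estimates:
            assert e.ci_low <= e.b <= e.ci_high

    def test_variance_components_nonnegative_and_named(self):
        cfg = GeneratorConfig(n_participants=6, n_stimuli=8, seed=2)
        obs = simulate_observations(cfg)
        fit = ms.fit_measure_model(obs, ms.ModelSpec("RR", "valence"))
        assert set(fit.variance_components) == {"item", "interval", "residual"}
        assert all(c["var"] >= 0 for c in fit.variance_components.values())
        assert fit.r2_marginal <= fit.r2_conditional <= 1.0

    def test_containment_df_pattern(self):
        """Dimension tested at item-level df, Task at observation-level df."""
        cfg = GeneratorConfig(n_participants=10, n_stimuli=16, seed=4)
        obs = simulate_observations(cfg)
        fit = ms.fit_measure_model(obs, ms.ModelSpec("HR", "valence"))
        n = fit.n_obs
        assert fit.f_tests["Valence"]["df_num"] == 2
        assert fit.f_tests["Valence"]["df_den"] == 16 - 3
        assert fit.f_tests["Task"]["df_den"] == n - 16 - 2

    def test_single_item_attaches_degenerate_warning(self):
        df = _balanced_toy()
        df = df[df["stimulus"] == 1].copy()
        df.loc[df.index[: len(df) // 2], "valence_level"] = "neutral"
        fit = ms.fit_measure_model(df, ms.ModelSpec("HR", "valence"))
        assert any("degenerate random effect" in w for w in fit.warnings)

    def test_missing_columns_schema_error(self):
        with pytest.raises(SchemaError):
            ms.fit_measure_model(pd.DataFrame({"value": [1.0]}), ms.ModelSpec("HR", "valence"))

    def test_task_coefficient_recovery_single_cohort(self):
        delta = 0.3
        cfg = GeneratorConfig(
            n_participants=10, n_stimuli=16, seed=123,
            task_effect={m: delta for m in MEASURES},
        )
        obs = simulate_observations(cfg)
        fit = ms.fit_measure_model(obs, ms.ModelSpec("HR", "valence"))
        tk = next(e for e in fit.estimates if e.term == "Task (perceived)")
        assert tk.ci_low <= delta <= tk.ci_high


class TestIntensity:
    def test_proportional_intensity_r_is_one(self, stimuli):
        energy = pd.Series(
            {s.index_ref: s.energy for s in stimuli}, name="intensity_z"
        )
        r, p = ms.correlate_intensity(2.0 * energy - 1.0, stimuli, "energy")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_constant_intensity_rejected(self, stimuli):
        const = pd.Series({s.index_ref: 0.5 for s in stimuli})
        with pytest.raises(DomainError):
            ms.correlate_intensity(const, stimuli, "energy")

    def test_permutation_null_rejection_rate(self, stimuli, rng):
        """|r| exceeds the 5% critical value about 5% of the time under
        permutation of an unrelated intensity vector."""
        base = rng.standard_normal(32)
        ids = [s.index_ref for s in stimuli]
        hits = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = rng.permutation(base)
            r, p = ms.correlate_intensity(pd.Series(perm, index=ids), stimuli, "energy")
            hits += p < 0.05
        assert 0.02 <= hits / n_perm <= 0.08

    def test_slope_recovery(self):
        cfg = GeneratorConfig(n_participants=12, n_stimuli=16, seed=21)
        obs = simulate_observations(cfg)
        fit = ms.fit_intensity_model(obs, "EMGZ")
        slope = next(e for e in fit.estimates if e.term == "Intensity (z)")
        assert np.isfinite(slope.b) and np.isfinite(slope.se)
        assert "Intensity (z)" in fit.t_tests
        assert fit.n_obs == 12 * 16 * 2  # felt rows only, 2 intervals

    def test_missing_intensity_column_schema_error(self):
        df = _balanced_toy()
        with pytest.raises(SchemaError):
            ms.fit_intensity_model(df, "HR")


class TestReport:
    def test_round_trip(self):
        df = _balanced_toy()
        fits = [ms.fit_measure_model(df, ms.ModelSpec("HR", "valence"))]
        back = ms.report_to_fits(ms.model_report(fits))
        assert back[0].measure == fits[0].measure
        assert back[0].estimates == fits[0].estimates
        assert back[0].f_tests == fits[0].f_tests
        assert back[0].r2_marginal == fits[0].r2_marginal
        assert back[0].variance_components == fits[0].variance_components

    def test_empty_report_warns(self):
        with pytest.warns(UserWarning):
            rep = ms.model_report([])
        assert rep == {"models": []}
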