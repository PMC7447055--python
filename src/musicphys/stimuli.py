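"""Stimulus table, affective-dimension categorization and grouping bookkeeping.

The packaged table lists 32 movie-soundtrack excerpts, each carrying mean
ratings (1-9 scale, collected from an independent rating study) on three
affective dimensions -- valence, energy and tension -- plus an emotion-grouping
label marking the excerpt as a highly (HIGH) or moderately (MOD) representative
example of one pole (POS/NEG) of one dimension.

For modelling, the continuous ratings are collapsed to three levels per
dimension: 1-3 = low/negative, 4-6 = medium/neutral, 7-9 = high/positive.
Ratings are continuous means, so the integer rule is extended by nearest-integer
binning: [1, 3.5) -> low, [3.5, 6.5) -> medium, [6.5, 9] -> high (edges
configurable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DomainError, ParseError, SchemaError

DIMENSIONS = ("valence", "energy", "tension")

#: Level names per dimension, ordered low -> high.
LEVELS = {
    "valence": ("negative", "neutral", "positive"),
    "energy": ("low", "medium", "high"),
    "tension": ("low", "medium", "high"),
}

#: Default bin edges separating low/medium and medium/high (nearest-integer
#: extension of the printed 1-3 / 4-6 / 7-9 rule).
DEFAULT_EDGES = (3.5, 6.5)

RATING_MIN, RATING_MAX = 1.0, 9.0

_GROUPING_RE = re.compile(r"^(VALENCE|ENERGY|TENSION) (POS|NEG) (HIGH|MOD)$")
_POLE_RE = re.compile(r"^(VALENCE|ENERGY|TENSION) (POS|NEG)$")

_REQUIRED_COLUMNS = (
    "album_name",
    "track",
    "start",
    "end",
    "index_ref",
    "valence",
    "energy",
    "tension",
    "grouping",
)


@dataclass(frozen=True)
class Stimulus:
    """One row of the stimulus table.

    ``index_ref`` is the excerpt's index in the source rating study and is
    used as the stimulus id throughout the pipeline.  ``looped`` marks
    excerpts that were looped to reach the ~30 s trial duration.
    """

    album_name: str
    track: int
    start: str
    end: str
    looped: bool
    index_ref: int
    valence: float
    energy: float
    tension: float
    grouping: str

    def rating(self, dimension: str) -> float:
        if dimension not in DIMENSIONS:
            raise DomainError(f"unknown dimension {dimension!r}")
        return getattr(self, dimension)

    def levels(self, edges=DEFAULT_EDGES) -> dict[str, str]:
        """Three-level category of this stimulus on every dimension."""
        return {d: categorize_rating(self.rating(d), d, edges=edges) for d in DIMENSIONS}


def packaged_table_path() -> Path:
    """Path of the stimulus table shipped with the package."""
    return Path(resources.files("musicphys").joinpath("data/stimulus_table.tsv"))


def load_stimulus_table(path=None) -> list[Stimulus]:
    """Load the stimulus table (the packaged one when ``path`` is None).

    The ``end`` column may carry a trailing ``L`` marking looped excerpts;
    the marker is stripped into the ``looped`` flag.

    Raises
    ------
    SchemaError
        If the file is empty or a required column is missing.
    ParseError
        If a rating is non-numeric.
    DomainError
        If a rating falls outside [1, 9] or a grouping label is malformed.
    """
    if path is None:
        path = packaged_table_path()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty stimulus table: {path}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"stimulus table missing columns {missing}")

    stimuli = []
    for i, row in df.iterrows():
        ratings = {}
        for dim in DIMENSIONS:
            try:
                ratings[dim] = float(row[dim])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {i}: non-numeric {dim} rating {row[dim]!r}"
                ) from exc
            if not RATING_MIN <= ratings[dim] <= RATING_MAX:
                raise DomainError(
                    f"row {i}: {dim} rating {ratings[dim]} outside [1, 9]"
                )
        grouping = str(row["grouping"]).strip()
        if not _GROUPING_RE.match(grouping):
            raise DomainError(f"row {i}: malformed grouping label {grouping!r}")
        end = str(row["end"]).strip()
        looped = end.endswith("L")
        stimuli.append(
            Stimulus(
                album_name=str(row["album_name"]),
                track=int(row["track"]),
                start=str(row["start"]).strip(),
                end=end.rstrip("L"),
                looped=looped,
                index_ref=int(row["index_ref"]),
                grouping=grouping,
                **ratings,
            )
        )
    return stimuli


def categorize_rating(value: float, dimension: str, edges=DEFAULT_EDGES) -> str:
    """Collapse a 1-9 rating to its three-level category.

    Parameters
    ----------
    value : rating in [1, 9]
    dimension : one of ``valence``, ``energy``, ``tension``
    edges : (low_edge, high_edge) separating the levels; values below
        ``low_edge`` are low/negative, values at or above ``high_edge`` are
        high/positive.
    """
    if dimension not in DIMENSIONS:
        raise DomainError(f"unknown dimension {dimension!r}")
    if not RATING_MIN <= value <= RATING_MAX:
        raise DomainError(f"rating {value} outside [1, 9]")
    low_edge, high_edge = edges
    if not RATING_MIN < low_edge < high_edge < RATING_MAX:
        raise DomainError(f"invalid bin edges {edges}")
    names = LEVELS[dimension]
    if value < low_edge:
        return names[0]
    if value < high_edge:
        return names[1]
    return names[2]


def count_grouping(stimuli, pole_pattern: str) -> int:
    """Number of stimuli whose grouping label starts with ``pole_pattern``.

    ``pole_pattern`` is a dimension-pole prefix such as ``"VALENCE POS"``.
    """
    if not _POLE_RE.match(pole_pattern):
        raise DomainError(f"invalid dimension-pole pattern {pole_pattern!r}")
    return sum(1 for s in stimuli if s.grouping.startswith(pole_pattern + " "))


def stimulus_frame(stimuli, edges=DEFAULT_EDGES) -> pd.DataFrame:
    """Stimuli as a DataFrame keyed on stimulus id, with level columns."""
    rows = []
    for s in stimuli:
        lv = s.levels(edges)
        rows.append(
            {
                "stimulus_id": s.index_ref,
                "album_name": s.album_name,
                "valence": s.valence,
                "energy": s.energy,
                "tension": s.tension,
                "grouping": s.grouping,
                "looped": s.looped,
                "valence_level": lv["valence"],
                "energy_level": lv["energy"],
                "tension_level": lv["tension"],
            }
        )
    return pd.DataFrame(rows).set_index("stimulus_id", drop=False)
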