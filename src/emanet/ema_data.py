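"""Data model and I/O for person-level EMA symptom time series.

Ecological momentary assessment (EMA) protocols prompt a respondent several
times a day to rate each symptom on a Likert scale.  This module holds the
long-format observations, pivots them to an observations x symptoms matrix,
screens symptoms for endorsement (enough non-zero variation to model), and
restricts to complete cases for the regression and network stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SymptomSchema",
    "EmaDataset",
    "EndorsementReport",
    "PCSS_ITEMS",
    "TABLE_SYMPTOMS",
    "read_ema_csv",
    "write_ema_csv",
    "screen_endorsement",
    "complete_cases",
    "EmaValidationError",
    "InsufficientDataError",
]

#: The 18 symptom labels used in the per-person analyses.
TABLE_SYMPTOMS: tuple[str, ...] = (
    "Headache",
    "Nausea",
    "Vomiting",
    "Dizziness",
    "Fatigue",
    "Drowsiness",
    "Light Sensitivity",
    "Noise Sensitivity",
    "Irritability",
    "Sadness",
    "Nervousness",
    "Feeling Emotional",
    "Numbness/Tingling",
    "Feeling Slow",
    "Feeling Foggy",
    "Difficulty Concentrating",
    "Memory Problems",
    "Vision Problems",
)

#: The full 22-item Post-Concussion Symptom Scale item set.
PCSS_ITEMS: tuple[str, ...] = TABLE_SYMPTOMS + (
    "Balance Problems",
    "Trouble Falling Asleep",
    "Sleeping More Than Usual",
    "Sleeping Less Than Usual",
)

RATING_MIN, RATING_MAX = 0, 6


class EmaValidationError(ValueError):
    """Raised when EMA input violates the data contract."""


class InsufficientDataError(ValueError):
    """Raised when too few observations remain for an analysis stage."""


@dataclass(frozen=True)
class SymptomSchema:
    """Ordered symptom item labels, and the subset entering the models.

    Parameters
    ----------
    items:
        All labels a record may carry.
    analysis_items:
        The subset used in modeling.  Defaults to ``items``.
    """

    items: tuple[str, ...] = PCSS_ITEMS
    analysis_items: tuple[str, ...] = TABLE_SYMPTOMS

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise EmaValidationError("schema items must be unique")
        extra = set(self.analysis_items) - set(self.items)
        if extra:
            raise EmaValidationError(f"analysis items not in schema: {sorted(extra)}")

    @classmethod
    def from_items(cls, items: Sequence[str]) -> "SymptomSchema":
        items = tuple(items)
        return cls(items=items, analysis_items=items)


@dataclass
class EmaDataset:
    """One person's EMA series as an observations x symptoms rating matrix.

    ``Y`` holds integer Likert ratings 0-6 as floats, with NaN marking
    missing entries; rows are sorted by strictly increasing ``timestamps``.
    """

    person_id: str
    Y: np.ndarray
    timestamps: pd.DatetimeIndex
    schema: SymptomSchema
    n_scheduled: int | None = None  # scheduled prompt count, if known

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.Y.ndim != 2:
            raise EmaValidationError("Y must be 2-D (observations x symptoms)")
        if self.Y.shape[0] != len(self.timestamps):
            raise EmaValidationError("row count must match timestamp count")
        if self.Y.shape[1] != len(self.schema.analysis_items):
            raise EmaValidationError("column count must match schema analysis items")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise EmaValidationError("timestamps must be increasing")
        if self.timestamps.has_duplicates:
            raise EmaValidationError("duplicate timestamps")
        vals = self.Y[~np.isnan(self.Y)]
        if vals.size and (
            (vals < RATING_MIN).any()
            or (vals > RATING_MAX).any()
            or (vals != np.round(vals)).any()
        ):
            raise EmaValidationError("ratings must be integers in 0..6")

    @property
    def symptoms(self) -> tuple[str, ...]:
        return tuple(self.schema.analysis_items)

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    def column(self, symptom: str) -> np.ndarray:
        return self.Y[:, self.symptoms.index(symptom)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=self.timestamps, columns=list(self.symptoms))


@dataclass
class EndorsementReport:
    """Per-symptom endorsement screen outcome plus audit counts."""

    person_id: str
    status: dict[str, str] = field(default_factory=dict)  # endorsed | insufficient_variance
    n_nonzero: dict[str, int] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    response_rate: float | None = None

    @property
    def endorsed(self) -> list[str]:
        return [s for s, st in self.status.items() if st == "endorsed"]

    @property
    def not_endorsed(self) -> list[str]:
        return [s for s, st in self.status.items() if st != "endorsed"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "symptom": s,
                "status": self.status[s],
                "n_nonzero": self.n_nonzero[s],
                "sd": self.sd[s],
            }
            for s in self.status
        ]
        return pd.DataFrame(rows)


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EmaValidationError(
            f"malformed timestamp {raw.iloc[row]!r} at data row {row}"
        )
    return parsed


def read_ema_csv(path, schema: SymptomSchema | None = None) -> dict[str, EmaDataset]:
    """Read a long-format EMA CSV into per-person datasets.

    The file must carry columns ``person_id, timestamp, symptom, rating``
    with ISO-8601 timestamps.  Returns a dict keyed by person id, each value
    an :class:`EmaDataset` pivoted to matrix form; prompts at which a
    symptom was not recorded become NaN.
    """
    schema = schema or SymptomSchema()
    df = pd.read_csv(path, dtype={"person_id": str, "symptom": str})
    required = {"person_id", "timestamp", "symptom", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise EmaValidationError(f"missing columns: {sorted(missing)}")
    df["timestamp"] = _parse_timestamps(df["timestamp"])

    unknown = set(df["symptom"]) - set(schema.items)
    if unknown:
        raise EmaValidationError(f"symptoms not in schema: {sorted(unknown)}")

    ratings = df["rating"].to_numpy(dtype=float)
    seen = ~np.isnan(ratings)  # empty rating cell = prompt delivered, unanswered
    bad = seen & (
        (ratings < RATING_MIN) | (ratings > RATING_MAX) | (ratings != np.round(ratings))
    )
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise EmaValidationError(
            f"rating {df['rating'].iloc[row]!r} outside 0..6 at data row {row}"
        )

    dup = df.duplicated(subset=["person_id", "timestamp", "symptom"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise EmaValidationError(
            f"duplicate (person, timestamp, symptom) at data row {row}"
        )

    out: dict[str, EmaDataset] = {}
    cols = list(schema.analysis_items)
    for pid, sub in df.groupby("person_id", sort=True):
        wide = sub.pivot(index="timestamp", columns="symptom", values="rating")
        wide = wide.reindex(columns=cols).sort_index()
        out[str(pid)] = EmaDataset(
            person_id=str(pid),
            Y=wide.to_numpy(dtype=float),
            timestamps=wide.index,
            schema=schema,
        )
    return out


def write_ema_csv(ds: EmaDataset, path) -> None:
    """Write one dataset back to the long CSV format read_ema_csv consumes.

    Missing entries are written with an empty rating cell so that
    unanswered prompts survive a round trip.
    """
    frame = ds.to_frame()
    long = frame.reset_index(names="timestamp").melt(
        id_vars="timestamp", var_name="symptom", value_name="rating"
    )
    long = long.sort_values(["timestamp", "symptom"])
    long.insert(0, "person_id", ds.person_id)
    long["timestamp"] = long["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    long["rating"] = long["rating"].astype("Int64")
    long.to_csv(path, index=False)


def write_wide_csv(ds: EmaDataset, path) -> None:
    """Write the observations x symptoms matrix as wide CSV (empty = missing)."""
    frame = ds.to_frame()
    frame.index.name = "timestamp"
    frame.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")


def screen_endorsement(
    ds: EmaDataset,
    min_nonzero: int = 3,
    min_sd: float = 0.1,
) -> EndorsementReport:
    """Flag symptoms with too little non-zero variation to model.

    A symptom is *insufficient variance* when it has fewer than
    ``min_nonzero`` non-zero ratings or a standard deviation below
    ``min_sd`` rating units; such symptoms are excluded from all
    downstream models.  Missing entries are ignored in both counts.
    """
    n_answered = int((~np.isnan(ds.Y)).any(axis=1).sum())
    if n_answered < 2:
        raise InsufficientDataError(
            f"person {ds.person_id}: fewer than 2 answered prompts"
        )
    rep = EndorsementReport(person_id=ds.person_id)
    # rows with every symptom missing stand in for unanswered prompts when
    # the true scheduled prompt count is unknown
    rep.response_rate = n_answered / (ds.n_scheduled or ds.n_obs)
    for j, s in enumerate(ds.symptoms):
        col = ds.Y[:, j]
        col = col[~np.isnan(col)]
        nz = int((col != 0).sum())
        sd = float(np.std(col, ddof=1)) if col.size >= 2 else 0.0
        rep.n_nonzero[s] = nz
        rep.sd[s] = sd
        ok = nz >= min_nonzero and sd >= min_sd
        rep.status[s] = "endorsed" if ok else "insufficient_variance"
    return rep


def complete_cases(
    ds: EmaDataset,
    symptoms: Sequence[str] | None = None,
    min_rows: int = 10,
) -> EmaDataset:
    """Restrict to rows with no missing entry among the requested symptoms.

    Listwise deletion keeps the regression and network stages aligned on
    identical rows.  Raises :class:`InsufficientDataError` when fewer than
    ``min_rows`` rows survive.
    """
    symptoms = list(symptoms) if symptoms is not None else list(ds.symptoms)
    idx = [ds.symptoms.index(s) for s in symptoms]
    keep = ~np.isnan(ds.Y[:, idx]).any(axis=1)
    n_keep = int(keep.sum())
    if n_keep < min_rows:
        raise InsufficientDataError(
            f"person {ds.person_id}: {n_keep} complete rows among "
            f"{symptoms} (floor {min_rows})"
        )
    sub_schema = SymptomSchema(items=ds.schema.items, analysis_items=tuple(symptoms))
    return EmaDataset(
        person_id=ds.person_id,
        Y=ds.Y[np.ix_(keep, idx)],
        timestamps=ds.timestamps[keep],
        schema=sub_schema,
        n_scheduled=ds.n_scheduled,
    )
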