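"""Clustered right-censored survival data: domain types, validation, I/O.

A dataset is one row per subject: an opaque subject id, an opaque cluster
(center/site) id, a binary treatment arm, a strictly positive follow-up
time, and an event indicator (1 = event observed, 0 = right-censored).
Cluster ids are ordered by first appearance so that parameter layouts and
seeded pipelines are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_COLUMNS = {
    "id": "id",
    "cluster": "cluster",
    "arm": "arm",
    "time": "time",
    "event": "event",
}


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ValidationError(ValueError):
    """A row violates the dataset invariants."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: follow-up ``time`` > 0, ``event``/``arm`` in {0, 1}."""

    subject_id: str
    cluster_id: str
    arm: int
    time: float
    event: int


@dataclass
class DatasetSummary:
    """Arm-level counts and censoring proportions for a dataset."""

    n_subjects: int
    n_clusters: int
    n_per_arm: dict[int, int]
    censoring_per_arm: dict[int, float | None]
    events_per_arm: dict[int, int]
    follow_up_range: tuple[float, float]
    missing_arms: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "n_subjects": self.n_subjects,
            "n_clusters": self.n_clusters,
            "n_per_arm": {str(k): v for k, v in self.n_per_arm.items()},
            "censoring_per_arm": {
                str(k): v for k, v in self.censoring_per_arm.items()
            },
            "events_per_arm": {str(k): v for k, v in self.events_per_arm.items()},
            "follow_up_range": list(self.follow_up_range),
            "missing_arms": self.missing_arms,
        }
        return json.dumps(payload, indent=2)


class ClusteredSurvivalData:
    """Subject-level survival records nested in clusters.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``id, cluster, arm, time, event`` (canonical names). Row
        order is preserved.

    Attributes
    ----------
    time, event, arm : ndarray
        Per-subject arrays, in input row order.
    cluster_codes : ndarray of int
        Integer cluster labels 0..n_clusters-1, ordered by first appearance.
    cluster_ids : list of str
        Original labels, position = code.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.reset_index(drop=True)
        if validate:
            _validate_frame(frame)
        self.frame = frame
        self.time = frame["time"].to_numpy(dtype=float)
        self.event = frame["event"].to_numpy(dtype=int)
        self.arm = frame["arm"].to_numpy(dtype=int)
        cats = pd.Categorical(
            frame["cluster"].astype(str),
            categories=pd.unique(frame["cluster"].astype(str)),
        )
        self.cluster_codes = np.asarray(cats.codes, dtype=int)
        self.cluster_ids = list(cats.categories)
        self.cluster_index: dict[str, np.ndarray] = {
            cid: np.flatnonzero(self.cluster_codes == code)
            for code, cid in enumerate(self.cluster_ids)
        }

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def records(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(str(r["id"]), str(r["cluster"]), int(r["arm"]),
                          float(r["time"]), int(r["event"]))
            for _, r in self.frame.iterrows()
        ]

    def subset_clusters(self, cluster_ids: Sequence[str]) -> "ClusteredSurvivalData":
        keep = set(map(str, cluster_ids))
        mask = self.frame["cluster"].astype(str).isin(keep)
        return ClusteredSurvivalData(self.frame[mask], validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClusteredSurvivalData):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(
            other.frame.reset_index(drop=True)
        )


def _validate_frame(frame: pd.DataFrame) -> None:
    for col in ("id", "cluster", "arm", "time", "event"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    time = pd.to_numeric(frame["time"], errors="coerce")
    bad = np.flatnonzero(~(time > 0) | time.isna())
    if bad.size:
        raise ValidationError(
            f"row {bad[0]}: time must be strictly positive, got "
            f"{frame['time'].iloc[bad[0]]!r}"
        )
    for col in ("arm", "event"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(~vals.isin([0, 1]))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: {col} must be 0 or 1, got {frame[col].iloc[bad[0]]!r}"
            )
    if frame["cluster"].nunique() < 2:
        raise ValidationError("dataset must contain at least 2 clusters")
    arms = set(pd.to_numeric(frame["arm"]))
    if arms != {0, 1}:
        # Single-arm data is usable for summaries but not for TTB modelling;
        # flagged here and in DatasetSummary.missing_arms rather than fatal.
        warnings.warn(
            f"pooled data does not contain both arms (found {sorted(arms)})",
            UserWarning,
            stacklevel=3,
        )


def read_survival_table(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> ClusteredSurvivalData:
    """Read a delimited survival table and validate it.

    ``column_map`` maps canonical names (``id, cluster, arm, time, event``)
    to the file's column names; unmapped names are used verbatim.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    frame = pd.DataFrame({canon: raw[src] for canon, src in cmap.items()})
    return ClusteredSurvivalData(frame)


def write_survival_table(data: ClusteredSurvivalData, path, sep: str = ",") -> None:
    data.frame.to_csv(path, sep=sep, index=False)


def summarize(data: ClusteredSurvivalData) -> DatasetSummary:
    """Arm-level counts, censoring proportions and follow-up range.

    Censoring proportion in an arm is (# event=0 in arm) / (# in arm);
    an arm absent from the data is flagged in ``missing_arms`` and its
    censoring proportion reported as None.
    """
    n_per_arm: dict[int, int] = {}
    cens: dict[int, float | None] = {}
    events: dict[int, int] = {}
    missing = []
    for a in (0, 1):
        mask = data.arm == a
        n = int(mask.sum())
        n_per_arm[a] = n
        if n == 0:
            missing.append(a)
            cens[a] = None
            events[a] = 0
        else:
            events[a] = int(data.event[mask].sum())
            cens[a] = float((data.event[mask] == 0).mean())
    return DatasetSummary(
        n_subjects=data.n_subjects,
        n_clusters=data.n_clusters,
        n_per_arm=n_per_arm,
        censoring_per_arm=cens,
        events_per_arm=events,
        follow_up_range=(float(data.time.min()), float(data.time.max())),
        missing_arms=missing,
    )
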