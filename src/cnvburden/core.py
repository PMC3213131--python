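"""Core domain containers: probe design, intensity/z tracks, samples, calls."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "COHORTS",
    "CNV_TYPES",
    "ProbeDesign",
    "IntensityTrack",
    "ZTrack",
    "CNVCall",
    "validate_sample_meta",
    "calls_to_frame",
    "frame_to_calls",
]

#: Closed cohort vocabulary, ordered by phenotypic severity (most severe last).
COHORTS = ("control", "dyslexia", "autism_no_ID", "autism_ID", "ID", "ID_MCA")

#: Closed CNV type vocabulary.  "homozyg deletion" in published tables maps to
#: ``homozygous_deletion``.
CNV_TYPES = ("deletion", "duplication", "homozygous_deletion")

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "design_class"]


class ProbeDesign:
    """An ordered array design: probes with a hotspot/backbone class.

    Wraps a DataFrame with columns ``chrom, start, end, probe_id,
    design_class`` sorted by (chromosome order, start).  Probe order is the
    coordinate scaffold every track and call refers back to.
    """

    def __init__(self, frame: pd.DataFrame, chrom_order: Optional[list[str]] = None):
        missing = [c for c in PROBE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"probe design missing columns: {missing}")
        frame = frame[PROBE_COLUMNS].copy()
        if frame["probe_id"].duplicated().any():
            dupes = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids: {dupes[:5]}")
        bad = frame["start"] >= frame["end"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} probes with start >= end")
        unknown = set(frame["design_class"]) - {"hotspot", "backbone"}
        if unknown:
            raise ValueError(f"unknown design classes: {sorted(unknown)}")
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(frame["chrom"]))
        order = {c: i for i, c in enumerate(chrom_order)}
        frame["_c"] = frame["chrom"].map(order)
        if frame["_c"].isna().any():
            raise ValueError("probes on chromosomes absent from chrom_order")
        frame = frame.sort_values(["_c", "start"], kind="stable").drop(columns="_c")
        frame = frame.reset_index(drop=True)
        self.frame = frame
        self.chrom_order = chrom_order
        self.chrom = frame["chrom"].to_numpy()
        self.start = frame["start"].to_numpy(dtype=np.int64)
        self.end = frame["end"].to_numpy(dtype=np.int64)
        self.design_class = frame["design_class"].to_numpy()
        # contiguous index slice per chromosome
        self._slices: dict[str, slice] = {}
        for c in chrom_order:
            idx = np.flatnonzero(self.chrom == c)
            if idx.size:
                self._slices[c] = slice(int(idx[0]), int(idx[-1]) + 1)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def probe_ids(self) -> pd.Series:
        return self.frame["probe_id"]

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices.get(chrom, slice(0, 0))

    def chromosomes(self) -> list[str]:
        return [c for c in self.chrom_order if c in self._slices]

    def probes_in(self, iv: GenomicInterval) -> np.ndarray:
        """Indices of probes whose midpoint lies inside ``iv``."""
        sl = self.chrom_slice(iv.chrom)
        mid = (self.start[sl] + self.end[sl]) // 2
        local = np.flatnonzero((mid >= iv.start) & (mid < iv.end))
        return local + sl.start


@dataclass
class IntensityTrack:
    """Per-sample normalized log2 intensity ratios, aligned to a ProbeDesign.

    Missing measurements are NaN, never silently 0.
    """

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("intensity values must be a 1-D array")


@dataclass
class ZTrack:
    """Chromosome-normalized z-scores with the (mu, sigma) used per chromosome."""

    sample_id: str
    z: np.ndarray
    chrom_stats: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class CNVCall:
    """A segmented, filtered copy-number variant for one sample."""

    sample_id: str
    interval: GenomicInterval
    type: str  # member of CNV_TYPES
    n_probes: int
    mean_z: float
    hotspot_class: str = ""  # HS / HS_assoc / non_HS, filled by annotation/QC
    qc_pass: bool = True
    reject_reason: str = ""

    def __post_init__(self) -> None:
        if self.type not in CNV_TYPES:
            raise ValueError(f"unknown CNV type {self.type!r}")
        if self.n_probes < 1:
            raise ValueError("a call must be supported by at least one probe")

    @property
    def size(self) -> int:
        return self.interval.size


CALL_COLUMNS = [
    "sample_id", "chrom", "start", "end", "size", "type",
    "n_probes", "mean_z", "hotspot_class", "qc_pass", "reject_reason",
]


def calls_to_frame(calls: Iterable[CNVCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "size": c.size,
            "type": c.type,
            "n_probes": c.n_probes,
            "mean_z": c.mean_z,
            "hotspot_class": c.hotspot_class,
            "qc_pass": c.qc_pass,
            "reject_reason": c.reject_reason,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def frame_to_calls(frame: pd.DataFrame) -> list[CNVCall]:
    calls = []
    for row in frame.itertuples(index=False):
        calls.append(
            CNVCall(
                sample_id=str(row.sample_id),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                type=str(row.type),
                n_probes=int(row.n_probes),
                mean_z=float(row.mean_z),
                hotspot_class=str(getattr(row, "hotspot_class", "") or ""),
                qc_pass=bool(getattr(row, "qc_pass", True)),
                reject_reason=str(getattr(row, "reject_reason", "") or ""),
            )
        )
    return calls


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table (sample_id, cohort, parents, QC).

    Parent ids, when present, must reference rows of the table; cohort labels
    must come from the closed vocabulary.  Returns the validated frame with
    NaN parent ids normalized to empty strings.
    """
    required = ["sample_id", "cohort"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"sample meta missing columns: {missing}")
    meta = meta.copy()
    for col in ("father_id", "mother_id"):
        if col not in meta.columns:
            meta[col] = ""
        meta[col] = meta[col].fillna("").astype(str)
    if "qc_status" not in meta.columns:
        meta["qc_status"] = "untested"
    bad_cohort = set(meta["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise ValueError(f"unknown cohort labels: {sorted(bad_cohort)}")
    bad_qc = set(meta["qc_status"]) - {"pass", "fail", "untested"}
    if bad_qc:
        raise ValueError(f"unknown qc_status values: {sorted(bad_qc)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    ids = set(meta["sample_id"].astype(str))
    for col in ("father_id", "mother_id"):
        referenced = set(meta.loc[meta[col] != "", col])
        orphans = referenced - ids
        if orphans:
            raise ValueError(f"{col} references unknown samples: {sorted(orphans)[:5]}")
    return meta
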