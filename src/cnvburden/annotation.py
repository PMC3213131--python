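"""Call annotation: hotspot class, rarity vs a control map, genes, disorders,
trio inheritance.

Rarity is defined against a frequency-annotated control CNV map: a call
matches a map event when both are the same CNV type and each covers at
least 50% of the other (reciprocal overlap).  A call is *strictly rare*
when its summed control match count is zero, and *relaxed rare* when the
control frequency is strictly below 0.1% — with 8,635 map controls, up to
8 carriers still count as rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import validate_sample_meta
from .intervals import GenomeLayout, GenomicInterval, classify_hotspot, reciprocal_overlap

__all__ = [
    "ControlCNVMap",
    "count_control_matches",
    "rarity_filter",
    "annotate_genes",
    "match_genomic_disorder",
    "classify_inheritance",
    "annotate_calls",
]

#: deletion-family types are mutually compatible when matching events
_TYPE_FAMILY = {
    "deletion": "deletion",
    "homozygous_deletion": "deletion",
    "duplication": "duplication",
}


@dataclass
class ControlCNVMap:
    """Control CNV intervals with per-event carrier counts.

    ``events`` columns: chrom, start, end, type, count; ``n_controls`` is
    the number of control individuals behind the map (8,635 in the study
    design this models).
    """

    events: pd.DataFrame
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls <= 0:
            raise ValueError("n_controls must be positive")
        need = {"chrom", "start", "end", "type", "count"}
        missing = need - set(self.events.columns)
        if missing:
            raise ValueError(f"control map missing columns: {sorted(missing)}")
        if len(self.events):
            counts = self.events["count"]
            if (counts < 0).any() or (counts > self.n_controls).any():
                raise ValueError("control counts must lie in [0, n_controls]")
        self.events = self.events.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.events)


def _row_interval(row) -> GenomicInterval:
    return GenomicInterval(str(row.chrom), int(row.start), int(row.end))


def count_control_matches(
    iv: GenomicInterval,
    cnv_type: str,
    cmap: ControlCNVMap,
    fraction: float = 0.5,
    type_blind: bool = False,
) -> int:
    """Summed control count of map events reciprocally overlapping the call.

    A map event matches when the reciprocal overlap is >= ``fraction`` in
    both directions and (unless ``type_blind``) its type family matches the
    call's (homozygous deletions match deletions).
    """
    total = 0
    fam = _TYPE_FAMILY.get(cnv_type, cnv_type)
    for row in cmap.events.itertuples(index=False):
        if str(row.chrom) != iv.chrom:
            continue
        if not type_blind and _TYPE_FAMILY.get(str(row.type), str(row.type)) != fam:
            continue
        fa, fb = reciprocal_overlap(iv, _row_interval(row))
        if fa >= fraction and fb >= fraction:
            total += int(row.count)
    return total


def rarity_filter(
    annotated: pd.DataFrame, mode: str, config: Optional[AnalysisConfig] = None
) -> pd.DataFrame:
    """Subset an annotated call table to rare calls.

    ``strict`` keeps calls with zero control matches; ``relaxed`` keeps
    calls with control frequency strictly below ``config.rare_freq``
    (default <0.1%).  Requires a ``control_count`` column.
    """
    config = config or AnalysisConfig()
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown rarity mode {mode!r}")
    counts = annotated["control_count"].to_numpy(dtype=float)
    if mode == "strict":
        keep = counts == 0
    else:
        keep = counts / config.n_controls < config.rare_freq
    return annotated.loc[keep].reset_index(drop=True)


def annotate_genes(iv: GenomicInterval, genes: pd.DataFrame) -> tuple[int, bool]:
    """(number of genes overlapped by >=1 bp, does the call break a gene).

    A call "breaks" a gene when either breakpoint coordinate falls strictly
    inside a gene interval.
    """
    count = 0
    breaks = False
    for row in genes.itertuples(index=False):
        if str(row.chrom) != iv.chrom:
            continue
        g = _row_interval(row)
        if iv.start < g.end and g.start < iv.end:
            count += 1
        if g.contains_point(iv.start) or g.contains_point(iv.end):
            breaks = True
    return count, breaks


def match_genomic_disorder(
    iv: GenomicInterval, disorders: pd.DataFrame, fraction: float = 0.5
) -> str:
    """Label of the best genomic-disorder region match, or "".

    A region qualifies at reciprocal overlap >= ``fraction`` both ways;
    among qualifying regions the one with the larger overlapped span wins
    (deterministic tie-break by table order).  The region table needs
    columns chrom/start/end/label.
    """
    best_label = ""
    best_ov = -1
    for row in disorders.itertuples(index=False):
        if str(row.chrom) != iv.chrom:
            continue
        region = _row_interval(row)
        fa, fb = reciprocal_overlap(iv, region)
        if fa >= fraction and fb >= fraction:
            ov = min(iv.end, region.end) - max(iv.start, region.start)
            if ov > best_ov:
                best_ov = ov
                best_label = str(row.label)
    return best_label


def _matches_in(
    iv: GenomicInterval, cnv_type: str, calls: pd.DataFrame, fraction: float
) -> bool:
    fam = _TYPE_FAMILY.get(cnv_type, cnv_type)
    for row in calls.itertuples(index=False):
        if str(row.chrom) != iv.chrom:
            continue
        if _TYPE_FAMILY.get(str(row.type), str(row.type)) != fam:
            continue
        fa, fb = reciprocal_overlap(iv, _row_interval(row))
        if fa >= fraction and fb >= fraction:
            return True
    return False


def classify_inheritance(
    proband_calls: pd.DataFrame,
    father_calls: Optional[pd.DataFrame],
    mother_calls: Optional[pd.DataFrame],
    fraction: float = 0.5,
) -> list[str]:
    """Inheritance label per proband call: de_novo/maternal/paternal/both/NA.

    A parent "carries" the call when the parent has a same-type-family call
    with reciprocal overlap >= ``fraction``.  With both parents genotyped:
    neither carries -> de_novo; exactly one -> that parent; both -> both.
    With one genotyped parent the sole parent's match gives its label,
    otherwise NA (a non-matching single parent cannot exclude transmission
    from the missing one).  With no parents: NA.
    """
    labels = []
    for row in proband_calls.itertuples(index=False):
        iv = _row_interval(row)
        in_fa = father_calls is not None and _matches_in(iv, str(row.type), father_calls, fraction)
        in_mo = mother_calls is not None and _matches_in(iv, str(row.type), mother_calls, fraction)
        if father_calls is not None and mother_calls is not None:
            if in_fa and in_mo:
                labels.append("both")
            elif in_fa:
                labels.append("paternal")
            elif in_mo:
                labels.append("maternal")
            else:
                labels.append("de_novo")
        elif father_calls is not None:
            labels.append("paternal" if in_fa else "NA")
        elif mother_calls is not None:
            labels.append("maternal" if in_mo else "NA")
        else:
            labels.append("NA")
    return labels


def annotate_calls(
    calls: pd.DataFrame,
    cmap: Optional[ControlCNVMap] = None,
    genes: Optional[pd.DataFrame] = None,
    disorders: Optional[pd.DataFrame] = None,
    meta: Optional[pd.DataFrame] = None,
    layout: Optional[GenomeLayout] = None,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Add every annotation column to a QC-passed call table.

    Columns added: ``hotspot_class`` (if a layout is given), ``control_count``,
    ``rare_strict``, ``rare_relaxed``, ``gene_count``, ``breaks_gene``,
    ``genomic_disorder``, ``inheritance``, ``parents_available``.
    Annotation is row-wise and therefore order-independent.
    """
    config = config or AnalysisConfig()
    fraction = config.reciprocal_overlap_fraction
    out = calls.copy().reset_index(drop=True)
    ivs = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in out.itertuples(index=False)
    ]
    types = out["type"].astype(str).tolist()

    if layout is not None:
        out["hotspot_class"] = [classify_hotspot(iv, layout, fraction) for iv in ivs]

    if cmap is not None:
        out["control_count"] = [
            count_control_matches(iv, t, cmap, fraction) for iv, t in zip(ivs, types)
        ]
        freq = out["control_count"] / cmap.n_controls
        out["rare_strict"] = out["control_count"] == 0
        out["rare_relaxed"] = freq < config.rare_freq

    if genes is not None:
        ann = [annotate_genes(iv, genes) for iv in ivs]
        out["gene_count"] = [a[0] for a in ann]
        out["breaks_gene"] = [a[1] for a in ann]

    if disorders is not None:
        out["genomic_disorder"] = [match_genomic_disorder(iv, disorders, fraction) for iv in ivs]

    if meta is not None:
        meta = validate_sample_meta(meta.copy())
        parents = meta.set_index("sample_id")[["father_id", "mother_id"]]
        by_sample = {sid: grp for sid, grp in out.groupby("sample_id")}
        inheritance = pd.Series("NA", index=out.index, dtype=object)
        avail = pd.Series("none", index=out.index, dtype=object)
        for sid, grp in by_sample.items():
            if sid not in parents.index:
                continue
            fa, mo = parents.loc[sid, "father_id"], parents.loc[sid, "mother_id"]
            fa_calls = by_sample.get(fa, out.iloc[0:0]) if fa else None
            mo_calls = by_sample.get(mo, out.iloc[0:0]) if mo else None
            labels = classify_inheritance(grp, fa_calls, mo_calls, fraction)
            inheritance.loc[grp.index] = labels
            avail.loc[grp.index] = (
                "both" if (fa and mo) else ("father" if fa else ("mother" if mo else "none"))
            )
        out["inheritance"] = inheritance
        out["parents_available"] = avail

    return out
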