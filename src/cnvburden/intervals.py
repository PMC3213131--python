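"""Genomic interval algebra and the genome layout (hotspot map).

Coordinates are 0-based, half-open throughout the package: an interval
``(chrom, start, end)`` covers the bases ``start .. end-1`` and has size
``end - start``.  Published call tables that use 1-based starts are
ingested through an explicit dialect flag in :mod:`cnvburden.io`, which
shifts the start by one and leaves the printed size intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "interval_size",
    "overlap_bp",
    "reciprocal_overlap",
    "normalize_intervals",
    "classify_hotspot",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome identifier (e.g. ``"chr7"``).
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        """True iff ``pos`` lies strictly inside the interval body.

        "Strictly inside" means ``start < pos < end``: a breakpoint landing
        exactly on an interval boundary does not traverse it.
        """
        return self.start < pos < self.end


def interval_size(iv: GenomicInterval) -> int:
    """Size of an interval in bp (``end - start``)."""
    return iv.size


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap of two intervals as a fraction of each interval's length.

    Returns ``(overlap/size(a), overlap/size(b))``; both are 0.0 when the
    intervals are disjoint or on different chromosomes.  Two intervals
    "reciprocally overlap at fraction f" when both returned values are >= f.
    """
    ov = overlap_bp(a, b)
    return ov / a.size, ov / b.size


def normalize_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent (start, end) pairs. Idempotent."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GenomeLayout:
    """Chromosome scaffold plus the hotspot map.

    Hotspots are regions flanked by high-identity segmental duplications and
    prone to recurrent rearrangement; the probe design oversamples them.  The
    ``flanks`` intervals are short segmental-duplication proxies bordering
    each hotspot, used to classify "hotspot-associated" calls whose
    breakpoints land in the flanking repeats.

    Attributes
    ----------
    chromosomes : list of str
        Ordered chromosome names.
    lengths : dict
        Chromosome name -> length in bp (> 0).
    hotspots : dict
        Chromosome name -> sorted, non-overlapping (start, end) pairs.
    flanks : dict
        Chromosome name -> sorted (start, end) pairs flanking the hotspots.
    """

    chromosomes: list[str]
    lengths: dict[str, int]
    hotspots: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    flanks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            if self.lengths.get(chrom, 0) <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for name, table in (("hotspot", self.hotspots), ("flank", self.flanks)):
            for chrom, ivs in table.items():
                if chrom not in self.lengths:
                    raise ValueError(f"{name} intervals on unknown chromosome {chrom}")
                norm = normalize_intervals(ivs)
                for s, e in norm:
                    if s < 0 or e > self.lengths[chrom]:
                        raise ValueError(
                            f"{name} interval {chrom}:{s}-{e} outside chromosome"
                        )
                table[chrom] = norm

    @property
    def genome_size(self) -> int:
        return sum(self.lengths[c] for c in self.chromosomes)

    @property
    def hotspot_size(self) -> int:
        return sum(e - s for ivs in self.hotspots.values() for s, e in ivs)

    def hotspot_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(chrom, s, e)
            for chrom in self.chromosomes
            for s, e in self.hotspots.get(chrom, [])
        ]

    def in_hotspot(self, chrom: str, pos: int) -> bool:
        return _point_in(self.hotspots.get(chrom, []), pos)

    def in_flank(self, chrom: str, pos: int) -> bool:
        return _point_in(self.flanks.get(chrom, []), pos)

    def hotspot_overlap_bp(self, iv: GenomicInterval) -> int:
        total = 0
        for s, e in self.hotspots.get(iv.chrom, []):
            total += max(0, min(iv.end, e) - max(iv.start, s))
        return total


def _point_in(ivs: Sequence[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in ivs)


def classify_hotspot(
    iv: GenomicInterval, layout: GenomeLayout, fraction: float = 0.5
) -> str:
    """Three-way hotspot classification of a call.

    ``"HS"`` when hotspot sequence covers at least ``fraction`` of the call's
    length; otherwise ``"HS_assoc"`` when either breakpoint falls inside a
    hotspot or a segmental-duplication flank; otherwise ``"non_HS"``.
    """
    if layout.hotspot_overlap_bp(iv) >= fraction * iv.size:
        return "HS"
    for pos in (iv.start, iv.end):
        if layout.in_hotspot(iv.chrom, pos) or layout.in_flank(iv.chrom, pos):
            return "HS_assoc"
    return "non_HS"
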