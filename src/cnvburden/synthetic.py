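"""Synthetic hotspot-array data: layouts, probe designs, cohorts, intensities.

This module emulates the statistical structure a hotspot-enriched aCGH
CNV-burden study assumes, so the whole calling/annotation/burden pipeline is
testable without raw arrays:

* a scaled-down genome whose hotspot regions cover ~8% of sequence
  (mirroring ~251 Mbp of hotspot targets on a ~3.1 Gbp genome),
* probes at ~2.6 kbp spacing inside hotspots and ~36 kbp in the backbone,
* cohorts with planted rare CNVs whose carrier rates, size profiles,
  de novo fractions and two-hit rates follow the published per-cohort
  estimates, plus common copy-number polymorphisms drawn from the control
  map so rarity filtering has something to remove,
* Gaussian probe noise with per-chromosome baseline offsets (exercising the
  chromosome-specific z-score normalization),
* a frequency-annotated control CNV map with both common and
  rare-but-present (<0.1%) loci.

All randomness flows from one integer seed; sub-generators derive child
streams deterministically, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import COHORTS, IntensityTrack, ProbeDesign, calls_to_frame, CNVCall
from .intervals import GenomeLayout, GenomicInterval, reciprocal_overlap

__all__ = [
    "CohortSpec",
    "NoiseModel",
    "PlantedCNV",
    "TruthSet",
    "DEFAULT_COHORTS",
    "make_layout",
    "make_probe_design",
    "simulate_cohorts",
    "simulate_intensities",
    "simulate_control_map",
    "truth_to_calls",
]


@dataclass(frozen=True)
class CohortSpec:
    """Planted-CNV profile of one cohort.

    ``carrier_p`` is the probability a proband carries at least one rare
    planted CNV; ``two_hit_p`` is the conditional probability a carrier
    carries a second one.  Rare-CNV sizes are log-uniform on
    ``[size_min_bp, size_max_bp]`` (median = sqrt(min*max)).
    ``de_novo_fraction`` applies per planted rare CNV; inherited events are
    copied into one parent's truth.  ``common_cnv_rate`` is the Poisson mean
    of common polymorphisms per sample, drawn from control-map loci.
    ``trio_fraction`` is the share of probands with both parents sampled.
    """

    label: str
    n_samples: int
    carrier_p: float
    size_min_bp: float
    size_max_bp: float
    deletion_fraction: float = 0.5
    de_novo_fraction: float = 0.0
    two_hit_p: float = 0.0
    common_cnv_rate: float = 3.3
    trio_fraction: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.carrier_p, self.deletion_fraction, self.de_novo_fraction,
                  self.two_hit_p, self.trio_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1] in cohort {self.label}")
        if not 0 < self.size_min_bp <= self.size_max_bp:
            raise ValueError(f"bad size bounds in cohort {self.label}")
        if self.label not in COHORTS:
            raise ValueError(f"unknown cohort label {self.label!r}")


#: Study-condition defaults: cohort sizes are the published pass-QC counts;
#: carrier rates follow the per-cohort rare-CNV carrier fractions; size
#: ranges put the log-uniform median near each cohort's reported median rare
#: CNV size; de novo fractions and two-hit rates follow the reported
#: inheritance and multiple-hit estimates.  Trios cover 75% of case
#: probands (parental DNA resolved inheritance for ~3/4 of rare CNVs in the
#: emulated design) and no controls (control parents were unavailable).
DEFAULT_COHORTS: tuple[CohortSpec, ...] = (
    CohortSpec("control", 306, 0.020, 60e3, 1.5e6, 0.5, 0.0, 0.0, 3.3, 0.0),
    CohortSpec("dyslexia", 322, 0.019, 60e3, 1.5e6, 0.7, 0.0, 0.0, 3.3, 0.75),
    CohortSpec("autism_no_ID", 246, 0.102, 100e3, 3e6, 0.5, 0.40, 0.0, 3.3, 0.75),
    CohortSpec("autism_ID", 90, 0.111, 150e3, 6e6, 0.5, 0.40, 0.10, 3.3, 0.75),
    CohortSpec("ID", 358, 0.168, 100e3, 5e6, 0.5, 0.64, 0.067, 3.3, 0.75),
    CohortSpec("ID_MCA", 73, 0.123, 400e3, 1e7, 0.5, 0.64, 0.44, 3.3, 0.75),
)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian intensity model for single-copy changes on the log2 scale.

    A heterozygous deletion halves copy number (log2(1/2) = -1), a
    duplication adds one copy (log2(3/2) = +0.585); homozygous deletions are
    floored at -3 rather than -inf.  ``sigma`` is per-probe noise SD; ``tau``
    is the SD of a per-chromosome, per-sample baseline offset.
    """

    sigma: float = 0.15
    tau: float = 0.05
    m_del: float = -1.0
    m_dup: float = 0.585
    m_homdel: float = -3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau < 0:
            raise ValueError("sigma must be > 0 and tau >= 0")
        if not (self.m_homdel < self.m_del < 0 < self.m_dup):
            raise ValueError("state means must satisfy m_homdel < m_del < 0 < m_dup")

    def mean_for(self, cnv_type: str) -> float:
        return {
            "deletion": self.m_del,
            "duplication": self.m_dup,
            "homozygous_deletion": self.m_homdel,
        }[cnv_type]


@dataclass(frozen=True)
class PlantedCNV:
    interval: GenomicInterval
    type: str
    inheritance: str  # de_novo / maternal / paternal / NA
    rare: bool = True


@dataclass
class TruthSet:
    """Planted CNVs per sample id."""

    events: dict[str, list[PlantedCNV]] = field(default_factory=dict)

    def add(self, sample_id: str, cnv: PlantedCNV) -> None:
        self.events.setdefault(sample_id, []).append(cnv)

    def for_sample(self, sample_id: str) -> list[PlantedCNV]:
        return self.events.get(sample_id, [])


# ---------------------------------------------------------------------------
# Layout and probe design


def make_layout(
    seed: int,
    n_chromosomes: int = 4,
    chromosome_length_bp: int = 25_000_000,
    n_hotspots: int = 32,
    hotspot_size_range: tuple[int, int] = (200_000, 300_000),
    flank_bp: int = 20_000,
) -> GenomeLayout:
    """Build a scaled-down genome with non-overlapping hotspot regions.

    At the defaults the hotspot fraction is ~8% of the genome, matching the
    ~251 Mbp of hotspot targets on a ~3.1 Gbp genome.  Each hotspot gets a
    segmental-duplication proxy flank of ``flank_bp`` on each side.
    """
    if n_chromosomes <= 0 or chromosome_length_bp <= 0 or n_hotspots < 0:
        raise ValueError("counts and lengths must be positive")
    rng = np.random.default_rng([seed, 0xA])
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    lengths = {c: chromosome_length_bp for c in chroms}
    per_chrom = np.zeros(n_chromosomes, dtype=int)
    for i in range(n_hotspots):
        per_chrom[i % n_chromosomes] += 1
    hotspots: dict[str, list[tuple[int, int]]] = {}
    flanks: dict[str, list[tuple[int, int]]] = {}
    lo, hi = hotspot_size_range
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            hotspots[chrom], flanks[chrom] = [], []
            continue
        sizes = rng.integers(lo, hi + 1, size=k)
        pad = 2 * flank_bp
        free = chromosome_length_bp - int(sizes.sum()) - k * pad
        if free < 0:
            raise ValueError("hotspots do not fit on the chromosome")
        # distribute free space as k+1 random gaps (at least one backbone
        # probe-spacing worth, so hotspots stay separated)
        cuts = np.sort(rng.uniform(0, 1, size=k))
        gaps = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * free
        hs, fl = [], []
        pos = 0
        for size, gap in zip(sizes, gaps[:-1]):
            pos += int(gap) + flank_bp
            hs.append((pos, pos + int(size)))
            fl.append((pos - flank_bp, pos))
            fl.append((pos + int(size), pos + int(size) + flank_bp))
            pos += int(size) + flank_bp
        hotspots[chrom] = hs
        flanks[chrom] = fl
    return GenomeLayout(chromosomes=chroms, lengths=lengths, hotspots=hotspots, flanks=flanks)


def make_probe_design(
    layout: GenomeLayout,
    hotspot_spacing_bp: int = 2_600,
    backbone_spacing_bp: int = 36_000,
    seed: int = 0,
    probe_length_bp: int = 60,
    jitter: float = 0.25,
) -> ProbeDesign:
    """Tile the layout with jittered probes at class-specific spacing.

    Probe start-to-start spacing is uniform on ``spacing * (1 +/- jitter)``,
    so the median spacing matches the nominal value.  The default jitter
    keeps the maximum backbone spacing (45 kbp) below the 50 kbp
    segment-merge limit, as on the real design where backbone probes are
    denser than the merge radius.
    """
    if hotspot_spacing_bp <= 0 or backbone_spacing_bp <= 0:
        raise ValueError("spacings must be positive")
    rng = np.random.default_rng([seed, 0xB])
    rows = []
    pid = 0
    for chrom in layout.chromosomes:
        length = layout.lengths[chrom]
        hs = layout.hotspots.get(chrom, [])
        pos = int(rng.integers(0, max(1, backbone_spacing_bp // 2)))
        while pos + probe_length_bp <= length:
            in_hs = layout.in_hotspot(chrom, pos)
            rows.append(
                (chrom, pos, pos + probe_length_bp, f"P{pid:06d}",
                 "hotspot" if in_hs else "backbone")
            )
            pid += 1
            spacing = hotspot_spacing_bp if in_hs else backbone_spacing_bp
            step = spacing * rng.uniform(1.0 - jitter, 1.0 + jitter)
            nxt = pos + max(probe_length_bp, int(round(step)))
            # entering a hotspot: don't overshoot it at backbone stride
            if not in_hs:
                for s, e in hs:
                    if pos < s < nxt:
                        nxt = s
                        break
            pos = nxt
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "design_class"])
    return ProbeDesign(frame, chrom_order=list(layout.chromosomes))


# ---------------------------------------------------------------------------
# Cohorts, trios, planted truth


def _place_interval(
    rng: np.random.Generator,
    layout: GenomeLayout,
    size: int,
    hotspot_anchor: bool,
) -> GenomicInterval:
    chroms = layout.chromosomes
    if hotspot_anchor:
        hs = layout.hotspot_intervals()
        if hs:
            anchor = hs[rng.integers(0, len(hs))]
            chrom = anchor.chrom
            center = (anchor.start + anchor.end) // 2
            start = max(0, min(center - size // 2, layout.lengths[chrom] - size))
            return GenomicInterval(chrom, start, start + size)
    chrom = chroms[rng.integers(0, len(chroms))]
    limit = layout.lengths[chrom] - size
    if limit <= 0:  # CNV larger than the chromosome: clamp to full span
        return GenomicInterval(chrom, 0, layout.lengths[chrom])
    start = int(rng.integers(0, limit))
    return GenomicInterval(chrom, start, start + size)


def _overlaps_any(iv: GenomicInterval, existing: list[PlantedCNV]) -> bool:
    return any(
        e.interval.chrom == iv.chrom
        and iv.start < e.interval.end
        and e.interval.start < iv.end
        for e in existing
    )


def simulate_cohorts(
    layout: GenomeLayout,
    specs: Sequence[CohortSpec] = DEFAULT_COHORTS,
    seed: int = 0,
    control_map: Optional[pd.DataFrame] = None,
    de_novo_hotspot_weight: float = 0.5,
) -> tuple[pd.DataFrame, TruthSet]:
    """Draw cohorts with trios and a planted-CNV truth set.

    Carrier status is Bernoulli(``carrier_p``) per proband; carriers receive
    one rare CNV, plus a second with probability ``two_hit_p``.  Rare events
    are de novo with the cohort's ``de_novo_fraction`` (absent from both
    parents) or inherited (copied into one random parent's truth).  De novo
    events anchor at hotspot loci with probability
    ``de_novo_hotspot_weight``, echoing hotspot-mediated mutation.  Common
    polymorphisms (if a control map is given) are drawn per sample from the
    map's loci at rate ``common_cnv_rate`` and always inherited.

    Returns the sample metadata table (probands then parents) and the truth.
    """
    if not specs:
        raise ValueError("at least one cohort spec required")
    rng = np.random.default_rng([seed, 0xC])
    rows = []
    truth = TruthSet()
    common_loci: list[tuple[GenomicInterval, str]] = []
    common_weights: Optional[np.ndarray] = None
    if control_map is not None and len(control_map):
        common_loci = [
            (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), str(r.type))
            for r in control_map.itertuples(index=False)
        ]
        w = control_map["count"].to_numpy(dtype=float)
        common_weights = w / w.sum()

    for spec in specs:
        for i in range(spec.n_samples):
            sid = f"{spec.label}_{i:04d}"
            has_trio = rng.random() < spec.trio_fraction
            father = f"{sid}_fa" if has_trio else ""
            mother = f"{sid}_mo" if has_trio else ""
            rows.append((sid, spec.label, father, mother, "untested", "proband"))
            if has_trio:
                rows.append((father, spec.label, "", "", "untested", "father"))
                rows.append((mother, spec.label, "", "", "untested", "mother"))
            planted: list[PlantedCNV] = []
            # rare planted CNVs
            n_rare = 0
            if rng.random() < spec.carrier_p:
                n_rare = 1 + (rng.random() < spec.two_hit_p)
            for _ in range(n_rare):
                size = int(
                    np.exp(rng.uniform(np.log(spec.size_min_bp), np.log(spec.size_max_bp)))
                )
                de_novo = has_trio and rng.random() < spec.de_novo_fraction
                anchor_hs = de_novo and rng.random() < de_novo_hotspot_weight
                for _try in range(50):
                    iv = _place_interval(rng, layout, size, anchor_hs)
                    if not _overlaps_any(iv, planted):
                        break
                cnv_type = (
                    "deletion" if rng.random() < spec.deletion_fraction else "duplication"
                )
                if de_novo:
                    inheritance = "de_novo"
                elif has_trio:
                    inheritance = "maternal" if rng.random() < 0.5 else "paternal"
                else:
                    inheritance = "NA"
                planted.append(PlantedCNV(iv, cnv_type, inheritance, rare=True))
            # common polymorphisms from control-map loci
            if common_loci:
                for _ in range(rng.poisson(spec.common_cnv_rate)):
                    j = rng.choice(len(common_loci), p=common_weights)
                    iv, cnv_type = common_loci[j]
                    if _overlaps_any(iv, planted):
                        continue
                    if has_trio:
                        inheritance = "maternal" if rng.random() < 0.5 else "paternal"
                    else:
                        inheritance = "NA"
                    planted.append(PlantedCNV(iv, cnv_type, inheritance, rare=False))
            for cnv in planted:
                truth.add(sid, cnv)
                if cnv.inheritance == "maternal" and mother:
                    truth.add(mother, replace(cnv, inheritance="NA"))
                elif cnv.inheritance == "paternal" and father:
                    truth.add(father, replace(cnv, inheritance="NA"))

    meta = pd.DataFrame(
        rows, columns=["sample_id", "cohort", "father_id", "mother_id", "qc_status", "role"]
    )
    return meta, truth


# ---------------------------------------------------------------------------
# Intensities


def simulate_intensities(
    design: ProbeDesign,
    truth: TruthSet,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[IntensityTrack]:
    """Per-probe log2 ratios: state mean + chromosome offset + Gaussian noise.

    Probe values are ``Normal(m_state + delta_c, sigma)`` where ``delta_c ~
    Normal(0, tau)`` is fixed per chromosome per sample and ``m_state`` is 0
    outside planted CNVs.  Deterministic for a fixed seed and sample order.
    """
    if sample_ids is None:
        sample_ids = sorted(truth.events)
    tracks = []
    for k, sid in enumerate(sample_ids):
        rng = np.random.default_rng([seed, 0xD, k])
        values = rng.normal(0.0, noise.sigma, size=len(design))
        for chrom in design.chromosomes():
            delta = rng.normal(0.0, noise.tau) if noise.tau > 0 else 0.0
            values[design.chrom_slice(chrom)] += delta
        for cnv in truth.for_sample(sid):
            idx = design.probes_in(cnv.interval)
            values[idx] += noise.mean_for(cnv.type)
        tracks.append(IntensityTrack(sample_id=sid, values=values))
    return tracks


# ---------------------------------------------------------------------------
# Control CNV map


def simulate_control_map(
    layout: GenomeLayout,
    n_controls: int = 8_635,
    n_loci: int = 60,
    hotspot_fraction: float = 0.7,
    rare_fraction: float = 0.4,
    size_range_bp: tuple[int, int] = (50_000, 600_000),
    spectrum: Optional[Sequence[tuple[int, float]]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Frequency-annotated control CNV loci, preferentially in hotspots.

    By default a ``rare_fraction`` of loci carry 1-8 control individuals
    (frequency < 0.1% of 8,635 — rare-but-present) and the rest are common
    polymorphisms with counts log-uniform up to ~10% of controls.  An
    explicit ``spectrum`` of (count, weight) pairs overrides this; loci
    drawing count 0 are dropped.

    Returns (events frame with chrom/start/end/type/count, n_controls).
    """
    if n_controls <= 0:
        raise ValueError("n_controls must be positive")
    rng = np.random.default_rng([seed, 0xE])
    rows = []
    for i in range(n_loci):
        size = int(np.exp(rng.uniform(np.log(size_range_bp[0]), np.log(size_range_bp[1]))))
        iv = _place_interval(rng, layout, size, rng.random() < hotspot_fraction)
        cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
        if spectrum is not None:
            counts = np.array([c for c, _ in spectrum])
            weights = np.array([w for _, w in spectrum], dtype=float)
            count = int(counts[rng.choice(len(counts), p=weights / weights.sum())])
        elif rng.random() < rare_fraction:
            count = int(rng.integers(1, 9))
        else:
            hi = max(10, n_controls // 10)
            count = int(np.exp(rng.uniform(np.log(9), np.log(hi))))
        if count == 0:
            continue
        rows.append((iv.chrom, iv.start, iv.end, cnv_type, min(count, n_controls)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "count"])
    frame = frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return frame, n_controls


# ---------------------------------------------------------------------------
# Gene and genomic-disorder interval tables


def simulate_gene_table(
    layout: GenomeLayout,
    n_genes: int = 400,
    size_range_bp: tuple[int, int] = (5_000, 120_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene intervals with symbols (chrom/start/end/gene)."""
    rng = np.random.default_rng([seed, 0xF])
    rows = []
    for i in range(n_genes):
        size = int(rng.integers(size_range_bp[0], size_range_bp[1] + 1))
        iv = _place_interval(rng, layout, size, hotspot_anchor=False)
        rows.append((iv.chrom, iv.start, iv.end, f"GENE{i:04d}"))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_disorder_regions(layout: GenomeLayout, n_regions: int = 8, seed: int = 0) -> pd.DataFrame:
    """Label a subset of hotspot regions as known genomic-disorder sites.

    Genomic disorders are recurrent, hotspot-mediated rearrangement regions;
    the returned table (chrom/start/end/label) is an editable stand-in, not
    a faithful reference coordinate list.
    """
    rng = np.random.default_rng([seed, 0x10])
    hs = layout.hotspot_intervals()
    n = min(n_regions, len(hs))
    picks = rng.choice(len(hs), size=n, replace=False) if n else []
    rows = [
        (hs[j].chrom, hs[j].start, hs[j].end, f"GD_{hs[j].chrom}_{hs[j].start // 1000}k")
        for j in sorted(picks)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


# ---------------------------------------------------------------------------
# Truth -> calls (for testing downstream stages without segmentation)


def truth_to_calls(truth: TruthSet, mean_z: float = -5.0) -> pd.DataFrame:
    """Render the truth set as an idealized call table (perfect caller)."""
    calls = []
    for sid in sorted(truth.events):
        for cnv in truth.events[sid]:
            z = abs(mean_z) if cnv.type == "duplication" else -abs(mean_z)
            calls.append(
                CNVCall(
                    sample_id=sid,
                    interval=cnv.interval,
                    type=cnv.type,
                    n_probes=max(1, cnv.interval.size // 2_600),
                    mean_z=z,
                )
            )
    return calls_to_frame(calls)
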