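"""Log2-ratio tracks to QC-filtered CNV calls.

The calling procedure, applied independently per chromosome:

1. z-score transform of the normalized log2 ratios using chromosome-specific
   means and standard deviations;
2. three-state Gaussian HMM (decreased / normal / increased copy number),
   Viterbi-decoded on the probe-order sequence — inter-probe distance does
   not enter the decode;
3. consecutive same-state probes merge into segments when the inter-probe
   gap is strictly less than 50 kbp;
4. two same-state non-normal segments separated by an intervening run of at
   most 5 probes spanning at most 10 kbp merge (with the intervening
   probes) into one variant, iterated to a fixed point;
5. variants are kept only with |mean z| > 1.5, more than 10 supporting
   probes, size > 50 kbp, and — for non-hotspot variants — size above the
   non-hotspot minimum (300 kbp), reflecting the array's lower backbone
   probe density.  Rejected variants are retained with a reason code.

Deletion segments whose mean z falls below a configurable floor are
labelled homozygous deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import CNVCall, IntensityTrack, ProbeDesign, ZTrack
from .intervals import GenomeLayout, GenomicInterval, classify_hotspot

__all__ = [
    "STATES",
    "HMMParams",
    "Segment",
    "zscore_transform",
    "viterbi_decode",
    "assemble_segments",
    "bridge_segments",
    "qc_filter_calls",
    "sample_qc",
    "call_sample",
]

#: HMM state order: index 0 = decreased, 1 = normal, 2 = increased.
STATES = ("decreased", "normal", "increased")


@dataclass
class HMMParams:
    """Gaussian-emission three-state HMM on the z-score scale.

    Defaults: emission means (-3, 0, +2.5) with unit SDs — deletions sit
    deeper than duplications on the z scale because a single-copy loss is a
    larger relative intensity change than a single-copy gain; sticky
    self-transitions (0.999) with the off-diagonal mass split evenly; the
    initial distribution strongly favors the normal state.
    """

    means: tuple[float, float, float] = (-3.0, 0.0, 2.5)
    sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    transition: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.999, 0.0005, 0.0005],
                [0.0005, 0.999, 0.0005],
                [0.0005, 0.0005, 0.999],
            ]
        )
    )
    initial: tuple[float, float, float] = (0.001, 0.998, 0.001)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if any(sd <= 0 for sd in self.sds):
            raise ValueError("emission SDs must be positive")
        if not self.means[0] < self.means[1] < self.means[2]:
            raise ValueError("emission means must be ordered decreased < normal < increased")


@dataclass
class Segment:
    """A run of same-state probes on one chromosome."""

    state: str
    first: int  # probe index, inclusive
    last: int   # probe index, inclusive
    interval: GenomicInterval
    n_probes: int
    mean_z: float


class DegenerateChromosomeError(ValueError):
    pass


def zscore_transform(
    track: IntensityTrack, design: ProbeDesign, robust: bool = False
) -> ZTrack:
    """Chromosome-wise z-scores: z = (x - mu_c) / sigma_c (sample SD, ddof=1).

    mu_c and sigma_c are computed over all non-missing probes of the
    chromosome, CNV probes included; they are recorded in the returned
    track.  With ``robust=True`` the location/scale are median and
    MAD x 1.4826 instead, which keeps z-scores calibrated when a CNV spans
    a large share of a chromosome's probes (easy to hit on a hotspot-dense
    design, where one hotspot deletion can cover a sizeable probe
    fraction).  A chromosome with zero variance (or fewer than two usable
    probes) raises :class:`DegenerateChromosomeError` naming it.
    """
    if len(track.values) != len(design):
        raise ValueError(
            f"track {track.sample_id}: {len(track.values)} values for {len(design)} probes"
        )
    z = np.full(len(design), np.nan)
    stats: dict[str, tuple[float, float]] = {}
    for chrom in design.chromosomes():
        sl = design.chrom_slice(chrom)
        x = track.values[sl]
        ok = np.isfinite(x)
        if ok.sum() < 2:
            raise DegenerateChromosomeError(
                f"chromosome {chrom}: fewer than two usable probes"
            )
        if robust:
            mu = float(np.median(x[ok]))
            sigma = float(np.median(np.abs(x[ok] - mu)) * 1.4826)
        else:
            mu = float(np.mean(x[ok]))
            sigma = float(np.std(x[ok], ddof=1))
        if sigma == 0.0:
            raise DegenerateChromosomeError(
                f"chromosome {chrom}: zero variance (constant intensities)"
            )
        z[sl] = (x - mu) / sigma
        stats[chrom] = (mu, sigma)
    return ZTrack(sample_id=track.sample_id, z=z, chrom_stats=stats)


def _viterbi_1d(z: np.ndarray, params: HMMParams) -> np.ndarray:
    """Max-probability state path for one chromosome (log space)."""
    n = len(z)
    means = np.asarray(params.means)
    sds = np.asarray(params.sds)
    log_trans = np.log(np.maximum(params.transition, 1e-300))
    log_init = np.log(np.maximum(np.asarray(params.initial, dtype=float), 1e-300))
    # Gaussian log density; missing probes are uninformative (flat emission)
    obs = z[:, None]
    with np.errstate(invalid="ignore"):
        log_emit = -0.5 * ((obs - means) / sds) ** 2 - np.log(sds) - 0.5 * np.log(2 * np.pi)
    log_emit[~np.isfinite(z)] = 0.0
    delta = log_init + log_emit[0]
    back = np.zeros((n, 3), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_trans  # cand[i, j]: from i to j
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(3)] + log_emit[t]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def viterbi_decode(ztrack: ZTrack, design: ProbeDesign, params: Optional[HMMParams] = None) -> np.ndarray:
    """Per-probe state indices (0=decreased, 1=normal, 2=increased).

    Decoding runs independently per chromosome on the probe-order sequence.
    """
    params = params or HMMParams()
    states = np.ones(len(design), dtype=np.int8)
    for chrom in design.chromosomes():
        sl = design.chrom_slice(chrom)
        states[sl] = _viterbi_1d(ztrack.z[sl], params)
    return states


def assemble_segments(
    states: np.ndarray,
    ztrack: ZTrack,
    design: ProbeDesign,
    gap_bp: int = 50_000,
) -> list[Segment]:
    """Merge consecutive same-state probes into segments.

    Two consecutive probes of the same state join one segment iff the gap
    between them (next probe start - previous probe end) is strictly less
    than ``gap_bp``.  Normal-state segments are retained (bridging needs
    them).  Chromosome boundaries always break segments.
    """
    segments: list[Segment] = []
    for chrom in design.chromosomes():
        sl = design.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        if not len(idx):
            continue
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            gap = design.start[i] - design.end[prev]
            if states[i] != states[prev] or gap >= gap_bp:
                segments.append(_make_segment(run_start, prev, states, ztrack, design))
                run_start = i
            prev = i
        segments.append(_make_segment(run_start, prev, states, ztrack, design))
    return segments


def _make_segment(first: int, last: int, states: np.ndarray, ztrack: ZTrack, design: ProbeDesign) -> Segment:
    z = ztrack.z[first : last + 1]
    return Segment(
        state=STATES[int(states[first])],
        first=int(first),
        last=int(last),
        interval=GenomicInterval(
            str(design.chrom[first]), int(design.start[first]), int(design.end[last])
        ),
        n_probes=int(last - first + 1),
        mean_z=float(np.nanmean(z)),
    )


def bridge_segments(
    segments: Sequence[Segment],
    ztrack: ZTrack,
    design: ProbeDesign,
    max_probes: int = 5,
    max_gap_bp: int = 10_000,
) -> list[Segment]:
    """Join same-state non-normal segments across short intervening runs.

    Two non-normal segments of the same state merge — together with the
    intervening probes — when the intervening sequence contains at most
    ``max_probes`` probes AND spans at most ``max_gap_bp`` (distance between
    the flanking segments' probe boundaries).  Applied left-to-right until a
    fixed point; probe counts include intervening probes and mean z is
    recomputed over the merged range.  Normal segments are dropped from the
    returned variant list.
    """
    variants = [s for s in segments if s.state != "normal"]
    changed = True
    while changed:
        changed = False
        out: list[Segment] = []
        i = 0
        while i < len(variants):
            cur = variants[i]
            if out:
                prev = out[-1]
                same_chrom = prev.interval.chrom == cur.interval.chrom
                if same_chrom and prev.state == cur.state:
                    n_between = cur.first - prev.last - 1
                    span = design.start[cur.first] - design.end[prev.last]
                    if n_between <= max_probes and span <= max_gap_bp:
                        merged = Segment(
                            state=prev.state,
                            first=prev.first,
                            last=cur.last,
                            interval=GenomicInterval(
                                prev.interval.chrom, prev.interval.start, cur.interval.end
                            ),
                            n_probes=cur.last - prev.first + 1,
                            mean_z=float(np.nanmean(ztrack.z[prev.first : cur.last + 1])),
                        )
                        out[-1] = merged
                        changed = True
                        i += 1
                        continue
            out.append(cur)
            i += 1
        variants = out
    return variants


def _variant_type(seg: Segment, homozygous_z: float) -> str:
    if seg.state == "increased":
        return "duplication"
    if seg.mean_z < homozygous_z:
        return "homozygous_deletion"
    return "deletion"


def qc_filter_calls(
    variants: Sequence[Segment],
    sample_id: str,
    config: AnalysisConfig,
    layout: Optional[GenomeLayout] = None,
) -> list[CNVCall]:
    """Apply the post-HMM filters; rejected variants keep a reason code.

    A variant passes iff |mean z| > z_threshold AND probe count >
    min_probes AND size > the hotspot-class minimum AND — when classified
    non-hotspot against the layout — size > the non-hotspot minimum.  All
    comparisons strict.
    """
    calls: list[CNVCall] = []
    for seg in variants:
        reasons = []
        if not abs(seg.mean_z) > config.z_threshold:
            reasons.append("z")
        if not seg.n_probes > config.min_probes:
            reasons.append("probes")
        if not seg.interval.size > config.min_size_hotspot_bp:
            reasons.append("min_size")
        hotspot_class = ""
        if layout is not None:
            hotspot_class = classify_hotspot(
                seg.interval, layout, config.reciprocal_overlap_fraction
            )
            if hotspot_class == "non_HS" and not (
                seg.interval.size > config.min_size_non_hotspot_bp
            ):
                reasons.append("non_hs_size")
        calls.append(
            CNVCall(
                sample_id=sample_id,
                interval=seg.interval,
                type=_variant_type(seg, config.homozygous_z),
                n_probes=seg.n_probes,
                mean_z=seg.mean_z,
                hotspot_class=hotspot_class,
                qc_pass=not reasons,
                reject_reason=",".join(reasons),
            )
        )
    return calls


def sample_qc(
    track: IntensityTrack,
    n_raw_variants: int,
    config: AnalysisConfig,
    cohort_median_variants: Optional[float] = None,
) -> tuple[str, str]:
    """Per-sample QC stand-in: (status, reason).

    Fails iff the log2-ratio SD strictly exceeds ``sample_sd_ceiling`` (a
    noisy hybridization) or the raw variant count strictly exceeds
    ``sample_call_multiple`` times the cohort median (an artifact-riddled
    track).  The published criteria behind the study's ~89% pass rate are
    unstated; this explicit rule plays the same role.
    """
    x = track.values[np.isfinite(track.values)]
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sd > config.sample_sd_ceiling:
        return "fail", f"sd={sd:.3f}>{config.sample_sd_ceiling}"
    if cohort_median_variants is not None:
        limit = config.sample_call_multiple * cohort_median_variants
        if n_raw_variants > limit:
            return "fail", f"raw_calls={n_raw_variants}>{limit:.1f}"
    return "pass", ""


def call_sample(
    track: IntensityTrack,
    design: ProbeDesign,
    config: Optional[AnalysisConfig] = None,
    layout: Optional[GenomeLayout] = None,
    params: Optional[HMMParams] = None,
) -> list[CNVCall]:
    """Full per-sample pipeline: z-score, decode, assemble, bridge, filter."""
    config = config or AnalysisConfig()
    ztrack = zscore_transform(track, design, robust=config.robust_zscore)
    states = viterbi_decode(ztrack, design, params)
    segments = assemble_segments(states, ztrack, design, config.segment_gap_bp)
    variants = bridge_segments(
        segments, ztrack, design, config.bridge_max_probes, config.bridge_max_gap_bp
    )
    return qc_filter_calls(variants, track.sample_id, config, layout)
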