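"""Segmentation: z-scores, Viterbi, segment assembly, bridging, QC filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cnvburden.config import AnalysisConfig
from cnvburden.core import IntensityTrack, ProbeDesign, ZTrack
from cnvburden.intervals import GenomeLayout, GenomicInterval
from cnvburden.segmentation import (
    DegenerateChromosomeError,
    HMMParams,
    Segment,
    assemble_segments,
    bridge_segments,
    qc_filter_calls,
    sample_qc,
    viterbi_decode,
    zscore_transform,
)


def design_from_starts(starts_by_chrom, probe_len=10):
    rows = []
    pid = 0
    for chrom, starts in starts_by_chrom.items():
        for s in starts:
            rows.append((chrom, s, s + probe_len, f"p{pid}", "backbone"))
            pid += 1
    return ProbeDesign(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "design_class"])
    )


# ---------------------------------------------------------------------------
# z-score transform


def test_zscore_hand_example():
    design = design_from_starts({"c1": [0, 100, 200, 300]})
    z = zscore_transform(IntensityTrack("s", [0.0, 0.0, 0.0, 2.0]), design)
    np.testing.assert_allclose(z.z, [-0.5, -0.5, -0.5, 1.5])
    mu, sigma = z.chrom_stats["c1"]
    assert (mu, sigma) == (0.5, 1.0)


def test_zscore_constant_chromosome_errors():
    design = design_from_starts({"c1": [0, 100, 200]})
    with pytest.raises(DegenerateChromosomeError, match="c1"):
        zscore_transform(IntensityTrack("s", [0.3, 0.3, 0.3]), design)


def test_zscore_location_invariance(rng):
    design = design_from_starts({"c1": list(range(0, 5_000, 100)),
                                 "c2": list(range(0, 5_000, 100))})
    x = rng.normal(size=len(design))
    base = zscore_transform(IntensityTrack("s", x), design)
    shifted = x.copy()
    shifted[design.chrom_slice("c2")] += 0.7
    after = zscore_transform(IntensityTrack("s", shifted), design)
    np.testing.assert_allclose(base.z, after.z, atol=1e-12)


def test_zscore_normalization_invariant(tiny_design, rng):
    """Per chromosome the fitted z has mean ~0 and SD ~1."""
    z = zscore_transform(IntensityTrack("s", rng.normal(0.1, 0.2, len(tiny_design))),
                         tiny_design)
    for chrom in tiny_design.chromosomes():
        zz = z.z[tiny_design.chrom_slice(chrom)]
        assert abs(zz.mean()) < 1e-9
        assert abs(zz.std(ddof=1) - 1.0) < 1e-9


def test_robust_zscore_resists_large_events(rng):
    """Median/MAD normalization keeps an event covering a third of a
    chromosome's probes at deep |z|; mean/SD normalization dilutes it."""
    design = design_from_starts({"c1": list(range(0, 90_000, 100))})
    x = rng.normal(0, 0.15, len(design))
    x[:300] -= 1.0  # deletion over a third of the probes
    track = IntensityTrack("s", x)
    naive = zscore_transform(track, design)
    robust = zscore_transform(track, design, robust=True)
    assert abs(np.mean(robust.z[:300])) > 1.5 * abs(np.mean(naive.z[:300]))
    assert np.mean(robust.z[:300]) < -2  # well past the |z| > 1.5 filter


# ---------------------------------------------------------------------------
# Viterbi


def brute_force_viterbi(z, params):
    """Exhaustive max-probability path over all 3^n state sequences."""
    means, sds = np.asarray(params.means), np.asarray(params.sds)
    lt = np.log(params.transition)
    li = np.log(np.asarray(params.initial))

    def logp(path):
        lp = li[path[0]]
        for t, s in enumerate(path):
            lp += -0.5 * ((z[t] - means[s]) / sds[s]) ** 2 - np.log(sds[s])
            if t:
                lp += lt[path[t - 1], s]
        return lp

    return max(itertools.product(range(3), repeat=len(z)), key=logp)


def test_viterbi_all_zero_is_all_normal():
    design = design_from_starts({"c1": list(range(0, 2_000, 100))})
    zt = ZTrack("s", np.zeros(len(design)))
    assert (viterbi_decode(zt, design) == 1).all()


def test_viterbi_matches_brute_force_on_short_sequences(rng):
    params = HMMParams()
    for _ in range(60):
        n = int(rng.integers(1, 9))
        z = rng.normal(0, 3, size=n)
        design = design_from_starts({"c1": list(range(0, n * 100, 100))})
        got = tuple(viterbi_decode(ZTrack("s", z), design, params))
        assert got == brute_force_viterbi(z, params)


def test_viterbi_recovers_embedded_deletion_run(rng):
    n = 200
    z = rng.normal(0, 1, size=n)
    z[80:110] = -4.0
    design = design_from_starts({"c1": list(range(0, n * 100, 100))})
    states = viterbi_decode(ZTrack("s", z), design)
    assert (states[80:110] == 0).all()
    assert (states[:80] != 0).all() and (states[110:] != 0).all()


# ---------------------------------------------------------------------------
# Segment assembly and bridging


def _z(design, fill=-4.0):
    return ZTrack("s", np.full(len(design), fill))


def test_assemble_gap_strictly_below_limit_merges():
    design = design_from_starts({"c1": [0, 50_009]})  # gap = 50_009 - 10 = 49_999
    segs = assemble_segments(np.array([0, 0]), _z(design), design)
    assert len(segs) == 1 and segs[0].n_probes == 2


def test_assemble_gap_at_limit_splits():
    design = design_from_starts({"c1": [0, 50_010]})  # gap = exactly 50_000
    segs = assemble_segments(np.array([0, 0]), _z(design), design)
    assert len(segs) == 2


def test_assemble_alternating_states_one_segment_per_probe():
    design = design_from_starts({"c1": list(range(0, 600, 100))})
    states = np.array([0, 1, 0, 1, 0, 1])
    segs = assemble_segments(states, _z(design), design)
    assert len(segs) == 6
    assert all(s.n_probes == 1 for s in segs)


def test_assemble_chromosome_boundary_breaks_runs():
    design = design_from_starts({"c1": [0, 100], "c2": [0, 100]})
    segs = assemble_segments(np.zeros(4, dtype=int), _z(design), design)
    assert [s.interval.chrom for s in segs] == ["c1", "c2"]


def _bridge_case(spacing, n_del1, n_normal, n_del2):
    n = n_del1 + n_normal + n_del2
    design = design_from_starts({"c1": [i * spacing for i in range(n)]})
    states = np.array([0] * n_del1 + [1] * n_normal + [0] * n_del2)
    z = ZTrack("s", np.where(states == 0, -4.0, 0.0))
    segs = assemble_segments(states, z, design)
    return bridge_segments(segs, z, design), design


def test_bridge_joins_across_short_normal_run():
    variants, _ = _bridge_case(spacing=2_000, n_del1=12, n_normal=4, n_del2=15)
    assert len(variants) == 1
    assert variants[0].n_probes == 31  # both segments plus intervening probes


def test_bridge_probe_bound_is_inclusive_at_five():
    variants, _ = _bridge_case(spacing=1_000, n_del1=12, n_normal=5, n_del2=15)
    assert len(variants) == 1 and variants[0].n_probes == 32


def test_bridge_refuses_six_intervening_probes():
    variants, _ = _bridge_case(spacing=1_000, n_del1=12, n_normal=6, n_del2=15)
    assert len(variants) == 2


def test_bridge_refuses_wide_span():
    # 3 intervening probes but the intervening sequence spans ~16 kbp
    variants, _ = _bridge_case(spacing=4_000, n_del1=12, n_normal=3, n_del2=15)
    assert len(variants) == 2


def test_bridge_never_joins_deletion_with_duplication():
    design = design_from_starts({"c1": [i * 1_000 for i in range(30)]})
    states = np.array([0] * 12 + [2] * 3 + [0] * 15)
    z = ZTrack("s", np.where(states == 0, -4.0, 3.0))
    variants = bridge_segments(assemble_segments(states, z, design), z, design)
    assert [v.state for v in variants] == ["decreased", "increased", "decreased"]


def test_bridge_iterates_to_fixed_point():
    # DEL(12) .. DEL(12) .. DEL(12) with bridgeable gaps: one variant out
    design = design_from_starts({"c1": [i * 1_000 for i in range(40)]})
    states = np.array([0] * 12 + [1] * 2 + [0] * 12 + [1] * 2 + [0] * 12)
    z = ZTrack("s", np.where(states == 0, -4.0, 0.0))
    variants = bridge_segments(assemble_segments(states, z, design), z, design)
    assert len(variants) == 1 and variants[0].n_probes == 40


# ---------------------------------------------------------------------------
# QC filters


def _segment(state="decreased", n_probes=20, size=60_000, mean_z=-3.0, start=100_000):
    return Segment(state=state, first=0, last=n_probes - 1,
                   interval=GenomicInterval("c1", start, start + size),
                   n_probes=n_probes, mean_z=mean_z)


def test_qc_rejects_exactly_ten_probes(config):
    (call,) = qc_filter_calls([_segment(n_probes=10)], "s", config)
    assert not call.qc_pass and "probes" in call.reject_reason


def test_qc_rejects_mean_z_at_threshold(config):
    (call,) = qc_filter_calls([_segment(state="increased", mean_z=1.5)], "s", config)
    assert not call.qc_pass and "z" in call.reject_reason


def test_qc_keeps_hotspot_deletion_above_all_thresholds(config):
    layout = GenomeLayout(["c1"], {"c1": 1_000_000},
                          hotspots={"c1": [(90_000, 200_000)]})
    (call,) = qc_filter_calls([_segment()], "s", config, layout)
    assert call.qc_pass and call.hotspot_class == "HS" and call.type == "deletion"


def test_qc_non_hotspot_needs_300kbp(config):
    layout = GenomeLayout(["c1"], {"c1": 10_000_000})
    (small,) = qc_filter_calls([_segment(size=200_000)], "s", config, layout)
    assert not small.qc_pass and "non_hs_size" in small.reject_reason
    (big,) = qc_filter_calls([_segment(size=400_000)], "s", config, layout)
    assert big.qc_pass


def test_qc_homozygous_deletion_label(config):
    (call,) = qc_filter_calls([_segment(mean_z=-8.5)], "s", config)
    assert call.type == "homozygous_deletion"


def test_qc_monotone_in_thresholds(rng, config):
    """Lowering the z or probe threshold never removes a passing call."""
    variants = [
        _segment(
            state="decreased" if rng.random() < 0.5 else "increased",
            n_probes=int(rng.integers(1, 40)),
            size=int(rng.integers(10_000, 500_000)),
            mean_z=float(rng.normal(0, 3)),
        )
        for _ in range(200)
    ]
    strict = {id(c) for c in variants
              if qc_filter_calls([c], "s", config)[0].qc_pass}
    loose_cfg = AnalysisConfig(z_threshold=0.5, min_probes=3)
    loose = {id(c) for c in variants
             if qc_filter_calls([c], "s", loose_cfg)[0].qc_pass}
    assert strict <= loose


# ---------------------------------------------------------------------------
# Sample QC


def test_sample_qc_clean_sample_passes(rng, config):
    track = IntensityTrack("s", rng.normal(0, 0.1, 2_000))
    assert sample_qc(track, 3, config, 3.0)[0] == "pass"


def test_sample_qc_noisy_sample_fails_on_sd(rng, config):
    track = IntensityTrack("s", rng.normal(0, 0.6, 2_000))
    status, reason = sample_qc(track, 3, config, 3.0)
    assert status == "fail" and reason.startswith("sd=")


def test_sample_qc_boundary_sd_passes(rng):
    x = rng.normal(0, 0.3, 500)
    cfg = AnalysisConfig(sample_sd_ceiling=float(np.std(x, ddof=1)))
    assert sample_qc(IntensityTrack("s", x), 0, cfg, None)[0] == "pass"


def test_sample_qc_excess_raw_calls_fail(rng, config):
    track = IntensityTrack("s", rng.normal(0, 0.1, 2_000))
    status, reason = sample_qc(track, 10, config, 3.0)
    assert status == "fail" and reason.startswith("raw_calls=")
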