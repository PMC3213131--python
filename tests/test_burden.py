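"""Burden statistics: Fisher/OR, survivor curves, cohort tests, power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cnvburden.burden import (
    ContingencyTable,
    bonferroni,
    cohort_summary,
    de_novo_test,
    fisher_or,
    haldane_anscombe_or,
    large_cnv_burden_test,
    largest_cnv_per_sample,
    median_rare_size,
    rare_carrier_test,
    sample_odds_ratio,
    size_histogram,
    survivor_curve,
    two_hit_test,
    two_proportion_power,
)
from cnvburden.study_tables import (
    carrier_table,
    de_novo_table,
    dyslexia_rare_calls,
    two_hit_table,
)


def fisher_p_enumeration(t: ContingencyTable) -> float:
    """Point-probability rule by exhaustive enumeration over fixed margins."""
    n1, k, N = t.a + t.b, t.a + t.c, t.a + t.b + t.c + t.d
    rv = stats.hypergeom(N, n1, k)
    lo, hi = max(0, k - (N - n1)), min(k, n1)
    probs = rv.pmf(np.arange(lo, hi + 1))
    p_obs = rv.pmf(t.a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


# ---------------------------------------------------------------------------
# Fisher / OR


def test_or_two_hit_table_is_11_2():
    res = fisher_or(ContingencyTable(4, 5, 4, 56))
    assert res.odds_ratio == pytest.approx(11.2)
    assert res.p_value == pytest.approx(0.008, abs=0.001)


def test_zero_cell_gives_infinite_or_and_published_p():
    res = fisher_or(ContingencyTable(30, 17, 0, 8))
    assert math.isinf(res.odds_ratio)
    assert res.p_value == pytest.approx(0.0009, abs=0.0001)


def test_symmetric_table_is_null():
    res = fisher_or(ContingencyTable(5, 5, 5, 5))
    assert res.odds_ratio == 1.0 and res.p_value == 1.0


def test_fisher_p_matches_enumeration_on_named_table():
    t = ContingencyTable(30, 17, 14, 21)
    assert fisher_or(t).p_value == pytest.approx(fisher_p_enumeration(t), rel=1e-9)


def test_fisher_p_matches_enumeration_random_tables(rng):
    for _ in range(300):
        cells = rng.integers(0, 16, size=4)
        t = ContingencyTable(*map(int, cells))
        if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
            continue
        assert fisher_or(t).p_value == pytest.approx(fisher_p_enumeration(t), rel=1e-9)


@settings(deadline=None, derandomize=True, max_examples=150)
@given(st.tuples(*[st.integers(0, 15)] * 4))
def test_fisher_p_matches_enumeration_property(cells):
    t = ContingencyTable(*cells)
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        return
    assert fisher_or(t).p_value == pytest.approx(fisher_p_enumeration(t), rel=1e-9)


def test_or_undefined_when_both_products_zero():
    assert math.isnan(sample_odds_ratio(ContingencyTable(0, 5, 0, 5)))


def test_or_invariances(rng):
    for _ in range(50):
        a, b, c, d = map(int, rng.integers(1, 30, size=4))
        t = ContingencyTable(a, b, c, d)
        swapped_both = ContingencyTable(d, c, b, a)  # swap rows and columns
        assert sample_odds_ratio(swapped_both) == pytest.approx(sample_odds_ratio(t))
        row_swap = ContingencyTable(c, d, a, b)
        assert sample_odds_ratio(row_swap) == pytest.approx(1 / sample_odds_ratio(t))


def test_haldane_anscombe_finite_on_zero_cell():
    assert np.isfinite(haldane_anscombe_or(ContingencyTable(30, 17, 0, 8)))


def test_bonferroni_caps_at_one():
    assert bonferroni([0.01, 0.4, 0.9]) == [0.03, 1.0, 1.0]


# ---------------------------------------------------------------------------
# Published contingency tables


@pytest.mark.parametrize(
    "table, printed_or",
    [
        (carrier_table("ID", "dyslexia"), 10),
        (carrier_table("ID", "autism"), 1.6),
        (carrier_table("autism", "dyslexia"), 6),
        (de_novo_table("ID", "autism"), 2.6),
        (two_hit_table("ID_MCA", "ID"), 11.2),
    ],
)
def test_published_tables_reproduce_printed_odds_ratios(table, printed_or):
    got = fisher_or(table).odds_ratio
    assert got == pytest.approx(printed_or, rel=0.03)


# ---------------------------------------------------------------------------
# Largest CNV / survivor curves


def _calls(rows):
    return pd.DataFrame(rows, columns=["sample_id", "size", "type", "qc_pass"])


def test_largest_cnv_per_sample_includes_zero_call_samples():
    calls = _calls([("s1", 120_000, "deletion", True),
                    ("s1", 1_600_000, "duplication", True),
                    ("s2", 90_000, "deletion", False)])
    maxima = largest_cnv_per_sample(calls, ["s1", "s2", "s3"])
    assert maxima.tolist() == [1_600_000, 0, 0]  # s2's call failed QC


def test_largest_cnv_order_invariant(rng):
    rows = [(f"s{rng.integers(5)}", int(rng.integers(1, 10**6)), "deletion", True)
            for _ in range(60)]
    ids = sorted({r[0] for r in rows})
    a = largest_cnv_per_sample(_calls(rows), ids)
    b = largest_cnv_per_sample(_calls(list(reversed(rows))), ids)
    assert a.equals(b)


def test_survivor_curve_single_sample():
    maxima = {"c": pd.Series([1_000_000])}
    curve = survivor_curve(maxima, [500_000, 1_000_000, 2_000_000])
    np.testing.assert_allclose(curve.fractions["c"], [1.0, 1.0, 0.0])


def test_survivor_curve_matches_counting_and_monotone(rng):
    vals = pd.Series(rng.integers(0, 3_000_000, size=100))
    grid = np.sort(rng.integers(0, 3_000_000, size=10))
    curve = survivor_curve({"c": vals}, grid)
    fr = curve.fractions["c"]
    for g, f in zip(grid, fr):
        assert f == (vals >= g).sum() / len(vals)
    assert (np.diff(fr) <= 0).all()
    assert curve.fractions["c"][0] <= 1.0


def test_survivor_curve_empty_cohort_errors():
    with pytest.raises(ValueError):
        survivor_curve({"c": pd.Series([], dtype=int)}, [0])


def test_large_burden_threshold_is_strict():
    a = pd.Series([1_000_000] * 10)  # exactly 1 Mbp: not a carrier
    b = pd.Series([1_000_001] * 10)
    res = large_cnv_burden_test(a, b)
    assert res.table.a == 0 and res.table.c == 10


def test_large_burden_detects_planted_difference(rng):
    n = 400
    a = pd.Series(np.where(rng.random(n) < 0.25, 2_000_000, 100_000))
    b = pd.Series(np.where(rng.random(n) < 0.02, 2_000_000, 100_000))
    res = large_cnv_burden_test(a, b)
    assert res.odds_ratio > 5 and res.p_value < 1e-6


# ---------------------------------------------------------------------------
# Cohort-level tests on constructed annotated tables


def _cohort_fixture():
    meta_rows, call_rows = [], []
    # cohort A: 40 samples, 10 rare carriers (4 with two hits); B: 40, 2 carriers
    for i in range(40):
        meta_rows.append((f"a{i}", "ID", "", "", "untested"))
        meta_rows.append((f"b{i}", "dyslexia", "", "", "untested"))
    for i in range(10):
        call_rows.append((f"a{i}", 500_000, "deletion", True, True, "de_novo"))
    for i in range(4):
        call_rows.append((f"a{i}", 300_000, "duplication", True, True, "maternal"))
    for i in range(2):
        call_rows.append((f"b{i}", 400_000, "deletion", True, True, "paternal"))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "cohort", "father_id",
                                            "mother_id", "qc_status"])
    calls = pd.DataFrame(call_rows, columns=["sample_id", "size", "type", "qc_pass",
                                             "rare_strict", "inheritance"])
    return calls, meta


def test_rare_carrier_test_counts_individuals():
    calls, meta = _cohort_fixture()
    res = rare_carrier_test(calls, meta, "ID", "dyslexia")
    assert (res.table.a, res.table.b, res.table.c, res.table.d) == (10, 30, 2, 38)


def test_de_novo_test_counts_events():
    calls, meta = _cohort_fixture()
    res = de_novo_test(calls, meta, "ID", "dyslexia")
    assert (res.table.a, res.table.b) == (10, 4)
    assert (res.table.c, res.table.d) == (0, 2)


def test_two_hit_test_counts_carriers_with_two():
    calls, meta = _cohort_fixture()
    res = two_hit_test(calls, meta, "ID", "dyslexia")
    assert (res.table.a, res.table.b) == (4, 6)


def test_cohort_test_errors_on_empty_cohort():
    calls, meta = _cohort_fixture()
    with pytest.raises(ValueError, match="dyslexia"):
        rare_carrier_test(calls, meta[meta.cohort == "ID"].assign(cohort="control"),
                          "control", "dyslexia")


# ---------------------------------------------------------------------------
# Summaries, histograms, medians


def test_cohort_summary_basics():
    calls = pd.DataFrame({
        "sample_id": ["a0", "a0"],
        "size": [100_000, 300_000],
        "type": ["deletion", "deletion"],
        "qc_pass": [True, True],
        "gene_count": [2, 4],
        "breaks_gene": [True, False],
    })
    meta = pd.DataFrame({"sample_id": ["a0"], "cohort": ["ID"]})
    row = cohort_summary(calls, meta).iloc[0]
    assert row.total_cnvs == 2
    assert row.mean_size_bp == 200_000
    assert row.deletion_fraction == 1.0
    assert row.breaks_gene_fraction == 0.5
    assert row.mean_gene_density == 3.0


def test_gene_density_matches_brute_force(rng):
    counts = rng.integers(0, 30, size=50)
    calls = pd.DataFrame({
        "sample_id": ["s"] * 50, "size": rng.integers(1, 10**6, 50),
        "type": ["deletion"] * 50, "qc_pass": [True] * 50,
        "gene_count": counts, "breaks_gene": [False] * 50,
    })
    meta = pd.DataFrame({"sample_id": ["s"], "cohort": ["ID"]})
    assert cohort_summary(calls, meta).iloc[0].mean_gene_density == pytest.approx(
        sum(counts) / 50
    )


def test_size_histogram_bins_left_closed():
    calls = pd.DataFrame({"sample_id": ["s"], "size": [560_000], "type": ["deletion"]})
    hist = size_histogram(calls, n_samples=1, bins=[0, 500_000, 1_000_000])
    assert hist.loc[1, "deletions_per_individual"] == 1.0
    assert hist.loc[0, "deletions_per_individual"] == 0.0
    # boundary call goes to the left-closed bin
    edge = size_histogram(pd.DataFrame({"sample_id": ["s"], "size": [500_000],
                                        "type": ["deletion"]}), 1, [0, 500_000, 1_000_000])
    assert edge.loc[1, "deletions_per_individual"] == 1.0


def test_size_histogram_empty_calls_zero():
    hist = size_histogram(pd.DataFrame({"sample_id": [], "size": [], "type": []}),
                          5, [0, 10**6])
    assert (hist[["deletions_per_individual", "duplications_per_individual"]] == 0).all().all()


def test_median_of_published_dyslexia_strict_set():
    """Strict-rare dyslexia sizes have median 302,914 bp (printed as 302 kbp)."""
    calls = dyslexia_rare_calls()
    strict = calls[calls["control_count"] == 0]
    assert median_rare_size(strict["size"]) == 302_914.0


def test_median_single_and_random(rng):
    assert median_rare_size([123]) == 123
    for _ in range(20):
        xs = rng.integers(1, 10**6, size=int(rng.integers(1, 12)))
        srt = sorted(xs)
        n = len(srt)
        expect = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
        assert median_rare_size(list(xs)) == expect


def test_median_empty_errors():
    with pytest.raises(ValueError):
        median_rare_size([])


# ---------------------------------------------------------------------------
# Power


def test_power_null_equals_alpha():
    assert two_proportion_power(0.1, 0.0, 300, 300) == pytest.approx(0.05, abs=1e-9)


def test_power_monotone_in_delta_and_n():
    base = two_proportion_power(0.03, 0.042, 322, 306)
    assert two_proportion_power(0.03, 0.06, 322, 306) > base
    assert two_proportion_power(0.03, 0.042, 800, 800) > base


def test_power_matches_monte_carlo(rng):
    p0, delta, n1, n2, alpha = 0.03, 0.042, 322, 306, 0.05
    reps = 20_000
    x1 = rng.binomial(n1, p0 + delta, size=reps)
    x2 = rng.binomial(n2, p0, size=reps)
    p1h, p2h = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1h - p2h) / se, 0.0)
    mc = (np.abs(z) > stats.norm.ppf(1 - alpha / 2)).mean()
    assert two_proportion_power(p0, delta, n1, n2, alpha) == pytest.approx(mc, abs=0.02)
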