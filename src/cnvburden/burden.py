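"""Cohort-level CNV burden statistics.

Every comparison reduces to a 2x2 contingency table tested with Fisher's
exact test (two-sided, point-probability rule) and summarized by the sample
(cross-product) odds ratio OR = ad/bc — reported as infinity when exactly
one of the products is zero, and NA when both are.  No multiple-testing
correction is applied by default; a Bonferroni helper is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "BurdenResult",
    "SurvivorCurve",
    "fisher_or",
    "largest_cnv_per_sample",
    "survivor_curve",
    "large_cnv_burden_test",
    "rare_carrier_test",
    "de_novo_test",
    "two_hit_test",
    "cohort_summary",
    "size_histogram",
    "median_rare_size",
    "two_proportion_power",
    "bonferroni",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class BurdenResult:
    label: str
    table: ContingencyTable
    odds_ratio: float  # may be inf or nan
    p_value: float
    test: str = "fisher_exact_two_sided"


@dataclass
class SurvivorCurve:
    """Per-cohort fraction of individuals whose largest CNV is >= each size."""

    grid: np.ndarray
    fractions: dict[str, np.ndarray] = field(default_factory=dict)


def sample_odds_ratio(t: ContingencyTable) -> float:
    ad, bc = t.a * t.d, t.b * t.c
    if bc > 0:
        return ad / bc
    if ad > 0:
        return math.inf
    return math.nan


def fisher_or(t: ContingencyTable, label: str = "", alternative: str = "two-sided") -> BurdenResult:
    """Fisher's exact test with the cross-product odds ratio.

    The two-sided p-value follows the point-probability rule: the sum of
    probabilities of all tables (with the observed margins) whose
    hypergeometric point probability does not exceed the observed table's.
    """
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) <= 0:
        raise ValueError("all margins must be positive for testing")
    _, p = stats.fisher_exact(t.as_array(), alternative=alternative)
    return BurdenResult(label=label, table=t, odds_ratio=sample_odds_ratio(t), p_value=float(p))


def haldane_anscombe_or(t: ContingencyTable) -> float:
    """Continuity-corrected odds ratio (+0.5 to every cell)."""
    return ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


# ---------------------------------------------------------------------------
# Largest-CNV survivor analysis


def largest_cnv_per_sample(
    calls: pd.DataFrame,
    sample_ids: Iterable[str],
    include_types: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Size of the largest qualifying CNV per sample (0 for call-free samples)."""
    sub = calls
    if include_types is not None:
        sub = sub[sub["type"].isin(include_types)]
    if "qc_pass" in sub.columns:
        sub = sub[sub["qc_pass"].astype(bool)]
    maxima = sub.groupby("sample_id")["size"].max()
    idx = pd.Index(list(sample_ids), name="sample_id")
    return maxima.reindex(idx, fill_value=0).astype(np.int64)


def survivor_curve(maxima_by_cohort: dict[str, pd.Series], grid: Sequence[int]) -> SurvivorCurve:
    """Fraction of each cohort whose largest CNV is >= each grid size."""
    grid = np.asarray(grid)
    if len(grid) and np.any(np.diff(grid) < 0):
        raise ValueError("size grid must be sorted ascending")
    curve = SurvivorCurve(grid=grid)
    for cohort, maxima in maxima_by_cohort.items():
        if len(maxima) == 0:
            raise ValueError(f"cohort {cohort!r} is empty")
        vals = maxima.to_numpy()
        curve.fractions[cohort] = np.array([(vals >= s).mean() for s in grid])
    return curve


def large_cnv_burden_test(
    maxima_a: pd.Series,
    maxima_b: pd.Series,
    threshold_bp: int = 1_000_000,
    label: str = "large_cnv_burden",
) -> BurdenResult:
    """Carriers of a CNV strictly larger than ``threshold_bp``, A vs B."""
    if len(maxima_a) == 0 or len(maxima_b) == 0:
        raise ValueError("both cohorts must be non-empty")
    a = int((maxima_a > threshold_bp).sum())
    c = int((maxima_b > threshold_bp).sum())
    t = ContingencyTable(a, len(maxima_a) - a, c, len(maxima_b) - c)
    return fisher_or(t, label=label)


# ---------------------------------------------------------------------------
# Rare-carrier / de novo / two-hit comparisons


def _cohort_samples(meta: pd.DataFrame, cohort: str) -> pd.Index:
    sub = meta[meta["cohort"] == cohort]
    if "role" in meta.columns:
        sub = sub[sub["role"] == "proband"]
    if "qc_status" in meta.columns:
        sub = sub[sub["qc_status"] != "fail"]
    return pd.Index(sub["sample_id"].astype(str))


def rare_carrier_test(
    annotated: pd.DataFrame, meta: pd.DataFrame, cohort_a: str, cohort_b: str
) -> BurdenResult:
    """Individuals carrying >=1 strictly-rare call, cohort A vs cohort B."""
    rare = annotated[annotated["rare_strict"].astype(bool)]
    res = []
    for cohort in (cohort_a, cohort_b):
        samples = _cohort_samples(meta, cohort)
        if len(samples) == 0:
            raise ValueError(f"rare_carrier: cohort {cohort!r} has no eligible samples")
        carriers = rare[rare["sample_id"].isin(samples)]["sample_id"].nunique()
        res.append((carriers, len(samples) - carriers))
    t = ContingencyTable(res[0][0], res[0][1], res[1][0], res[1][1])
    return fisher_or(t, label=f"rare_carrier:{cohort_a}_vs_{cohort_b}")


def de_novo_test(
    annotated: pd.DataFrame, meta: pd.DataFrame, cohort_a: str, cohort_b: str
) -> BurdenResult:
    """De novo vs inherited among rare CNVs with resolved inheritance.

    The unit is the CNV event, not the individual; calls with unresolved
    inheritance (NA or anything outside the closed vocabulary) are excluded.
    """
    rare = annotated[annotated["rare_strict"].astype(bool)]
    resolved = rare[rare["inheritance"].isin(["de_novo", "maternal", "paternal", "both"])]
    counts = []
    for cohort in (cohort_a, cohort_b):
        samples = _cohort_samples(meta, cohort)
        sub = resolved[resolved["sample_id"].isin(samples)]
        if len(sub) == 0:
            raise ValueError(f"de_novo: cohort {cohort!r} has no resolved rare CNVs")
        dn = int((sub["inheritance"] == "de_novo").sum())
        counts.append((dn, len(sub) - dn))
    t = ContingencyTable(counts[0][0], counts[0][1], counts[1][0], counts[1][1])
    return fisher_or(t, label=f"de_novo:{cohort_a}_vs_{cohort_b}")


def two_hit_test(
    annotated: pd.DataFrame, meta: pd.DataFrame, cohort_a: str, cohort_b: str
) -> BurdenResult:
    """Among rare-CNV carriers, those with >=2 strictly-rare calls, A vs B."""
    rare = annotated[annotated["rare_strict"].astype(bool)]
    counts = []
    for cohort in (cohort_a, cohort_b):
        samples = _cohort_samples(meta, cohort)
        per_sample = rare[rare["sample_id"].isin(samples)].groupby("sample_id").size()
        if len(per_sample) == 0:
            raise ValueError(f"two_hit: cohort {cohort!r} has no rare-CNV carriers")
        two = int((per_sample >= 2).sum())
        counts.append((two, len(per_sample) - two))
    t = ContingencyTable(counts[0][0], counts[0][1], counts[1][0], counts[1][1])
    return fisher_or(t, label=f"two_hit:{cohort_a}_vs_{cohort_b}")


# ---------------------------------------------------------------------------
# Summaries


def cohort_summary(annotated: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort call summary: count, mean size, deletion fraction,
    gene-disrupting fraction, mean genes per CNV."""
    rows = []
    for cohort in meta["cohort"].unique():
        samples = _cohort_samples(meta, cohort)
        sub = annotated[annotated["sample_id"].isin(samples)]
        if "qc_pass" in sub.columns:
            sub = sub[sub["qc_pass"].astype(bool)]
        row = {
            "cohort": cohort,
            "n_samples": len(samples),
            "total_cnvs": len(sub),
            "mean_size_bp": float(sub["size"].mean()) if len(sub) else float("nan"),
            "deletion_fraction": (
                float(sub["type"].isin(["deletion", "homozygous_deletion"]).mean())
                if len(sub)
                else float("nan")
            ),
        }
        if "breaks_gene" in sub.columns:
            row["breaks_gene_fraction"] = (
                float(sub["breaks_gene"].astype(bool).mean()) if len(sub) else float("nan")
            )
        if "gene_count" in sub.columns:
            row["mean_gene_density"] = (
                float(sub["gene_count"].mean()) if len(sub) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def size_histogram(
    calls: pd.DataFrame, n_samples: int, bins: Sequence[int]
) -> pd.DataFrame:
    """Per-individual CNV counts per size bin, deletions and duplications apart.

    Bins are left-closed, right-open on the supplied sorted edges.
    """
    bins = np.asarray(bins)
    if np.any(np.diff(bins) < 0):
        raise ValueError("bins must be sorted ascending")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    out = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (calls["size"] >= lo) & (calls["size"] < hi)
        sub = calls[sel]
        out.append(
            {
                "bin_lo": int(lo),
                "bin_hi": int(hi),
                "deletions_per_individual": float(
                    sub["type"].isin(["deletion", "homozygous_deletion"]).sum() / n_samples
                ),
                "duplications_per_individual": float(
                    (sub["type"] == "duplication").sum() / n_samples
                ),
            }
        )
    return pd.DataFrame(out)


def median_rare_size(sizes: Sequence[int]) -> float:
    """Median CNV size; even counts average the two middle values."""
    sizes = list(sizes)
    if not sizes:
        raise ValueError("median of an empty size set")
    return float(np.median(sizes))


# ---------------------------------------------------------------------------
# Power


def two_proportion_power(
    p0: float, delta: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Normal-approximation power of a two-sided two-proportion z-test.

    Group 1 has success probability ``p0 + delta``, group 2 has ``p0``.  The
    test statistic uses the pooled SE under the null; power integrates the
    rejection region under the alternative with the unpooled SE.  At
    ``delta = 0`` the power equals ``alpha``.
    """
    p1 = p0 + delta
    if not (0 < p0 < 1 and 0 < p1 < 1):
        raise ValueError("p0 and p0+delta must lie in (0, 1)")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    pbar = (n1 * p1 + n2 * p0) / (n1 + n2)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n2)
    upper = stats.norm.cdf((delta - z_crit * se0) / se1)
    lower = stats.norm.cdf((-delta - z_crit * se0) / se1)
    return float(upper + lower)
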