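"""Published reference counts and call rows used as fixed analysis inputs.

These are the printed per-cohort contingency counts and the dyslexia-cohort
rare-CNV call list from the hotspot-array CNV-burden study of dyslexia,
autism and intellectual-disability cohorts that this package models.  They
serve as inputs for recomputing the published summary statistics (odds
ratios, rare-set sizes, medians); nothing here is a result — every number
derived from them is computed at run time by package operations.

Call rows are printed with ``size == end - start`` (1-based start,
exclusive end); both bounds are shifted by one on ingest so internal
0-based half-open coordinates preserve the printed sizes exactly.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .burden import ContingencyTable

__all__ = [
    "dyslexia_rare_calls",
    "CONTROL_MAP_SIZE",
    "RARE_CARRIERS",
    "COHORT_N",
    "DE_NOVO_RESOLVED",
    "TWO_HIT",
    "DE_NOVO_TOTAL",
    "DE_NOVO_LARGE",
    "carrier_table",
    "de_novo_table",
    "two_hit_table",
]

#: Total control individuals behind the rarity map (8,329 array controls
#: plus 306 pass-QC platform controls).
CONTROL_MAP_SIZE = 8_635

#: Rare-CNV carriers / cohort size (pass-QC individuals).
RARE_CARRIERS = {"ID": 69, "autism": 35, "dyslexia": 6, "control": 6}
COHORT_N = {"ID": 431, "autism": 336, "dyslexia": 322, "control": 306}

#: De novo / total rare CNVs with resolved inheritance, per cohort.
DE_NOVO_RESOLVED = {"ID": (30, 47), "autism": (14, 35), "dyslexia": (0, 8)}

#: Individuals with >=2 rare CNVs / rare-CNV carriers.
TWO_HIT = {"ID_MCA": (4, 9), "ID": (4, 60)}

#: Of all resolved rare CNVs across cohorts, 44/90 arose de novo and 34 of
#: those 44 were large (>1 Mbp).
DE_NOVO_TOTAL = (44, 90)
DE_NOVO_LARGE = 34

# Dyslexia-cohort rare CNV calls (relaxed filter: control frequency <0.1%).
# Columns: chrom, start (1-based), end, size, band, type, sample, hotspot
# class, gene count, inheritance, control count.
_DYSLEXIA_ROWS = """\
chrom	start	end	size	band	type	sample_id	hotspot_class	gene_count	inheritance	control_count
chr1	144106777	144451305	344528	1q21.1	deletion	2602	HS	1	NA	2
chr3	139732796	140171095	438299	3q22.3	duplication	1806	non_HS	142	NA	1
chr6	65179840	66364033	1184193	6q12	deletion	2803	non_HS	1	paternal	1
chr4	123017758	123458923	441165	4q27	duplication	2286	non_HS	0	maternal	0
chr7	40606348	40819984	213636	7p14.1	deletion	2244	non_HS	1	maternal	0
chr7	68820751	68904999	84248	7q11.22	deletion	2867	HS	2	paternal	0
chr7	69876932	70546042	669110	7q11.22	duplication	1102	HS	1	paternal	0
chr7	110381300	110851860	470560	7q31.1	deletion	3437	non_HS	102	paternal	2
chr8	11373083	11434911	61828	8p23.1	deletion	1012	HS	16	maternal	0
chr9	6348644	6740836	392192	9p24.1	deletion	1004	non_HS	11	paternal	0
"""


def dyslexia_rare_calls() -> pd.DataFrame:
    """Dyslexia rare-CNV rows as a 0-based half-open annotated call table.

    The printed 1-based starts are shifted by one on ingest; the returned
    ``size`` column equals ``end - start`` and matches the printed sizes.
    """
    frame = pd.read_csv(_io.StringIO(_DYSLEXIA_ROWS), sep="\t")
    frame["start"] = frame["start"] - 1
    frame["end"] = frame["end"] - 1
    assert (frame["size"] == frame["end"] - frame["start"]).all()
    frame["qc_pass"] = True
    return frame


def carrier_table(cohort_a: str, cohort_b: str) -> ContingencyTable:
    """Rare-CNV carriers vs non-carriers, cohort A vs cohort B."""
    a, na = RARE_CARRIERS[cohort_a], COHORT_N[cohort_a]
    c, nc = RARE_CARRIERS[cohort_b], COHORT_N[cohort_b]
    return ContingencyTable(a, na - a, c, nc - c)


def de_novo_table(cohort_a: str, cohort_b: str) -> ContingencyTable:
    """De novo vs inherited among resolved rare CNVs, cohort A vs cohort B."""
    a, ta = DE_NOVO_RESOLVED[cohort_a]
    c, tc = DE_NOVO_RESOLVED[cohort_b]
    return ContingencyTable(a, ta - a, c, tc - c)


def two_hit_table(cohort_a: str, cohort_b: str) -> ContingencyTable:
    """Two-hit carriers vs single-hit carriers, cohort A vs cohort B."""
    a, ta = TWO_HIT[cohort_a]
    c, tc = TWO_HIT[cohort_b]
    return ContingencyTable(a, ta - a, c, tc - c)
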