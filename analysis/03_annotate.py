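#!/usr/bin/env python
"""Annotate QC-passed calls.

Adds hotspot class, control-map match counts with strict/relaxed rarity
flags (50% reciprocal overlap, same type), gene counts, genomic-disorder
labels, and trio-based inheritance, then prints per-cohort rare-carrier
counts.
"""

import argparse
from pathlib import Path

from cnvburden import io as cio
from cnvburden.pipeline import run_annotate

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "pipeline" / "sim"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    outdir = ROOT / "scratch" / "pipeline" / "annotated"
    ann_path = run_annotate(
        ROOT / "scratch" / "pipeline" / "calls" / "calls.tsv",
        SIM / "control_map.tsv", outdir, SIM / "genes.bed", SIM / "disorders.bed",
        SIM / "samples.tsv", SIM / "layout.tsv", seed=args.seed,
    )
    ann = cio.read_cnv_calls(ann_path)
    meta = cio.read_sample_meta(SIM / "samples.tsv")
    probands = meta[meta["role"] == "proband"]
    rare = ann[ann["rare_strict"].astype(bool)]
    merged = rare.merge(probands[["sample_id", "cohort"]], on="sample_id")
    carriers = merged.groupby("cohort")["sample_id"].nunique()
    sizes = probands.groupby("cohort").size()
    print("strict-rare CNV carriers per cohort:")
    for cohort in sizes.index:
        k = int(carriers.get(cohort, 0))
        print(f"  {cohort:>13}: {k}/{sizes[cohort]} ({k / sizes[cohort]:.1%})")
    print(f"\nannotated calls: {ann_path}")


if __name__ == "__main__":
    main()
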