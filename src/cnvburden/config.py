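"""Analysis configuration: every threshold of the calling/filtering pipeline.

Comparison strictness matters and is part of the contract:

* post-HMM filters keep a variant only with ``|mean z| > z_threshold`` and
  ``n_probes > min_probes`` (both strict),
* same-state probes merge into a segment only when the inter-probe gap is
  strictly below ``segment_gap_bp``,
* bridging across an intervening run requires ``<= bridge_max_probes`` and
  ``<= bridge_max_gap_bp`` (both inclusive),
* "rare (relaxed)" means control frequency strictly below ``rare_freq`` —
  with the default map of 8,635 controls, up to 8 carriers pass,
* a "large" CNV is strictly larger than ``large_cnv_bp``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # post-HMM call filters
    z_threshold: float = 1.5          # keep |mean z| strictly greater
    min_probes: int = 10              # keep probe count strictly greater
    min_size_hotspot_bp: int = 50_000     # minimum size, hotspot-class calls
    min_size_non_hotspot_bp: int = 300_000  # minimum size, non-hotspot calls
    # segment assembly / bridging
    segment_gap_bp: int = 50_000      # strict <
    bridge_max_probes: int = 5        # inclusive
    bridge_max_gap_bp: int = 10_000   # inclusive
    # rarity / matching
    reciprocal_overlap_fraction: float = 0.5  # >= in both directions
    rare_freq: float = 0.001          # strict <
    n_controls: int = 8_635
    # burden
    large_cnv_bp: int = 1_000_000     # strict >
    # homozygous-deletion labelling and sample QC (stand-in rules)
    homozygous_z: float = -6.0        # segment mean z below this => homozygous
    sample_sd_ceiling: float = 0.35   # fail sample iff autosomal SD exceeds
    sample_call_multiple: float = 3.0  # fail iff raw calls > multiple x cohort median
    # robust (median/MAD) chromosome normalization instead of mean/SD; guards
    # against events so large they drag their own chromosome's statistics
    robust_zscore: bool = False

    def __post_init__(self) -> None:
        positive = [
            self.z_threshold, self.min_probes, self.min_size_hotspot_bp,
            self.min_size_non_hotspot_bp, self.segment_gap_bp,
            self.bridge_max_probes, self.bridge_max_gap_bp, self.rare_freq,
            self.n_controls, self.large_cnv_bp, self.sample_sd_ceiling,
            self.sample_call_multiple,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds must be positive")
        if not 0.0 < self.reciprocal_overlap_fraction <= 1.0:
            raise ValueError("reciprocal overlap fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        # allow either a flat mapping or a top-level "analysis" block
        if "analysis" in data and isinstance(data["analysis"], dict):
            data = data["analysis"]
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable digest of the configuration, stamped on outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
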