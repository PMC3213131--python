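"""Readers and writers for every tabular format the pipeline touches.

Conventions
-----------
* Intervals are BED-like TSV: leading columns ``chrom  start  end``, 0-based
  half-open, with optional extra columns preserved as annotations.
  Published tables with 1-based starts are ingested with ``dialect=
  "one_based"``, which subtracts 1 from the start so the printed
  ``size == end - start`` is preserved.
* Matrices and metadata are headered TSV.
* Every writer emits a leading comment line recording the config hash and
  seed of the run that produced the file; readers skip ``#`` lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CALL_COLUMNS, IntensityTrack, ProbeDesign

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_probe_design",
    "write_probe_design",
    "read_log_ratio_matrix",
    "write_log_ratio_matrix",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_sample_meta",
    "write_sample_meta",
    "read_control_map",
    "write_control_map",
    "read_layout",
    "write_layout",
    "provenance_line",
]


class ParseError(ValueError):
    """A malformed input line; the message names the file and line number."""


def provenance_line(config_hash: str = "", seed: Optional[int] = None) -> str:
    parts = ["# cnvburden"]
    if config_hash:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def _write_frame(frame: pd.DataFrame, path: str | Path, header_line: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header_line + "\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------------------
# BED-like intervals


def read_intervals(path: str | Path, dialect: str = "bed") -> pd.DataFrame:
    """Read a BED-like file into a sorted interval table.

    Parameters
    ----------
    path : path
        TSV with leading columns chrom/start/end.  A header line beginning
        with ``chrom`` is recognized; otherwise extra columns are named
        ``col3, col4, ...``.
    dialect : {"bed", "one_based"}
        ``one_based`` declares 1-based inclusive starts (as printed in
        published call tables); starts are decremented on ingest.

    Returns a DataFrame with 0-based half-open records sorted by
    (chrom, start).  If a ``size`` column is present it must equal
    ``end - start`` after ingestion.
    """
    if dialect not in ("bed", "one_based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[list[str]] = []
    header: Optional[list[str]] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0].strip().lower() in ("chrom", "chr", "chromosome"):
                header = [f.strip() for f in fields]
                header[0] = "chrom"
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            rows.append(fields)
    if not rows:
        cols = header or ["chrom", "start", "end"]
        return pd.DataFrame(columns=cols)
    width = max(len(r) for r in rows)
    if header is None:
        header = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, width)]
    header = header[:width] + [f"col{i}" for i in range(len(header), width)]
    rows = [r + [""] * (width - len(r)) for r in rows]
    frame = pd.DataFrame(rows, columns=header)
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    if dialect == "one_based":
        # printed tables satisfy size == end - start, i.e. 1-based start with
        # exclusive end; shifting both bounds preserves the printed size
        frame["start"] -= 1
        frame["end"] -= 1
    bad = frame.index[frame["start"] >= frame["end"]]
    if len(bad):
        r = frame.loc[bad[0]]
        raise ParseError(
            f"{path}: interval with start >= end after ingest: "
            f"{r['chrom']}:{r['start']}-{r['end']}"
        )
    if frame["start"].min() < 0:
        raise ParseError(f"{path}: negative start after ingest")
    if "size" in frame.columns:
        sizes = frame["size"].astype(np.int64)
        mism = frame.index[sizes != frame["end"] - frame["start"]]
        if len(mism):
            r = frame.loc[mism[0]]
            raise ParseError(
                f"{path}: size column disagrees with end-start at "
                f"{r['chrom']}:{r['start']}-{r['end']}"
            )
        frame["size"] = sizes
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_intervals(
    frame: pd.DataFrame, path: str | Path, config_hash: str = "", seed: Optional[int] = None
) -> None:
    _write_frame(frame, path, provenance_line(config_hash, seed))


# ---------------------------------------------------------------------------
# Probe design


def write_probe_design(
    design: ProbeDesign, path: str | Path, config_hash: str = "", seed: Optional[int] = None
) -> None:
    _write_frame(design.frame, path, provenance_line(config_hash, seed))


def read_probe_design(path: str | Path) -> ProbeDesign:
    frame = read_intervals(path)
    return ProbeDesign(frame)


# ---------------------------------------------------------------------------
# Log2-ratio matrices


def read_log_ratio_matrix(path: str | Path, design: ProbeDesign) -> list[IntensityTrack]:
    """Read a probe x sample log2-ratio TSV aligned against ``design``.

    The first column must be ``probe_id``; every design probe must appear in
    the same order.  Missing cells come back as NaN.
    """
    frame = _read_tsv(path)
    if frame.columns[0] != "probe_id":
        raise ValueError(f"{path}: first column must be probe_id")
    file_ids = frame["probe_id"].astype(str).tolist()
    want = design.probe_ids.astype(str).tolist()
    if file_ids != want:
        offenders = [i for i, (a, b) in enumerate(zip(file_ids, want)) if a != b]
        extra = abs(len(file_ids) - len(want))
        raise ValueError(
            f"{path}: probe ids do not match design "
            f"({len(offenders)} mismatched, {extra} missing/extra); "
            f"first offenders: {offenders[:5]}"
        )
    tracks = []
    for col in frame.columns[1:]:
        tracks.append(IntensityTrack(sample_id=str(col), values=frame[col].to_numpy(dtype=float)))
    return tracks


def write_log_ratio_matrix(
    tracks: Sequence[IntensityTrack],
    design: ProbeDesign,
    path: str | Path,
    config_hash: str = "",
    seed: Optional[int] = None,
) -> None:
    data = {"probe_id": design.probe_ids}
    for t in tracks:
        if len(t.values) != len(design):
            raise ValueError(
                f"track {t.sample_id}: {len(t.values)} values for {len(design)} probes"
            )
        data[t.sample_id] = t.values
    _write_frame(pd.DataFrame(data), path, provenance_line(config_hash, seed))


# ---------------------------------------------------------------------------
# Call tables, sample metadata, control map


def write_cnv_calls(
    calls: pd.DataFrame, path: str | Path, config_hash: str = "", seed: Optional[int] = None
) -> None:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    # keep schema columns first, extra annotation columns after
    extras = [c for c in calls.columns if c not in CALL_COLUMNS]
    _write_frame(calls[CALL_COLUMNS + extras], path, provenance_line(config_hash, seed))


def read_cnv_calls(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path)
    missing = [c for c in CALL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: call table missing columns: {missing}")
    frame["reject_reason"] = frame["reject_reason"].fillna("")
    frame["hotspot_class"] = frame["hotspot_class"].fillna("")
    return frame


def write_sample_meta(
    meta: pd.DataFrame, path: str | Path, config_hash: str = "", seed: Optional[int] = None
) -> None:
    _write_frame(meta, path, provenance_line(config_hash, seed))


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    from .core import validate_sample_meta

    return validate_sample_meta(_read_tsv(path))


def write_layout(layout, path: str | Path, config_hash: str = "", seed: Optional[int] = None) -> None:
    """Serialize a GenomeLayout as a BED-like table with a ``kind`` column.

    ``chromosome`` rows span the whole chromosome (recording its length);
    ``hotspot`` and ``flank`` rows carry the region intervals.
    """
    rows = [(c, 0, layout.lengths[c], "chromosome") for c in layout.chromosomes]
    for c in layout.chromosomes:
        rows += [(c, s, e, "hotspot") for s, e in layout.hotspots.get(c, [])]
        rows += [(c, s, e, "flank") for s, e in layout.flanks.get(c, [])]
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind"])
    _write_frame(frame, path, provenance_line(config_hash, seed))


def read_layout(path: str | Path):
    from .intervals import GenomeLayout

    frame = read_intervals(path)
    if "kind" not in frame.columns:
        raise ValueError(f"{path}: layout file missing 'kind' column")
    chrom_rows = frame[frame["kind"] == "chromosome"]
    chroms = chrom_rows["chrom"].tolist()
    lengths = dict(zip(chrom_rows["chrom"], chrom_rows["end"].astype(int)))
    hotspots = {
        c: [(int(r.start), int(r.end)) for r in grp.itertuples(index=False)]
        for c, grp in frame[frame["kind"] == "hotspot"].groupby("chrom")
    }
    flanks = {
        c: [(int(r.start), int(r.end)) for r in grp.itertuples(index=False)]
        for c, grp in frame[frame["kind"] == "flank"].groupby("chrom")
    }
    return GenomeLayout(chromosomes=chroms, lengths=lengths, hotspots=hotspots, flanks=flanks)


def write_control_map(
    events: pd.DataFrame,
    n_controls: int,
    path: str | Path,
    config_hash: str = "",
    seed: Optional[int] = None,
) -> None:
    header = provenance_line(config_hash, seed) + f"\n# n_controls={n_controls}"
    _write_frame(events, path, header)


def read_control_map(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read a control CNV map; returns (events frame, N controls)."""
    n_controls = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# n_controls="):
                n_controls = int(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    if n_controls is None:
        raise ValueError(f"{path}: missing '# n_controls=' header")
    frame = _read_tsv(path)
    for col in ("chrom", "start", "end", "type", "count"):
        if col not in frame.columns:
            raise ValueError(f"{path}: control map missing column {col!r}")
    return frame, n_controls
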