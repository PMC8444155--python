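"""Readers and writers for the text formats used across the pipeline.

All genomic coordinates are 0-based half-open internally (the BED
convention).  1-based inclusive dialects — UCSC-style region strings and
the position column of RNAplfold accessibility tracks — are converted on
ingest and restored on export.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "parse_region",
    "read_bed",
    "write_bed",
    "read_contacts",
    "write_contacts",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_groups",
    "write_sample_groups",
    "read_lunp",
    "write_lunp",
    "write_json_report",
]

BED_COLUMNS = ["chrom", "start", "end", "name"]
CONTACT_COLUMNS = [
    "rna_chrom", "rna_start", "rna_end",
    "dna_chrom", "dna_start", "dna_end", "id",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into ``{name: sequence}``.

    Names are the first whitespace token of each header; sequences are
    uppercased.  Empty files and duplicated names are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse a UCSC-style region string into 0-based half-open coordinates.

    ``"chr19:33298573-33303358"`` is read as 1-based inclusive (the genome
    browser convention) and becomes ``("chr19", 33298572, 33303358)``.
    """
    text = text.replace(",", "").replace(" ", "")
    chrom, _, span = text.partition(":")
    if not span or "-" not in span:
        raise ValueError(f"cannot parse region string {text!r}")
    lo, _, hi = span.partition("-")
    start1, end1 = int(lo), int(hi)
    if end1 < start1:
        raise ValueError(f"region end precedes start in {text!r}")
    return chrom, start1 - 1, end1


# ---------------------------------------------------------------------------
# Interval tables

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED(-like) file: chrom, start, end[, name[, score[, strand]]]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                row["score"] = parts[4]
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    return pd.DataFrame(rows, columns=None if rows else BED_COLUMNS)


def write_bed(path: str | Path, df: pd.DataFrame, columns: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"]
    extra = columns if columns is not None else [
        c for c in ("name", "score", "strand") if c in df.columns
    ]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Read BEDPE-like RNA-chromatin contacts.

    Columns 1-3 are the RNA anchor, 4-6 the DNA anchor, column 7 (optional)
    a record id.  Coordinates are BED-style 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            try:
                coords = [int(parts[i]) for i in (1, 2, 4, 5)]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if coords[1] <= coords[0] or coords[3] <= coords[2]:
                raise ValueError(f"{path}:{lineno}: end <= start")
            rows.append({
                "rna_chrom": parts[0], "rna_start": coords[0], "rna_end": coords[1],
                "dna_chrom": parts[3], "dna_start": coords[2], "dna_end": coords[3],
                "id": parts[6] if len(parts) > 6 else f"contact_{lineno}",
            })
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)


def write_contacts(path: str | Path, df: pd.DataFrame) -> None:
    df[CONTACT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Methylation matrices

def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV beta-value matrix with probes as rows, samples as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df


def write_beta_matrix(path: str | Path, beta: pd.DataFrame) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_groups(path: str | Path) -> pd.Series:
    """Read a two-column (sample, group) TSV; groups must be 'mut' or 'wt'."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    groups = df.set_index("sample")["group"]
    bad = sorted(set(groups.unique()) - {"mut", "wt"})
    if bad:
        raise ValueError(f"unknown sample group labels: {bad}")
    return groups


def write_sample_groups(path: str | Path, groups: pd.Series) -> None:
    groups.rename("group").to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# RNAplfold-style accessibility tracks ("_lunp" dialect)

def read_lunp(path: str | Path, span: int = 1) -> pd.DataFrame:
    """Read an RNAplfold ``_lunp`` unpaired-probability track.

    The file holds one row per (1-based) sequence position; column ``k``
    after the position is the probability that the ``k``-mer ending at that
    position is fully unpaired.  ``span`` selects which column to use as
    the per-position unpaired probability (1 = single nucleotide).

    Returns a frame with 0-based ``position``, ``p_unpaired`` and
    ``p_paired`` (taken as ``1 - p_unpaired`` since the track carries no
    per-pair information).
    """
    positions: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                pos = int(parts[0])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed position column") from exc
            if span >= len(parts):
                raise ValueError(
                    f"{path}:{lineno}: no column for window span {span}"
                )
            raw = parts[span]
            val = np.nan if raw == "NA" else float(raw)
            if np.isfinite(val) and not 0.0 <= val <= 1.0 + 1e-9:
                raise ValueError(f"{path}:{lineno}: probability out of range: {raw}")
            positions.append(pos - 1)
            values.append(val)
    if not positions:
        raise ValueError(f"no data rows in {path}")
    u = np.asarray(values, dtype=float)
    return pd.DataFrame({
        "position": np.asarray(positions, dtype=int),
        "p_unpaired": u,
        "p_paired": 1.0 - u,
    })


def write_lunp(path: str | Path, profile: pd.DataFrame) -> None:
    """Write a single-span ``_lunp``-dialect track (inverse of read_lunp)."""
    with open(path, "w") as fh:
        fh.write("#unpaired probabilities\n #i$\tl=1\n")
        for pos, u in zip(profile["position"], profile["p_unpaired"]):
            fh.write(f"{int(pos) + 1}\t{u:.10g}\n")


# ---------------------------------------------------------------------------
# Reports

def _json_safe(obj):
    """Recursively replace non-finite floats (invalid in strict JSON)."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if np.isnan(f):
            return None
        if np.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json_report(path: str | Path, report: dict) -> None:
    """Write the machine-readable run report (deterministic key order;
    non-finite floats are encoded portably)."""
    with open(path, "w") as fh:
        json.dump(_json_safe(report), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
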