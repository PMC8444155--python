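"""CpG-centered DNA target windows.

The triplex search screens fixed-width DNA windows centered on each CpG
probe (100 nt by default).  Probe coordinates are taken to point at the C
of the CpG dinucleotide (the 450K manifest convention); with an even
width the C sits at 0-based offset ``width // 2`` of its window.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["build_windows", "extract_window_sequences", "annotate_nearest_gene"]

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = ["probe_id", "chrom", "start", "end", "pos", "klass", "clipped"]


def build_windows(classifications: pd.DataFrame,
                  chrom_lengths: Mapping[str, int],
                  width: int = 100) -> pd.DataFrame:
    """One ``width``-nt window centered at each classified CpG.

    ``start = pos - width // 2``; windows overhanging a chromosome end are
    clipped and flagged, probes off known chromosomes are skipped with a
    log entry.  Input needs columns probe_id, chrom, pos and (optionally)
    klass.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    rows = []
    for row in classifications.itertuples(index=False):
        length = chrom_lengths.get(row.chrom)
        if length is None or not 0 <= row.pos < length:
            logger.warning("probe %s at %s:%s is off-chromosome; skipped",
                           row.probe_id, row.chrom, row.pos)
            continue
        start = int(row.pos) - width // 2
        end = start + width
        clipped = start < 0 or end > length
        rows.append({
            "probe_id": row.probe_id,
            "chrom": row.chrom,
            "start": max(start, 0),
            "end": min(end, length),
            "pos": int(row.pos),
            "klass": getattr(row, "klass", None),
            "clipped": clipped,
        })
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def extract_window_sequences(windows: pd.DataFrame,
                             genome: Mapping[str, str]) -> pd.DataFrame:
    """Attach the uppercase reference-strand sequence of every window."""
    seqs = []
    for row in windows.itertuples(index=False):
        if row.chrom not in genome:
            raise KeyError(f"chromosome {row.chrom!r} missing from genome")
        seq = genome[row.chrom][row.start:row.end].upper()
        if len(seq) != row.end - row.start:
            raise ValueError(
                f"window {row.probe_id} [{row.start},{row.end}) exceeds "
                f"chromosome {row.chrom} length"
            )
        seqs.append(seq)
    out = windows.copy()
    out["seq"] = seqs
    return out


def annotate_nearest_gene(windows: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per window, by distance from window midpoint to gene span.

    Distance is signed (positive when the gene starts downstream of the
    midpoint, negative when it ends upstream, 0 when the midpoint falls
    inside the gene).  Ties on |distance| break on smaller gene start,
    then lexicographic name.  Chromosomes with no genes get distance inf
    and an empty name.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values(["start", "name"]).reset_index(drop=True)
        for c, sub in genes.groupby("chrom")
    }
    names, dists = [], []
    for row in windows.itertuples(index=False):
        sub = by_chrom.get(str(row.chrom))
        if sub is None or len(sub) == 0:
            names.append("")
            dists.append(np.inf)
            continue
        mid = (int(row.start) + int(row.end)) // 2
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        signed = np.where(mid < starts, starts - mid,
                          np.where(mid >= ends, (ends - 1) - mid, 0))
        order = np.lexsort((sub["name"].to_numpy(), starts, np.abs(signed)))
        best = order[0]
        names.append(sub["name"].iloc[best])
        dists.append(int(signed[best]))
    return pd.DataFrame({
        "probe_id": windows["probe_id"].to_numpy(),
        "gene": names,
        "distance": dists,
    })
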