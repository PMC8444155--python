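"""Validation of predicted triplex targets against RNA-chromatin contacts.

Proximity-ligation interactome assays (MARGI-style) report paired records:
an RNA anchor (where the chromatin-associated RNA maps) and a DNA anchor
(the genomic locus it was ligated to).  Contacts whose RNA anchor overlaps
the lncRNA's source locus are the lncRNA's contacts; a contact *confirms*
a predicted triplex target window when its DNA anchor falls within
``flank`` bp of the window (windows are symmetrically expanded by the
flank before intersection, 3 kb by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, fisher_exact_2x2, rank_sum_test

__all__ = [
    "ColocParams",
    "filter_rna_contacts",
    "expand_intervals",
    "validate_triplexes",
    "protection_at_validated_sites",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocParams:
    """``rna_locus`` is the (chrom, start, end) source region of the lncRNA."""

    flank: int = 3000
    rna_locus: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


def filter_rna_contacts(contacts: pd.DataFrame, params: ColocParams) -> pd.DataFrame:
    """Contacts whose RNA anchor overlaps the lncRNA locus by >= 1 bp."""
    if params.rna_locus is None:
        raise ValueError("ColocParams.rna_locus is required to filter contacts")
    chrom, lo, hi = params.rna_locus
    keep = (
        (contacts["rna_chrom"] == chrom)
        & (contacts["rna_start"] < hi)
        & (contacts["rna_end"] > lo)
    )
    return contacts[keep].reset_index(drop=True)


def expand_intervals(df: pd.DataFrame, flank: int,
                     chrom_lengths: Mapping[str, int] | None = None,
                     chrom_col: str = "chrom", start_col: str = "start",
                     end_col: str = "end") -> pd.DataFrame:
    """Symmetric +/-flank expansion, clipped at 0 and (when known) at the
    chromosome end."""
    out = df.copy()
    out[start_col] = np.maximum(df[start_col] - flank, 0)
    if chrom_lengths is None:
        out[end_col] = df[end_col] + flank
    else:
        limits = df[chrom_col].map(lambda c: chrom_lengths.get(c, np.inf))
        out[end_col] = np.minimum(df[end_col] + flank, limits).astype(int)
    return out


def _overlaps_any(q_chrom, q_start, q_end, subjects: pd.DataFrame,
                  chrom_col="chrom", start_col="start", end_col="end") -> np.ndarray:
    """Boolean per query: does it overlap any subject interval?

    Sort-based: among subjects on the same chromosome with start < query
    end, the running maximum of ends decides overlap in O(log n) per query.
    """
    by_chrom = {}
    for c, sub in subjects.groupby(chrom_col):
        order = np.argsort(sub[start_col].to_numpy(), kind="stable")
        starts = sub[start_col].to_numpy()[order]
        ends = sub[end_col].to_numpy()[order]
        by_chrom[c] = (starts, np.maximum.accumulate(ends))
    out = np.zeros(len(q_chrom), dtype=bool)
    for i, (c, s, e) in enumerate(zip(q_chrom, q_start, q_end)):
        entry = by_chrom.get(c)
        if entry is None:
            continue
        starts, cummax_ends = entry
        k = np.searchsorted(starts, e, side="left")  # subjects with start < e
        out[i] = k > 0 and cummax_ends[k - 1] > s
    return out


def validate_triplexes(windows: pd.DataFrame, contacts: pd.DataFrame,
                       params: ColocParams,
                       chrom_lengths: Mapping[str, int] | None = None) -> dict:
    """Cross predicted triplex windows with RNA-chromatin contacts.

    Every window is expanded by ``+/-flank``; a contact is *confirmed* when
    its DNA anchor intersects at least one expanded triplex-positive
    window, and a window is *contacted* when at least one contact's DNA
    anchor intersects its expanded interval.  The association between
    window triplex status and contact status is summarised in a 2x2 Fisher
    table (rows positive/negative, columns contacted/not).
    """
    windows = windows.reset_index(drop=True)
    if len(contacts) == 0:
        logger.warning("no contacts supplied; colocalization table is degenerate")
    expanded = expand_intervals(windows, params.flank, chrom_lengths)
    pos_mask = windows["triplex_positive"].astype(bool).to_numpy()

    confirmed_mask = _overlaps_any(
        contacts["dna_chrom"].to_numpy(), contacts["dna_start"].to_numpy(),
        contacts["dna_end"].to_numpy(), expanded[pos_mask],
    ) if len(contacts) else np.zeros(0, dtype=bool)

    contacted_mask = _overlaps_any(
        expanded["chrom"].to_numpy(), expanded["start"].to_numpy(),
        expanded["end"].to_numpy(), contacts,
        chrom_col="dna_chrom", start_col="dna_start", end_col="dna_end",
    ) if len(contacts) else np.zeros(len(windows), dtype=bool)

    validated_windows = windows[pos_mask & contacted_mask].reset_index(drop=True)
    confirmed_contacts = contacts[confirmed_mask].reset_index(drop=True)
    table = ContingencyTable2x2(
        a=int((pos_mask & contacted_mask).sum()),
        b=int((pos_mask & ~contacted_mask).sum()),
        c=int((~pos_mask & contacted_mask).sum()),
        d=int((~pos_mask & ~contacted_mask).sum()),
    )
    odds, p = fisher_exact_2x2(table)
    return {
        "validated_windows": validated_windows,
        "confirmed_contacts": confirmed_contacts,
        "table": table,
        "odds_ratio": odds,
        "p_value": p,
    }


def protection_at_validated_sites(classifications: pd.DataFrame,
                                  validated_windows: pd.DataFrame,
                                  other_windows: pd.DataFrame) -> dict:
    """Rank-sum comparison of methylation deltas at contact-validated
    triplex windows versus all other windows; protection shows up as the
    validated group sitting lower."""
    deltas = classifications.set_index("probe_id")["delta"]
    val = deltas.reindex(validated_windows["probe_id"]).dropna().to_numpy()
    oth = deltas.reindex(other_windows["probe_id"]).dropna().to_numpy()
    if val.size == 0 or oth.size == 0:
        raise ValueError("both groups need at least one delta value")
    u, p = rank_sum_test(val, oth)
    return {
        "n_validated": int(val.size),
        "n_other": int(oth.size),
        "mean_delta_validated": float(val.mean()),
        "mean_delta_other": float(oth.mean()),
        "U": u,
        "p_value": p,
        "validated_lower": bool(np.median(val) < np.median(oth)),
    }
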