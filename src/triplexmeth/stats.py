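"""Protection and enrichment statistics.

Three questions are answered here: (i) are triplex-positive CpG windows
under-represented among hypermethylated loci (Fisher's exact test on the
HM/NHM x positive/negative table — protection shows up as an odds ratio
below 1); (ii) where on the RNA do triplex-forming oligonucleotides
cluster into DNA-binding domains (DBDs), and is each DBD's target count
larger than expected under random draws from a background region pool
(z-score plus add-one empirical p over resamples); (iii) do methylation
deltas differ between groups of loci (Mann-Whitney rank-sum, exact for
small samples).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .methylation import bh_fdr
from .triplex import TriplexHit

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentParams",
    "DBD",
    "fisher_exact_2x2",
    "hm_protection_table",
    "cluster_dbds",
    "dbd_enrichment",
    "rank_sum_test",
]

_EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = (HM, NHM) and columns = (positive, negative) by
    default; any 2x2 layout is accepted."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class EnrichmentParams:
    n_resamples: int = 100
    gap_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")


@dataclass(frozen=True)
class DBD:
    """A DNA-binding domain: a merged cluster of TFO intervals on the RNA."""

    rna_start: int
    rna_end: int
    n_tfos: int
    n_target_regions_hit: int
    background_mean: float = math.nan
    background_sd: float = math.nan
    z_score: float = math.nan
    empirical_p: float = math.nan
    q_value: float = math.nan


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test (probability-mass criterion).

    Returns the sample odds ratio ``(a*d)/(b*c)`` — inf when only ``b*c``
    is zero, nan for a degenerate (zero) margin, in which case p = 1.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return math.nan, 1.0
    res = sps.fisher_exact(arr, alternative="two-sided")
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, float(res.pvalue)


def hm_protection_table(classifications: pd.DataFrame,
                        windows: pd.DataFrame) -> dict:
    """Fisher test of hypermethylation against triplex positivity.

    ``windows`` must carry ``probe_id`` and ``triplex_positive``; probes
    classified OTHER are excluded.  Returns the table (a = HM & positive,
    b = HM & negative, c = NHM & positive, d = NHM & negative), the odds
    ratio and the two-sided p-value.
    """
    merged = classifications.merge(
        windows[["probe_id", "triplex_positive"]], on="probe_id", how="inner"
    )
    merged = merged[merged["klass"].isin(["HM", "NHM"])]
    hm = merged["klass"] == "HM"
    pos = merged["triplex_positive"].astype(bool)
    table = ContingencyTable2x2(
        a=int((hm & pos).sum()), b=int((hm & ~pos).sum()),
        c=int((~hm & pos).sum()), d=int((~hm & ~pos).sum()),
    )
    if min(table.a + table.b, table.c + table.d) == 0:
        import logging
        logging.getLogger(__name__).warning("degenerate protection table: %s", table)
    odds, p = fisher_exact_2x2(table)
    return {"table": table, "odds_ratio": odds, "p_value": p}


def cluster_dbds(hits: Sequence[TriplexHit],
                 params: EnrichmentParams = EnrichmentParams()) -> list[DBD]:
    """Merge TFO intervals within ``gap_tolerance`` into maximal DBDs.

    Each DBD records how many TFOs it absorbed and how many distinct
    target regions its TFOs hit; enrichment fields stay NaN until
    :func:`dbd_enrichment` fills them.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.rna_start, h.rna_end))
    clusters: list[list[TriplexHit]] = [[ordered[0]]]
    cur_end = ordered[0].rna_end
    for h in ordered[1:]:
        if h.rna_start <= cur_end + params.gap_tolerance:
            clusters[-1].append(h)
            cur_end = max(cur_end, h.rna_end)
        else:
            clusters.append([h])
            cur_end = h.rna_end
    return [
        DBD(
            rna_start=min(h.rna_start for h in cl),
            rna_end=max(h.rna_end for h in cl),
            n_tfos=len(cl),
            n_target_regions_hit=len({h.region for h in cl if h.region is not None}),
        )
        for cl in clusters
    ]


def _regions_hit_by_dbd(dbd: DBD, hits: Sequence[TriplexHit]) -> set[str]:
    return {
        h.region for h in hits
        if h.region is not None
        and h.rna_start < dbd.rna_end and h.rna_end > dbd.rna_start
    }


def dbd_enrichment(dbd: DBD, hits: Sequence[TriplexHit],
                   target_ids: Sequence[str],
                   background_ids: Sequence[str],
                   background_hits: Sequence[TriplexHit],
                   params: EnrichmentParams,
                   rng: np.random.Generator) -> DBD:
    """Background-resampled enrichment of one DBD.

    For each of ``n_resamples`` draws of ``len(target_ids)`` regions from
    the background pool, counts how many drawn regions carry a hit whose
    TFO overlaps the DBD; reports ``z = (observed - mean) / sd`` and the
    one-sided add-one empirical p-value
    ``(1 + #{resample >= observed}) / (n_resamples + 1)``.  Draws are
    without replacement when the pool allows it.
    """
    target_ids = list(target_ids)
    background_ids = list(background_ids)
    if not background_ids:
        raise ValueError("empty background region pool")
    observed = len(_regions_hit_by_dbd(dbd, hits) & set(target_ids))
    bg_hit = _regions_hit_by_dbd(dbd, background_hits)
    hit_flags = np.array([r in bg_hit for r in background_ids])
    k = len(target_ids)
    replace_draws = k > len(background_ids)
    counts = np.empty(params.n_resamples, dtype=int)
    for r in range(params.n_resamples):
        idx = rng.choice(len(background_ids), size=k, replace=replace_draws)
        counts[r] = int(hit_flags[idx].sum())
    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else math.nan
    emp_p = (1 + int((counts >= observed).sum())) / (params.n_resamples + 1)
    return replace(dbd, n_target_regions_hit=observed, background_mean=mean,
                   background_sd=sd, z_score=z, empirical_p=emp_p)


def enrich_dbds(dbds: list[DBD], hits, target_ids, background_ids,
                background_hits, params: EnrichmentParams,
                rng: np.random.Generator) -> list[DBD]:
    """Enrichment for every DBD plus BH correction across DBDs."""
    enriched = [
        dbd_enrichment(d, hits, target_ids, background_ids, background_hits,
                       params, rng)
        for d in dbds
    ]
    if enriched:
        qs = bh_fdr([d.empirical_p for d in enriched])
        enriched = [replace(d, q_value=float(q)) for d, q in zip(enriched, qs)]
    return enriched


def dbds_to_frame(dbds: Sequence[DBD]) -> pd.DataFrame:
    cols = ["rna_start", "rna_end", "n_tfos", "n_target_regions_hit",
            "background_mean", "background_sd", "z_score", "empirical_p", "q_value"]
    return pd.DataFrame([{c: getattr(d, c) for c in cols} for d in dbds], columns=cols)


# ---------------------------------------------------------------------------
# Rank-sum test

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating all group assignments of the pooled
    sample (ties handled by the U statistic itself)."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    mu = n1 * y.size / 2.0
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(idx)] = True
        xs, ys = pooled[mask], pooled[~mask]
        u = float((xs[:, None] > ys[None, :]).sum()
                  + 0.5 * (xs[:, None] == ys[None, :]).sum())
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on two samples.

    Uses exact enumeration of all group assignments when the pooled size
    is at most 12 (valid under ties), otherwise the normal approximation
    with tie correction and continuity correction.  Returns (U, p) with U
    computed for the first sample.  All values tied gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    u = float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u, 1.0
    if x.size + y.size <= _EXACT_RANKSUM_MAX_N:
        return u, _exact_ranksum_p(x, y, u)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)
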