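"""Fisher exactness, DBD clustering/enrichment, rank-sum conventions."""

import itertools
import math
from math import comb

import numpy as np
import pytest

from triplexmeth.stats import (DBD, ContingencyTable2x2, EnrichmentParams,
                               cluster_dbds, dbd_enrichment, fisher_exact_2x2,
                               hm_protection_table, rank_sum_test)
from triplexmeth.triplex import TriplexHit


def fisher_p_by_enumeration(a, b, c, d):
    """Two-sided Fisher p from first principles: enumerate every table with
    the same margins and sum the hypergeometric probabilities of tables no
    more probable than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(k):  # P(a = k | margins)
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = table_prob(a)
    return sum(table_prob(k) for k in range(lo, hi + 1)
               if table_prob(k) <= p_obs * (1 + 1e-12))


def test_fisher_balanced_table_is_null():
    odds, p = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
    assert odds == 1.0
    assert p == 1.0


def test_fisher_small_table_matches_enumeration():
    odds, p = fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3))
    assert odds == 9.0
    assert p == pytest.approx(fisher_p_by_enumeration(3, 1, 1, 3), abs=1e-12)


def test_fisher_fuzzed_tables_match_enumeration(rng):
    for _ in range(150):
        a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
        if a + b + c + d == 0 or min(a + b, c + d, a + c, b + d) == 0:
            continue
        _, p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_p_by_enumeration(a, b, c, d), abs=1e-12)


def test_fisher_degenerate_margins():
    odds, p = fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))
    assert math.isnan(odds)
    assert p == 1.0
    odds, _ = fisher_exact_2x2(ContingencyTable2x2(3, 0, 0, 3))
    assert odds == math.inf
    with pytest.raises(ValueError, match="empty table"):
        ContingencyTable2x2(0, 0, 0, 0)


def _hit(rs, re, region="r1"):
    return TriplexHit(rna_start=rs, rna_end=re, tts_chrom="chr1", tts_start=0,
                      tts_end=re - rs, motif="R", orientation="antiparallel",
                      strand="+", n_errors=0, guanine_rate=1.0, region=region)


def test_single_hit_forms_its_own_dbd():
    dbds = cluster_dbds([_hit(5, 17)])
    assert len(dbds) == 1
    assert (dbds[0].rna_start, dbds[0].rna_end) == (5, 17)
    assert dbds[0].n_tfos == 1
    assert dbds[0].n_target_regions_hit == 1
    assert cluster_dbds([]) == []


def test_overlapping_tfos_merge_and_gap_tolerance():
    dbds = cluster_dbds([_hit(0, 10), _hit(9, 20)])
    assert len(dbds) == 1
    assert (dbds[0].rna_start, dbds[0].rna_end) == (0, 20)
    # abutting intervals merge at gap 0 (half-open), separated ones do not
    assert len(cluster_dbds([_hit(0, 10), _hit(10, 20)])) == 1
    assert len(cluster_dbds([_hit(0, 10), _hit(12, 20)])) == 2
    assert len(cluster_dbds([_hit(0, 10), _hit(12, 20)],
                            EnrichmentParams(gap_tolerance=2))) == 1


def test_dbd_clustering_matches_interval_union(rng):
    """Fuzzed clustering equals a brute-force merge of interval overlaps."""
    for _ in range(30):
        n = int(rng.integers(1, 25))
        hits = []
        for k in range(n):
            s = int(rng.integers(0, 200))
            hits.append(_hit(s, s + int(rng.integers(10, 30)), region=f"w{k % 5}"))
        gap = int(rng.integers(0, 4))
        dbds = cluster_dbds(hits, EnrichmentParams(gap_tolerance=gap))
        # brute force: two hits connect if gap between intervals <= gap
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(n):
                a, b = hits[i], hits[j]
                if a.rna_start <= b.rna_end + gap and b.rna_start <= a.rna_end + gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i, h in enumerate(hits):
            groups.setdefault(find(i), []).append(h)
        expected = sorted(
            (min(h.rna_start for h in g), max(h.rna_end for h in g), len(g),
             len({h.region for h in g}))
            for g in groups.values()
        )
        got = sorted((d.rna_start, d.rna_end, d.n_tfos, d.n_target_regions_hit)
                     for d in dbds)
        assert got == expected


def test_dbd_enrichment_conventions(rng):
    hits = [_hit(0, 12, region="t1"), _hit(2, 14, region="t2")]
    dbd = cluster_dbds(hits)[0]
    bg_ids = [f"b{i}" for i in range(40)]
    bg_hits = [_hit(1, 13, region=f"b{i}") for i in range(4)]
    params = EnrichmentParams(n_resamples=100)
    out = dbd_enrichment(dbd, hits, ["t1", "t2"], bg_ids, bg_hits, params,
                         np.random.default_rng(0))
    assert out.n_target_regions_hit == 2
    assert 0 < out.empirical_p <= 1
    assert out.z_score > 0
    # deterministic under a fixed seed
    out2 = dbd_enrichment(dbd, hits, ["t1", "t2"], bg_ids, bg_hits, params,
                          np.random.default_rng(0))
    assert (out.background_mean, out.background_sd, out.empirical_p) == \
        (out2.background_mean, out2.background_sd, out2.empirical_p)
    # a DBD hitting nothing is never called enriched
    cold = DBD(rna_start=100, rna_end=120, n_tfos=0, n_target_regions_hit=0)
    out3 = dbd_enrichment(cold, [], ["t1", "t2"], bg_ids, bg_hits, params,
                          np.random.default_rng(1))
    assert out3.empirical_p >= 0.5


def test_rank_sum_identical_and_tied_inputs():
    assert rank_sum_test([1, 2, 3], [3, 1, 2])[1] == 1.0
    assert rank_sum_test([5.0] * 4, [5.0] * 4)[1] == 1.0
    assert rank_sum_test([5.0] * 20, [5.0] * 20)[1] == 1.0
    with pytest.raises(ValueError, match="one observation"):
        rank_sum_test([], [1.0])


def test_rank_sum_exact_enumeration_small():
    # all 6 assignments of {1,2,3,4} into two pairs; U=0 and U=4 are the
    # two extreme tables -> two-sided p = 2/6
    u, p = rank_sum_test([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(1 / 3, abs=1e-12)


def test_rank_sum_asymptotic_close_to_exact(rng):
    """Normal-approximation p within 0.01 of the exhaustive-enumeration p
    for 10+10 samples (184756 assignments, vectorised)."""
    idx = np.array(list(itertools.combinations(range(20), 10)))
    for _ in range(3):
        pooled = rng.normal(size=20)
        x, y = pooled[:10], pooled[10:] + 0.8
        u_obs, p_asym = rank_sum_test(x, y)
        values = np.concatenate([x, y])
        ranks = values.argsort().argsort() + 1.0
        u_all = ranks[idx].sum(axis=1) - 55.0  # U of the drawn group
        mu = 50.0
        p_exact = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12))
        assert abs(p_asym - p_exact) < 0.01


def test_protection_table_from_fitted_model(fitted):
    bundle, res = fitted
    table = res.protection["table"]
    counts = res.classification["klass"].value_counts()
    assert table.a + table.b == counts.get("HM", 0)
    assert table.c + table.d == counts.get("NHM", 0)
    # planted protection: hypermethylation is depleted among
    # triplex-positive windows
    assert res.protection["odds_ratio"] < 1.0
    assert res.protection["p_value"] < 1e-3


def test_planted_dbd_is_enriched(fitted):
    bundle, res = fitted
    ts, te = bundle.truth.planted_tfo_interval
    tract_dbds = [d for d in res.dbds if d.rna_start < te and d.rna_end > ts]
    assert tract_dbds
    assert min(d.empirical_p for d in tract_dbds) <= 0.05
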