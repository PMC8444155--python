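"""Classifier: t-test conventions, BH step-up, class partition, recovery."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplexmeth.methylation import (ClassifierParams, bh_fdr, classify_cpgs,
                                     welch_t_test)
from triplexmeth.synthetic import SyntheticConfig, generate_genome, generate_methylation


def test_identical_samples_give_null_result():
    t, p = welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == 0.0
    assert p == 1.0


def test_welch_matches_hand_computation():
    """Welch statistic and Satterthwaite df recomputed from first principles."""
    x = np.array([0.2, 0.3, 0.25, 0.28])
    y = np.array([0.5, 0.55, 0.6, 0.52])
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / 4 + vy / 4
    t_hand = (x.mean() - y.mean()) / math.sqrt(se2)
    df_hand = se2 ** 2 / ((vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3)
    from scipy.stats import t as tdist
    p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
    t, p = welch_t_test(x, y)
    assert t == pytest.approx(t_hand, abs=1e-12)
    assert p == pytest.approx(p_hand, abs=1e-12)
    # swapping the samples negates t and preserves p
    t2, p2 = welch_t_test(y, x)
    assert t2 == pytest.approx(-t, abs=1e-12)
    assert p2 == pytest.approx(p, abs=1e-12)


def test_welch_close_to_exhaustive_permutation_p():
    """The t-test p agrees with the exhaustive label-permutation p on a
    small two-group sample (252 assignments enumerated)."""
    rng = np.random.default_rng(5)
    x = np.round(0.35 + rng.normal(0, 0.05, 5), 4)
    y = np.round(0.30 + rng.normal(0, 0.05, 5), 4)
    t_obs, p = welch_t_test(x, y)
    pooled = np.concatenate([x, y])
    extreme = total = 0
    for idx in itertools.combinations(range(10), 5):
        mask = np.zeros(10, dtype=bool)
        mask[list(idx)] = True
        t_perm, _ = welch_t_test(pooled[mask], pooled[~mask])
        total += 1
        extreme += abs(t_perm) >= abs(t_obs) - 1e-12
    assert total == 252
    assert abs(p - extreme / total) < 0.06


def test_degenerate_variance_conventions():
    t, p = welch_t_test([0.5] * 3, [0.5] * 4)
    assert (t, p) == (0.0, 1.0)
    t, p = welch_t_test([0.8] * 3, [0.2] * 4)
    assert p == 0.0 and t == math.inf
    with pytest.raises(ValueError, match="two observations"):
        welch_t_test([1.0], [1.0, 2.0])


def test_bh_fdr_known_values():
    assert bh_fdr([0.05]).tolist() == [0.05]
    # step-up by hand: q_i = min over j>=i of p_(j)*m/j
    # p=(0.01,0.02,0.03,0.04), m=4 -> all q = 0.04
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([]).size == 0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_fdr_bounds_and_rank_preservation(p):
    q = bh_fdr(p)
    assert np.all(q <= 1.0 + 1e-12)
    assert q.min() >= min(p) - 1e-12
    # step-up preserves the ordering of the input p-values
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


def _toy_beta(rng, n_probes=40, n_mut=5, n_wt=6, shift_first=0):
    base = rng.uniform(0.3, 0.5, n_probes)
    mut = np.clip(base[:, None] + rng.normal(0, 0.04, (n_probes, n_mut)), 0, 1)
    wt = np.clip(base[:, None] + rng.normal(0, 0.04, (n_probes, n_wt)), 0, 1)
    mut[:shift_first] = np.clip(mut[:shift_first] + 0.3, 0, 1)
    cols = [f"m{i}" for i in range(n_mut)] + [f"w{i}" for i in range(n_wt)]
    beta = pd.DataFrame(np.hstack([mut, wt]), columns=cols,
                        index=[f"cg{i:03d}" for i in range(n_probes)])
    groups = pd.Series(["mut"] * n_mut + ["wt"] * n_wt, index=cols)
    return beta, groups


def test_classification_partition_and_sign_convention(rng):
    beta, groups = _toy_beta(rng, shift_first=8)
    out = classify_cpgs(beta, groups)
    assert len(out) == len(beta)
    assert set(out["klass"]) <= {"HM", "NHM", "OTHER"}
    params = ClassifierParams()
    hm = out["klass"] == "HM"
    nhm = out["klass"] == "NHM"
    assert ((out.loc[hm, "q_value"] <= params.fdr_threshold)
            & (out.loc[hm, "delta"] >= params.delta_threshold)).all()
    assert ((out.loc[nhm, "q_value"] > params.fdr_threshold)
            & (out.loc[nhm, "delta"].abs() < params.delta_threshold)).all()
    # delta is mut minus wt: the shifted probes have positive delta
    assert (out["delta"].iloc[:8] > 0.2).all()
    assert set(out.loc[hm, "probe_id"]) == set(beta.index[:8])


def test_classification_invariant_to_sample_order(rng):
    beta, groups = _toy_beta(rng, shift_first=5)
    out1 = classify_cpgs(beta, groups)
    shuffled = beta.sample(frac=1, axis=1, random_state=1)
    out2 = classify_cpgs(shuffled, groups)
    pd.testing.assert_frame_equal(out1, out2)


def test_probes_with_missing_values_are_dropped(rng):
    beta, groups = _toy_beta(rng)
    beta.iloc[3, 2] = np.nan
    out = classify_cpgs(beta, groups)
    assert len(out) == len(beta) - 1
    assert "cg003" not in set(out["probe_id"])


def test_zero_variance_probe_conventions(rng):
    beta, groups = _toy_beta(rng)
    beta.iloc[0, :] = 0.5                      # flat everywhere -> NHM
    beta.iloc[1, :5] = 0.9                      # flat but different means
    beta.iloc[1, 5:] = 0.2
    out = classify_cpgs(beta, groups).set_index("probe_id")
    assert out.loc["cg000", "p_value"] == 1.0
    assert out.loc["cg000", "klass"] == "NHM"
    assert out.loc["cg001", "p_value"] == 0.0
    assert out.loc["cg001", "klass"] == "HM"


def test_group_size_and_label_validation(rng):
    beta, groups = _toy_beta(rng)
    with pytest.raises(ValueError, match="group labels"):
        classify_cpgs(beta.rename(columns={"m0": "zzz"}), groups)
    tiny = groups.copy()
    tiny[:] = "wt"
    tiny["m0"] = "mut"
    with pytest.raises(ValueError, match="two samples"):
        classify_cpgs(beta, tiny)


def test_planted_effect_recovery_small():
    """Sensitivity and empirical FDR on one planted-effect simulation."""
    cfg = SyntheticConfig(n_probes=400, n_chrom=2, chrom_length=120_000, seed=17)
    _, probes = generate_genome(cfg)
    beta, groups, truth = generate_methylation(cfg, probes)
    out = classify_cpgs(beta, groups)
    called = set(out.loc[out["klass"] == "HM", "probe_id"])
    planted = set(truth.hyper_probe_ids)
    assert len(called & planted) / len(planted) >= 0.9
    if called:
        assert len(called - planted) / len(called) <= 0.1


def test_null_simulation_controls_false_positives():
    cfg = SyntheticConfig(n_probes=300, n_chrom=2, chrom_length=100_000,
                          effect_delta=0.0, seed=23)
    _, probes = generate_genome(cfg)
    rates = []
    for seed in range(20):
        beta, groups, truth = generate_methylation(
            dataclasses.replace(cfg, seed=seed), probes)
        assert truth.hyper_probe_ids == frozenset()
        out = classify_cpgs(beta, groups)
        rates.append((out["klass"] == "HM").mean())
    assert np.mean(rates) <= 0.05
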