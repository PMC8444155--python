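"""Generator contracts: determinism, planted signals, layout guarantees."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from triplexmeth.structure import (StructureParams, mask_paired,
                                   pair_probabilities, unpaired_profile)
from triplexmeth.synthetic import (SyntheticConfig, generate_contacts,
                                   generate_genome, generate_lncrna,
                                   generate_methylation, simulate)


def _scan_for_tract(seq: str, width=10, min_hits=7) -> bool:
    """Independent scan: any ``width``-mer with >= 7 G (or >= 7 C)."""
    for base in "GC":
        flags = np.array([c == base for c in seq])
        counts = np.convolve(flags, np.ones(width, dtype=int), mode="valid")
        if counts.size and counts.max() >= min_hits:
            return True
    return False


def test_fixed_seed_gives_identical_outputs(small_cfg):
    a, b = simulate(small_cfg), simulate(small_cfg)
    assert a.genome == b.genome
    assert a.rna == b.rna
    pd.testing.assert_frame_equal(a.probes, b.probes)
    pd.testing.assert_frame_equal(a.beta, b.beta)
    assert a.truth == b.truth


def test_probes_sit_on_cpg_and_tract_planting_is_exact():
    cfg = SyntheticConfig(n_probes=50, frac_protected=0.4, chrom_length=60_000,
                          seed=3)
    genome, probes = generate_genome(cfg)
    assert len(probes) == 50
    n_tract = 0
    for row in probes.itertuples(index=False):
        seq = genome[row.chrom]
        assert seq[row.pos:row.pos + 2] == "CG"
        window = seq[row.pos - 50:row.pos + 50]
        has_tract = _scan_for_tract(window)
        assert has_tract == row.in_purine_tract
        n_tract += has_tract
    assert n_tract == 20  # exactly round(0.4 * 50)


def test_empty_probe_request_still_emits_genome():
    cfg = SyntheticConfig(n_probes=0, seed=1)
    genome, probes = generate_genome(cfg)
    assert len(probes) == 0
    assert all(len(s) == cfg.chrom_length for s in genome.values())


def test_chromosome_too_short_raises_sizing_error():
    with pytest.raises(ValueError, match="too short"):
        generate_genome(SyntheticConfig(n_probes=200, chrom_length=20_000))


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="frac_hyper"):
        SyntheticConfig(frac_hyper=1.5)
    with pytest.raises(ValueError, match="4 samples"):
        SyntheticConfig(n_mut_samples=1, n_wt_samples=2)
    with pytest.raises(ValueError, match="tfo_tract"):
        SyntheticConfig(lnc_length=300, tfo_tract=(200, 400))


def test_planted_hyper_count_is_exact():
    cfg = SyntheticConfig(n_probes=1000, n_chrom=2, chrom_length=250_000,
                          frac_hyper=0.3, seed=7)
    _, probes = generate_genome(cfg)
    beta, groups, truth = generate_methylation(cfg, probes)
    assert len(truth.hyper_probe_ids) == 300
    assert beta.shape == (1000, 186)
    assert (groups == "mut").sum() == 13
    assert (groups == "wt").sum() == 173
    # coupled protection: hyper probes avoid the protected pool
    assert not (truth.hyper_probe_ids & truth.protected_probe_ids)


def test_null_effect_plants_nothing(sim, small_cfg):
    cfg = dataclasses.replace(small_cfg, effect_delta=0.0)
    beta, groups, truth = generate_methylation(cfg, sim.probes)
    assert truth.hyper_probe_ids == frozenset()
    mut = beta.loc[:, (groups == "mut").to_numpy()].mean(axis=1)
    wt = beta.loc[:, (groups == "wt").to_numpy()].mean(axis=1)
    assert (mut - wt).abs().max() < 0.08  # noise only (sd 0.05, n=13)


def test_uncoupled_protection_gives_independent_effects(sim, small_cfg):
    cfg = dataclasses.replace(small_cfg, couple_protection=False, seed=99)
    beta, groups, truth = generate_methylation(cfg, sim.probes)
    # with coupling off the hyper draw ignores protection entirely
    assert truth.hyper_probe_ids & truth.protected_probe_ids


def test_lncrna_planted_structure_contract(sim, small_cfg):
    """Planted stems are called paired (and masked) by the accessibility
    model while the TFO tract stays >= 95% unpaired at the 0.1 cutoff."""
    params = StructureParams()
    P = pair_probabilities(sim.rna, params)
    prof = unpaired_profile(P)
    pp = prof["p_paired"].to_numpy()
    ts, te = sim.truth.planted_tfo_interval
    assert (pp[ts:te] < params.pairing_cutoff).mean() >= 0.95
    masked = mask_paired(sim.rna, prof, params)
    assert np.mean([masked[i] != "N" for i in range(ts, te)]) >= 0.95
    stem_len = 14
    for s, e in sim.truth.hairpins:
        stem_positions = list(range(s, s + stem_len)) + list(range(e - stem_len, e))
        # every stem nucleotide is masked ...
        assert all(masked[i] == "N" for i in stem_positions)
        # ... and interior stem pairs dominate the ensemble
        inner = [P[s + t, e - 1 - t] for t in range(2, stem_len - 2)]
        assert min(inner) > 0.5


def test_lncrna_without_hairpins_stays_open(small_cfg):
    cfg = dataclasses.replace(small_cfg, n_hairpins=0)
    rna, truth = generate_lncrna(cfg)
    assert truth.hairpins == ()
    pp = unpaired_profile(pair_probabilities(rna))["p_paired"].to_numpy()
    assert pp.max() < 0.5


def test_hairpin_layout_error_when_no_room():
    with pytest.raises(ValueError, match="hairpins"):
        generate_lncrna(SyntheticConfig(lnc_length=120, tfo_tract=(4, 116),
                                        n_hairpins=2))


def _interval_gap(a_start, a_end, b_start, b_end):
    return max(a_start - b_end, b_start - a_end, 0)


def test_contact_placement_contract(fitted):
    bundle, res = fitted
    cfg = bundle.cfg
    contacts = bundle.contacts
    assert len(contacts) == cfg.n_true_contacts + cfg.n_decoy_contacts
    wins = res.windows
    pos = wins[wins["triplex_positive"]]
    flank = cfg.contact_flank
    for row in contacts.itertuples(index=False):
        assert row.rna_chrom == bundle.rna_locus[0]
        same = wins[wins["chrom"] == row.dna_chrom]
        gaps_all = [_interval_gap(w.start, w.end, row.dna_start, row.dna_end)
                    for w in same.itertuples(index=False)]
        pos_same = pos[pos["chrom"] == row.dna_chrom]
        gaps_pos = [_interval_gap(w.start, w.end, row.dna_start, row.dna_end)
                    for w in pos_same.itertuples(index=False)]
        if row.id.startswith("true_"):
            assert min(gaps_pos) < flank
        else:
            assert not gaps_all or min(gaps_all) >= 2 * flank


def test_contact_edge_cases(sim, small_cfg):
    wins = pd.DataFrame({"probe_id": ["w1"], "chrom": ["chr1"],
                         "start": [2000], "end": [2100]})
    cfg = dataclasses.replace(small_cfg, n_true_contacts=0, n_decoy_contacts=0)
    contacts, true_ids = generate_contacts(cfg, sim.rna_locus, wins, wins,
                                           sim.chrom_lengths)
    assert len(contacts) == 0 and true_ids == frozenset()
    cfg2 = dataclasses.replace(small_cfg, n_true_contacts=5)
    with pytest.raises(ValueError, match="no triplex-positive windows"):
        generate_contacts(cfg2, sim.rna_locus, wins.iloc[:0], wins,
                          sim.chrom_lengths)
    cfg3 = dataclasses.replace(small_cfg, n_decoy_contacts=100_000)
    with pytest.raises(ValueError, match="insufficient genome space"):
        generate_contacts(cfg3, sim.rna_locus, wins, wins, sim.chrom_lengths)


def test_offsite_contacts_are_filtered_out(sim, small_cfg):
    from triplexmeth.coloc import ColocParams, filter_rna_contacts
    wins = pd.DataFrame({"probe_id": ["w1"], "chrom": ["chr1"],
                         "start": [2000], "end": [2100]})
    cfg = dataclasses.replace(small_cfg, n_true_contacts=4, n_decoy_contacts=6,
                              n_offsite_contacts=5)
    contacts, _ = generate_contacts(cfg, sim.rna_locus, wins, wins,
                                    sim.chrom_lengths)
    assert len(contacts) == 15
    kept = filter_rna_contacts(contacts, ColocParams(rna_locus=sim.rna_locus))
    assert len(kept) == 10
    assert not kept["id"].str.startswith("offsite").any()
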