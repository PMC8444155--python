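import numpy as np
import pytest

import triplexmeth as tm
from triplexmeth.synthetic import SyntheticConfig, attach_contacts, simulate


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Small but fully structured study conditions for fast tests."""
    return SyntheticConfig(n_probes=60, chrom_length=60_000, lnc_length=400, seed=11)


@pytest.fixture(scope="session")
def sim(small_cfg):
    return simulate(small_cfg)


def _fit_with_contacts(cfg):
    """Simulate, fit once to learn triplex positivity, plant contacts
    against it, and fit again with the contact table attached."""
    bundle = simulate(cfg)
    coloc = tm.ColocParams(rna_locus=bundle.rna_locus)
    probes = bundle.probes[["probe_id", "chrom", "pos"]]
    first = tm.TriplexProtectionModel(
        bundle.beta, bundle.groups, probes, bundle.genome, bundle.rna,
        coloc_params=coloc,
    ).fit(seed=cfg.seed)
    attach_contacts(bundle, first.windows[first.windows["triplex_positive"]],
                    first.windows)
    model = tm.TriplexProtectionModel(
        bundle.beta, bundle.groups, probes, bundle.genome, bundle.rna,
        contacts=bundle.contacts, coloc_params=coloc,
    )
    return bundle, model.fit(seed=cfg.seed)


@pytest.fixture(scope="session")
def fitted(small_cfg):
    """(bundle, results) of a full fit on the small fixture, with planted
    contacts included."""
    return _fit_with_contacts(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
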