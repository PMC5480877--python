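import dataclasses

import pytest

import rodsig

#: the fixed seed used for every stochastic check in the suite
SEED = 0


def small_config(**overrides) -> rodsig.SimConfig:
    """A reduced generator configuration for fast structural tests."""
    base = dict(
        seed=SEED, n_genes_single=12, n_genes_two_tss=6, n_genes_three_tss=2,
        n_planted_sites=4, n_chroms=2,
    )
    base.update(overrides)
    return rodsig.SimConfig(**base)


@pytest.fixture(scope="session")
def sim_default():
    """Full default-condition generator run (the study cohort structure)."""
    return rodsig.simulate(seed=SEED)


@pytest.fixture(scope="session")
def fm_default(sim_default):
    return rodsig.build_feature_matrix(
        sim_default.tss_records, sim_default.tracks,
        chrom_sizes=sim_default.chrom_sizes,
    )


@pytest.fixture(scope="session")
def clf_default(fm_default):
    return rodsig.RodSignatureClassifier().fit(fm_default)


@pytest.fixture(scope="session")
def sim_small():
    return rodsig.simulate(small_config())


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
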