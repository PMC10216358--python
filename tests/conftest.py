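import numpy as np
import pytest

from vgerp import (
    ERPComponent,
    EvalProtocol,
    SyntheticConfig,
    extract_features,
    generate_cohort,
    preprocess_cohort,
)

THREE_CHANNELS = ("Fz", "Cz", "Pz")
TWO_CONDITIONS = ("AN", "AO")


def tiny_config(**overrides) -> SyntheticConfig:
    """A small two-group cohort used across tests: 6+6 subjects, 3 channels,
    2 conditions, 8 trials, a strong late-positive deflection diminished in
    the patient group."""
    base = dict(
        n_subjects_per_group={"RNE": 6, "AD": 6},
        n_trials=8,
        channels=THREE_CHANNELS,
        conditions=TWO_CONDITIONS,
        erp_components=(
            ERPComponent(0.6, 0.12, 8.0, {"AD": 0.1}),
            ERPComponent(0.4, 0.10, -5.0, {"AD": 0.2}),
        ),
        noise_sd=10.0,
        seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def null_config(**overrides) -> SyntheticConfig:
    """Same layout, no group-dependent effects."""
    overrides.setdefault("erp_components", (ERPComponent(0.6, 0.12, 8.0),))
    return tiny_config(**overrides)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_averaged(tiny_cohort):
    return preprocess_cohort(tiny_cohort, bands=["raw", "delta"])


@pytest.fixture(scope="session")
def tiny_features(tiny_averaged):
    feats, ref = extract_features(tiny_averaged)
    return feats


@pytest.fixture
def fast_protocol():
    return EvalProtocol(n_repeats=20, seed=5)


def random_connected_graph(rng, n_max=14, p_range=(0.2, 0.9)):
    """A random connected simple graph for approximation-vs-oracle checks."""
    import networkx as nx

    while True:
        n = int(rng.integers(2, n_max + 1))
        g = nx.gnp_random_graph(n, float(rng.uniform(*p_range)),
                                seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g
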