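import numpy as np
import pytest

import diaryvar as dv


@pytest.fixture(scope="session")
def sparse3():
    """A sparse 3-variable truth: two cross-lagged edges, one contemporaneous."""
    structure = dv.GraphStructure(3, {(1, 0), (0, 2)}, {frozenset((0, 1))})
    beta, sigma = dv.make_parameters(
        structure,
        effect_range=(0.3, 0.4),
        partial_corr_range=(0.25, 0.35),
        seed=11,
    )
    return structure, beta, sigma


@pytest.fixture(scope="session")
def panel3(sparse3):
    structure, beta, sigma = sparse3
    return dv.simulate_panel(
        dv.SimulationSpec(structure, beta, sigma, n_subjects=30, n_times=100, seed=21)
    )


@pytest.fixture(scope="session")
def design3(panel3):
    return dv.lagged_design(panel3)


@pytest.fixture(scope="session")
def sparse4():
    structure = dv.GraphStructure(
        4, {(1, 0), (0, 2)}, {frozenset((0, 1)), frozenset((2, 3))}
    )
    beta, sigma = dv.make_parameters(
        structure,
        effect_range=(0.3, 0.4),
        partial_corr_range=(0.25, 0.35),
        seed=13,
    )
    return structure, beta, sigma


@pytest.fixture(scope="session")
def panel4(sparse4):
    structure, beta, sigma = sparse4
    return dv.simulate_panel(
        dv.SimulationSpec(structure, beta, sigma, n_subjects=16, n_times=112, seed=23)
    )


@pytest.fixture(scope="session")
def design4(panel4):
    return dv.lagged_design(panel4)


@pytest.fixture
def random_panel():
    """Factory for small random fully observed panels."""

    def make(K=3, T=8, n=2, seed=0, groups=False, missing=0.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(K, T, n))
        mask = np.ones((K, T, n), dtype=bool)
        if missing > 0:
            mask = rng.random((K, T, n)) >= missing
            values = np.where(mask, values, np.nan)
        labels = None
        if groups:
            labels = {f"s{k}": ("A" if k % 2 == 0 else "B") for k in range(K)}
        return dv.PanelTimeSeries(
            subject_ids=[f"s{k}" for k in range(K)],
            variable_names=[f"v{i}" for i in range(n)],
            values=values,
            observed_mask=mask,
            group_labels=labels,
        )

    return make
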