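"""Shared fixtures: quadrature grids, hand-built items, and synthetic datasets."""

import numpy as np
import pytest

from sercat import (
    BankSpec,
    ItemBank,
    ItemParameters,
    PopulationSpec,
    QuadratureGrid,
    StoppingRules,
    make_reference_dataset,
)


@pytest.fixture(scope="session")
def grid() -> QuadratureGrid:
    """Default EAP support: 81 nodes on [-6, 6], standard-normal prior."""
    return QuadratureGrid.standard_normal()


@pytest.fixture(scope="session")
def dense_grid() -> QuadratureGrid:
    """Independent dense-grid numerical-integration oracle support."""
    return QuadratureGrid.standard_normal(n_nodes=10001)


@pytest.fixture
def binary_item() -> ItemParameters:
    return ItemParameters("bin", alpha=1.4, betas=(0.5,))


@pytest.fixture
def poly_item() -> ItemParameters:
    """Four-category item with alpha=2 and thresholds (-1, 0, 1)."""
    return ItemParameters("poly", alpha=2.0, betas=(-1.0, 0.0, 1.0))


@pytest.fixture
def small_bank() -> ItemBank:
    """Five hand-placed 5-category items spanning theta in about [-1, 2]."""
    items = tuple(
        ItemParameters(f"q{i}", alpha=a, betas=tuple(b + k * 0.6 for k in range(4)))
        for i, (a, b) in enumerate([(1.2, -1.0), (1.5, -0.4), (1.8, 0.2), (1.3, 0.8), (1.6, 1.2)])
    )
    return ItemBank(items=items)


def random_item(rng: np.random.Generator, item_id: str = "it") -> ItemParameters:
    """A random valid GRM item: 2-5 categories, alpha in [0.5, 2.5]."""
    n_cat = int(rng.integers(2, 6))
    alpha = float(rng.uniform(0.5, 2.5))
    betas = np.sort(rng.normal(0.3, 1.0, size=n_cat - 1))
    betas = np.maximum.accumulate(betas + np.arange(n_cat - 1) * 1e-3)
    return ItemParameters(item_id, alpha, tuple(betas))


def random_response_set(rng: np.random.Generator, max_items: int = 12):
    """A random list of (item, category) pairs for EAP oracle checks."""
    n = int(rng.integers(1, max_items + 1))
    out = []
    for i in range(n):
        item = random_item(rng, f"it{i}")
        out.append((item, int(rng.integers(0, item.n_categories))))
    return out


@pytest.fixture(scope="session")
def small_dataset(grid):
    """Fifty recorded traces from the default synthetic world (floor-heavy)."""
    bank, traces, floor_flags = make_reference_dataset(
        BankSpec(seed=7),
        PopulationSpec(n_respondents=50, floor_proportion=0.2, seed=8),
        StoppingRules(),
        grid,
    )
    return bank, traces, floor_flags
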