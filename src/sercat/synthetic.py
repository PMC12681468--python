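"""Synthetic item banks, theta populations with a floor mass, and response data.

The generator emulates the structure of pediatric symptom item banks
administered as CAT in a general-population setting: 14-15 five-category
items whose thresholds sit in the symptomatic (high-theta) region, and a
respondent population in which a meaningful fraction reports no symptoms at
all (the floor).  The floor is generated as a low-theta normal component
(default N(-2.5, 0.3)) rather than a literal point mass, so all-lowest
response patterns arise probabilistically, as in real data.

Named presets mirror the two published bank profiles: "anxiety-like"
(15 items, discriminations in [1.09, 1.89]) and "depression-like"
(14 items, discriminations in [0.74, 2.53]).

All randomness flows through explicit integer seeds carried in the spec
objects; there is no global random state, so every artifact is reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Tuple

import numpy as np

from .engine import CatTrace, StoppingRules, run_cat
from .grm import ItemBank, ItemParameters, QuadratureGrid

__all__ = [
    "BankSpec",
    "PopulationSpec",
    "PRESETS",
    "bank_spec_preset",
    "generate_item_bank",
    "generate_thetas",
    "generate_responses",
    "make_reference_dataset",
]

logger = logging.getLogger(__name__)

#: Minimal separation enforced between coincident thresholds after sorting.
_MIN_THRESHOLD_SEP = 1e-3


@dataclasses.dataclass(frozen=True)
class BankSpec:
    """Recipe for a synthetic item bank.

    Thresholds are drawn i.i.d. from N(threshold_center, threshold_span^2) and
    sorted, concentrating item information in the symptomatic region.  The
    defaults place the informative range roughly on theta in [0, 2], well
    above the floor component of :class:`PopulationSpec`, so respondents at
    the floor produce all-lowest patterns with high probability — the
    mechanism behind the floor effect the package studies.
    """

    n_items: int = 15
    alpha_range: Tuple[float, float] = (1.09, 1.89)
    n_categories: int = 5
    threshold_center: float = 1.0
    threshold_span: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.alpha_range
        if not (0 < lo < hi):
            raise ValueError("alpha_range must satisfy 0 < low < high")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if not self.threshold_span > 0:
            raise ValueError("threshold_span must be positive")


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a theta population: a main component plus a floor component.

    Each respondent is floor with probability ``floor_proportion``; floor
    thetas come from N(floor_location, floor_sd^2) (defaults -2.5, 0.3) and
    the rest from N(main_mean, main_sd^2) (defaults 0, 1).  The default floor
    proportion (7%) matches the order of magnitude of published floor
    prevalences for pediatric symptom banks.
    """

    n_respondents: int = 2000
    floor_proportion: float = 0.07
    floor_location: float = -2.5
    floor_sd: float = 0.3
    main_mean: float = 0.0
    main_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor_proportion < 1.0):
            raise ValueError("floor_proportion must lie in [0, 1)")
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be >= 0")
        if self.floor_sd < 0:
            raise ValueError("floor_sd must be non-negative")
        if not self.main_sd > 0:
            raise ValueError("main_sd must be positive")


PRESETS = {
    "anxiety-like": dict(n_items=15, alpha_range=(1.09, 1.89)),
    "depression-like": dict(n_items=14, alpha_range=(0.74, 2.53)),
}


def bank_spec_preset(name: str, **overrides: object) -> BankSpec:
    """A :class:`BankSpec` from a named preset, with optional field overrides."""
    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose one of {sorted(PRESETS)}") from None
    base.update(overrides)
    return BankSpec(**base)  # type: ignore[arg-type]


def generate_item_bank(spec: BankSpec) -> ItemBank:
    """Draw a synthetic GRM item bank; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_items))
    alphas = rng.uniform(*spec.alpha_range, size=spec.n_items)
    items = []
    for i in range(spec.n_items):
        betas = np.sort(
            rng.normal(spec.threshold_center, spec.threshold_span, size=spec.n_categories - 1)
        )
        for k in range(1, len(betas)):
            if betas[k] <= betas[k - 1]:
                logger.warning(
                    "item %d: coincident thresholds jittered by %.0e", i + 1, _MIN_THRESHOLD_SEP
                )
                betas[k] = betas[k - 1] + _MIN_THRESHOLD_SEP
        items.append(
            ItemParameters(
                item_id=f"item_{i + 1:0{width}d}",
                alpha=float(alphas[i]),
                betas=tuple(betas),
            )
        )
    return ItemBank(items=tuple(items), metadata={"spec": dataclasses.asdict(spec)})


def generate_thetas(spec: PopulationSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Draw thetas and their floor flags; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    is_floor = rng.random(n) < spec.floor_proportion
    floor_draw = rng.normal(spec.floor_location, spec.floor_sd, size=n)
    main_draw = rng.normal(spec.main_mean, spec.main_sd, size=n)
    return np.where(is_floor, floor_draw, main_draw), is_floor


def generate_responses(bank: ItemBank, thetas: np.ndarray, seed: int) -> np.ndarray:
    """A full response matrix (respondent x every bank item), 0-based categories.

    Each cell is a single multinomial draw from the item's GRM category
    probabilities at the respondent's theta, via inverse-CDF sampling on the
    cumulative curves; deterministic under ``seed``.
    """
    from .grm import _cumulative  # internal: cumulative category curves

    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(thetas)
    out = np.empty((n, len(bank)), dtype=np.int64)
    u = rng.random((n, len(bank)))
    for j, item in enumerate(bank):
        pstar = _cumulative(item, thetas, 1.0)  # (n, K-1)
        # category index = number of cumulative curves still above 1-u
        out[:, j] = np.sum(pstar > (1.0 - u[:, j])[:, None], axis=1)
    return out


def make_reference_dataset(
    bank_spec: BankSpec = BankSpec(),
    population_spec: PopulationSpec = PopulationSpec(),
    rules: StoppingRules = StoppingRules(),
    grid: Optional[QuadratureGrid] = None,
    response_seed: Optional[int] = None,
) -> Tuple[ItemBank, Tuple[CatTrace, ...], np.ndarray]:
    """Bank + recorded CAT traces + floor flags: a stand-in for extracted CAT data.

    Generates the bank and population, samples a full response matrix, then
    administers a CAT per respondent under ``rules`` (default 4/12/0.32, no
    SER), yielding recorded traces structurally equivalent to portal-extracted
    data.  ``response_seed`` defaults to ``population_spec.seed + 1``.
    """
    if grid is None:
        grid = QuadratureGrid.standard_normal()
    bank = generate_item_bank(bank_spec)
    thetas, floor_flags = generate_thetas(population_spec)
    if response_seed is None:
        response_seed = population_spec.seed + 1
    matrix = generate_responses(bank, thetas, response_seed)
    ids = bank.item_ids
    width = max(4, len(str(max(population_spec.n_respondents, 1))))
    traces = []
    for i in range(population_spec.n_respondents):
        responder = dict(zip(ids, (int(c) for c in matrix[i])))
        traces.append(
            run_cat(responder, bank, rules, grid, respondent_id=f"r{i + 1:0{width}d}")
        )
    return bank, tuple(traces), floor_flags
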