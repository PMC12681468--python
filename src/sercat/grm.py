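"""Graded response model (GRM) kernel.

Everything else in the package is built on the four quantities defined here:
category response probabilities under Samejima's graded response model,
Fisher item/test information, the information <-> standard-error identity
SE = 1/sqrt(I), and Bayesian EAP (expected a posteriori) trait scoring on a
fixed quadrature grid.

Conventions
-----------
* The latent trait ``theta`` is on the calibration metric (mean 0, SD 1).
* The logistic scaling constant D defaults to 1.0 (pure logistic metric, the
  PROMIS convention); it is exposed as the ``d`` keyword everywhere it enters.
* Response categories are 0-based integers internally (0 .. K-1); file I/O
  converts from the 1-based convention used on disk.
* T-scores are the linear rescaling ``theta * 10 + 50``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Iterator, Mapping, Sequence, Tuple

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ItemParameters",
    "ItemBank",
    "QuadratureGrid",
    "ThetaEstimate",
    "Response",
    "category_probabilities",
    "item_information",
    "test_information",
    "se_from_information",
    "se_from_reliability",
    "eap_estimate",
    "tscore",
    "theta_from_tscore",
]


@dataclasses.dataclass(frozen=True)
class ItemParameters:
    """One calibrated GRM item: discrimination ``alpha`` and ordered thresholds ``betas``.

    A K-category item carries K-1 strictly increasing thresholds; ``betas[k]``
    is the trait level at which the cumulative probability of responding in
    category k+1 or above equals one half.
    """

    item_id: str
    alpha: float
    betas: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if not self.item_id:
            raise ValueError("item_id must be a non-empty string")
        if not math.isfinite(self.alpha) or self.alpha <= 0.0:
            raise ValueError(f"item {self.item_id!r}: alpha must be positive, got {self.alpha}")
        if len(self.betas) < 1:
            raise ValueError(f"item {self.item_id!r}: at least one threshold required")
        if any(not math.isfinite(b) for b in self.betas):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        if any(b1 >= b2 for b1, b2 in zip(self.betas, self.betas[1:])):
            raise ValueError(f"item {self.item_id!r}: thresholds must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return len(self.betas) + 1


@dataclasses.dataclass(frozen=True)
class ItemBank:
    """A calibrated pool of items a CAT selects from."""

    items: Tuple[ItemParameters, ...]
    metadata: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) == 0:
            raise ValueError("an item bank must contain at least one item")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids in bank: {dupes}")
        object.__setattr__(self, "_by_id", {it.item_id: it for it in self.items})

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id  # type: ignore[attr-defined]

    def __getitem__(self, item_id: str) -> ItemParameters:
        try:
            return self._by_id[item_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"item {item_id!r} not in bank") from None

    @property
    def item_ids(self) -> Tuple[str, ...]:
        return tuple(it.item_id for it in self.items)


@dataclasses.dataclass(frozen=True, eq=False)
class QuadratureGrid:
    """Fixed quadrature support for EAP scoring: theta nodes plus prior weights.

    Weights are normalized to sum to one on construction; the default grid is
    81 equally spaced nodes on [-6, 6] weighted by the standard-normal density
    (covering the T-score range 10-110).
    """

    nodes: np.ndarray
    prior_weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.prior_weights, dtype=float)
        if nodes.ndim != 1 or weights.shape != nodes.shape:
            raise ValueError("nodes and prior_weights must be 1-D arrays of equal length")
        if len(nodes) < 2:
            raise ValueError("at least two quadrature nodes required")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
            raise ValueError("prior weights must be positive and finite")
        weights = weights / weights.sum()
        nodes.flags.writeable = False
        weights.flags.writeable = False
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "prior_weights", weights)

    @classmethod
    def standard_normal(
        cls,
        n_nodes: int = 81,
        lower: float = -6.0,
        upper: float = 6.0,
        mean: float = 0.0,
        sd: float = 1.0,
    ) -> "QuadratureGrid":
        nodes = np.linspace(lower, upper, n_nodes)
        return cls(nodes=nodes, prior_weights=norm.pdf(nodes, loc=mean, scale=sd))


@dataclasses.dataclass(frozen=True)
class ThetaEstimate:
    """An EAP trait estimate: posterior mean ``theta`` and posterior SD ``se``."""

    theta: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be positive, got {self.se}")

    @property
    def t_score(self) -> float:
        return self.theta * 10.0 + 50.0

    @property
    def t_se(self) -> float:
        return self.se * 10.0


#: A scored response: the item answered and the 0-based category selected.
Response = Tuple[ItemParameters, int]


def _cumulative(item: ItemParameters, theta: np.ndarray, d: float) -> np.ndarray:
    """P*_k(theta) = logistic(d * alpha * (theta - beta_k)), shape (..., K-1)."""
    betas = np.asarray(item.betas)
    return expit(d * item.alpha * (theta[..., None] - betas))


def category_probabilities(
    item: ItemParameters, theta: float | np.ndarray, d: float = 1.0
) -> np.ndarray:
    """GRM category response probabilities at ``theta``.

    Returns an array of shape (K,) for scalar theta or (n, K) for an array,
    where ``P_k = P*_{k-1} - P*_k`` with boundary curves P*_0 = 1, P*_K = 0.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise ValueError("theta must be finite")
    pstar = _cumulative(item, theta_arr, d)
    pad = np.broadcast_to(np.ones(1), pstar.shape[:-1] + (1,))
    zero = np.broadcast_to(np.zeros(1), pstar.shape[:-1] + (1,))
    bounded = np.concatenate([pad, pstar, zero], axis=-1)
    return bounded[..., :-1] - bounded[..., 1:]


def item_information(item: ItemParameters, theta: float | np.ndarray, d: float = 1.0) -> float | np.ndarray:
    """Samejima GRM Fisher information of one item at ``theta``.

    I(theta) = sum_k (d*alpha)^2 * (w_{k-1} - w_k)^2 / P_k with
    w_k = P*_k (1 - P*_k) and w_0 = w_K = 0.  For a binary item this reduces
    algebraically to (d*alpha)^2 * p * q.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise ValueError("theta must be finite")
    a = d * item.alpha
    pstar = _cumulative(item, theta_arr, d)
    w = pstar * (1.0 - pstar)
    zero = np.broadcast_to(np.zeros(1), w.shape[:-1] + (1,))
    w_pad = np.concatenate([zero, w, zero], axis=-1)
    num = a * a * (w_pad[..., :-1] - w_pad[..., 1:]) ** 2
    probs = category_probabilities(item, theta_arr, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0.0, num / probs, 0.0)
    info = terms.sum(axis=-1)
    return float(info) if np.isscalar(theta) or np.ndim(theta) == 0 else info


def test_information(
    items: Sequence[ItemParameters] | Iterable[ItemParameters],
    theta: float | np.ndarray,
    d: float = 1.0,
) -> float | np.ndarray:
    """Total Fisher information of a set of items: the sum of item informations."""
    items = tuple(items)
    if len(items) == 0:
        raise ValueError("test_information requires a non-empty item set")
    total = item_information(items[0], theta, d)
    for it in items[1:]:
        total = total + item_information(it, theta, d)
    return total


def se_from_information(info: float) -> float:
    """Standard error of theta from test information: SE = 1 / sqrt(I)."""
    if not (math.isfinite(info) and info > 0):
        raise ValueError(f"information must be positive, got {info}")
    return 1.0 / math.sqrt(info)


def se_from_reliability(sigma: float, r_xx: float) -> float:
    """SE implied by a classical reliability: SE = sigma * sqrt(1 - r_xx).

    With sigma = 1 and r_xx = 0.90 this gives 0.316..., the origin of the
    conventional 0.32 SE stopping threshold.
    """
    if not (math.isfinite(sigma) and sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (0.0 <= r_xx <= 1.0):
        raise ValueError(f"reliability must lie in [0, 1], got {r_xx}")
    return sigma * math.sqrt(1.0 - r_xx)


def posterior_moments(grid: QuadratureGrid, posterior: np.ndarray) -> ThetaEstimate:
    """Mean and SD of an (unnormalized) posterior tabulated on ``grid``."""
    total = float(posterior.sum())
    if not (math.isfinite(total) and total > 0.0):
        raise ValueError("posterior is numerically zero everywhere; responses are "
                         "inconsistent with the quadrature support")
    mean = float((posterior @ grid.nodes) / total)
    var = float((posterior @ (grid.nodes - mean) ** 2) / total)
    return ThetaEstimate(theta=mean, se=math.sqrt(var))


def eap_estimate(
    responses: Sequence[Response],
    grid: QuadratureGrid,
    d: float = 1.0,
) -> ThetaEstimate:
    """EAP (expected a posteriori) trait estimate from scored responses.

    The posterior over the grid nodes is the prior weight times the product of
    the selected-category probabilities; ``theta`` is the posterior mean and
    ``se`` the posterior SD.  An empty response list returns the prior mean/SD.
    """
    posterior = grid.prior_weights.copy()
    for item, category in responses:
        if not (isinstance(category, (int, np.integer)) and 0 <= category < item.n_categories):
            raise ValueError(
                f"category {category!r} out of range for item {item.item_id!r} "
                f"(0..{item.n_categories - 1})"
            )
        posterior *= category_probabilities(item, grid.nodes, d)[:, category]
    return posterior_moments(grid, posterior)


def tscore(theta: float) -> float:
    """T-score metric: theta * 10 + 50 (reference population mean 50, SD 10)."""
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    return theta * 10.0 + 50.0


def theta_from_tscore(t: float) -> float:
    """Inverse of :func:`tscore`."""
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    return (t - 50.0) / 10.0
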