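"""Adaptive test administration.

Implements maximum-information item selection, the combined stopping rules
(minimum/maximum item count, SE threshold, SER threshold) and full CAT runs
against a response source.

Stopping rules
--------------
The default configuration is the pediatric PROMIS convention: a minimum of 4
and a maximum of 12 items, stopping early once SE(theta) <= 0.32 (reliability
0.90).  The optional standard-error-reduction (SER) rule additionally stops
when the improvement in SE between consecutive steps,

    SER_t = SE_{t-1} - SE_t,

falls below a threshold: extra items are no longer buying precision.  The
reduction is stored with a positive sign when precision improves; a negative
reduction (SE worsened) also triggers the stop.  Rules are evaluated after
every response in a fixed order so the recorded stop reason is reproducible:
min-items gate, max-items, SE threshold, SER threshold, item exhaustion.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Optional, Sequence, Tuple

from .grm import ItemBank, ItemParameters, QuadratureGrid, eap_estimate, item_information

__all__ = [
    "StoppingRules",
    "CatStep",
    "CatTrace",
    "ItemsExhaustedError",
    "STOP_MAX_ITEMS",
    "STOP_SE_THRESHOLD",
    "STOP_SER_THRESHOLD",
    "STOP_ITEMS_EXHAUSTED",
    "STOP_REASONS",
    "select_next_item",
    "first_item",
    "ser_reduction",
    "should_stop",
    "run_cat",
    "efficiency",
]

STOP_MAX_ITEMS = "max_items"
STOP_SE_THRESHOLD = "se_threshold"
STOP_SER_THRESHOLD = "ser_threshold"
STOP_ITEMS_EXHAUSTED = "items_exhausted"
STOP_REASONS = (STOP_MAX_ITEMS, STOP_SE_THRESHOLD, STOP_SER_THRESHOLD, STOP_ITEMS_EXHAUSTED)


class ItemsExhaustedError(RuntimeError):
    """Raised when item selection is asked for and no unadministered items remain."""


@dataclasses.dataclass(frozen=True)
class StoppingRules:
    """CAT stopping configuration.

    ``se_threshold`` and ``ser_threshold`` may be ``None`` to disable the
    corresponding rule; the defaults reproduce the 4/12/0.32 configuration
    with no SER rule.
    """

    min_items: int = 4
    max_items: int = 12
    se_threshold: Optional[float] = 0.32
    ser_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_items < 1:
            raise ValueError("min_items must be >= 1")
        if self.max_items < self.min_items:
            raise ValueError("max_items must be >= min_items")
        if self.se_threshold is not None and not self.se_threshold > 0:
            raise ValueError("se_threshold must be positive when present")
        if self.ser_threshold is not None and not self.ser_threshold > 0:
            raise ValueError("ser_threshold must be positive when present")

    def with_ser(self, ser_threshold: Optional[float]) -> "StoppingRules":
        """A copy of these rules with the SER threshold replaced."""
        return dataclasses.replace(self, ser_threshold=ser_threshold)


@dataclasses.dataclass(frozen=True)
class CatStep:
    """One administered item within a trace, with the post-response estimate."""

    step: int
    item_id: str
    category: int  # 0-based
    theta: float
    se: float
    ser: Optional[float]  # SE_{t-1} - SE_t; None at the first step

    @property
    def t_score(self) -> float:
        return self.theta * 10.0 + 50.0


@dataclasses.dataclass(frozen=True)
class CatTrace:
    """A completed CAT administration for one respondent."""

    respondent_id: str
    steps: Tuple[CatStep, ...]
    stop_reason: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if len(self.steps) == 0:
            raise ValueError("a trace must contain at least one step")
        if self.stop_reason not in STOP_REASONS:
            raise ValueError(f"unknown stop_reason {self.stop_reason!r}")
        ids = [s.item_id for s in self.steps]
        if len(set(ids)) != len(ids):
            raise ValueError(f"trace {self.respondent_id!r}: repeated item ids")

    @property
    def n_items(self) -> int:
        return len(self.steps)

    @property
    def final(self) -> CatStep:
        return self.steps[-1]

    @property
    def item_ids(self) -> Tuple[str, ...]:
        return tuple(s.item_id for s in self.steps)

    @property
    def categories(self) -> Tuple[int, ...]:
        return tuple(s.category for s in self.steps)


def select_next_item(
    bank: ItemBank,
    administered: Sequence[str] | set,
    theta: float,
    d: float = 1.0,
) -> str:
    """The unadministered item with maximum Fisher information at ``theta``.

    Ties are broken toward the lexicographically smallest item id so the
    selection is fully deterministic.
    """
    administered = set(administered)
    candidates = [it for it in bank if it.item_id not in administered]
    if not candidates:
        raise ItemsExhaustedError("all bank items have been administered")
    best = min(candidates, key=lambda it: (-item_information(it, theta, d), it.item_id))
    return best.item_id


def first_item(bank: ItemBank, start_theta: float = 0.0, d: float = 1.0) -> str:
    """The opening item: most informative near the prior mean."""
    return select_next_item(bank, set(), start_theta, d)


def ser_reduction(previous_se: float, current_se: float) -> float:
    """Standard-error reduction between consecutive steps (positive = improved)."""
    if not previous_se > 0 or not current_se > 0:
        raise ValueError("standard errors must be positive")
    return previous_se - current_se


def should_stop(
    n_items: int,
    current_se: float,
    last_ser: Optional[float],
    rules: StoppingRules,
    items_remaining: bool,
) -> Tuple[bool, Optional[str]]:
    """Evaluate the stopping rules after ``n_items`` administered items.

    Fixed precedence: (1) never stop below ``min_items`` unless no items
    remain; (2) ``max_items``; (3) SE threshold; (4) SER threshold (needs at
    least two estimates); (5) item exhaustion.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if n_items < rules.min_items:
        if not items_remaining:
            return True, STOP_ITEMS_EXHAUSTED
        return False, None
    if n_items >= rules.max_items:
        return True, STOP_MAX_ITEMS
    if rules.se_threshold is not None and current_se <= rules.se_threshold:
        return True, STOP_SE_THRESHOLD
    if (
        rules.ser_threshold is not None
        and last_ser is not None
        and n_items >= 2
        and last_ser < rules.ser_threshold
    ):
        return True, STOP_SER_THRESHOLD
    if not items_remaining:
        return True, STOP_ITEMS_EXHAUSTED
    return False, None


def run_cat(
    responder: Callable[[str], int] | Mapping[str, int],
    bank: ItemBank,
    rules: StoppingRules = StoppingRules(),
    grid: Optional[QuadratureGrid] = None,
    respondent_id: str = "r0",
    start_theta: float = 0.0,
    d: float = 1.0,
) -> CatTrace:
    """Administer a full CAT against a response source.

    ``responder`` maps an item id to a 0-based category, either as a mapping
    or a callable.  The run is deterministic given its inputs: items are
    selected by maximum information at the current EAP estimate, the estimate
    is refreshed after every response, and the stopping rules are evaluated in
    the fixed :func:`should_stop` order.
    """
    if grid is None:
        grid = QuadratureGrid.standard_normal()
    answer: Callable[[str], int]
    if isinstance(responder, Mapping):
        mapping = responder
        def answer(item_id: str) -> int:
            try:
                return mapping[item_id]
            except KeyError:
                raise KeyError(f"responder has no answer for item {item_id!r}") from None
    else:
        answer = responder

    responses: list[Tuple[ItemParameters, int]] = []
    steps: list[CatStep] = []
    administered: set[str] = set()
    theta = start_theta
    prev_se: Optional[float] = None
    while True:
        item_id = select_next_item(bank, administered, theta, d)
        item = bank[item_id]
        category = answer(item_id)
        if not 0 <= int(category) < item.n_categories:
            raise ValueError(
                f"responder returned category {category!r} for item {item_id!r} "
                f"(valid: 0..{item.n_categories - 1})"
            )
        responses.append((item, int(category)))
        administered.add(item_id)
        estimate = eap_estimate(responses, grid, d)
        t = len(responses)
        ser = ser_reduction(prev_se, estimate.se) if t >= 2 else None
        steps.append(
            CatStep(step=t, item_id=item_id, category=int(category),
                    theta=estimate.theta, se=estimate.se, ser=ser)
        )
        remaining = len(administered) < len(bank)
        stop, reason = should_stop(t, estimate.se, ser, rules, remaining)
        if stop:
            assert reason is not None
            return CatTrace(respondent_id=respondent_id, steps=tuple(steps), stop_reason=reason)
        theta = estimate.theta
        prev_se = estimate.se


def efficiency(se: float, n_items: int) -> float:
    """Measurement efficiency: test information per administered item, (1/SE^2)/n."""
    if not se > 0:
        raise ValueError("se must be positive")
    if not n_items >= 1:
        raise ValueError("n_items must be >= 1")
    return (1.0 / (se * se)) / n_items
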