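"""SER threshold grid search and the differential efficiency function.

The optimization procedure: replay every recorded trace under the reference
rules plus a candidate SER threshold, for every threshold on a fine grid
(default 0.01 to 0.20 in steps of 0.001, 191 values); summarize the four
evaluation outcomes per threshold, overall and within the floor / non-floor
subgroups; take first differences of mean efficiency across successive
thresholds (the differential function of efficiency, with the first entry
measured against the no-SER baseline, i.e. the gain from introducing the rule
at all); and select a threshold at a peak of that function.

Two selection policies are provided: ``highest_peak`` takes the largest
differential anywhere (which in floor-heavy populations is typically the
introduction point itself), and ``highest_peak_after_introduction`` (the
default) takes the largest peak beyond the first grid point — the threshold at
which efficiency jumps most once the rule already exists, typically where
floor respondents collapse to the minimum test length.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Sequence, Tuple

import numpy as np

from .engine import CatTrace, StoppingRules
from .grm import ItemBank, QuadratureGrid
from .posthoc import OutcomeSummary, _stop_step, _summarize, prefix_estimates

__all__ = [
    "SerGridResult",
    "DifferentialSeries",
    "POLICIES",
    "ser_grid",
    "evaluate_grid",
    "differential_efficiency",
    "optimal_ser",
]

POLICIES = ("highest_peak", "highest_peak_after_introduction")


@dataclasses.dataclass(frozen=True)
class SerGridResult:
    """Outcome summaries per SER threshold, overall and by floor subgroup."""

    thresholds: Tuple[float, ...]
    overall: Tuple[OutcomeSummary, ...]
    floor: Tuple[OutcomeSummary, ...]
    nonfloor: Tuple[OutcomeSummary, ...]
    baseline: OutcomeSummary
    baseline_floor: OutcomeSummary
    baseline_nonfloor: OutcomeSummary
    floor_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if any(t2 <= t1 for t1, t2 in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not len(self.thresholds) == len(self.overall) == len(self.floor) == len(self.nonfloor):
            raise ValueError("one summary triple required per threshold")


@dataclasses.dataclass(frozen=True)
class DifferentialSeries:
    """First differences of mean efficiency across the SER grid, with peaks.

    ``delta_efficiency[0]`` is the efficiency at the smallest threshold minus
    the no-SER baseline efficiency; subsequent entries are differences between
    consecutive thresholds.  ``peaks`` are the strict local maxima (a plateau
    is represented by its smallest threshold), sorted by delta descending.
    """

    thresholds: Tuple[float, ...]
    delta_efficiency: Tuple[float, ...]
    peaks: Tuple[Tuple[float, float], ...]  # (threshold, delta)

    def __post_init__(self) -> None:
        if len(self.delta_efficiency) != len(self.thresholds):
            raise ValueError("one delta per threshold required")


def ser_grid(start: float = 0.01, stop: float = 0.20, step: float = 0.001) -> Tuple[float, ...]:
    """Arithmetic SER threshold grid, rounded to the step's decimal precision.

    The default reproduces 0.01, 0.011, ..., 0.200 (191 values).  ``stop`` is
    included when the span is an integer multiple of ``step``.
    """
    if not (start > 0 and step > 0 and stop >= start):
        raise ValueError(f"invalid grid bounds: start={start}, stop={stop}, step={step}")

    def _precision(x: float) -> int:
        for dp in range(11):
            if abs(round(x, dp) - x) < 1e-12:
                return dp
        return 10

    decimals = max(_precision(start), _precision(step))
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return tuple(round(start + i * step, decimals) for i in range(n))


def evaluate_grid(
    recorded: Sequence[CatTrace],
    bank: ItemBank,
    base_rules: StoppingRules,
    thresholds: Sequence[float],
    grid: QuadratureGrid,
    d: float = 1.0,
) -> SerGridResult:
    """Replay all recorded traces under every SER threshold and summarize.

    ``base_rules`` is the reference configuration and must not itself carry a
    SER threshold.  The per-step SE sequence of each trace is re-estimated
    once (it does not depend on the threshold); each threshold then only moves
    the truncation point, so the sweep costs O(traces x steps) EAP work plus
    O(thresholds x traces) bookkeeping.  Floor membership is fixed from the
    recorded responses, not redefined per threshold.
    """
    recorded = tuple(recorded)
    if len(recorded) == 0:
        raise ValueError("evaluate_grid requires at least one recorded trace")
    if base_rules.ser_threshold is not None:
        raise ValueError("base_rules must not include a SER threshold (they are the reference)")
    thresholds = tuple(float(t) for t in thresholds)
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")

    # One EAP pass per trace: prefix estimates are threshold-independent.
    theta_seq: List[np.ndarray] = []
    se_seq: List[np.ndarray] = []
    for trace in recorded:
        pairs = [(bank[s.item_id], s.category) for s in trace.steps]
        ests = prefix_estimates(pairs, grid, d)
        theta_seq.append(np.array([e.theta for e in ests]))
        se_seq.append(np.array([e.se for e in ests]))

    def _outcomes(rules: StoppingRules) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta = np.empty(len(recorded))
        se = np.empty(len(recorded))
        n_items = np.empty(len(recorded))
        for i, trace in enumerate(recorded):
            t, _ = _stop_step(se_seq[i], rules, trace.n_items)
            theta[i] = theta_seq[i][t - 1]
            se[i] = se_seq[i][t - 1]
            n_items[i] = t
        return theta, se, n_items

    ref_theta, ref_se, ref_n = _outcomes(base_rules)
    floor_mask = np.array(
        [all(c == 0 for c in trace.categories) for trace in recorded]
    )
    floor_ids = tuple(t.respondent_id for t, f in zip(recorded, floor_mask) if f)

    def _triple(
        theta: np.ndarray, se: np.ndarray, n_items: np.ndarray
    ) -> Tuple[OutcomeSummary, OutcomeSummary, OutcomeSummary]:
        eff = (1.0 / se**2) / n_items
        delta_t = (theta - ref_theta) * 10.0
        overall = _summarize(eff, n_items, se, delta_t)
        floor = _summarize(eff[floor_mask], n_items[floor_mask], se[floor_mask],
                           delta_t[floor_mask])
        nonfloor = _summarize(eff[~floor_mask], n_items[~floor_mask], se[~floor_mask],
                              delta_t[~floor_mask])
        return overall, floor, nonfloor

    baseline, baseline_floor, baseline_nonfloor = _triple(ref_theta, ref_se, ref_n)
    overall: List[OutcomeSummary] = []
    floor: List[OutcomeSummary] = []
    nonfloor: List[OutcomeSummary] = []
    for s in thresholds:
        o, f, nf = _triple(*_outcomes(base_rules.with_ser(s)))
        overall.append(o)
        floor.append(f)
        nonfloor.append(nf)
    return SerGridResult(
        thresholds=thresholds,
        overall=tuple(overall),
        floor=tuple(floor),
        nonfloor=tuple(nonfloor),
        baseline=baseline,
        baseline_floor=baseline_floor,
        baseline_nonfloor=baseline_nonfloor,
        floor_ids=floor_ids,
    )


def differential_efficiency(result: SerGridResult) -> DifferentialSeries:
    """First differences of overall mean efficiency across the SER grid.

    The first entry measures the introduction of the SER rule (smallest
    threshold vs the no-SER baseline); entry k is the efficiency at
    threshold k minus at threshold k-1.
    """
    eff = [s.mean_efficiency for s in result.overall]
    deltas = [eff[0] - result.baseline.mean_efficiency]
    deltas.extend(eff[k] - eff[k - 1] for k in range(1, len(eff)))
    peaks = _find_peaks(result.thresholds, deltas)
    return DifferentialSeries(
        thresholds=result.thresholds,
        delta_efficiency=tuple(deltas),
        peaks=tuple(peaks),
    )


def _find_peaks(
    thresholds: Sequence[float], deltas: Sequence[float]
) -> List[Tuple[float, float]]:
    """Strict local maxima; a plateau is represented by its smallest threshold."""
    n = len(deltas)
    peaks: List[Tuple[float, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and deltas[j + 1] == deltas[i]:
            j += 1
        left_ok = i == 0 or deltas[i - 1] < deltas[i]
        right_ok = j == n - 1 or deltas[j + 1] < deltas[i]
        if left_ok and right_ok:
            peaks.append((thresholds[i], deltas[i]))
        i = j + 1
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return peaks


def optimal_ser(
    series: DifferentialSeries,
    policy: str = "highest_peak_after_introduction",
) -> float:
    """Select the SER threshold at a peak of the differential efficiency function.

    ``highest_peak``: the threshold of the largest delta anywhere.
    ``highest_peak_after_introduction`` (default): the largest peak strictly
    beyond the first grid point, skipping the introduction spike.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose one of {POLICIES}")
    if policy == "highest_peak":
        candidates = series.peaks
    else:
        intro = series.thresholds[0]
        candidates = tuple(p for p in series.peaks if p[0] > intro)
    if not candidates:
        raise ValueError(
            f"no qualifying peak under policy {policy!r}: the differential series has "
            f"{len(series.peaks)} peak(s) at thresholds "
            f"{[p[0] for p in series.peaks]}"
        )
    return candidates[0][0]
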