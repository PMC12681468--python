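"""Post-hoc replay of recorded CAT administrations under alternative stopping rules.

A recorded trace fixes the item order and the responses; replay walks that
sequence, re-estimating theta/SE by EAP at every step, and truncates at the
first step where the candidate rules fire.  Replay can only shorten a trace,
never extend it, so the replayed item sequence is always a prefix of the
recording.  The module also computes the four evaluation outcomes (mean
efficiency, mean item count, mean SE, mean T-score difference vs a reference
run), the floor/non-floor subgroup split, and theta-resolved difference
profiles.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import (
    STOP_ITEMS_EXHAUSTED,
    CatStep,
    CatTrace,
    StoppingRules,
    efficiency,
    run_cat,
    should_stop,
)
from .grm import (
    ItemBank,
    ItemParameters,
    QuadratureGrid,
    ThetaEstimate,
    category_probabilities,
    posterior_moments,
)

__all__ = [
    "OutcomeSummary",
    "DifferenceProfile",
    "FloorPartition",
    "prefix_estimates",
    "replay_trace",
    "rescore_trace",
    "outcome_summary",
    "floor_subgroup",
    "smoothed_differences",
]


@dataclasses.dataclass(frozen=True)
class OutcomeSummary:
    """Respondent-averaged evaluation outcomes for one stopping-rule configuration.

    T-score differences against the reference run are reported both absolute
    (the headline magnitude) and signed (the bias direction).  SDs are sample
    SDs (ddof=1), 0.0 when fewer than two respondents.
    """

    mean_efficiency: float
    sd_efficiency: float
    mean_n_items: float
    sd_n_items: float
    mean_se: float
    sd_se: float
    mean_abs_delta_t: float
    sd_abs_delta_t: float
    mean_signed_delta_t: float
    sd_signed_delta_t: float
    n_respondents: int

    def as_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True, eq=False)
class DifferenceProfile:
    """Binned mean T-score and SE differences across the reference theta range."""

    bin_centers: np.ndarray
    mean_delta_t: np.ndarray  # NaN where the bin is empty
    mean_delta_se: np.ndarray
    bin_counts: np.ndarray


@dataclasses.dataclass(frozen=True)
class FloorPartition:
    """Floor / non-floor split of a respondent set.

    The primary definition is response-based: a respondent is at the floor iff
    every recorded response is in the least-symptomatic (lowest) category.
    The T-score-based definition — final T-score equal to the bank's minimum
    attainable T-score — is computed as a cross-check; ``definitions_agree``
    is the fraction of respondents on which the two coincide.
    """

    floor_ids: Tuple[str, ...]
    nonfloor_ids: Tuple[str, ...]
    min_tscore: float
    tscore_floor_ids: Tuple[str, ...]
    definitions_agree: float


def prefix_estimates(
    pairs: Sequence[Tuple[ItemParameters, int]],
    grid: QuadratureGrid,
    d: float = 1.0,
) -> List[ThetaEstimate]:
    """EAP estimates after each successive response of a fixed sequence.

    Updates the posterior incrementally, with the identical operation order as
    :func:`sercat.grm.eap_estimate` computed from scratch at each prefix, so
    the two agree bit-for-bit.
    """
    posterior = grid.prior_weights.copy()
    out: List[ThetaEstimate] = []
    for item, category in pairs:
        if not 0 <= category < item.n_categories:
            raise ValueError(
                f"category {category!r} out of range for item {item.item_id!r}"
            )
        posterior = posterior * category_probabilities(item, grid.nodes, d)[:, category]
        out.append(posterior_moments(grid, posterior))
    return out


def _stop_step(
    ses: Sequence[float],
    rules: StoppingRules,
    total_len: int,
) -> Tuple[int, str]:
    """First step (1-based) of a recorded SE sequence at which ``rules`` fire.

    ``total_len`` is the recorded length: at the final recorded step no
    further items are available, so exhaustion fires if nothing else does.
    """
    prev: Optional[float] = None
    for t, se in enumerate(ses, start=1):
        ser = (prev - se) if t >= 2 else None
        stop, reason = should_stop(t, se, ser, rules, items_remaining=t < total_len)
        if stop:
            assert reason is not None
            return t, reason
        prev = se
    raise AssertionError("unreachable: exhaustion fires at the final step")


def replay_trace(
    recorded: CatTrace,
    rules: StoppingRules,
    bank: ItemBank,
    grid: QuadratureGrid,
    d: float = 1.0,
) -> CatTrace:
    """Replay a recorded trace under alternative stopping rules.

    Re-estimates theta/SE from scratch at every step of the recorded item and
    response sequence (recorded estimates are not trusted) and truncates at
    the first step where ``rules`` fire.  Under the rules that produced the
    recording (with this package's engine) the replay is bit-identical,
    stop reason included.
    """
    if (
        recorded.n_items < rules.min_items
        and recorded.stop_reason != STOP_ITEMS_EXHAUSTED
    ):
        raise ValueError(
            f"trace {recorded.respondent_id!r} has {recorded.n_items} steps, fewer "
            f"than min_items={rules.min_items}, without an items_exhausted stop"
        )
    pairs = [(bank[s.item_id], s.category) for s in recorded.steps]
    estimates = prefix_estimates(pairs, grid, d)
    stop_t, reason = _stop_step([e.se for e in estimates], rules, len(pairs))
    steps = []
    prev_se: Optional[float] = None
    for t in range(stop_t):
        est = estimates[t]
        ser = (prev_se - est.se) if t >= 1 else None
        rec = recorded.steps[t]
        steps.append(
            CatStep(step=t + 1, item_id=rec.item_id, category=rec.category,
                    theta=est.theta, se=est.se, ser=ser)
        )
        prev_se = est.se
    return CatTrace(respondent_id=recorded.respondent_id, steps=tuple(steps), stop_reason=reason)


def rescore_trace(
    respondent_id: str,
    item_categories: Sequence[Tuple[str, int]],
    bank: ItemBank,
    rules: StoppingRules,
    grid: QuadratureGrid,
    d: float = 1.0,
) -> CatTrace:
    """Build a full CatTrace from a bare (item id, category) sequence.

    Used to lift long-format response recordings (which carry no estimates)
    into trace form: estimates are computed by EAP and the stop reason is
    derived from ``rules`` on the recorded sequence.
    """
    pairs = [(bank[item_id], category) for item_id, category in item_categories]
    if not pairs:
        raise ValueError(f"respondent {respondent_id!r}: empty response sequence")
    estimates = prefix_estimates(pairs, grid, d)
    stop_t, reason = _stop_step([e.se for e in estimates], rules, len(pairs))
    steps = []
    prev_se: Optional[float] = None
    for t in range(stop_t):
        est = estimates[t]
        ser = (prev_se - est.se) if t >= 1 else None
        item_id, category = item_categories[t]
        steps.append(
            CatStep(step=t + 1, item_id=item_id, category=category,
                    theta=est.theta, se=est.se, ser=ser)
        )
        prev_se = est.se
    return CatTrace(respondent_id=respondent_id, steps=tuple(steps), stop_reason=reason)


def _summarize(
    eff: np.ndarray, n_items: np.ndarray, se: np.ndarray, delta_t: np.ndarray
) -> OutcomeSummary:
    def _mean(x: np.ndarray) -> float:
        return float(np.mean(x)) if x.size else float("nan")

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return OutcomeSummary(
        mean_efficiency=_mean(eff), sd_efficiency=_sd(eff),
        mean_n_items=_mean(n_items), sd_n_items=_sd(n_items),
        mean_se=_mean(se), sd_se=_sd(se),
        mean_abs_delta_t=_mean(np.abs(delta_t)), sd_abs_delta_t=_sd(np.abs(delta_t)),
        mean_signed_delta_t=_mean(delta_t), sd_signed_delta_t=_sd(delta_t),
        n_respondents=int(eff.size),
    )


def _matched_arrays(
    traces: Sequence[CatTrace], reference: Sequence[CatTrace]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ref_by_id = {t.respondent_id: t for t in reference}
    if len(ref_by_id) != len(reference):
        raise ValueError("reference contains duplicate respondent ids")
    ids = [t.respondent_id for t in traces]
    if len(set(ids)) != len(ids):
        raise ValueError("traces contain duplicate respondent ids")
    if set(ids) != set(ref_by_id):
        missing = sorted(set(ids) ^ set(ref_by_id))
        raise ValueError(f"traces and reference are not matched one-to-one: {missing[:5]}")
    eff = np.empty(len(traces))
    n_items = np.empty(len(traces))
    se = np.empty(len(traces))
    delta_t = np.empty(len(traces))
    for i, trace in enumerate(traces):
        ref = ref_by_id[trace.respondent_id]
        se[i] = trace.final.se
        n_items[i] = trace.n_items
        eff[i] = efficiency(trace.final.se, trace.n_items)
        delta_t[i] = (trace.final.theta - ref.final.theta) * 10.0
    return eff, n_items, se, delta_t


def outcome_summary(
    traces: Sequence[CatTrace], reference: Sequence[CatTrace]
) -> OutcomeSummary:
    """The four evaluation outcomes averaged over respondents.

    Per respondent: efficiency (1/SE^2)/n from the final estimate, item count,
    final SE, and the T-score difference against the matched reference trace;
    then means and SDs across respondents.
    """
    if len(traces) == 0:
        raise ValueError("outcome_summary requires at least one trace")
    return _summarize(*_matched_arrays(traces, reference))


def floor_subgroup(
    traces: Sequence[CatTrace],
    bank: ItemBank,
    grid: QuadratureGrid,
    rules: StoppingRules = StoppingRules(),
    d: float = 1.0,
    tol: float = 1e-9,
) -> FloorPartition:
    """Split respondents into floor (no reported symptoms) and the rest.

    Primary definition: every recorded response in the lowest category.  The
    bank's minimum attainable T-score — the EAP of the all-lowest pattern run
    to the stopping rules — is computed and used for the cross-check
    definition (final T-score equal to that minimum).
    """
    floor_ids = tuple(t.respondent_id for t in traces if all(c == 0 for c in t.categories))
    floor_set = set(floor_ids)
    nonfloor_ids = tuple(t.respondent_id for t in traces if t.respondent_id not in floor_set)

    all_lowest = run_cat(lambda item_id: 0, bank, rules, grid, respondent_id="__floor__", d=d)
    min_tscore = all_lowest.final.t_score
    tscore_floor_ids = tuple(
        t.respondent_id for t in traces if abs(t.final.t_score - min_tscore) <= tol
    )
    tscore_set = set(tscore_floor_ids)
    n = len(traces)
    agree = (
        sum((t.respondent_id in floor_set) == (t.respondent_id in tscore_set) for t in traces) / n
        if n else 1.0
    )
    return FloorPartition(
        floor_ids=floor_ids,
        nonfloor_ids=nonfloor_ids,
        min_tscore=min_tscore,
        tscore_floor_ids=tscore_floor_ids,
        definitions_agree=agree,
    )


def smoothed_differences(
    traces: Sequence[CatTrace],
    reference: Sequence[CatTrace],
    n_bins: int = 30,
    window: int = 1,
) -> DifferenceProfile:
    """Mean T-score and SE differences, binned across the reference theta range.

    Respondents are binned by their reference final theta into ``n_bins``
    equal-width bins; per-bin means of delta-T (T-points) and delta-SE (theta
    metric) are reported, NaN for empty bins.  ``window`` > 1 applies a
    centered moving average over the non-empty bin means as an optional
    smoother.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(traces) == 0:
        raise ValueError("smoothed_differences requires at least one trace")
    ref_by_id = {t.respondent_id: t for t in reference}
    _, _, _, delta_t = _matched_arrays(traces, reference)
    ref_theta = np.array([ref_by_id[t.respondent_id].final.theta for t in traces])
    delta_se = np.array(
        [t.final.se - ref_by_id[t.respondent_id].final.se for t in traces]
    )

    lo, hi = float(ref_theta.min()), float(ref_theta.max())
    if hi == lo:  # degenerate: all reference estimates identical
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(ref_theta, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.bincount(idx, minlength=n_bins)
    mean_dt = np.full(n_bins, np.nan)
    mean_dse = np.full(n_bins, np.nan)
    nonempty = counts > 0
    sums_dt = np.bincount(idx, weights=delta_t, minlength=n_bins)
    sums_dse = np.bincount(idx, weights=delta_se, minlength=n_bins)
    mean_dt[nonempty] = sums_dt[nonempty] / counts[nonempty]
    mean_dse[nonempty] = sums_dse[nonempty] / counts[nonempty]

    if window > 1:
        mean_dt = _moving_average(mean_dt, window)
        mean_dse = _moving_average(mean_dse, window)
    return DifferenceProfile(
        bin_centers=centers, mean_delta_t=mean_dt, mean_delta_se=mean_dse, bin_counts=counts
    )


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered NaN-aware moving average over bins."""
    half = window // 2
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        seg = values[max(0, i - half): i + half + 1]
        seg = seg[~np.isnan(seg)]
        if seg.size:
            out[i] = float(seg.mean())
    return out
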