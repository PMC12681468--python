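# Methods

This note documents the models, numerical choices and design decisions
behind `sercat`, and what its synthetic data can and cannot establish.

## Measurement model

Items follow Samejima's graded response model on the logistic metric
(scaling constant D = 1.0, the PROMIS convention; `d` is a keyword argument
throughout for users who want the normal-ogive-approximation metric
D = 1.702).  For a K-category item with discrimination α > 0 and strictly
increasing thresholds β₁ < … < β_{K−1}:

    P*_k(θ) = 1 / (1 + exp(−D·α·(θ − β_k))),   P*_0 ≡ 1,  P*_K ≡ 0
    P_k(θ)  = P*_{k−1}(θ) − P*_k(θ)

Fisher information is the full polytomous form

    I(θ) = Σ_k (D·α)² · (w_{k−1} − w_k)² / P_k,    w_k = P*_k (1 − P*_k)

which reduces algebraically to (Dα)²·p·q for binary items — the familiar
two-category formula.  The binary formula is *underdetermined* for K ≥ 3, so
the implementation always uses the polytomous form; tests pin the binary
reduction and check the general form against the expected negative
log-likelihood curvature by finite differences.

Categories are 0-based in memory; every file format uses the 1-based "1..K"
convention and converts at the boundary.

## Scoring and the two standard errors

θ̂ is the EAP estimate: the posterior mean over a fixed quadrature grid,
by default 81 equally spaced nodes on [−6, 6] weighted by the standard
normal density (covering T-scores 10–110).  The **SE of record is the EAP
posterior SD**, not 1/√I; the two differ (the posterior SD includes the
prior and does not assume asymptotics), and published CAT engines use the
posterior SD with the 0.32 rule.  `se_from_information` exposes the
information identity SE = 1/√I for the reliability interpretation
(SE = σ√(1−r_xx)); efficiency is always computed from whichever SE is in
the trace, i.e. the posterior SD.

Quadrature accuracy: because the integrands are smooth and decay fast, the
81-node equal-spacing rule agrees with a 10,001-node reference to better
than 1e−7 in both posterior mean and SD across random response sets; the
test suite enforces 1e−6.  Posteriors are accumulated as running products
without intermediate normalization (12 five-category items cannot underflow
float64), and the incremental prefix update used by replay performs the
identical operation sequence as scratch re-estimation, so replayed
estimates are bit-identical to engine output.

## Adaptive administration

Item selection is maximum Fisher information at the current EAP estimate
(start at θ = 0, the prior mean), ties broken toward the smaller item id.
No exposure control or content balancing — selection algorithms are
pluggable in principle but out of scope.

Stopping rules are evaluated after every response in a fixed order, and the
first satisfied rule is the recorded stop reason:

1. below `min_items` (default 4): never stop, unless the bank is exhausted;
2. `max_items` reached (default 12);
3. SE threshold (default 0.32, **≤** convention — configurable, since
   published descriptions vary between < and ≤);
4. SER threshold (absent by default): fires when the *reduction*
   SE_{t−1} − SE_t is **below** the threshold.  The reduction is stored
   positive when precision improves; a negative reduction (SE got worse,
   which EAP permits) also stops.  SER needs two estimates and never
   overrides the minimum-length rule;
5. bank exhausted.

The SER sign convention deserves a note: the step difference is sometimes
written SE_t − SE_{t−1}, which is negative when precision improves, yet
thresholds are universally quoted positive (0.01–0.20).  We store the
positive reduction and compare `reduction < threshold`.

## Post-hoc replay

Replay walks a recorded item/response sequence in order, re-estimating
θ̂/SE at every step from scratch (recorded estimates are *not* trusted —
they may come from an engine with unknown quadrature), and truncates at the
first step where the candidate rules fire.  Replay can only shorten, never
extend: the replayed sequence is a prefix of the recording.  Under the
generating rules replay is bit-identical, stop reason included.  An external
recording that reaches its end without any rule firing is closed with
`items_exhausted`.

Outcomes per rule configuration (means ± SDs over respondents): efficiency
(1/SE²)/n_items from the final estimate, item count, final SE, and the
T-score difference ΔT against the matched reference trace.  **ΔT is
reported both signed and absolute.**  The signed mean captures bias (for
floor respondents, truncation pulls estimates toward the prior mean, i.e.
upward); the absolute mean captures per-person disturbance.  Published
summary tables that show near-zero mean ΔT alongside large reductions in
test length are only arithmetically consistent with the *signed* mean —
halving a test perturbs individual EAP estimates by far more than a few
hundredths of a T-point — so headline comparisons here use the magnitude of
the signed mean, with the absolute mean reported alongside.

The floor subgroup is defined response-based (every administered response
in the lowest category); the alternative definition — final T-score equal
to the bank's minimum attainable T-score, the EAP of the all-lowest pattern
run to the stopping rules — is computed as a cross-check and the agreement
rate is reported.  For engine-produced traces the two coincide exactly.
Subgroup membership is fixed from the reference run, not redefined per SER
threshold.

θ-resolved difference profiles use equal-width binned means (default 30
bins) over the reference θ̂, not an unnamed smoother: binned means are
reproducible bit-exactly; an optional centered moving average over bins is
available.

## SER grid search

The grid is 0.01 to 0.20 in steps of 0.001 (191 values), rounded to the
step's decimal precision to avoid floating drift.  The per-step SE sequence
of a trace does not depend on the threshold, so the sweep re-estimates each
trace once and then only moves the truncation point per threshold —
O(traces × steps) EAP work instead of O(thresholds × traces × steps).

The differential function of efficiency is the first-difference series of
mean efficiency across the grid.  Its first entry is defined against the
no-SER baseline, so the "introduction" jump (the gain from having the rule
at all) exists as a point in the series.  Peaks are strict local maxima;
plateaus are represented by their smallest threshold.  Two selection
policies:

- `highest_peak`: the largest differential anywhere.  In floor-heavy
  populations this is typically the introduction point itself.
- `highest_peak_after_introduction` (default): the largest peak beyond the
  first grid point — in practice the threshold at which floor respondents
  collapse from 5 to the minimum 4 items.

Both are exposed because the two published descriptions of the selection
("the highest peak" vs optima that are second peaks) conflict; neither is
claimed canonical.

## Synthetic data: the stated world

`BankSpec` defaults: 15 items (anxiety-like) with α ~ U(1.09, 1.89), five
categories, thresholds i.i.d. N(+1.0, 0.5²) sorted (coincident draws are
separated by 1e−3 and logged).  This concentrates information in the
symptomatic region θ ∈ [0, 2] and leaves essentially none below θ ≈ −1,
the mechanism behind the floor effect.  A depression-like preset (14 items,
α ∈ [0.74, 2.53]) ships alongside.  The span 0.5 was fixed once by a design
computation before any test existed; within-item threshold ranges
(~1.3 θ-units) are narrower than real PROM banks (~2–3), a deliberate
trade-off keeping the informative region compact.

`PopulationSpec` defaults: θ is a two-component mixture — with probability
0.07 a *floor* draw from N(−2.5, 0.3²), else N(0, 1).  The floor is a
low-θ normal component rather than a point mass so all-lowest response
patterns arise probabilistically, as in real data; the 7% default matches
the order of magnitude of published floor prevalences.  Responses are
single multinomial draws per cell; full matrices are generated so replay
can follow any item order.  All randomness flows through explicit seeds.

What the generator does *not* emulate: local dependence, careless or
inconsistent responding, demographic structure, item-position effects, and
the specific calibrated parameters of any real bank.  A green end-to-end
test therefore establishes that the *pipeline* reproduces the qualitative
floor-effect signature (floor respondents hit the item maximum under
default rules; the introduction of the SER rule produces the largest
efficiency jump; the selected threshold is where the floor subgroup reaches
the minimum length; floor outcome curves are step functions), not that any
particular published number is recovered.

One quantitative intent could not be met: with the floor component fixed at
N(−2.5, 0.3) and thresholds centered at +1.0, a low-discrimination item
(α ≈ 1.1, β₁ ≈ 1) still leaves a ≈ 2% chance of a non-lowest response per
item, so over 12 administered items at most ≈ 89% of floor respondents can
produce a fully-lowest pattern even in the degenerate zero-span limit
(≈ 76% at the realistic defaults).  The floor-realization test therefore
asserts the mechanism (rate > 0.7, and exact agreement between generated
all-lowest patterns and the classifier) rather than a higher rate the
stated parameters cannot reach.

## Degenerate inputs and tie-breaks

- Empty response set → EAP returns the prior mean/SD.
- Posterior numerically zero everywhere → error (responses outside the
  quadrature support).
- Bank smaller than `min_items` → the run ends `items_exhausted` at bank
  size; replay accepts such recordings.
- Selection ties → lexicographically smallest item id.
- Differential-series plateaus → smallest threshold represents the plateau.
- SDs in outcome summaries are sample SDs (ddof = 1), reported as 0.0 for a
  single respondent; empty subgroups yield NaN means with
  `n_respondents = 0`.

## Known limitations

- Unidimensional GRM only; no parameter calibration (item parameters are
  inputs); no exposure control; no multidimensional or predicted-SER
  variants.
- The replay design assumes the recorded item order would not have changed
  under the alternative rules — true for stopping-rule changes (stopping
  only truncates), but not for hypothetical changes to item *selection*.
- Efficiency uses the EAP posterior SD, so "information per item" inherits
  the prior; with very few items efficiency is bounded by the prior even
  for uninformative responses.
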