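# Methods

This note documents the models behind `hystnet`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical conventions a user relying on the outputs should know.

## Ground-truth source model

Source-level EEG is modeled as a stable multivariate autoregressive (MVAR)
process over six cortical regions: VC (BA 17), dACC (BA 32), vACC (BA 24),
dPCC (BA 31), PFC (BA 10) and PC (BA 7/39), with the usual
cognitive-architecture module assignments (declarative memory ↔ PFC/DLPFC,
goal maintenance ↔ anterior cingulate, imaginal buffer ↔ parietal cortex,
vision ↔ occipital/fusiform cortex).

Each node's intrinsic dynamics is an AR(2) resonator with pole radius 0.88
and a region-specific center frequency (VC 10 Hz, dPCC 11 Hz, PC 12 Hz,
vACC 18 Hz, dACC 20 Hz, PFC 22 Hz — posterior alpha, frontal beta, all
inside the 7–30 Hz analysis band). Distinct center frequencies are both
more physiological than identical oscillators and necessary for stability:
identical 10-Hz resonators coupled reciprocally at the default strengths
push companion-matrix eigenvalues outside the unit circle.

Directed coupling `i → j` with strength `c` at lag `ℓ` sets coefficient
`A(ℓ)[j, i] = c`; the innovation covariance is diagonal. The realizer
*refuses* couplings that destabilize the model, naming the strongest edge,
rather than silently rescaling — ground truth must be exactly what was
requested. The three condition presets are:

| condition | edges (strength) | reading |
|---|---|---|
| L1 | VC→vACC (0.30), vACC→dPCC (0.25), VC→dACC (0.30) | visually driven flow |
| H2 | dACC→PFC (0.28), dACC→PC (0.20), PC→dACC (0.10), PFC→dACC (0.15) | dACC/PFC hubs, parietal-cingulate loop |
| L3 | PFC→vACC (0.35), PFC→dACC (0.30) | PFC a pure causal source |

The published account of these networks names representative edges and hub
roles per condition but not complete graphs; the preset fixes full edge
sets with those properties (L1 sources include VC; H2's top outflow nodes
are dACC and PFC; L3's hub is PFC; vACC ends as a sink of PFC). The
parietal–cingulate coupling in H2 is realized as two directed edges, with
asymmetric strengths — a symmetric pair strong enough to matter is
unstable against the resonator background, and the asymmetry also gives
PFC the H2 outflow its hub role requires. Acceptance rests on recovering a
*known* network, not on reproducing an exact published graph; alternative
presets are user-registrable.

Sessions simulate the fixed L1 → H2 → L3 schedule (4 min per condition by
default; tests and the acceptance script use 0.5–2 min to keep runtimes
short), one generating network per block, Gaussian i.i.d. innovations, a
burn-in of 10× model order discarded, and per-sample condition labels.
Everything is bit-reproducible for a fixed integer seed.

**What the generator does not emulate:** volume conduction and scalp
mixing, electrode montages, artifacts (ocular, muscular, line noise),
nonstationarity within a condition, 1/f background spectra, and
source-localization error. Passing recovery tests on these data therefore
demonstrates the *inferential chain* is correct, not that it is robust to
the full noise structure of real EEG.

## Task environment

The multitasking battery is reduced to its event statistics. Each of six
event types (communications target/distractor calls, warning lights,
drifting gauges, pump failures, pump shut-offs) has a published per-minute
rate range per demand level; a block draws one rate per type uniformly
from its range and then emits an independent homogeneous Poisson stream
(uniform draw and homogeneous Poisson are the least-informative choices —
the within-range mechanism is not published). Tracking has no discrete
events; it is a continuous disturbance handled by the agent. Simultaneous
events are ordered deterministically by the table's row order.

## Cognitive agent

The agent implements the architecture, not any particular production set:
the published model's rules are not available, and the phenomena of
interest (timing quantization, retrieval dynamics, carryover) are
architectural. Productions are evaluated on a strict 50 ms cycle; the
declarative buffer holds one chunk, so retrievals serialize and queue.

A system-monitoring event is answered by visual encoding (85 ms) →
declarative retrieval of the event→key mapping chunk → keypress (210 ms).
Retrieval uses the standard sub-symbolic equations with defaults
`d = 0.5`, `τ = −2.0`, `s = 0.4`, `F = 0.5 s`, transient noise SD 0.25
(the timing and decay values are cognitive-architecture community
conventions, not fitted to any dataset; all are configurable and logged).
A failed retrieval costs `F e^{−τ}` and the event is missed. The
published retrieval-probability equation is typographically corrupted in
its source; the standard logistic form `1/(1+e^{(τ−A)/s})`, consistent
with its parameter glosses, is implemented. Communications and
resource-management events are handled but not scored (their event rates
are too low for per-bin statistics); they occupy attention for a 1.5 s
dwell, which is the main load channel through which high demand slows
monitoring responses (queueing).

Tracking error follows an Ornstein–Uhlenbeck-like bounded walk
(`σ = 30 %/√s`, correction gain 1 s⁻¹, bound 100 %), corrected only in
cycles where no event is being processed — so tracking degrades exactly
when event load is high, reproducing the demand profile of the tracking
root-mean-square error.

Each chunk starts with a small practice history (5 presentations spread
over the 5 minutes before the block). With `carryover=True` histories
persist across blocks: the dense retrieval practice of the high-demand
block raises base-level activation, and the final low-demand block is
answered reliably faster than the first — the hysteresis direction seen in
human operators. With `carryover=False` histories reset at each block
boundary and the two low-demand blocks are statistically indistinguishable
— the behavior of memory-reset cognitive models. The contrast is reported
as a per-seed L3−L1 difference in mean correct reaction time with a
percentile interval across seeds; inferential statistics (ANOVA, post-hoc
tests) are standard tools and are deliberately out of scope.

## MVAR fitting

Ensemble normalization z-scores each (channel, time) point across trials
(sample SD, `ddof=1`); with a single trial it falls back to a per-channel
z-score over time. Zero variance anywhere is an error naming the point.

The production estimator is the multichannel lattice (Levinson–
Whittle–Wiggins–Robinson recursion) with Vieira–Morf geometric-mean
normalization of the reflection coefficients: at each stage the
forward/backward partial cross-covariance is whitened by the Cholesky
square roots of the forward and backward error covariances, which keeps
every fitted model stable by construction. Plain multivariate least
squares is retained as an independent estimator; the two agree to
coefficient RMSE < 0.02 on long stationary data (and are algebraically
identical at order 1), which the test suite checks.

Sliding windows are 350 ms (45 samples at 128 Hz; the millisecond value
is rounded to samples) advanced in 30-sample steps, the published window
geometry; the trailing partial window is dropped. Order selection
minimizes the Hannan–Quinn criterion

    HQ(p) = ln det Σ̂_E(p) + 2 p k² ln(ln N) / N

over orders 1–40 (ties to the smaller order). One lattice sweep to the
maximum order yields the residual covariance of every intermediate order,
so all candidates are scored in a single pass. On 60 s of data from an
order-16 generating model the criterion recovers 16 across seeds; on white
noise the penalty dominates and the minimum order is returned.

## Validation battery

Applied to every fitted model before connectivity is computed:

* **Stability** — `ln max|eig(companion)| < 0`. Checked against a
  brute-force iteration oracle in the tests.
* **Residual ACF whiteness** — all `k²·n_lags` residual cross-correlations
  against the `±1.96/√N` band. Under exact whiteness 5% of entries are
  *expected* outside the band, so the pass rule allows the binomial
  sampling slack (two SEs on the outside fraction); without the slack the
  nominal "95% inside" rule rejects ~40% of truly white residual sets.
* **Li–McLeod Portmanteau** —
  `Q = N Σ_{l≤h} tr(Ĉ_lᵀĈ₀⁻¹Ĉ_lĈ₀⁻¹) + k²h(h+1)/(2N)`, referred to
  χ² with `k²(h−p)` degrees of freedom. Monte-Carlo type-I error is within
  [0.03, 0.07] at α = 0.05, with high power against underfit models.
* **Percent consistency** — surrogate data of matched shape are simulated
  from the fitted model (fixed seed) and
  `PC = 100·(1 − ‖R_sim − R_real‖/‖R_real‖)` is computed over all
  auto/cross-correlations at lags 0–20 (the norm and lag range are this
  package's convention; they are configurable). Pass threshold 85%.

Validation units matter. The whiteness and consistency statistics are
calibrated for epoch-length data; on 45-sample windows the Portmanteau
statistic (which needs `h > p`) and the consistency norm (dominated by
correlation-estimation noise at that length) are not meaningful. The
pipeline therefore runs the full battery per condition epoch and screens
the short windows on stability and ACF whiteness only, excluding and
counting failures. At very large sample counts the Portmanteau test
resolves the lattice's O(1/N) coefficient bias and can reject even
well-specified fits; its p-value is reported but the epoch gate uses
stability, consistency and the ACF band.

## Connectivity measures

On a 1-Hz grid over 2–32 Hz (strictly inside the Nyquist interval):

* transfer matrix `H(f) = Ā(f)⁻¹`, spectral matrix `S = H Σ_E Hᴴ`;
* DTF `γ²_{i←j}(f) = |H_ij|²/Σ_m|H_im|²` (rows sum to 1 — tested to
  10⁻¹⁰);
* partial coherence `χ²_ij = |M_ij|²/(M_ii M_jj)`, `M = S⁻¹`, which
  suppresses indirect links (verified on a 3-node chain);
* dDTF `= η_ij(f)·χ_ij(f)` with `η²` the full-frequency-normalized DTF —
  the product-of-ffDTF-and-partial-coherence definition that standard
  EEG connectivity toolboxes implement.

Edges are retained per frequency when they *strictly* exceed the 97.5th
percentile of that frequency's off-diagonal values (ties drop out, so an
all-equal slice keeps nothing; the percentile uses linear interpolation).
Thresholding precedes band averaging. Network metrics average dDTF over
the 7–30 Hz (alpha + beta) band by default: outflow and inflow are
off-diagonal row/column sums, the asymmetry ratio is
`(out − in)/(out + in)` — the unique simple ratio with range [−1, 1] and
the source/+1, sink/−1, balanced/0 endpoint semantics — and a node is
labeled source above +0.5, sink below −0.5 (configurable; an isolated
node's ratio is reported as missing, not zero). Per-condition network
summaries come from the epoch-level fit; the windowed fits provide the
time-varying tensor, where short-window estimation noise adds a uniform
flow floor that dilutes asymmetry ratios toward zero.

## Problem sizes and determinism

Defaults in tests and the acceptance script: 2-minute conditions with 8
trials for the validation battery, 60 s for order recovery, 2-minute
single-trial sessions for the 20-network structure-recovery sweep, and
20–25 seeds for behavioral contrasts. These sizes put every statistic
comfortably past its decision threshold (consistency ≈ 97% vs. the 85%
criterion; order recovery exact across seeds) while keeping the full suite
in the low minutes on one CPU. All randomness flows through
`numpy.random.default_rng` seeds; equal seeds give byte-identical outputs,
which the pipeline test asserts on serialized results.

## Known limitations

* The synthetic sources omit scalp physics and artifacts (above); recovery
  results bound the method's correctness, not its field robustness.
* The Vieira–Morf lattice trades a small finite-sample bias for guaranteed
  stability; at N ≳ 10⁵ the Portmanteau test can detect this bias.
* Percent consistency depends on data length: below ~10⁴ samples the
  correlation-estimation noise of *both* the data and the surrogate sets a
  ceiling well under 100% even for the true model.
* The agent's production set is minimal (monitoring + tracking, with
  communications/resource events as attention dwell); it reproduces
  architectural timing and the carryover contrast, not full task
  performance profiles, and its absolute reaction times are faster than
  human means.
* Event rates within a demand block are homogeneous Poisson; real
  batteries schedule some events quasi-periodically.
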