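# Methods

## Data model and conventions

A session is a continuous recording spanning `n_rounds` exercise rounds
(default 6 × 180 s) separated by rests (default 60 s).  Time is in seconds
with t = 0 at session start; analysis windows are half-open
`[start, start + duration)`, and window-local time restarts at 0, so a
breakpoint time is always relative to its own round or rest.  Rest windows
are the inter-round recoveries only (five for a six-round session); data
recorded after the final round are retained but not windowed.

SmO₂ is the oxygenated fraction of haem chromophores,
`100·(O₂Hb + O₂Mb) / ((O₂Hb + O₂Mb) + (HHb + HMb))`, bounded to [0, 100] %.
Device exports arrive as 1 s averages of a 0.5 s update; `resample_to_1hz`
reproduces that convention by averaging consecutive non-overlapping pairs
and stamping each output at its pair's midpoint, which keeps the samples of
any linear trend exactly on the underlying line (an odd trailing input
sample is dropped and flagged).

Sensor dropouts of ≤ 2 s are bridged by linear interpolation and recorded;
longer gaps mark every overlapping window unanalysable rather than
guessing.  A rectus-femoris fat thickness above 14 mm flags the optical
signal as unreliable; the check is advisory and analysis proceeds with a
warning.

## Filtering

Movement artifacts appear as isolated single-sample excursions.  A running
5 s median (5 samples at 1 Hz) is applied to the whole SmO₂ trace *before*
windowing, so round/rest boundaries never create artificial edges.  At the
trace ends the window shrinks symmetrically (half-width `min(2, distance to
edge)`), preserving length without padding and without discarding the first
seconds that contain the delay phase.  Median filtering is selection-based:
output values never leave the input's range, constants and monotone ramps
pass through unchanged, and an isolated spike on a locally flat segment is
removed exactly.  On a sloped segment the spike's removal can displace the
local median by one order statistic (≈ slope × 1 s); we therefore call an
artifact *removed* when its residual influence after filtering is ≤ 2 %
SmO₂ — an order of magnitude below the smallest injected spike (≥ 10 %
after export averaging) and at the scale of the sensor noise itself.  Under
the default artifact rate (0.02 s⁻¹) this holds at ≥ 99.8 % of samples.

## Three-phase segmentation

Each window is fitted with three ordinary-least-squares line segments.
Breakpoint pairs (b₁, b₂) are enumerated exhaustively on the sample grid
with every segment at least `min_segment_s` long (default 5 s — short
enough to resolve the briefest delays seen at round start, long enough to
average 1 Hz noise; configurable).  A candidate is feasible only when the
middle slope is strictly the steepest in the phase direction (most negative
for desaturation, most positive for resaturation); the delay and
equilibrium slopes are otherwise unconstrained, since the equilibrium is
only *relatively* consistent, not flat.  The winner minimises total SSE;
exact ties resolve to the smaller b₁, then smaller b₂, making the estimator
deterministic.  Per-segment statistics come from prefix sums, so the search
over the ≈ 1.4 × 10⁴ candidates of a 180-sample round is a single
vectorised pass; an independent brute-force enumeration (`np.polyfit` per
segment) is retained as a validation oracle and agrees exactly on small
windows.

Reported breakpoints are the *continuous* intersections of adjacent fitted
lines, `b = (a₂ − a₁)/(s₁ − s₂)`, not the grid indices: on noise-free
piecewise-linear input this recovers fractional generating breakpoints to
machine precision.  When the intersection departs more than 2 s from its
grid breakpoint (near-parallel adjacent segments, common when the delay and
fast phases have similar slopes under noise), the fit is flagged
low-confidence instead of being silently accepted or rejected.  Parallel
lines fall back to the grid time, flagged.

Derived quantities: TD/RD = first intersection; DD/FRD = second − first;
FDR/FRR = middle slope; SS_level = mean fitted value over the equilibrium
samples; SR_slope = third-segment slope in recovery.  Heart rate at a
breakpoint is linearly interpolated from the 1 Hz HR trace at the
fractional intersection time (an HR-domain fit of SmO₂ against heart rate
would be a possible alternative; the time-domain route is implemented).
Phase variability is the raw median absolute deviation of residuals about
the segment line — no 1.4826 consistency constant, since the statistic is
reported as a robust spread in % saturation, not as a normal-σ estimate.

## Punch metrics

Punch events (session seconds) are attributed to phases by half-open
intervals `[0, TD)`, `[TD, TD+DD)`, `[0, round)` so each punch belongs to
exactly one phase; logs carrying only per-round totals populate the round
total and leave phase counts unresolved.  The per-punch desaturation cost
is `FDReN = FDR × DD / FD_count`, i.e. the total saturation change across
the fast desaturation divided by the punches thrown within it, computed per
athlete-round *before* any averaging (means of ratios, not ratios of
means).  `FD_count = 0` yields a flagged undefined value, never an
infinity; athletes with any undefined cell are dropped from that outcome's
group analysis (complete-case within-subject design).

## Group statistics

Outcomes are analysed with the classical univariate repeated-measures
ANOVA on balanced complete data: sums of squares by inclusion–exclusion
over marginal means, every main effect and interaction tested against its
own subject-by-effect interaction mean square.  No sphericity correction
is applied by default.  The implementation exposes the full decomposition
(the SS identity `SS_total = Σ SS_terms` holds to ~1e-12 relative) and
reproduces statsmodels' `AnovaRM` F, dfs and p exactly on random balanced
designs; under 1 000 simulated null designs the per-effect rejection rate
at α = 0.05 sits inside binomial 99 % bounds.

Effect size is the adjusted partial eta squared
`df_e(F − 1)/(df_e F + df_err)` — the partial-epsilon-squared form that
removes the null expectation of F — clipped below at 0 so null-ish effects
report 0.00, with bands: trivial < 0.01 ≤ small < 0.06 ≤ moderate < 0.14 ≤
large.  Significant omnibus effects (α = 0.05) license Fisher's LSD
pairwise contrasts on the omnibus error term (no multiplicity adjustment);
the per-cell superscripts of the summary tables use paired t tests across
athletes for each cell pair (the cell pair's own error term rather than a
pooled one — a deliberate choice where the convention is ambiguous).
Normality screening is by normal Q–Q points at plotting positions
`(i − ½)/n`, returned for inspection with no automated accept/reject.

## Synthetic sessions

The simulator generates what the analysis assumes, at the phase level (no
haemodynamic ODE): a continuous piecewise-linear SmO₂ mean per leg built
round-by-round (each recovery starts where its round ended, so the level
trajectory is continuous and stays physiological), evaluated at 0.5 s,
corrupted with Gaussian noise (default SD 1 %) and Poisson-placed
single-sample spikes of 20–60 % (default 0.02 s⁻¹), clipped to [0, 100]
(clips logged), then pair-averaged to the 1 Hz export.  Heart rate follows
an exponential approach to round-specific targets (τ = 25 s) with partial
exponential recovery in rests (τ = 60 s, 45 bpm span below target).
Punches are phase-inhomogeneous Poisson trains; rests contain none.  All
randomness flows from one explicit seed through spawned child generators,
so e.g. switching off the artifact stream leaves the noise stream
untouched.

Preset scenarios encode modality-typical magnitudes: round-total punch
counts near 190 (bag), 170 (pad) and 58 (spar) per round; round-1 delays
of 12–13 s with fast desaturation near −1.7 %/s over ~20 s; round-to-round
drift (delay lengthening, |FDR| shrinking, HR climbing); recoveries with
~10 s delay and 0.6–0.9 %/s fast resaturation over ~30 s.  The rear
(push-off) leg desaturates earlier and ~40 % faster over a shorter phase.
Cohorts add two layers of variability: athlete-level random effects (delay
shift, correlated rate multipliers, HR offset) shared across that
athlete's three sessions, and round-to-round session jitter within each
session, so the within-subject design carries realistic residual variance.

What the simulator does *not* emulate: baseline wander and slow sensor
drift, heteroscedastic or autocorrelated noise, multi-sample artifact
bursts, HR dropouts, or non-linear (exponential) kinetic shapes.  Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not robustness to every
field-data pathology.

## Validation problem sizes

The shipped checks use 50 noise-free traces for exact recovery (tolerance
1e-6), 200 small windows for oracle equivalence, 100 seeded sessions for
noisy recovery (delay within ±2 s and rate within ±15 % relative for
≥ 90 % of rounds; observed ≈ 99–100 %), 100 sessions for artifact
suppression, 1 000 null designs for ANOVA calibration, and a 10-athlete ×
3-modality cohort for the end-to-end run — sizes chosen so the entire
validation completes in about a minute on one CPU while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

* The three-line model is intentionally minimal; exponential-kinetics
  alternatives are out of scope.
* Occlusion-onset detection (baseline − 3 SD with 2-sample persistence,
  onset at the sample preceding the first qualifying excursion) is a
  repository definition of an informally described procedure.
* With near-parallel adjacent segments the intersection time is poorly
  conditioned; such fits are flagged low-confidence (roughly a quarter of
  windows at the default noise level) and should be weighed accordingly.
* Fisher's LSD performs no multiplicity control by design; with ~100
  contrasts per outcome family, isolated spurious superscripts are
  expected.
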