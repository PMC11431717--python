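# Methods

## Time-to-threshold enumeration

A well inoculated with N₀ viable cells and grown at doubling time T_d
reaches a fixed cell count N* (equivalently, a fixed absolute OD threshold)
at

    t_c = lag + T_d · log₂(N*/N₀)

so crossing times are linear in log₂ N₀: one missing doubling delays t_c by
exactly T_d. All quantification reduces to differences of crossing times
scaled by a doubling time:

* relative survival of a sample vs a reference: Vn = 2^(−Δt_c/T_d);
* inferred initial-biomass ratio between two wells: same formula;
* absolute concentration: Q = N_min · Vn · (1000/V_inoc) CFU/mL, where
  N_min is one spread-plate count (CFU per inoculum) at the least-diluted
  rung of the linear range, which is defined as 100% viability. With the
  standard 5 µL inoculum the volume factor is exactly 200.

The crossing is computed on **raw** OD against the strain's absolute
threshold (0.3 OD for yeast-/*E. coli*-type presets, 0.15 for the
lactobacillus-type preset), linearly interpolated between the two bracketing
readings; a run that ends below threshold is censored, and a censored
sample's survival is reported as an upper bound 2^(−(duration − t_ref)/T_d).

## Per-well kinetics

1. **Baseline**: median of the first `baseline_n` (default 5) readings;
   corrected OD = max(OD − baseline, 10⁻⁴). The 10⁻⁴ floor keeps logarithms
   finite. Baseline noise is the sample SD of the same readings.
2. **Doubling time**: sliding windows of `window_w` = 5 consecutive points
   restricted to the band [max(3·noise, 5·floor), 0.75·od_max] of corrected
   OD are fit by least squares on log₂(OD). The window maximising
   slope − 2·SE(slope) wins, where SE is predicted from the multiplicative
   noise model (CV estimated from the baseline readings, so the penalty
   vanishes on noise-free data and selection is the plain max-slope rule).
   The winner is then refit over a w//2-widened in-band neighbourhood.
   T_d = 1/slope. No in-band window, or a non-positive best slope, raises a
   no-growth signal, which is distinct from a censored crossing.
3. **Lag**: the max-slope tangent extrapolated back to the initial corrected
   OD level (≥ floor), clamped at 0.

Two deliberate refinements over the textbook max-slope rule, both of which
reduce to it when noise is zero: near the baseline noise floor the log-scale
scatter is enormous, and a plain argmax over windows systematically rides
upward noise excursions (in simulation at 1% reader CV it halves the
apparent doubling time). The SE penalty removes the noise-floor windows
without any hard SNR cutoff, and the widened refit removes the residual
winner's-curse bias of the argmax. Measured on simulated ladders at 1% CV,
per-well T_d lands within a few percent of truth; noise-free wells recover
T_d to < 0.5%.

### What the lag estimate means

The tangent is referenced to the first corrected reading, which after
baseline subtraction is the floor for any realistic inoculum. The estimator
therefore returns lag + T_d·log₂(floor/(N₀·od_per_cell)): it recovers the
generative lag exactly when the initial biomass signal equals the floor, and
otherwise absorbs the (unobservable) inoculum level into the lag term. This
is an intrinsic property of floor-referenced tangent lags, not a bug: from a
single curve, initial biomass and lag are confounded — any combination with
the same lag + T_d·log₂(1/N₀) produces the same curve up to saturation.
The same confounding applies to heat-injury comparisons: a kill fraction and
a lag extension of the survivors both appear as a pure crossing delay, so
`damage.compare_treated` reports the raw time-to-threshold survival (the
delay expressed as a surviving fraction) plus descriptive crossing/lag
shifts, and the three-state call (normal / damaged / dead) uses configurable
thresholds: survival < 0.5, or lag shift > two sampling intervals, or a
fully censored well. The numeric thresholds are this package's convention;
the underlying assay reports damage qualitatively.

## Ladder calibration

Per dilution exponent, survival is pooled as the **geometric** mean over
detected replicates (survival is multiplicative). The provisional reference
is the least-diluted exponent with all replicates detected and none
saturated at t = 0. The doubling time used in Vn is pooled (median) over all
wells **more dilute than the reference** (`td_source="dilute"`): the
reference wells themselves carry a visible inoculum OD that the baseline
subtraction folds in, which biases their own slope windows (inflated by
N/(N−N₀) just above the band floor, deflated by 1−N/K near capacity), while
dilute wells grow through a clean exponential window. `td_source` can be
set to `"reference"` (each rung scaled by the reference's own fit) or
`"pooled"`.

The linear range is the longest run of ≥ 3 consecutive exponents whose
log₁₀(survival)-vs-exponent regression has slope within 1 ± 0.1 and
R² ≥ 0.99 (both configurable; the assay itself states no acceptance rule).
Ties go to the run containing the less-diluted points; survivals are then
renormalised so the accepted reference is exactly 1. The fit is done on the
log-log scale — decade-spaced data regressed on the linear scale would be
dominated by the top point. The stock estimate pools, geometrically, the
per-rung back-extrapolations N_min·Vn_k·200·10^(−k+ref) over the accepted
range.

## Trace statistics

Dropping n colonies independently and uniformly over s grid sectors gives
each sector Binomial(n, 1/s) occupancy; the Poisson(λ = n/s) approximation
is reported alongside (within 0.01 of the binomial for s ≥ 50). Observed
grid-plating fractions are realisations of this model and are compared
within two binomial standard errors at the grid size, not for equality —
with ~50 sectors the sampling noise dominates. The limiting-dilution (MPN)
estimator λ = −ln p₀ inverts the sterile fraction. `detectable_decades`
counts ten-fold dilutions from the reference while the expected cells per
well stay ≥ 1: the counting-statistics floor of the dynamic range. (A slow
strain can be time-limited to fewer decades by the 24 h horizon before it is
count-limited; that ceiling lives in the ladder calibration, not here.)

## The simulator

`simulate` generates the study conditions and is the oracle for every other
module. One well: N(t) = N₀ up to the lag, then logistic
K/(1 + (K/N₀ − 1)e^(−µ(t−lag))) with µ = ln2/T_d and K =
carrying_capacity_od/od_per_cell; OD = background + od_per_cell·N(t), each
reading multiplied by lognormal noise of CV `noise_cv`. Defaults: 5-min
grid, 24 h horizon, background 0.05 OD, carrying capacity 1.0 OD,
od_per_cell 3×10⁻⁸ (≈10⁷ cells read 0.3 above background — a hundred-cell
yeast inoculum reaches threshold within a day only after many doublings),
noise CV 1%. Ladders seed each well Poisson(stock·10^e·V/1000); a
deterministic mode (`poisson_seeding=False`) rounds the expectation, for
exact recovery tests. Heat treatment thins seeded cells binomially by the
kill fraction and extends the survivors' lag. All randomness flows from one
integer seed; identical inputs give bit-identical runs.

Presets: detection thresholds 0.3/0.3/0.15 OD are the assay's real
per-strain cutoffs; doubling times 90/25/60 min and lags 120/60/90 min for
the yeast-, *E. coli*- and lactobacillus-like presets are synthetic test
defaults, not measurements.

Key exactness property used by the tests: logistic curves sharing K and µ
but differing in N₀ are exact time-translates, so simulated crossing shifts
obey the shift law to machine precision (up to a (1 − N₀/K) correction that
matters only when the inoculum approaches capacity).

What the simulator does **not** emulate: medium/temperature effects on
growth (media appear only as metadata), condensation and edge effects,
reader saturation and pathlength artefacts, aggregated cells (one CFU = one
founder), or non-exponential injury recovery. Passing tests therefore show
the inference is correct *given* lagged-logistic growth with multiplicative
noise — not that real plates obey that model.

## Problem sizes and numerical choices

Test and acceptance simulations use 96-well-scale runs: ladders of 5–8
exponents × 6 replicates at 289 time points, three independent plates for
the noisy recovery checks (median-pooled, mirroring the repeated-plate
protocol), and 10⁵ Monte-Carlo placements for occupancy — everything runs in
seconds. Ties in window selection go to the earliest window; duplicate
(well, time) readings, ragged wells and non-monotone time grids are hard
errors; CSV round trips are bit-exact (shortest-repr floats on write,
round-trip parsing on read). Degenerate fits (≤ 2 in-band points) signal
no-growth rather than returning numbers.

## Known limitations

* Survival > 1 (sample denser than its reference) is allowed but flagged;
  whether that is meaningful depends on the experiment.
* N_min must come from outside (one spread-plate count); without it the
  method yields only relative survival.
* The lag estimate is floor-referenced (see above) and comparable only
  between wells of equal inoculum.
* Heavily saturated rungs (already above threshold at t = 0) cannot be
  quantified and are excluded from reference eligibility; the linear-range
  search handles the rest.
* At 5% reader CV the deep rungs of a single ladder amplify doubling-time
  error (the exponent multiplies Δt/T_d); pooling a few independent plates
  is the practical remedy.
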