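# Methods

## Model

The circuit is described by delay differential equations for eight
intracellular concentrations: T7-polymerase mRNA and protein
(`m_T7`, `p_T7`), GFP mRNA (`m_G`), the GFP folding intermediate (`g_F`),
natively folded GFP (`g_N`), inclusion-body GFP (`g_I`), and TetR mRNA and
protein (`m_R`, `p_R`).  Units are hours and arbitrary concentration units
(nominally nM); IPTG is in mM.

Transcription of each gene reads the regulator state one transcription
delay `tau_tx` earlier; translation reads mRNA one translation delay
`tau_tl` earlier.  Regulatory inputs are Hill functions:

- IPTG activation of the T7-polymerase gene,
  `basal_T7 + (1−basal_T7)·I^n/(K_iptg^n + I^n)` — at the standard 1 mM
  induction this is effectively saturated;
- TetR repression of the hybrid T7/tetO GFP promoter,
  `1/(1 + (p_R/K_tetR)^n)`;
- stress activation of the TetR gene,
  `basal_R + (1−basal_R)·s^n/(K_stress^n + s^n)` with stress signal
  `s = g_F + g_I`.  The sensor tracks the **misfolded + aggregated load**,
  not total product, because IbpA/B-type regulators respond to aggregated
  protein; a basal activity remains without stress.

Every species is diluted by growth at a constant rate `mu0` and degraded
first-order; TetR carries a degradation tag (`d_R` large), which keeps the
feedback responsive.

**Protein fate.** Folding intermediates either fold to the native state,
aggregate into inclusion bodies (first order, `k_agg`), or are
degraded/diluted.  Folding is saturable,
`fold(g_F) = k_fold·g_F/(1 + g_F/K_fold_sat)`, representing finite
chaperone/foldase capacity: at high expression load the folding flux
saturates and the surplus partitions into aggregates.  This is the
mechanism that makes the soluble fraction *load-dependent* — with strictly
first-order folding the soluble fraction would be invariant to expression
flux and the feedback could not improve product quality, only reduce yield.
Setting `K_fold_sat = inf` recovers the purely first-order partition.
Soluble aggregates are not a separate pool; `g_F` plays the dual role of
intermediate and soluble-aggregate pool, since end-point data resolve only
soluble vs insoluble.  Inclusion-body protein is cleared at `k_ib_deg`
(proteolytic targeting of aggregated polypeptides).

**Observables.** `total_gfp = g_F+g_N+g_I`; `soluble_fraction =
(g_F+g_N)/total` (defined as 1 for an empty cell); fluorescence corresponds
to **native GFP only** (`g_N/c_fluor`), because fluorescence of IB-trapped
GFP is contested and mapping fluorescence to the folded pool keeps the
calibration interpretable.  Total GFP is exposed separately for
SDS-PAGE-like data.

**Feedback variants** scale the stress-promoter strength
(`promoter_scale`, multiplying both maximal and basal TetR transcription)
and the TetR RBS strength (`rbs_scale`, multiplying `k_tl_R`).  The four
canonical setups are NO_FB (0, 1), WT_STRONG (1, 1), MUT_STRONG (0.5, 1)
and MUT_WEAK (0.5, 0.4).  NO_FB with zero basal stress activity is exactly
equivalent to deleting the TetR equations.

## Parameters

The default `CircuitParameters()` is the package's canonical calibrated
fixture: a batch M9-glucose-like culture (`mu0 = 0.6/h`), mRNA half-life
~14 min (`d_m = 3/h`), delays `tau_tx = tau_tl = 0.2 h`, a strong GFP
cassette (`k_tx_G = 4/h` per polymerase, `k_tl_G = 40/h`), folding capacity
`k_fold = 2/h` with `K_fold_sat = 1000`, aggregation `k_agg = 2/h`,
IB clearance `k_ib_deg = 0.25/h`, tight TetR repression (`K_tetR = 30`,
`n = 2`, `d_R = 2/h`), and stress half-activation `K_stress = 1200` with
`n = 2`.  These values were chosen so the simulated study conditions
reproduce the characterized behavior of the circuit family: end-point GFP
ordered NO_FB > MUT_WEAK > MUT_STRONG > WT_STRONG, a maximal post-induction
reduction of ~70% for the strong feedback, and 8-h soluble fractions
increasing with feedback strength (0.47 → 0.53).  Individual kinetic
constants are not independently measured quantities and should be re-fitted
when real data are available; `c_fluor` (concentration per normalized
fluorescence unit) in particular is instrument-specific and is kept
configurable/fittable.

## Numerics

**Method of steps.** The horizon is split at multiples of the shortest
positive delay (plus the induction time and its delay-propagated images);
on each interval the delayed terms are read from stored dense-output
history, so each interval is an ordinary IVP solved by `solve_ivp`
(LSODA, rtol 1e-8/atol 1e-10 by default).  History before t=0 is the
constant pre-induction steady state.  With both delays zero the scheme
degenerates to plain stepping.  Delayed lookups use the solver's own
interpolant (`history_interp="cubic"`) or linear interpolation between
accepted steps.

**Pre-induction steady state.** Constant solutions of the DDE satisfy the
same balance equations as the delay-free system, so the burn-in integrates
the plain ODE from an empty cell in chunks (budget `50/mu0` hours) until
every species' |derivative| < `steady_state_tol` (1e-7 conc/h);
non-convergence raises an error naming the slowest species.  Auxiliary
flux accumulators are zeroed in the returned state.

**Negative states.** Accepted solution values below −1e−9 abort the
integration; values in [−1e−9, 0] are clamped to zero.  Solver *trial*
values are clamped before evaluating the right-hand side (implicit methods
probe negative excursions legitimately); direct calls to `rhs` with
negative species still raise.

**Verification.** An intentionally naive fixed-step explicit Euler
integrator with ring-buffer delayed lookups serves as an independent
oracle: at dt = 1e−4 h it agrees with the production integrator to a
species-scaled maximum relative error ~1e−4 (< 1e−3 asserted), and the
zero-delay limit matches a Radau reference at rtol 1e−11 to < 1e−6.
Mass balance is checked through auxiliary cumulative-flux states
(translated = Δpools + degraded + diluted).

## Calibration

Fitting minimizes squared **log** residuals between the model fluorescence
observable and observed fluorescence-per-OD (multiplicative noise), plus
linear residuals on end-point soluble fractions weighted by
`sqrt(n_records/n_fractions)` so both data kinds contribute comparably.  A
fixed offset of 1e−6 × max(observed) keeps logs finite and the objective
order-invariant.  Free parameters are optimized in log10 space by
trust-region-reflective least squares within bounds (default: one decade
either side of the initial value), with Latin-hypercube multi-start
(default 20 starts; the first start is the user's initial guess) seeded for
reproducibility.  A finite-difference step of 2% in log10 space keeps the
numerical Jacobian above the integrator's error floor.  Underdetermined
requests (fewer distinct measurement coordinates than free parameters, or
a rank-deficient Jacobian at the optimum) emit `IdentifiabilityWarning`.

Not all parameter subsets are identifiable from fluorescence alone: the
TetR transcription rate and the repression constant are ridge-correlated
(approximately only their ratio enters once the stress promoter
saturates), so they separate cleanly only on noiseless data.  The
parameter-recovery benchmark therefore uses the identifiable trio
{`k_tx_G`, `K_tetR`, `k_agg`} and achieves median relative errors of
2–7% per parameter over 20 datasets at 5% noise (4 clones, 2 starts).

**Sensitivity.** Normalized coefficients are logarithmic central
differences `S = Δln y / Δln θ` over `θ(1±h)` (default h = 0.05), exact
for power-law dependence (e.g. S = −1 for `c_fluor` against fluorescence);
zero outputs fall back to an absolute-scale difference with a flag, and
zero parameters report S = 0.  Parameters are ranked by mean |S| over the
requested outputs.  At the calibrated operating point the top-ranked
processes are growth/dilution (`mu0`) and repressor production
(`k_tl_R`/`k_tx_R`) — the two processes the circuit's robustness hinges on.

**Cross-validation.** Grouped k-fold over biological clones (or whole
variants): units are shuffled with the seed, each fold's free parameters
are refitted on the remaining units, and mean squared residuals are
reported for both splits.  Noiseless synthetic data yield test ≈ train ≈ 0;
at 10% noise the test/train ratio stays near 1.

## Synthetic data

The generator emulates the study conditions: inoculation at OD600 0.1,
exponential growth at the clone's rate capped at OD 4.0, induction with
1 mM IPTG at 2 h, sampling every 0.5 h over 12 h, four biological
replicates per construct, and an 8-h fractionation with totals relative to
the no-feedback construct (reference content 1).  Clone variability is
lognormal on promoter scale, RBS scale and growth rate (sigmas 0.2, 0.2,
0.05 — replicate scatter of the kind attributed to clone-specific cell
state and growth differences); measurement noise is mean-one lognormal on
fluorescence and OD (CVs 0.10 and 0.05) and additive truncated Gaussian on
fractions (sd 0.05).  True replicate noise magnitudes are not independently
known; these defaults are conventions of the fixture.  What the generator
does **not** emulate: growth burden feedback on `mu0` (the model's growth
rate is constant; a medium change is represented only by changing `mu0`),
lag/stationary-phase physiology, autofluorescence background, and
single-cell stochasticity.  Passing recovery/cross-validation tests on
these data therefore demonstrates correctness of the estimation machinery
under the model's own assumptions, not robustness to structural mismatch
with real cultures.

## Design notes and limitations

- Growth dilution uses a constant `mu0` throughout (the pre-induction
  value); burden-coupled growth is deliberately out of scope.
- The soluble-fraction monotonicity invariant is asserted over a 5×5
  promoter × RBS scale grid spanning [0, 1] — the range the characterized
  variants occupy.  Beyond wild-type strength (scales > 1) the end-point
  fraction can wobble non-monotonically by a few tenths of a percent due to
  delayed-feedback overshoot phasing; this regime is extrapolation and is
  not asserted.
- Discontinuity tracking is limited to the induction event and its
  delay-propagated images; state-dependent delays are not supported.
- The headline "maximal reduction" is computed on total GFP; the
  fluorescence-based reduction is reported alongside and is smaller
  because feedback simultaneously shifts the partition toward the
  fluorescent native pool.
- Problem sizes used by the test and acceptance suites (20 recovery
  datasets, 2 optimizer starts, hourly cross-validation sampling, 5×5
  invariant grid) are the package's standard benchmark configuration,
  chosen to exercise every code path at meaningful statistical resolution.
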