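# Methods

## The model

`fmpools` simulates one presynaptic terminal as a small compartment model of
vesicle pools, tracked in continuous mean field with per-dye label
bookkeeping. The default, *parallel* organization has two independent paths:
a fast-releasing readily releasable (RRP) subdivision fed by a quickly
mobilized reserve, and a reluctant RRP subdivision fed by a slowly mobilized
reserve. Alternative organizations are provided as comparators: *serial*
(one release path whose proximal reserve is backfilled by a deep reserve)
and *lifo* (a single reserve stored as a last-in/first-out stack).

Per action potential, each readily releasable vesicle releases with a
per-path probability; released dye is lost instantly and completely (no
partial kiss-and-run retention), and the recycled membrane re-enters a
reserve pool, labeled with whatever dye is in the bath. Total vesicle
number is therefore conserved by construction; only labels move. Between
pulses, vacant RRP space is refilled from the path's reserve by first-order
recruitment (rate shared across paths), computed as exact exponential
updates rather than Euler steps.

Two kinetic regimes follow from the parameters rather than being imposed:

- **Low frequency (1 Hz).** Recruitment outpaces release, the RRP stays
  >90% occupied, and each path destains as a single exponential in its own
  rate; the terminal's trace is exactly the weighted sum of two
  exponentials. This exactness (used as a 1e-6 equivalence test against the
  closed form) relies on two idealizations: recycled vesicles returning to
  their source path, and instantaneous label homogenization within a path.
  The latter idealizes the spontaneous RRP↔reserve exchange, whose ~1/min
  timescale is fast against the 5–30 min destaining time constants.
- **High frequency (20 Hz).** Release drives both RRP subdivisions to a
  near-empty steady state within a few seconds, and destaining becomes
  recruitment limited. Because the recruitment timing is shared, the 20 Hz
  trace is a single exponential with τ = 1/recruit_rate ≈ 28 s regardless
  of how stain is distributed across paths — which is why a 20 Hz train
  measured after prior 1 Hz destaining overlays the naive 20 Hz trace for a
  parallel organization, and why that overlay discriminates topologies.

### Release probability is regime dependent

A single per-AP release probability calibrated to the 1 Hz destaining rates
(≈0.026 fast, ≈0.004 reluctant per vesicle) cannot empty the reluctant RRP
subdivision at 20 Hz: its demand (20·p·R ≈ 0.3 vesicles/s) would stay below
the recruitment supply (≈0.9 vesicles/s) and the pool would never approach
the near-empty steady state that high-frequency trains are known to
produce. The model therefore carries a second pair of per-AP probabilities
used at and above `hf_threshold_hz` (default 10 Hz): `p_release_hf =
(0.15, 0.08)`, i.e. the fast subdivision empties with τ ≈ 0.3 s and the
reluctant one with τ ≈ 0.6 s of 20 Hz drive. This represents the
Ca²⁺-dependent facilitation of reluctant release at high stimulation rates;
the two regimes bracket the frequencies the protocols actually use.

### Recycled-vesicle targeting

The default recycle rule is `quick_first`: during low-frequency stimulation
recycled vesicles join the quickly mobilized reserve, and the resulting
inflow excess displaces quick-reserve-composition vesicles into the slow
reserve, conserving pool sizes; during high-frequency stimulation vesicles
return to their source path (at 20 Hz both reserves cycle, so dye loads
into both). This reproduces, rather than assumes, the two observations the
staining experiments established: loading at 1 Hz labels (almost) only the
quickly mobilized reserve, loading at 20 Hz labels both. Under the simpler
`return_to_source_path` rule (retained, and used wherever exact
biexponentiality is wanted) the reluctant path's own releases during a
1 Hz stain contaminate the slow reserve with ~27% of the new dye, capping
the simulated two-color ratio near 3.4 instead of the observed ≥4.
`proportional_split` is retained for ablation.

### Comparator topologies and the full-stain premise

- **Serial** (`default_serial`): deep reserve → proximal reserve → RRP.
  Maturation (default 1/30 min⁻¹) both backfills proximal vacancies
  (capacity capped, so pool sizes hold) and exchanges labels between the
  two reserves — the two-compartment relaxation that predicts recovery of
  fractional destaining during rest intervals, growing with rest duration.
  The default rate is slow against the fast path rate (so 1 Hz rundown
  still appears and the deep reserve retains stain over 25 min) yet fast
  enough that 1–8 min rests produce measurable recovery.
- **LIFO** (`default_lifo`): recycled vesicles push onto the top of a
  reserve stack and are mobilized first. At 1 Hz, the growing unlabeled cap
  collapses fractional destaining (extreme rundown). With
  `mixing_rate > 0` and `mixing_active_above_hz` set, a 20 Hz probe
  homogenizes the stack — the activity-dependent mixing signature that the
  interleaved-probe experiment tests for.

Simulated 20 Hz loading cannot stain the serial deep reserve or the LIFO
stack interior (bath dye only enters at each topology's recycling entry
point), while the corresponding experiments verified that loading labels
the whole recycling pool. Discriminator runs for these comparators
therefore start from an ideally, uniformly stained state
(`run_experiment(..., ideal_stain=...)`, automatic for serial/LIFO); the
parallel model is always loaded by simulation.

## The destaining analysis

- **Normalization.** `F = (F_raw/bg − plateau)/(baseline − plateau)`:
  background-divided, plateau-subtracted (the signal remaining after the
  exhaustive final 20 Hz train), scaled so the baseline-window mean is 1.
- **QC.** Traces are accepted when the pre-stimulation baseline loss is
  ≤ 1.5 %/min in absolute value (boundary inclusive), measured as the OLS
  slope over the rest window divided by the fitted window-start intensity.
- **Windowed fractional destaining.** Over a half-open window (frames
  assigned by acquisition time), an OLS line gives the slope and the fitted
  intensity at the window start; `k̂ = −slope/F_start` (min⁻¹). The
  estimator is scale invariant. It is *interval averaged*: on a pure
  exponential it reads low by ≈ k·T/2 for window length T, so the standard
  early (1.5 min) and late (4 min) windows give a ratio of ≈ e^(1.25k)
  rather than exactly 1 on a single pool. The single-pool constancy check
  therefore runs at the calibrated slowly mobilized rate (0.032 min⁻¹,
  ratio 1.039) — the regime the late windows probe; at faster rates the
  estimator bias itself exceeds the 5% band without any second pool.
- **Baseline correction** subtracts an independently estimated loss rate b
  (min⁻¹) from the windowed estimates. Drift is modeled as multiplicative
  exponential loss, which adds (to first order) to the destaining rates and
  so matches the subtraction-based correction.
- **Exponential fits.** The single-exponential fit is `e^(−k·t)` with unit
  amplitude and k bounded to [0, 0.3] min⁻¹ (bounded trust-region least
  squares started at 0.002 plus a log-slope start; the printed start point
  −0.002 lies outside the bounds, so its bound-clipped equivalent is used,
  and multi-start guards the upper bound). The double-exponential fit is
  `w·e^(−kf·t) + (1−w)·e^(−ks·t)` with unit total amplitude, five starts,
  rates ordered kf ≥ ks on output, and a non-identifiability flag when the
  rates coincide or a weight collapses (the weight then carries no
  information).
- **Residual diagnostics.** Lack of fit is tested with the Wald–Wolfowitz
  runs test (continuity corrected) on the signs of the raw residuals; the
  paper does not name its non-parametric test, and the runs test is the
  natural choice for the smooth residual structure at stake. Its measured
  type-I error at the standard trace length (375 frames) is 0.049 at
  α = 0.05. A trace is flagged an outlier when any raw residual exceeds
  0.25 in magnitude; the 5-frame centered moving average (edge truncated)
  is reported for display.
- **Population summary.** Per-frame median within each preparation, then
  mean ± s.e.m. across preparations (the exact averaging formula is not
  printed; this matches the figure captions' description).

## Calibration of the synthetic defaults

`calibrate()` solves for the biexponential rates such that the windowed
estimator applied to the noiseless trace (4 s frames) returns exactly
0.087 min⁻¹ on minutes [0, 1.5) and 0.032 min⁻¹ on [21, 25) with the fast
weight fixed at 0.39: a 2-D root find giving k_fast = 0.2008 min⁻¹ and
k_slow = 0.0319 min⁻¹ (fold decrease 2.72). The baseline rate b solves
(0.087 − b)/(0.032 − b) = 4.4 by bisection: b = 0.01582 min⁻¹. Because the
raw printed interval values already contain the baseline loss, the
*drifting* generator uses rates re-solved with the loss active
(0.1849, 0.0161 min⁻¹) so its raw windowed estimates still print
0.087/0.032; subtracting the re-estimated b̂ then yields the corrected
ratio (≈4.34 computed, the ≈1.5% shortfall being the curvature bias of
estimating an exponential loss with a linear fit over 2.5 min).

The simulator's default per-AP release probabilities derive from these
rates by the exact per-pulse conversion `p = (1 − e^(−k/60))·N/R`, with
pool sizes RRP 6 and reserve 40 vesicles split 0.39/0.61 between paths and
recruitment 1/28 s⁻¹ (so 100 s of 20 Hz completes destaining, τ ≈ 28 s).

## The synthetic-data generator

Per-ROI traces follow the full experiment timeline (2.5 min baseline,
25 min 1 Hz, 4 min rest, 100 s 20 Hz, plateau tail; frame grid anchored at
the destain onset) with: per-ROI fast weights Beta-distributed around 0.39,
rates log-normal around the calibrated defaults (log-sd 0.25), log-normal
brightness, an optional multiplicative drift on a fraction of ROIs (uniform
up to the 1.5 %/min QC limit), and additive Gaussian noise (sd 0.01 on the
normalized scale — the reference data's noise magnitude is not printed, so
this is a working default). Heterogeneity laws are generator configuration
emulating the observed punctae-to-punctae variability, not claims about the
data. The generator does not emulate shot noise or camera gain, focal
drift, photobleaching, image misregistration, overlapping punctae in dense
fields, or the deposit's file layout — so green tests bound estimator and
pipeline behavior under the stated noise model, not under every pathology
of real recordings. Optional image stacks render each punctum as an
isotropic Gaussian PSF scaled by its trace over a constant background with
Gaussian camera noise; the ROI detector is a deliberately simple
blob-detection stand-in validated only against this synthetic truth
(punctae closer than the PSF scale merge — a documented limitation).

## Numerical choices

- All pool updates (recruitment, maturation, mixing, drift) are exact
  exponential relaxations over each interval; pulse updates are exact
  per-pulse maps. Samples at time t reflect pulses strictly before t.
- Windows are half-open `[t0, t1)` everywhere (frames by acquisition time);
  pixel ROIs are half-open in both axes, coordinates 0-based.
- The per-pulse/continuous rate conversion uses `1 − e^(−k/(60f))` exactly,
  so simulated and closed-form traces agree to machine precision where the
  idealizations hold.
- Degenerate inputs: flat traces normalize to zero signal rather than
  erroring; non-convergent fits are flagged, not raised; a biexponential
  fit of single-exponential data reports the degenerate solution flagged
  non-identifiable.
- Problem sizes in the shipped tests and acceptance runs: 375-frame traces
  (25 min at 4 s), 1000-ROI populations, 200-replicate recovery and
  1000-replicate type-I Monte Carlos — sizes chosen so every stage runs in
  seconds to a few minutes on one core while keeping binomial error small
  against the tested margins.

## Known limitations

- The parallel model's no-recovery statistic after an interleaved 20 Hz
  probe computes to ≈0.96 rather than exactly 1.0: the probe leaves the
  RRP near empty, and the first frames of the resumed 1 Hz train sit on
  the (tens of seconds) refill transient; the corresponding check asserts
  "no recovery" (≤1.02), not exact unity.
- The deep reserve beyond the recycling pool is not modeled; vesicles that
  do not mobilize within the protocols simply do not exist in the model.
- Temperature enters only as alternative rate parameters; there is no
  mechanistic temperature model.
- The LIFO comparator's mean-field stack cannot be stained by simulated
  loading (recycled layers churn at the top), hence the ideal-stain
  convention above.
- Electrophysiology (EPSCs, calcium dynamics), vesicle spatial diffusion,
  and condensate physics are out of scope.
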