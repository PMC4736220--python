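# Methods

## The measurement model

A phantom dose experiment delivers, per protocol, n_exposures exposures of
exposure_s seconds to a phantom head with k TLDs at each of L locations.
The read-out oven reports pulse counts. The deterministic calculation
chain is:

1. **Calibration.** A set of n_cal dosimeters receives a known dose
   D_cal (mGy). Each dosimeter's calibration factor is CF_i =
   pulses_i / D_cal; the chain uses the mean CF (pulses/mGy). The RSD of
   {CF_i} (sample SD, n−1 denominator, as everywhere in the package) is
   the calibration error component.
2. **Background.** n_bg unexposed dosimeters per protocol; their mean
   pulse count is subtracted from every exposed reading *in pulse units,
   before CF division*: dose(loc) = (mean pulses at loc − mean bg)/CF.
   Subtracting in pulse units is the only order consistent with CF
   having units pulses/mGy. Negative corrected doses are clamped to 0
   with a warning (physical doses are non-negative); clamping is
   switchable off for variance studies.
3. **Tissue doses.** D_T = fraction_T · mean(dose over the tissue's
   locations). A location may feed several tissues (e.g. bone surface
   and red bone marrow sampled at the same drill hole); the layout
   format permits that overlap.
4. **Effective dose.** E = e_scale · Σ_T w_T·D_T. With doses in mGy the
   weighted sum is numerically in mSv (radiation weighting factor 1 for
   X-rays); the layout's `e_scale` (default 1000) reports E in µSv. The
   shipped ICRP-103 weight table sums to 1; a head/neck layout that
   carries only in-field tissues is a *partial* table, allowed and
   exposed via `PhantomLayout.has_complete_weight_table`.
5. **Single-exposure conversion.** E is reported per clinical exposure
   by dividing by ratio = n_exposures·exposure_s / single_exposure_s
   (50 × 5 s / 0.6 s ≈ 416.7).

## Error models

All random errors are modelled as Normal perturbations around the
measured value with SD = value·RSD/100.

* **CF**: component RSD = RSD of the individual CFs. Because the chain
  uses the *mean* of n_cal dosimeters, the default "mean-of-n" mode
  perturbs the mean CF with RSD/√n_cal; a "direct" mode applying the raw
  RSD is provided because the scaling convention is a genuine modelling
  choice (the final RSD of E is only arithmetically consistent with
  published totals under mean-of-n, which is why it is the default —
  but both are first-class).
* **Background**: same two modes, per protocol, with n = number of
  background dosimeters (default 3).
* **Read-out**: RSD depends on the value. It is estimated by computing
  the pair RSD of the k duplicate dosimeters at every protocol ×
  location, and fitting an unweighted OLS quadratic of pair RSD on the
  pair *mean* value (the symmetric choice of abscissa). Fits predicting
  RSD ≤ 0 anywhere inside the observed value range are rejected; a
  constructed all-zero model (a noise-free read-out) is allowed for
  round-trip testing. The shipped default coefficients
  (4.57, −1.98e−7, 3.29e−15), valid on 0–3.0e7 pulses, derive from a
  lateral-cephalography TLD study; the quadratic is strictly decreasing
  over that range (its vertex lies just beyond 3.0e7). Coefficient
  standard errors from the OLS covariance are stored when ≥4 points are
  available, enabling recovery tests at 3·SE.
* **Generator**: a per-exposure output RSD r (default 2.4%, a
  bench-measured magnitude); averaging over n exposures gives r/√n,
  which perturbs the single-exposure conversion ratio. It is the one
  component not estimable from the TLD tables.

## The Monte Carlo engine

Per cycle: one CF draw **shared by all protocols** (the experiment
calibrated once; a CF error shifts all protocols together and cancels
from their differences — independent draws would overestimate the RE of
protocol differences, and an `shared_cf=False` mode exists precisely to
quantify that), one background draw per protocol, one draw per dosimeter
reading with RSD evaluated at that reading, and one conversion-ratio
draw per protocol with RSD = r/√n_exposures. Background draws are
independent across protocols (backgrounds were measured per protocol).
Negative perturbed pulses and doses are clamped at 0 and counted in the
result diagnostics; at the shipped component magnitudes clamping is
rare.

Summaries: mean, sample SD, RSD, empirical percentile CI and the
five-number box-plot summary, all using numpy's linear-interpolation
(type-7) quantiles for bit-exactness. Comparisons are cycle-wise paired
differences with a percentile CI; "significant" means the CI excludes 0.
Comparisons are a method of one `SimulationResult`, so comparing
protocols from different runs is unconstructible by design; requesting a
protocol absent from the run raises.

Reproducibility: one master seed; streams are split per component and
per protocol (seeded from the master seed plus a CRC of the protocol
name), with a fixed draw order (readings, background, ratio) inside a
protocol's stream. Adding or removing a protocol therefore does not
disturb any other protocol's draws, and identical inputs + seed +
cycles give bit-identical samples. Default cycles: 10,000.

## The synthetic-data generator

`default_truth()` emulates a 4-protocol × 25-location × 2-TLD
cephalography study: CF spread 3.2% on a 53-dosimeter calibration set
(2·25 + 3, the experiment's own TLD count — the real calibration-set
size is an assumption), background RSDs 9.5/4.6/8.6/1.3% on 3 dosimeters
per protocol, the default read-out quadratic, generator 2.4% per
exposure, 50 × 5 s exposures reported per 0.6 s. The true dose pattern
across locations is unpublished in any study, so it is *illustrative*:
log-spaced over 1–100 mGy (at CF 2.5e5 pulses/mGy that spans 2.5e5–2.5e7
pulses, exercising both the high-RSD and low-RSD ends of the read-out
quadratic), shuffled once with a fixed seed, and scaled per protocol
(1.0/0.85/0.70/0.55) to mimic shielding. The illustrative head/neck
layout likewise has the right structure (partial ICRP table, shared
locations, partial irradiated fractions) without representing a specific
phantom.

Generated tables: exposed readings = true_dose·CF_true + background mean,
perturbed with the read-out RSD evaluated at the noise-free pulse value;
calibration pulses carry the per-dosimeter CF spread; background readings
are drawn per protocol. Two deliberate simplifications: (a) the exposed
readings use the common true CF — the pair scatter of duplicates is
wholly attributed to the read-out model, which keeps the generator
consistent with the estimator that refits that model from pair RSDs;
(b) generator fluctuation does not appear in the tables (TLDs integrate
whatever dose was delivered; the component enters the simulation at the
conversion step). Consequence of (b): in power analyses the simulated CI
is very slightly conservative, since the engine adds ratio noise that
the generated data do not carry.

What passing tests on synthetic data do *not* show: recovery of any real
study's per-protocol E values (data-dependent and unpublished), TLD
physics (fading, energy response), or systematic errors — which are by
nature unquantifiable and excluded from scope.

Pair RSDs from k = 2 duplicates are biased low as estimators of the
underlying RSD (E[s] = c4(2)·σ ≈ 0.80σ); parameter-recovery tests of the
quadratic therefore use a 40-dosimeter-per-location design (c4 ≈ 0.994),
while the default design stays at the realistic k = 2.

## Design / power analysis

A `DesignVariant` fixes dosimeters per location, exposures per protocol,
the injected true relative E difference, alpha, and the simulation sizes.
`estimate_rsd_for_design` averages the per-protocol RSD of E over
replicate synthetic experiments; `estimate_power` builds a two-protocol
truth in which the second protocol's true doses are the first's scaled by
(1 + Δ%), and reports the fraction of replicates whose paired percentile
CI excludes 0. With Δ = 0 this estimates the type-I error, which
calibrates to alpha. Changing the exposure count scales the true
protocol doses proportionally (each exposure adds the same dose), leaving
true E per single exposure unchanged. Defaults (200 replicates × 2,000
cycles) keep a full sweep in the minutes range on one CPU; the shipped
examples and tests use smaller sizes, stated inline, chosen so the whole
suite runs in seconds.

## Numerical notes

* Sample SDs use the n−1 denominator throughout; a single background
  reading reports RSD 0 (spread unobservable).
* The quadratic fit uses `numpy.polyfit` directly on pulse abscissae;
  at the 1e7-pulse scale the recovery error is ~1e−15 relative, so no
  rescaling is needed.
* Quantiles are type-7 everywhere (documented for bit-exactness of
  box-plot output).
* Monte Carlo assertions in the tests use the large-sample standard
  error of a sample SD, SE ≈ SD/√(2(n−1)), with 3·SE bands; binomial
  proportions use exact-variance normal bands.
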