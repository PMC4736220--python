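# dosesim

Monte Carlo random-error propagation for phantom-head dosimetry.

## The problem

Comparative dose studies in maxillofacial radiology expose an
anthropomorphic phantom head carrying thermoluminescent dosimeters (TLDs)
at specified locations, once per candidate exposure protocol, and derive
the ICRP effective dose

    E = Σ_T  w_T · D_T        (w_T: tissue weighting factor,
                               D_T: fraction-weighted mean tissue dose)

from the TLD read-outs. Every step of that chain carries random error
(RE): the calibration factor (CF) that converts oven pulse counts to mGy,
the background correction from unexposed TLDs, the read-out process
itself — whose relative error *depends on the read-out value* — and the
fluctuating output of the X-ray generator. Because the same dosimeter
readings enter several tissue doses, analytic error propagation is
impractical; without it, studies report E without a confidence interval
and protocol comparisons cannot be tested.

`dosesim` quantifies each RE source from the measured data, then
propagates them by brute force: it recomputes E thousands of times
(default 10,000 cycles) while perturbing every measured quantity with a
Normal draw scaled by its RSD (relative standard deviation,
100·SD/mean). The sampled distribution of E yields its SD/RSD and
percentile confidence intervals; because all protocols are recomputed
inside the same cycle with one shared CF draw, cycle-wise paired
differences give properly calibrated protocol comparisons. The same
machinery runs prospectively as a design/power analysis (how many TLDs
per location? how many exposures?).

The error models are:

* **CF**: RSD of the individual dosimeter CFs (a mean of n dosimeters is
  perturbed with RSD/√n by default);
* **background**: per-protocol RSD of the unexposed TLDs;
* **read-out**: a quadratic fitted to duplicate-pair RSDs,
  `RSD(v) = a0 + a1·v + a2·v²` with v in pulses — high read-out values
  are relatively more precise, and ignoring that would overestimate the
  RE of E since large values dominate the weighted sum;
* **generator**: a per-exposure output RSD r that enters the protocol →
  single-exposure conversion as r/√n_exposures (mean-of-n propagation;
  2.4% per exposure becomes 0.34% over 50 exposures).

Raw read-out tables of real studies are rarely published, so the package
includes a synthetic-data generator with the full statistical structure
of a 4-protocol × 25-location × 2-TLD cephalography study and known
ground truth, making every estimator testable for parameter recovery.

## Worked example

```python
from dosesim import default_truth, generate_experiment, run_simulation

truth = default_truth()                      # 4 protocols × 25 locations × 2 TLDs
measurements, true_e = generate_experiment(truth, seed=7)
result = run_simulation(measurements, truth.layout, truth.error_model(),
                        cycles=10_000, seed=2)
for p in result.protocols:
    s = result.summaries[p]
    print(p, round(s.mean, 3), round(s.sd, 3), round(s.rsd_percent, 2))
```

prints (see `examples/03_monte_carlo_simulation.py`):

```
protocol    true E  mean E     SD  RSD%   95% CI (µSv/exposure)
P1           5.478   5.472  0.060  1.10   [5.353, 5.591]
P2           4.656   4.630  0.055  1.19   [4.523, 4.739]
P3           3.835   3.896  0.051  1.30   [3.797, 3.996]
P4           3.013   2.996  0.043  1.43   [2.912, 3.080]
```

Each row is one protocol's E per single 0.6 s exposure in µSv: the mean
and SD of the 10,000 recomputations, the resulting total RSD of E
(≈1.1–1.4% here, driven by the four error components above), and the
empirical 95% percentile interval. `result.compare("P1", "P2")` then
tests the paired difference; `examples/04_protocol_comparison.py` shows
why the shared CF draw shrinks the difference CI, and
`examples/05_power_analysis.py` turns the simulator into a design/power
tool.

A thin CLI mirrors the library: `dosesim synth`, `dosesim fit-rsd`,
`dosesim simulate`, `dosesim power` (see `--help`).

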