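"""Prospective design analysis: dosimeters per location, and power.

Before running a phantom study the simulator can answer two planning
questions: how much random error a design leaves in E (here: one vs two
TLDs per location), and the power to detect a stated true difference
between two protocols at the chosen design.

Replicate/cycle counts are kept modest so the example runs in seconds;
increase them for smoother estimates.
"""

from dosesim import DesignVariant, default_truth, estimate_power, estimate_rsd_for_design

truth = default_truth()

for k in (2, 1):
    variant = DesignVariant(
        dosimeters_per_location=k, replicates=10, cycles=2000
    )
    rsd = estimate_rsd_for_design(truth, variant, seed=0)
    print(f"{k} dosimeter(s) per location: RSD of E = {rsd:.2f}%")
print("(fewer dosimeters -> larger read-out component -> larger RSD)")

for diff in (1.0, 3.0, 6.0):
    variant = DesignVariant(
        relative_difference_percent=diff, replicates=60, cycles=1000
    )
    power = estimate_power(truth, variant, seed=1)
    print(
        f"power to detect a true {diff:.0f}% E difference (alpha 0.05): "
        f"{power:.2f}"
    )
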