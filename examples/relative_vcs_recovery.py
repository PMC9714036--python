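"""Recover a known relative citrate-synthase flux from noisy data.

Two conditions are simulated with a true V_CS ratio of 2.0, pushed
through the measurement model (natural-abundance convolution + additive
MS noise, 5 replicates), corrected, and the relative flux is estimated
as the ratio of M+2 citrate slopes over the 0-30 min window.
"""

from tcaflux.experiments import vcs_recovery_experiment

res = vcs_recovery_experiment(seed=1, true_ratio=2.0)

print(f"true V_CS ratio:       {res['true_ratio']:.2f}")
print(f"recovered ratio:       {res['recovered_ratio']:.3f}")
print(f"relative error:        {100 * res['relative_error']:.1f}%")
print(f"reference slope:       {res['slope_reference']:.5f} /min")
print(f"test slope:            {res['slope_test']:.5f} /min")
print("\nA relative error within ~10% shows the slope readout recovers "
      "flux ratios under realistic measurement noise.")
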