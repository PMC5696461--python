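"""Voltage activation of a Cx46 hemichannel: model G-V curve and the
Boltzmann fit of a synthetic tail-current experiment."""

import numpy as np

import hcgate as hg

params = hg.reference.CX46_MLV  # published six-site most-likely values

# stationary open probability over the pulse-protocol voltages, zero Ca2+
voltages = np.arange(20.0, -61.0, -10.0)
po = hg.open_probability(params, voltages, 0.0)
print("V (mV)   Po")
for v, p in zip(voltages, po):
    print(f"{v:6.0f}  {p:.3f}")

v_half = hg.half_activation_voltage(params)
print(f"\nmodel half-activation voltage: {v_half:.1f} mV")
print("(the tail-current Boltzmann fit of the real channel gives -18 mV)")

# a seeded synthetic tail-current curve, refit with the Boltzmann equation
gv = hg.gen_gv_dataset(hg.TruthConfig(), hg.NoiseSpec(), seed=42)
fit = hg.fit_boltzmann(gv)
print(
    f"\nsynthetic G-V refit: V1/2 = {fit.v_half:.1f} +/- {fit.se_v_half:.1f} mV, "
    f"z-delta = {fit.z_delta:.2f} +/- {fit.se_z_delta:.2f} e0"
)
print("V1/2 is the voltage of half-maximal tail current; z-delta the apparent gating charge.")
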