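"""Single-shell Clausius-Mossotti factor and its zero crossing.

Evaluates Re[CM] for the default MCF-7-like cell model across frequency,
locates the crossover by root finding, and shows the low-frequency nDEP
plateau (-0.5 limit for a non-conducting particle) and the pDEP band above
the crossover.  Re[CM] is bounded in [-0.5, 1] for any passive cell.
"""

import numpy as np

from deptrack.physics import ShellModel, crossover_frequency, re_cm_single_shell

model = ShellModel()
print(f"cell: r = {model.r_cell * 1e6:.1f} um, membrane "
      f"{model.membrane_thickness * 1e9:.0f} nm "
      f"(C_mem = {model.membrane_capacitance * 1e3:.2f} mF/m^2), "
      f"medium {model.sigma_medium * 1e4:.0f} uS/cm")

fco = crossover_frequency(model)
print(f"crossover frequency: {fco / 1e3:.2f} kHz  (Re[CM] = "
      f"{re_cm_single_shell(model, fco):+.2e})")

print(f"{'f (kHz)':>8} {'Re[CM]':>8}")
for f in [1e3, 5e3, fco / 2, fco, 2 * fco, 1e5, 1e6, 1e8]:
    print(f"{f / 1e3:8.1f} {re_cm_single_shell(model, f):+8.4f}")

vals = re_cm_single_shell(model, np.logspace(2, 9, 500))
print(f"range over [100 Hz, 1 GHz]: [{vals.min():+.4f}, {vals.max():+.4f}] "
      "(always within [-0.5, 1])")
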