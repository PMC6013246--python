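"""The single-file/double-file transition as a pitchfork bifurcation.

The infinite-strip reduction predicts the offset of the two nuclear files
in closed form.  For the repulsive model (M2) the single file is stable
while the half-width b stays below sqrt(M_S/2) times the axial spacing
lambda; beyond it the stable offset grows like a square root — the classic
pitchfork.
"""

import numpy as np

from myopos import StripParams, df_equilibrium, make_model, sf_is_stable

model = make_model(1, -1, 1, -1, M_S=2.0)
lam = 40.0  # axial spacing, um
print(f"M2, M_S=2, spacing lambda = {lam} um: critical half-width = "
      f"{np.sqrt(2.0 / 2.0) * lam:.0f} um")
print(f"{'b (um)':>8} {'SF stable':>10} {'file offset x_bar (um)':>24}")
for b in (25, 35, 40, 45, 50, 60, 70):
    p = StripParams(lam, float(b), model)
    print(f"{b:8.0f} {str(sf_is_stable(p).stable):>10} {df_equilibrium(p):24.3f}")
# x_bar = 0 below the threshold; above it the double file opens up.
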