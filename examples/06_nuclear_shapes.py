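"""Nuclear shapes from the anisotropy of the positioning forces.

Nuclei are modelled as deformable discs: the net compressive forces f_x
(from the sides and the lateral neighbour push) and f_y (from axial
neighbours) set the aspect ratio N_AR = (kappa - f_y)^2 / (kappa - f_x)^2,
where kappa is the nuclear stiffness.  Synthetic aspect-ratio tables
generated at kappa = 35 are refit to recover the stiffness.
"""

import numpy as np

from myopos import (
    CellGeometry,
    StripParams,
    aspect_ratio_predicted,
    fit_kappa,
    make_model,
    sf_is_stable,
    shape_forces,
)

model = make_model(1, -1, 1, -1, M_S=2.2)
kappa = 35.0

print(f"{'2b (um)':>8} {'N':>4} {'pattern':>8} {'f_x':>7} {'f_y':>7} {'N_AR':>6}")
cells = []
rng = np.random.default_rng(5)
for width, n in [(42, 7), (55, 10), (73, 13), (85, 16), (117, 23)]:
    geom = CellGeometry(width / 2.0, 250.0, n)
    p = StripParams.from_geometry(geom, model)
    pattern = "SF" if sf_is_stable(p).stable else "DF"
    fx, fy = shape_forces(p, pattern, "long")
    ar = aspect_ratio_predicted(fx, fy, kappa)
    print(f"{width:8.0f} {n:4d} {pattern:>8} {fx:7.2f} {fy:7.2f} {ar:6.3f}")
    cells.append((geom, ar * float(np.exp(rng.normal(0, 0.05)))))

fit = fit_kappa(cells, model, "long")
print(f"\nkappa refit from 5 noisy cells: {fit.kappa:.1f} (generated at {kappa})")
# Wider cells push harder from the sides, elongating nuclei along the cell
# axis (N_AR > 1), as seen in the imaged muscles.
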