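"""Single file vs double file from the same force model.

The calibrated model (nuclei and boundaries repel, forces fall with
distance) is relaxed in a narrow and a wide reference cell.  The narrow
cell ends with all nuclei on the midline (single file); the wide cell ends
in a zigzag double file — the width, not the model, selects the pattern.
"""

import numpy as np

from myopos import (
    CellGeometry,
    classify_pattern,
    initial_conditions,
    make_model,
    mean_abs_x,
    nearest_neighbor_distances,
    relax_to_equilibrium,
)

model = make_model(1, -1, 1, -1, 1, -1, M_S=2.2, M_P=3.2)

for name, geom in [
    ("narrow (VL4-like, 2b=50, N=9)", CellGeometry(25.0, 250.0, 9)),
    ("wide   (VL3-like, 2b=80, N=15)", CellGeometry(40.0, 250.0, 15)),
]:
    cfg = initial_conditions(geom, "random", seed=1)
    eq = relax_to_equilibrium(cfg, model, geom)
    label = classify_pattern(eq.final, geom).label
    print(f"{name}: converged={eq.converged}")
    print(f"  pattern={label}, mean |x| = {mean_abs_x(eq.final):.1f} um, "
          f"mean NND = {nearest_neighbor_distances(eq.final).mean():.1f} um")
    # mean |x| near 0 means a central file; tens of um means two files.
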