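"""A miniature of the model screen: why most force combinations fail.

Three representative model classes are screened against the two reference
geometries: the calibrated repulsive class survives, an all-attractive
class collapses the nuclei (too close / stuck), and a repulsive-constant
class needs a finely tuned force range.  The full reduced screen over all
36 classes is `run_filter1()` (or `myopos screen filter1` on the command
line) and takes a few minutes.
"""

from myopos.screen import run_filter1

classes = [
    (1, -1, 1, -1),    # repulsive, falling with distance (survives)
    (-1, -1, -1, -1),  # all attractive (collapses)
    (1, 0, 1, 0),      # constant repulsion (works only near a 50-um reach)
]
res = run_filter1(classes=classes, seed=0)
print(f"{res.n_runs} simulations")
for cls in classes:
    verdict = "survives" if cls in res.survivors else "eliminated"
    print(f"  class (sigma_N, alpha_N, sigma_S, alpha_S) = {cls}: {verdict}")
df = res.records
print("\nper-criterion pass rates of all runs:")
print(df[["K1", "K2", "K3", "K4", "K5"]].mean().round(2).to_string())
# K1/K2: no boundary/nucleus sticking; K3: correct SF/DF; K4: spread; K5: spacing.
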