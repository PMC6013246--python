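"""The force-law family behind the positioning model.

Every interaction is a signed power law F(d) = sigma M (d/40)^alpha with an
optional finite reach, plus a divergent short-range size exclusion.  Signs
and exponents of the three laws (internuclear, side, pole) span 216 models;
dropping the pole law leaves 36 model classes.
"""

from myopos import ForceLaw, enumerate_classes, enumerate_models, evaluate_size_exclusion

law = ForceLaw(sign=1, exponent=-1, magnitude=2.0)
print("repulsive force, falling with distance (M = 2):")
for d in (20, 40, 80):
    print(f"  F({d} um) = {law(d):+.3f}  (internuclear-force units)")
# At the reference distance 40 um the law equals its amplitude.

print("\nsize exclusion between two 7-um nuclei:")
for d in (7, 10, 13.9, 14):
    print(f"  F_SE({d} um) = {evaluate_size_exclusion(d, 14.0):8.2f}")
# Diverges on contact, vanishes once the nuclei no longer overlap.

print(f"\nmodel space: {len(enumerate_models())} models, "
      f"{len(enumerate_classes())} classes")
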