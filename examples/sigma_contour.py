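"""Distortion-factor algebra: sigma for given axis folds and its inversion.

sigma(i, j) is the CCS inflation of an ellipsoidal assembly with semi-
axes (1, i, j) relative to the sphere of equal volume. The inversion
shows the degeneracy: many (i, j) shapes share one sigma, so a fitted
sigma constrains but does not determine the assembly shape.
"""

import numpy as np

from oligogrowth.growth import distortion_factor, eccentricity_from_sigma, solve_axis_ratios

print("sigma for selected shapes:")
for i, j in [(1, 1), (1, 2), (2, 2), (1, 5)]:
    print(f"  (1,{i},{j}) -> sigma = {distortion_factor(i, j):.4f}")

target = 1.05
pairs = solve_axis_ratios(target, i_grid=np.arange(1.0, 1.35, 0.05))
print(f"\n(i, j) pairs with sigma = {target}:")
for i, j in pairs:
    print(f"  i = {i:.2f}, j = {j:.4f}")

print(f"\nprolate spheroid with sigma = 1.0761 has eccentricity "
      f"{eccentricity_from_sigma(1.0761, 'prolate'):.3f} (axes 1:1:2)")
print("Each pair above is a different ellipsoid with the same rotationally")
print("averaged shadow area: CCS alone cannot pick among them.")
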