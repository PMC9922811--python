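"""Score the tumor-stroma ratio inside a pathologist-selected hot-spot.

Builds a small label map whose circular field of view contains 60%
tumor-associated stroma and 40% tumor glands plus a mucus pocket, then
computes the semi-automated stroma percentage (mucus, necrosis and
background are excluded from the denominator).
"""

import numpy as np

from tsrscore import CircularROI, LabelMap, default_scheme, semi_auto_tsr

scheme = default_scheme()
spacing_um = 20.0  # working resolution of this miniature example

# a 41x41 grid: ROI circle of radius 10 px (0.4 mm field of view)
grid = np.zeros((41, 41), dtype=np.int64)
rr, cc = np.ogrid[:41, :41]
inside = (rr - 20) ** 2 + (cc - 20) ** 2 <= 100
stroma = scheme.code_of("tumor-associated stroma")
tumor = scheme.code_of("tumor glands")
mucus = scheme.code_of("mucus")
grid[inside] = np.where(np.random.default_rng(0).random(inside.sum()) < 0.6,
                        stroma, tumor)
grid[18:23, 12:15] = mucus  # a mucus pocket inside the field

labelmap = LabelMap(grid=grid, spacing_um=spacing_um)
roi = CircularROI(center_row=20, center_col=20, diameter_mm=0.4)

result = semi_auto_tsr(labelmap, roi, scheme)
print(f"stroma percentage : {result.stroma_percent:.1f}%")
print(f"on the 10% grid   : {result.rounded_to_10()}%")
print(f"classification    : {result.dichotomy}")
print(f"denominator pixels: {result.denominator_px}")
# The percentage is stromal pixels over all field pixels minus mucus/
# necrosis/background; >50% means the prognostically unfavorable
# stroma-high class.
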