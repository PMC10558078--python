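"""Exact fixation curves for the three symmetric families, with verdicts.

Builds the symmetry-reduced Markov chain for each family, solves the
absorption system across a fitness grid, and classifies each curve against
the Moran baseline.  The printed deltas show the suppressor signature:
x_1 above Moran for r < 1 and below it for r > 1.
"""

import numpy as np

from hyperfix import (
    classify_selection,
    default_r_grid,
    fixation_curve_exact,
    moran_fixation,
)

N = 20
grid = default_r_grid(n=11)

print(f"single-mutant fixation probability x_1, N = {N}")
header = "family      " + "".join(f"  r={r:<6.3g}" for r in grid[::2])
print(header)
moran = [moran_fixation(N, r, 1) for r in grid]
print("Moran       " + "".join(f"  {m:<8.3g}" for m in moran[::2]))
for family in ("complete3", "cyclic3", "star3"):
    curve = fixation_curve_exact(family, 1, 1, grid, N=N)
    verdict = classify_selection(curve)
    row = "".join(f"  {x:<8.3g}" for x in curve.x[::2])
    print(f"{family:<12}{row}  -> {verdict.classification}")

print()
print("Each row is the probability that one mutant of relative fitness r")
print("takes over the whole population; all three families sit below the")
print("Moran value when r > 1 and above it when r < 1 (suppression).")
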