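"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the two-slope
fit uses closed-form normal equations instead of scipy, and the Sholl oracle
loops over segments and radii one by one.
"""

import numpy as np
import pandas as pd

from ampakit import morphometry as mo


def two_slope_oracle(v, i):
    """Closed-form two-slope rectification fit (no scipy)."""
    below = i < 0
    vb, ib = v[below], i[below]
    n = len(vb)
    sx, sy = vb.sum(), ib.sum()
    sxx, sxy = (vb * vb).sum(), (vb * ib).sum()
    s1 = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - s1 * sx) / n
    e_rev = -intercept / s1
    above = v > e_rev
    dv = v[above] - e_rev
    s2 = (dv * i[above]).sum() / (dv * dv).sum()
    return s2 / s1, e_rev


def random_tree(rng, n=30, spread=120.0):
    rows = [(1, mo.SOMA, 0.0, 0.0, 0.0, 5.0, -1)]
    for k in range(2, n + 2):
        parent = int(rng.integers(1, k))
        stype = mo.AXON if rng.random() < 0.6 else mo.DENDRITE
        rows.append(
            (k, stype, rng.normal(0, spread), rng.normal(0, spread),
             rng.normal(0, 5.0), 0.5, parent)
        )
    return mo.Morphology(
        nodes=pd.DataFrame(
            rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]
        )
    )


def naive_sholl(morph, radii, structure_name):
    """One-segment-at-a-time straddle count."""
    stype = mo.AXON if structure_name == "axon" else mo.DENDRITE
    sx, sy = morph.soma_position
    seg = morph.segments(stype)
    counts = np.zeros(len(radii), dtype=int)
    for k, r in enumerate(radii):
        for row in seg.itertuples(index=False):
            d0 = np.hypot(row.x0 - sx, row.y0 - sy)
            d1 = np.hypot(row.x1 - sx, row.y1 - sy)
            if min(d0, d1) <= r < max(d0, d1):
                counts[k] += 1
    return counts
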