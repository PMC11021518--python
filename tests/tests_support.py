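"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd


def cell_table_two_bins(rng, n=200):
    """Two length bins holding identical signal values."""
    vals = rng.lognormal(0, 0.3, size=n)
    return pd.DataFrame(
        {
            "cell_id": [f"t:c{i}" for i in range(2 * n)],
            "length_um": np.r_[np.full(n, 8.2), np.full(n, 9.7)],
            "signal_HPG": np.r_[vals, vals],
            "is_background": False,
        }
    )


def brute_force_feret(points):
    pts = np.asarray(points, dtype=float)
    best = 0.0
    for i in range(len(pts)):
        d = np.hypot(*(pts[i] - pts[i + 1 :]).T) if i + 1 < len(pts) else [0.0]
        best = max(best, float(np.max(d)))
    return best


def random_mask(rng, max_pixels=500):
    """Random connected-ish blob of pixel coordinates on a small canvas."""
    n = int(rng.integers(1, max_pixels))
    pts = {(int(rng.integers(0, 40)), int(rng.integers(0, 40)))}
    while len(pts) < n:
        y, x = next(iter(pts)) if len(pts) == 1 else list(pts)[rng.integers(len(pts))]
        dy, dx = rng.integers(-2, 3, size=2)
        pts.add((int(np.clip(y + dy, 0, 39)), int(np.clip(x + dx, 0, 39))))
    return np.array(sorted(pts))
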