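"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_isolation(positions, frame, neighbor_min=1.5, edge_min=0.5):
    """O(n^2) reference implementation of the crystal isolation filter."""
    pos = np.atleast_2d(positions)
    xmin, xmax, ymin, ymax = frame
    kept = []
    for i, (x, y) in enumerate(pos):
        if min(x - xmin, xmax - x, y - ymin, ymax - y) < edge_min:
            continue
        ok = True
        for j, (u, v) in enumerate(pos):
            if i != j and np.hypot(x - u, y - v) < neighbor_min:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept
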