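"""Shared brute-force oracles used by multiple test modules."""

import numpy as np


def brute_force_hd95(a, b, spacing, percentile=95.0):
    """O(n^2) pooled bidirectional surface-distance percentile oracle."""
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))

    def surface(m):
        pts = []
        for idx in np.argwhere(m):
            for d in (
                (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
            ):
                j = idx + d
                if np.any(j < 0) or np.any(j >= np.array(m.shape)) or not m[tuple(j)]:
                    pts.append(idx * spacing)
                    break
        return np.array(pts)

    pa, pb = surface(a), surface(b)
    d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
    d_ba = [min(np.linalg.norm(q - p) for p in pa) for q in pb]
    return float(np.percentile(np.array(d_ab + d_ba), percentile))
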