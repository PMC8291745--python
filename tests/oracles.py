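"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from histalign.similarity import MIN_WINDOW_STD


def naive_ncc(fixed, moving, r):
    """Per-window Pearson correlation with boundary-clipped windows and the
    same featureless-window policy as the production code; no sum tables."""
    H, W = fixed.shape
    out = np.zeros((H, W))
    thr = MIN_WINDOW_STD**2
    for y in range(H):
        y0, y1 = max(0, y - r), min(H, y + r + 1)
        for x in range(W):
            x0, x1 = max(0, x - r), min(W, x + r + 1)
            a = fixed[y0:y1, x0:x1].ravel()
            b = moving[y0:y1, x0:x1].ravel()
            va = a.var()
            vb = b.var()
            if va <= thr or vb <= thr:
                continue
            cov = ((a - a.mean()) * (b - b.mean())).mean()
            out[y, x] = np.clip(cov / np.sqrt(va * vb), -1.0, 1.0)
    return out
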