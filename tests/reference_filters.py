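"""Independent direct-form reference implementation of SOS filtering.

A naive per-sample difference-equation loop (direct-form II transposed,
one biquad at a time), written without scipy's filtering routines, used as
an oracle for the package's filter applications.
"""

import numpy as np


def sosfilt_reference(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    y = np.asarray(x, dtype=float).copy()
    for b0, b1, b2, a0, a1, a2 in np.asarray(sos, dtype=float):
        b0, b1, b2, a1, a2 = b0 / a0, b1 / a0, b2 / a0, a1 / a0, a2 / a0
        out = np.empty_like(y)
        w1 = 0.0
        w2 = 0.0
        for n, xn in enumerate(y):
            yn = b0 * xn + w1
            w1 = b1 * xn - a1 * yn + w2
            w2 = b2 * xn - a2 * yn
            out[n] = yn
        y = out
    return y
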