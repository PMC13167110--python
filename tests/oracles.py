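"""Independent numerical oracles used by the test suite."""

import numpy as np


def fista_nnls(design, target, iters=3000):
    """Projected-gradient (FISTA) nonnegative least squares.

    Independent of the active-set solver used by the package; serves as the
    cross-check for beta fitting.
    """
    lip = np.linalg.norm(design, 2) ** 2
    gram, corr = design.T @ design, design.T @ target
    x = np.zeros(design.shape[1])
    z, t = x.copy(), 1.0
    for _ in range(iters):
        xn = np.clip(z - (gram @ z - corr) / lip, 0, None)
        tn = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = xn + ((t - 1) / tn) * (xn - x)
        x, t = xn, tn
    return x
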