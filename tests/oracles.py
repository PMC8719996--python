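"""Shared independent oracles used by multiple test modules."""

import numpy as np


def otsu_oracle(pixels):
    """Exhaustive scan of all 256 candidate split points maximizing
    between-class variance, computed directly from class memberships."""
    hist, edges = np.histogram(pixels, bins=256, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    best_k, best_var = None, -np.inf
    for k in range(255):
        n0, n1 = hist[: k + 1].sum(), hist[k + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return None if best_k is None else float(edges[best_k + 1])
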