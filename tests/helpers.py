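"""Shared random generators for property-style tests."""

import numpy as np


def random_psd_tensor(rng, scale=1e-3):
    """Random symmetric PSD 3x3 tensor with eigenvalues O(scale)."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    w = rng.uniform(0.1, 10.0, size=3) * scale
    return (Q * w) @ Q.T


def random_directions(rng, n):
    """n random unit 3-vectors, redrawn until the tensor design is full rank."""
    from pvsdwi.estimation import _design, build_bmatrix

    while True:
        g = rng.normal(size=(n, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        A = _design(build_bmatrix(np.full(n, 100.0), g))
        if np.linalg.matrix_rank(A) == 6 and np.linalg.cond(A) < 100:
            return g
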