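"""Independent reference implementations used only as test oracles.

These deliberately take a different algorithmic route from the package:
the tensor oracle fits in the *signal* domain with a Levenberg-Marquardt
nonlinear solver (the package solves log-linear least squares), so agreement
between the two is a meaningful cross-check rather than a tautology.
"""

import numpy as np
from scipy.optimize import least_squares


def nonlinear_tensor_fit(signals, S0, bmatrix):
    """Nonlinear signal-domain tensor fit: S_i = S0 exp(-B_i : D).

    Parameter vector order (xx, yy, zz, xy, xz, yz) — intentionally distinct
    from the package's flattening.
    """
    signals = np.asarray(signals, dtype=float)
    bmatrix = np.asarray(bmatrix, dtype=float)

    def unpack(d):
        return np.array(
            [
                [d[0], d[3], d[4]],
                [d[3], d[1], d[5]],
                [d[4], d[5], d[2]],
            ]
        )

    def residuals(d):
        D = unpack(d)
        pred = S0 * np.exp(-np.einsum("nij,ij->n", bmatrix, D))
        return pred - signals

    # start from the isotropic ADC implied by the mean signal
    btr = np.trace(bmatrix, axis1=1, axis2=2).mean()
    adc0 = max(np.log(S0 / signals.mean()) / max(btr, 1e-9), 1e-6)
    x0 = np.array([adc0, adc0, adc0, 0.0, 0.0, 0.0])
    sol = least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000
    )
    return unpack(sol.x)
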