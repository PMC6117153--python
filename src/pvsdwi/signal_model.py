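"""Closed-form forward model for ultra-long-TE, low-b diffusion-weighted MRI.

The measured signal from a fluid compartment is modelled as the product of

* spin-echo T2 attenuation at the effective echo time,
* optional T1 saturation at the repetition time, and
* mono-exponential pseudo-diffusion weighting ``exp(-b * g' D g)``,

where ``D`` is a symmetric positive semi-definite pseudo-diffusion tensor
(units mm^2/s), ``b`` the diffusion weighting in s/mm^2 and ``g`` a unit
gradient direction in the image frame (x = readout, y = phase, z = slice).

Interface units: times in ms, gradient amplitudes in G/cm, b-values in
s/mm^2, diffusivities in mm^2/s.  All unit conversions happen in this
module, once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "ParameterError",
    "AcquisitionParams",
    "Compartment",
    "t2_attenuation",
    "stejskal_tanner_b",
    "dwi_signal",
    "steady_state_scale",
    "axisymmetric_tensor",
    "icosahedral_directions",
    "gauss_per_cm_to_tesla_per_m",
    "ms_to_s",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.675e8

#: Tolerance for accepting a gradient direction as unit-norm.
UNIT_NORM_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a physical parameter is outside its valid domain."""


def gauss_per_cm_to_tesla_per_m(g_per_cm: float) -> float:
    """Convert a gradient amplitude from G/cm to T/m (1 G/cm = 1e-2 T/m)."""
    return float(g_per_cm) * 1e-2


def ms_to_s(t_ms: float) -> float:
    """Convert milliseconds to seconds."""
    return float(t_ms) * 1e-3


def _check_unit(g: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape != (3,):
        raise ParameterError(f"direction must be a 3-vector, got shape {g.shape}")
    n = float(np.linalg.norm(g))
    if abs(n - 1.0) > tol:
        raise ParameterError(f"direction must be unit-norm (|g| = {n:.6g})")
    return g


def _check_psd(D: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ParameterError(f"tensor must be 3x3, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-12 * max(1.0, float(np.abs(D).max()))):
        raise ParameterError("tensor must be symmetric")
    w = np.linalg.eigvalsh(D)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ParameterError(f"tensor must be positive semi-definite (min eig {w.min():.3g})")
    return D


def t2_attenuation(TE: float, T2: float) -> float:
    """Fraction of the TE=0 spin-echo signal remaining at echo time ``TE``.

    Parameters
    ----------
    TE : float
        Echo time, ms.  Must be >= 0.
    T2 : float
        Transverse relaxation time, ms.  Must be > 0.

    Returns
    -------
    float
        ``exp(-TE / T2)``, in (0, 1].
    """
    if T2 <= 0:
        raise ParameterError(f"T2 must be positive, got {T2}")
    if TE < 0:
        raise ParameterError(f"TE must be non-negative, got {TE}")
    return math.exp(-TE / T2)


def stejskal_tanner_b(delta_small: float, delta_big: float, G: float) -> float:
    """b-value of a rectangular pulsed-gradient pair, in s/mm^2.

    Evaluates ``gamma^2 G^2 delta^2 (Delta - delta/3)`` for a pair of
    rectangular gradient lobes of duration ``delta_small`` (ms), leading-edge
    separation ``delta_big`` (ms) and amplitude ``G`` (G/cm).

    Note this is the motion-probing-gradient contribution only; contributions
    from imaging gradients are not modelled and externally calculated
    b-values may be supplied via :attr:`AcquisitionParams.b_nominal`.
    """
    if delta_small <= 0:
        raise ParameterError(f"delta_small must be positive, got {delta_small}")
    if delta_big < delta_small:
        raise ParameterError(
            f"delta_big ({delta_big}) must be >= delta_small ({delta_small})"
        )
    if G < 0:
        raise ParameterError(f"G must be non-negative, got {G}")
    g_si = gauss_per_cm_to_tesla_per_m(G)  # T/m
    d = ms_to_s(delta_small)
    D = ms_to_s(delta_big)
    b_si = (GAMMA_PROTON ** 2) * (g_si ** 2) * (d ** 2) * (D - d / 3.0)  # s/m^2
    return b_si * 1e-6  # s/mm^2


def dwi_signal(S0: float, b: float, g: Sequence[float], D: np.ndarray) -> float:
    """Diffusion-weighted signal ``S0 * exp(-b * g' D g)``.

    Parameters
    ----------
    S0 : float
        Unweighted (b = 0) signal amplitude.
    b : float
        Diffusion weighting, s/mm^2.  Must be >= 0.
    g : sequence of 3 floats
        Unit gradient direction.
    D : (3, 3) array
        Symmetric PSD pseudo-diffusion tensor, mm^2/s.
    """
    if b < 0:
        raise ParameterError(f"b must be non-negative, got {b}")
    g = _check_unit(g)
    D = _check_psd(D)
    adc = float(g @ D @ g)
    return float(S0) * math.exp(-b * adc)


def steady_state_scale(
    S0: float, TR: float, TE: float, T2: float, T1: Optional[float] = None
) -> float:
    """Steady-state spin-echo amplitude with T2 decay and optional T1 saturation.

    Returns ``S0 * exp(-TE/T2)`` when ``T1`` is None (long-TR limit), else
    ``S0 * (1 - exp(-TR/T1)) * exp(-TE/T2)``.
    """
    if TR <= 0:
        raise ParameterError(f"TR must be positive, got {TR}")
    s = S0 * t2_attenuation(TE, T2)
    if T1 is not None:
        if T1 <= 0:
            raise ParameterError(f"T1 must be positive, got {T1}")
        s *= 1.0 - math.exp(-TR / T1)
    return float(s)


def icosahedral_directions() -> np.ndarray:
    """Six non-collinear unit directions from icosahedron vertices.

    A standard minimal-condition-number design for 6-direction tensor
    acquisitions; returned as a (6, 3) array.
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = np.array(
        [
            [0.0, 1.0, phi],
            [0.0, -1.0, phi],
            [1.0, phi, 0.0],
            [-1.0, phi, 0.0],
            [phi, 0.0, 1.0],
            [phi, 0.0, -1.0],
        ]
    )
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def axisymmetric_tensor(md: float, fa: float, axis: Sequence[float]) -> np.ndarray:
    """Axially symmetric PSD tensor with given mean diffusivity and anisotropy.

    Solves for eigenvalues ``(l_par, l_perp, l_perp)`` such that the tensor's
    mean diffusivity equals ``md`` and its fractional anisotropy equals
    ``fa``, with the leading eigenvector along ``axis``.  With
    ``a = fa / sqrt(3 - 2 fa^2)``: ``l_par = md (1 + 2a)``,
    ``l_perp = md (1 - a)``.

    Parameters
    ----------
    md : float
        Target mean diffusivity, mm^2/s (> 0).
    fa : float
        Target fractional anisotropy in [0, 1].
    axis : sequence of 3 floats
        Principal axis (normalised internally).
    """
    if md <= 0:
        raise ParameterError(f"md must be positive, got {md}")
    if not 0.0 <= fa <= 1.0:
        raise ParameterError(f"fa must lie in [0, 1], got {fa}")
    a = fa / math.sqrt(3.0 - 2.0 * fa * fa)
    l_par = md * (1.0 + 2.0 * a)
    l_perp = md * (1.0 - a)
    t = np.asarray(axis, dtype=float)
    n = np.linalg.norm(t)
    if n == 0:
        raise ParameterError("axis must be non-zero")
    t = t / n
    return l_perp * np.eye(3) + (l_par - l_perp) * np.outer(t, t)


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-timing and gradient parameters of the acquisition.

    Times in ms, gradient amplitude in G/cm, b in s/mm^2.  ``b_nominal``,
    when given, overrides the rectangular Stejskal-Tanner value (use it when
    an externally calculated b incorporating imaging gradients is available).
    """

    TR: float = 5000.0
    TE_eff: float = 142.0
    echo_train_length: int = 16
    echo_spacing: float = 10.0
    first_echo_time: float = 72.0
    delta_small: float = 5.0
    delta_big: float = 26.0
    G: float = 4.2
    directions: tuple = field(default_factory=lambda: tuple(map(tuple, icosahedral_directions())))
    b_nominal: Optional[float] = 107.0
    rwave_delay: Optional[float] = None

    def __post_init__(self):
        if self.delta_small <= 0:
            raise ParameterError("delta_small must be positive")
        if self.delta_big < self.delta_small:
            raise ParameterError("delta_big must be >= delta_small")
        if self.TE_eff < self.first_echo_time:
            raise ParameterError("TE_eff must be >= first_echo_time")
        for g in self.directions:
            v = np.asarray(g, dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > UNIT_NORM_TOL:
                raise ParameterError(f"direction {g} is not unit-norm")
        object.__setattr__(self, "directions", tuple(tuple(float(c) for c in g) for g in self.directions))

    @property
    def b_value(self) -> float:
        """Effective b-value: ``b_nominal`` if supplied, else the closed form."""
        if self.b_nominal is not None:
            return float(self.b_nominal)
        return stejskal_tanner_b(self.delta_small, self.delta_big, self.G)

    @property
    def direction_array(self) -> np.ndarray:
        return np.asarray(self.directions, dtype=float)


@dataclass
class Compartment:
    """Named tissue/fluid class with T2 contrast and a pseudo-diffusion tensor.

    ``principal_axis`` is redundant convenience: it is derived from the
    leading eigenvector of ``Dstar`` when not given, and validated against it
    when it is.
    """

    name: str
    T2: float
    S0: float
    Dstar: np.ndarray
    principal_axis: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.T2 <= 0:
            raise ParameterError(f"{self.name}: T2 must be positive")
        if self.S0 < 0:
            raise ParameterError(f"{self.name}: S0 must be non-negative")
        self.Dstar = _check_psd(np.asarray(self.Dstar, dtype=float))
        w, v = np.linalg.eigh(self.Dstar)
        lead = v[:, np.argmax(w)]
        if self.principal_axis is None:
            self.principal_axis = lead if lead[np.flatnonzero(lead)[0]] >= 0 else -lead
        else:
            ax = np.asarray(self.principal_axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            # degenerate (isotropic-ish) tensors accept any axis
            if w[-1] - w[0] > 1e-15 and abs(float(ax @ lead)) < 1.0 - 1e-6:
                raise ParameterError(
                    f"{self.name}: principal_axis does not match leading eigenvector"
                )
            self.principal_axis = ax
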