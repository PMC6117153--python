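"""Pseudo-diffusion estimation: per-direction D*, tensor fit, FA/MD maps.

The tensor fit is log-linear least squares over the six unique tensor
elements, matching the two-point (b0 + one shell) acquisition design.
Externally calculated per-direction b-matrices (3x3, s/mm^2) are accepted;
the default builder uses the rank-one approximation ``b * g g'``.

Tensor element ordering in flattened outputs is (Dxx, Dxy, Dxz, Dyy, Dyz,
Dzz).  Voxel coordinates are 0-based array indices; gradient directions are
expressed in the image frame (x = readout, y = phase, z = slice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .phantom import DWIVolume
from .signal_model import ParameterError

__all__ = [
    "RankDeficientError",
    "TensorFitResult",
    "estimate_dstar",
    "dstar_volume",
    "build_bmatrix",
    "fit_tensor",
    "fit_tensor_volume",
    "eig_sorted",
    "fractional_anisotropy",
    "mean_diffusivity",
    "threshold_mask",
    "smooth_edge_preserving",
    "tensor_ellipsoids",
]

#: Flattened tensor element order used everywhere downstream.
TENSOR_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# index pairs of TENSOR_ORDER into a 3x3 matrix
_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


class RankDeficientError(ValueError):
    """Raised when the direction design cannot determine all 6 tensor elements."""


def estimate_dstar(S: float, S0: float, b: float) -> float:
    """Pseudo-diffusion coefficient from a two-point measurement.

    Inverts ``S = S0 exp(-b D*)``: returns ``ln(S0/S) / b`` in mm^2/s.
    ``S > S0`` yields a negative value (permitted, to be flagged by the
    caller); non-positive ``S`` returns NaN.
    """
    if b <= 0:
        raise ParameterError(f"b must be positive, got {b}")
    if S0 <= 0:
        raise ParameterError(f"S0 must be positive, got {S0}")
    if S <= 0:
        return float("nan")
    return float(np.log(S0 / S) / b)


def dstar_volume(vol: DWIVolume) -> Tuple[np.ndarray, np.ndarray]:
    """Per-direction D* maps from a DWI stack.

    Returns ``(dstar, valid)`` where ``dstar`` has one 3D map per
    diffusion-weighted volume (NaN where invalid) and ``valid`` marks voxels
    with positive b0 and DW signal.  Negative D* values are retained but
    can be screened via the maps themselves.
    """
    b0 = vol.b0
    dw_idx = np.flatnonzero(vol.bvals > 0)
    if dw_idx.size == 0:
        raise ParameterError("no diffusion-weighted volumes present")
    dstar = np.full(b0.shape + (dw_idx.size,), np.nan)
    valid = np.zeros(b0.shape + (dw_idx.size,), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for k, i in enumerate(dw_idx):
            s = vol.data[..., i]
            ok = (b0 > 0) & (s > 0)
            dstar[..., k] = np.where(ok, np.log(b0 / np.where(s > 0, s, 1.0)) / vol.bvals[i], np.nan)
            valid[..., k] = ok
    return dstar, valid


def build_bmatrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rank-one b-matrices ``b * g g'`` for each volume, shape (N, 3, 3)."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    return bvals[:, None, None] * np.einsum("ni,nj->nij", bvecs, bvecs)


def _design(bmatrix: np.ndarray) -> np.ndarray:
    """Design matrix rows mapping the 6 unique elements to ``B : D``."""
    bmatrix = np.asarray(bmatrix, dtype=float)
    cols = []
    for (i, j) in _IDX:
        w = 1.0 if i == j else 2.0
        cols.append(w * bmatrix[:, i, j])
    return np.stack(cols, axis=1)


def _check_design(A: np.ndarray) -> None:
    if A.shape[0] < 6:
        raise RankDeficientError(
            f"at least 6 diffusion-weighted directions are required, got {A.shape[0]}"
        )
    rank = np.linalg.matrix_rank(A)
    if rank < 6:
        raise RankDeficientError(
            f"direction design is rank-deficient (rank {rank} < 6); "
            "directions are coplanar or degenerate"
        )


def fit_tensor(signals: np.ndarray, S0: float, bmatrix: np.ndarray) -> np.ndarray:
    """Log-linear least-squares tensor from per-direction signals.

    Solves ``ln(S0 / S_i) = B_i : D`` for the six unique elements of ``D``;
    exact in the noiseless consistent case.  Raises
    :class:`RankDeficientError` for under-determined direction designs.
    """
    signals = np.asarray(signals, dtype=float)
    if np.any(signals <= 0):
        raise ParameterError("all signals must be positive")
    if S0 <= 0:
        raise ParameterError("S0 must be positive")
    A = _design(bmatrix)
    _check_design(A)
    y = np.log(S0 / signals)
    d, *_ = np.linalg.lstsq(A, y, rcond=None)
    D = np.zeros((3, 3))
    for val, (i, j) in zip(d, _IDX):
        D[i, j] = D[j, i] = val
    return D


@dataclass
class TensorFitResult:
    """Per-voxel tensor fit over a 3D volume.

    ``tensor_map`` holds the 6 unique elements in :data:`TENSOR_ORDER`;
    eigenvalues are sorted descending and clipped at 1e-12 for FA/MD where
    the raw fit was non-PSD (such voxels are cleared in ``valid_mask``).
    """

    tensor_map: np.ndarray    # (..., 6)
    eigenvalues: np.ndarray   # (..., 3) descending
    eigenvectors: np.ndarray  # (..., 3, 3), columns are eigenvectors
    fa_map: np.ndarray
    md_map: np.ndarray
    residual: np.ndarray      # RMS log-residual
    valid_mask: np.ndarray

    def tensor_at(self, *idx) -> np.ndarray:
        t = self.tensor_map[idx]
        D = np.zeros((3, 3))
        for val, (i, j) in zip(t, _IDX):
            D[i, j] = D[j, i] = val
        return D


def fit_tensor_volume(
    vol: DWIVolume,
    mask: Optional[np.ndarray] = None,
    bmatrix: Optional[np.ndarray] = None,
) -> TensorFitResult:
    """Vectorised log-linear tensor fit over every voxel in ``mask``.

    Parameters
    ----------
    vol : DWIVolume
        Input stack with exactly one shell plus b0 volume(s).
    mask : 3D bool array, optional
        Voxels to fit (default: all voxels with positive b0).
    bmatrix : (N_dw, 3, 3) array, optional
        Externally calculated b-matrices for the diffusion-weighted volumes;
        default is ``b * g g'`` from the stored b-table.
    """
    dw_idx = np.flatnonzero(vol.bvals > 0)
    b0 = vol.b0
    if bmatrix is None:
        bmatrix = build_bmatrix(vol.bvals[dw_idx], vol.bvecs[dw_idx])
    A = _design(bmatrix)
    _check_design(A)
    A_pinv = np.linalg.pinv(A)

    if mask is None:
        mask = b0 > 0
    shape = b0.shape
    signals = vol.data[..., dw_idx]

    fittable = mask & (b0 > 0) & np.all(signals > 0, axis=-1)
    S = signals[fittable]                       # (V, N)
    s0 = b0[fittable][:, None]
    Y = np.log(s0 / S)                          # (V, N)
    d = Y @ A_pinv.T                            # (V, 6)
    resid = np.sqrt(np.mean((d @ A.T - Y) ** 2, axis=1))

    # assemble full 3x3 tensors for the eigen decomposition
    V = d.shape[0]
    D = np.zeros((V, 3, 3))
    for k, (i, j) in enumerate(_IDX):
        D[:, i, j] = D[:, j, i] = d[:, k]
    evals, evecs = eig_sorted(D)

    psd = evals[:, 2] >= 0
    evals_c = np.clip(evals, 1e-12, None)
    md = evals_c.mean(axis=1)
    fa = fractional_anisotropy(evals_c[:, 0], evals_c[:, 1], evals_c[:, 2])

    def scatter(vals, fill=np.nan, extra=()):
        out = np.full(shape + tuple(extra), fill)
        out[fittable] = vals
        return out

    return TensorFitResult(
        tensor_map=scatter(d, extra=(6,)),
        eigenvalues=scatter(evals_c, extra=(3,)),
        eigenvectors=scatter(evecs, extra=(3, 3)),
        fa_map=scatter(fa),
        md_map=scatter(md),
        residual=scatter(resid),
        valid_mask=scatter(psd, fill=False).astype(bool) & fittable,
    )


def eig_sorted(D: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and a right-handed orthonormal eigenvector triad.

    Accepts a single symmetric 3x3 tensor or a stack (..., 3, 3).  Columns
    ``evecs[..., :, k]`` are eigenvectors.  Sign convention: the first and
    second eigenvectors have their first non-negligible component >= 0; the
    third is their cross product, which guarantees a right-handed triad.
    """
    D = np.asarray(D, dtype=float)
    single = D.ndim == 2
    if single:
        D = D[None]
    w, v = np.linalg.eigh(D)                    # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]

    # sign fix per eigenvector: first component with |c| > tol must be >= 0
    tol = 1e-12
    for k in range(2):
        vk = v[..., :, k]
        comp = np.where(np.abs(vk) > tol, vk, 0.0)
        first = np.argmax(np.abs(comp) > tol, axis=-1)
        lead = np.take_along_axis(vk, first[..., None], axis=-1)[..., 0]
        flip = lead < 0
        v[flip, :, k] *= -1.0
    v[..., :, 2] = np.cross(v[..., :, 0], v[..., :, 1])

    if single:
        return w[0], v[0]
    return w, v


def fractional_anisotropy(l1, l2, l3):
    """FA from eigenvalues: sqrt(3/2) * ||lambda - MD|| / ||lambda||, in [0, 1].

    All-zero inputs are flagged NaN.
    """
    l1, l2, l3 = np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    )
    if np.any(np.minimum(np.minimum(l1, l2), l3) < 0):
        raise ParameterError("eigenvalues must be non-negative")
    md = (l1 + l2 + l3) / 3.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan))
    fa = np.clip(fa, 0.0, 1.0)
    out = np.where(den > 0, fa, np.nan)
    return float(out) if out.ndim == 0 else out


def mean_diffusivity(l1, l2, l3):
    """Mean diffusivity ``(l1 + l2 + l3) / 3`` (rotation invariant)."""
    out = (np.asarray(l1, float) + np.asarray(l2, float) + np.asarray(l3, float)) / 3.0
    return float(out) if out.ndim == 0 else out


def threshold_mask(
    b0: np.ndarray,
    method: str = "percentile",
    percentile: float = 90.0,
    value: float = 0.0,
) -> np.ndarray:
    """Intensity mask isolating voxels dominated by fluid-compartment signal.

    ``percentile`` (default): keep voxels strictly above the given in-slice
    intensity percentile.  ``otsu``: Otsu's threshold.  ``fixed``: keep
    voxels strictly above ``value``.
    """
    b0 = np.asarray(b0, dtype=float)
    if np.any(b0 < 0):
        raise ParameterError("b0 image must be non-negative")
    if b0.max() == b0.min():
        warnings.warn("constant b0 image: threshold mask is empty", stacklevel=2)
        return np.zeros(b0.shape, dtype=bool)
    if method == "percentile":
        cut = np.percentile(b0, percentile)
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        cut = threshold_otsu(b0)
    elif method == "fixed":
        cut = value
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    mask = b0 > cut
    if not mask.any():
        warnings.warn("threshold produced an empty mask", stacklevel=2)
    return mask


def smooth_edge_preserving(
    image: np.ndarray, radius: int, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Edge-preserving median filter of the given radius.

    Filters inside ``mask`` only (voxels outside are neither read nor
    written); radius 0 is the identity.  Operates on the leading two axes of
    2D/3D single-slice maps.
    """
    if radius < 0:
        raise ParameterError("radius must be non-negative")
    image = np.asarray(image, dtype=float)
    if radius == 0:
        return image.copy()
    work = image.copy()
    if mask is not None:
        work[~mask] = np.nan
    size = 2 * radius + 1
    # nan-aware median so masked-out neighbours never bleed in
    squeeze = False
    if work.ndim == 3 and work.shape[2] == 1:
        work = work[..., 0]
        squeeze = True
    with warnings.catch_warnings():
        # all-NaN windows at mask borders are expected and resolve to NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        sm = ndimage.generic_filter(work, np.nanmedian, size=size, mode="nearest")
    if squeeze:
        sm = sm[..., None]
    out = image.copy()
    sel = np.ones(image.shape, dtype=bool) if mask is None else mask
    out[sel] = sm[sel]
    return out


def tensor_ellipsoids(fit: TensorFitResult) -> pd.DataFrame:
    """Per-voxel ellipsoid parameters for glyph rendering.

    Semi-axes are the (clipped) eigenvalues; orientation is the eigenvector
    triad encoded as a unit quaternion (w, x, y, z); colour channels are the
    absolute components of the principal eigenvector (red = x/readout,
    green = y/phase, blue = z/slice).
    """
    idx = np.argwhere(fit.valid_mask)
    rows = []
    for vox in idx:
        t = tuple(vox)
        evals = fit.eigenvalues[t]
        evecs = fit.eigenvectors[t]
        q = Rotation.from_matrix(evecs).as_quat()  # (x, y, z, w)
        v1 = np.abs(evecs[:, 0])
        rows.append(
            tuple(vox)
            + tuple(evals)
            + (q[3], q[0], q[1], q[2])
            + tuple(v1)
        )
    ax_names = [f"i{k}" for k in range(idx.shape[1])]
    cols = ax_names + [
        "semi_axis_1", "semi_axis_2", "semi_axis_3",
        "qw", "qx", "qy", "qz",
        "color_r", "color_g", "color_b",
    ]
    return pd.DataFrame(rows, columns=cols)
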