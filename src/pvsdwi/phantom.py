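"""Seeded digital phantom: a single ventral-brain slice with fluid compartments.

The phantom is a schematic 2D slice (default 128 x 128 over a 25 x 25 mm
field of view) containing six labels: background, parenchyma, blood, the
subarachnoid CSF bathing an arterial ring, perivascular tracts flanking two
arterial branches, and a midline ventricle.  Fluid compartments carry
anisotropic pseudo-diffusion tensors whose principal axes follow the local
vessel/tract geometry; the scenario switch rescales the perivascular leading
eigenvalue to emulate pulsation, inotrope and post-mortem contrasts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .signal_model import (
    AcquisitionParams,
    Compartment,
    ParameterError,
    axisymmetric_tensor,
    steady_state_scale,
)

__all__ = [
    "LABELS",
    "BACKGROUND",
    "PARENCHYMA",
    "BLOOD",
    "SUBARACHNOID",
    "PVS",
    "VENTRICLE",
    "FLUID_LABELS",
    "GeometrySpec",
    "PhantomSpec",
    "GroundTruth",
    "DWIVolume",
    "default_compartments",
    "build_geometry",
    "apply_scenario",
    "render_dwi",
    "add_rician_noise",
    "sigma_for_snr",
    "simulate",
    "roi_masks",
]

BACKGROUND, PARENCHYMA, BLOOD, SUBARACHNOID, PVS, VENTRICLE = range(6)
LABELS: Dict[int, str] = {
    BACKGROUND: "background",
    PARENCHYMA: "parenchyma",
    BLOOD: "blood",
    SUBARACHNOID: "subarachnoid",
    PVS: "pvs",
    VENTRICLE: "ventricle",
}
#: Labels whose signal derives from CSF-like fluid.
FLUID_LABELS = (SUBARACHNOID, PVS, VENTRICLE)

SCENARIOS = ("baseline", "pulsation", "diastole", "dobutamine", "postmortem")

_Y_AXIS = (0.0, 1.0, 0.0)  # caudal-rostral image axis


def default_compartments() -> Dict[int, Compartment]:
    """Default compartment table.

    CSF-like fluid has T2 = 111 ms; parenchyma 38 ms; blood 30 ms (9.4 T).
    Perivascular and subarachnoid tensors are axially symmetric, solved from
    target FA/MD pairs (0.44 / 0.0042 and 0.60 / 0.0065 mm^2/s); the
    ventricle is mildly anisotropic along the caudal-rostral axis.
    """
    return {
        PARENCHYMA: Compartment("parenchyma", T2=38.0, S0=100.0, Dstar=7e-4 * np.eye(3)),
        BLOOD: Compartment("blood", T2=30.0, S0=100.0, Dstar=1e-2 * np.eye(3)),
        SUBARACHNOID: Compartment(
            "subarachnoid", T2=111.0, S0=100.0,
            Dstar=axisymmetric_tensor(0.0065, 0.60, _Y_AXIS),
        ),
        PVS: Compartment(
            "pvs", T2=111.0, S0=100.0,
            Dstar=axisymmetric_tensor(0.0042, 0.44, (1.0, 0.0, 0.0)),
        ),
        VENTRICLE: Compartment(
            "ventricle", T2=111.0, S0=100.0,
            Dstar=axisymmetric_tensor(0.0052, 0.30, _Y_AXIS),
        ),
    }


@dataclass(frozen=True)
class GeometrySpec:
    """Parametric slice geometry, all lengths in mm, origin at slice centre."""

    brain_radius: float = 11.5
    cow_centre: Tuple[float, float] = (0.0, 0.0)
    cow_radius: float = 3.5
    cow_tube_halfwidth: float = 0.25
    sa_annulus_halfwidth: float = 0.8
    sa_band_halfwidth: float = 0.8
    sa_band_extent: float = 4.6
    mca_right: Tuple[Tuple[float, float], ...] = (
        (3.5, 0.0), (6.0, 0.3), (8.5, 1.0), (10.8, 2.0),
    )
    vessel_radius: float = 0.3
    pvs_halfwidth: float = 0.3
    ventricle_centre: Tuple[float, float] = (0.0, 6.2)
    ventricle_semiaxes: Tuple[float, float] = (0.8, 1.8)

    @property
    def mca_left(self) -> Tuple[Tuple[float, float], ...]:
        return tuple((-x, y) for x, y in self.mca_right)


@dataclass(frozen=True)
class PhantomSpec:
    matrix: Tuple[int, int] = (128, 128)
    fov_mm: Tuple[float, float] = (25.0, 25.0)
    slice_thickness_mm: float = 1.0
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    scenario: str = "baseline"
    pulsation_gain: float = 4.0
    dobutamine_gain: float = 1.65
    postmortem_factor: float = 0.1
    noise_sigma: float = 0.0
    seed: int = 0
    compartments: Optional[tuple] = None  # ((label, Compartment), ...) override

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ParameterError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if min(self.pulsation_gain, self.dobutamine_gain, self.postmortem_factor) <= 0:
            raise ParameterError("scenario gains must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")

    def compartment_table(self) -> Dict[int, Compartment]:
        if self.compartments is not None:
            return dict(self.compartments)
        return default_compartments()

    def sha(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Per-voxel labels, tensors and tract tangents on the slice grid."""

    label_map: np.ndarray          # (nx, ny) int
    tensor_map: np.ndarray         # (nx, ny, 3, 3) mm^2/s
    tangent_map: np.ndarray        # (nx, ny, 3); zero where undefined

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.label_map.copy(), self.tensor_map.copy(), self.tangent_map.copy()
        )


@dataclass
class DWIVolume:
    """4D DWI stack with per-volume b-values and unit gradient directions."""

    data: np.ndarray               # (nx, ny, nz, nvol), >= 0
    bvals: np.ndarray              # (nvol,) s/mm^2
    bvecs: np.ndarray              # (nvol, 3); zero row for b0
    voxel_size_mm: Tuple[float, float, float]
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise ParameterError("DWI data must be 4D")
        n = self.data.shape[-1]
        if len(self.bvals) != n or len(self.bvecs) != n:
            raise ParameterError(
                f"b-table length ({len(self.bvals)}/{len(self.bvecs)}) does not "
                f"match volume count ({n})"
            )
        if not np.any(self.bvals == 0):
            raise ParameterError("at least one b0 volume is required")

    @property
    def b0_index(self) -> int:
        return int(np.flatnonzero(self.bvals == 0)[0])

    @property
    def b0(self) -> np.ndarray:
        return self.data[..., self.b0_index]


def _grids(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    nx, ny = spec.matrix
    dx, dy = spec.fov_mm[0] / nx, spec.fov_mm[1] / ny
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    return np.meshgrid(x, y, indexing="ij")


def _polyline_distance(x, y, pts):
    """Distance from each grid point to a polyline, plus nearest-segment tangent."""
    pts = np.asarray(pts, dtype=float)
    best = np.full(x.shape, np.inf)
    tang = np.zeros(x.shape + (2,))
    for k in range(len(pts) - 1):
        p, q = pts[k], pts[k + 1]
        v = q - p
        L2 = float(v @ v)
        t = np.clip(((x - p[0]) * v[0] + (y - p[1]) * v[1]) / L2, 0.0, 1.0)
        d = np.hypot(x - (p[0] + t * v[0]), y - (p[1] + t * v[1]))
        sel = d < best
        best[sel] = d[sel]
        tang[sel] = v / np.sqrt(L2)
    return best, tang


def build_geometry(spec: PhantomSpec) -> GroundTruth:
    """Assign one compartment label, tensor and tangent to every voxel.

    Perivascular tensors are oriented along the local arterial tangent;
    subarachnoid (and ventricular) tensors along the caudal-rostral image
    axis.  Painting precedence (last wins): parenchyma < subarachnoid <
    ventricle < perivascular < blood.
    """
    geo = spec.geometry
    if geo.pvs_halfwidth <= 0:
        raise ParameterError("pvs_halfwidth must be positive (degenerate tract)")
    if geo.vessel_radius <= 0 or geo.cow_tube_halfwidth <= 0:
        raise ParameterError("vessel dimensions must be positive")

    x, y = _grids(spec)
    cx, cy = geo.cow_centre
    r_cow = np.hypot(x - cx, y - cy)
    brain = np.hypot(x, y) <= geo.brain_radius

    labels = np.zeros(spec.matrix, dtype=np.int16)
    labels[brain] = PARENCHYMA

    # subarachnoid CSF: annulus bathing the arterial ring + midline band
    annulus = np.abs(r_cow - geo.cow_radius) <= geo.sa_annulus_halfwidth
    band = (np.abs(x - cx) <= geo.sa_band_halfwidth) & (
        np.abs(y - cy) <= geo.sa_band_extent
    )
    labels[brain & (annulus | band)] = SUBARACHNOID

    # third ventricle
    vx, vy = geo.ventricle_centre
    ax_, ay_ = geo.ventricle_semiaxes
    vent = ((x - vx) / ax_) ** 2 + ((y - vy) / ay_) ** 2 <= 1.0
    labels[brain & vent] = VENTRICLE

    # perivascular tracts flanking both arterial branches (lumen excluded)
    d_r, t_r = _polyline_distance(x, y, geo.mca_right)
    d_l, t_l = _polyline_distance(x, y, geo.mca_left)
    d_branch = np.minimum(d_r, d_l)
    shell = (d_branch > geo.vessel_radius) & (
        d_branch <= geo.vessel_radius + 2.0 * geo.pvs_halfwidth
    )
    labels[brain & shell] = PVS

    # blood last so lumen/ring always win
    lumen = d_branch <= geo.vessel_radius
    ring = np.abs(r_cow - geo.cow_radius) <= geo.cow_tube_halfwidth
    labels[brain & (lumen | ring)] = BLOOD

    # tangents: local branch direction on PVS, caudal-rostral on subarachnoid
    tangents = np.zeros(spec.matrix + (3,))
    use_right = d_r <= d_l
    t2d = np.where(use_right[..., None], t_r, t_l)
    pvs_mask = labels == PVS
    tangents[pvs_mask, 0] = t2d[pvs_mask, 0]
    tangents[pvs_mask, 1] = t2d[pvs_mask, 1]
    tangents[labels == SUBARACHNOID] = _Y_AXIS

    # per-voxel tensors
    table = spec.compartment_table()
    tensors = np.zeros(spec.matrix + (3, 3))
    for lbl, comp in table.items():
        mask = labels == lbl
        if lbl == PVS:
            # rotate the canonical axisymmetric tensor onto the local tangent
            w = np.linalg.eigvalsh(comp.Dstar)
            l_perp, l_par = w[0], w[-1]
            t = tangents[mask]
            tensors[mask] = l_perp * np.eye(3) + (l_par - l_perp) * np.einsum(
                "vi,vj->vij", t, t
            )
        else:
            tensors[mask] = comp.Dstar
    return GroundTruth(labels, tensors, tangents)


def apply_scenario(gt: GroundTruth, spec: PhantomSpec) -> GroundTruth:
    """Rescale ground-truth tensors according to the physiological scenario.

    ``pulsation`` multiplies the perivascular leading eigenvalue by
    ``pulsation_gain`` relative to diastole; ``dobutamine`` by
    ``dobutamine_gain`` relative to baseline; ``postmortem`` multiplies every
    fluid-compartment tensor by ``postmortem_factor``.  ``baseline`` and
    ``diastole`` leave the tensors unchanged.
    """
    out = gt.copy()
    scn = spec.scenario
    if scn in ("baseline", "diastole"):
        return out
    if scn in ("pulsation", "dobutamine"):
        gain = spec.pulsation_gain if scn == "pulsation" else spec.dobutamine_gain
        mask = gt.label_map == PVS
        t = gt.tangent_map[mask]
        D = gt.tensor_map[mask]
        l_par = np.einsum("vi,vij,vj->v", t, D, t)
        out.tensor_map[mask] = D + (gain - 1.0) * l_par[:, None, None] * np.einsum(
            "vi,vj->vij", t, t
        )
        return out
    if scn == "postmortem":
        mask = np.isin(gt.label_map, FLUID_LABELS)
        out.tensor_map[mask] *= spec.postmortem_factor
        return out
    raise ParameterError(f"unknown scenario {scn!r}")


def render_dwi(
    gt: GroundTruth, params: AcquisitionParams, spec: PhantomSpec
) -> DWIVolume:
    """Composite the forward signal model over the phantom geometry.

    Volume 0 is the b0 image; one volume per gradient direction follows at
    the acquisition's b-value.  Rician noise of ``spec.noise_sigma`` is added
    with the spec's seed (sigma 0 gives the noiseless image).
    """
    dirs = params.direction_array
    if dirs.size == 0:
        raise ParameterError("at least one gradient direction is required")
    b = params.b_value
    table = spec.compartment_table()

    s0_map = np.zeros(spec.matrix)
    for lbl, comp in table.items():
        s0_map[gt.label_map == lbl] = steady_state_scale(
            comp.S0, params.TR, params.TE_eff, comp.T2
        )

    nvol = 1 + len(dirs)
    data = np.zeros(spec.matrix + (1, nvol))
    data[..., 0, 0] = s0_map
    for k, g in enumerate(dirs):
        adc = np.einsum("i,xyij,j->xy", g, gt.tensor_map, g)
        data[..., 0, k + 1] = s0_map * np.exp(-b * adc)

    if spec.noise_sigma > 0:
        data = add_rician_noise(data, spec.noise_sigma, spec.seed)

    bvals = np.concatenate([[0.0], np.full(len(dirs), b)])
    bvecs = np.vstack([np.zeros(3), dirs])
    nx, ny = spec.matrix
    voxel = (spec.fov_mm[0] / nx, spec.fov_mm[1] / ny, spec.slice_thickness_mm)
    meta = {
        "spec_sha": spec.sha(),
        "seed": spec.seed,
        "scenario": spec.scenario,
        "b_value": b,
        "noise_sigma": spec.noise_sigma,
    }
    return DWIVolume(data, bvals, bvecs, voxel, meta)


def add_rician_noise(data: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Rician-corrupt a magnitude image: sqrt((data + n1)^2 + n2^2).

    ``n1, n2`` are iid Normal(0, sigma) channel noise; ``sigma = 0`` returns
    the input unchanged.  Reproducible under ``seed``.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be non-negative, got {sigma}")
    data = np.asarray(data, dtype=float)
    if sigma == 0:
        return data.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=data.shape)
    n2 = rng.normal(0.0, sigma, size=data.shape)
    return np.sqrt((data + n1) ** 2 + n2 ** 2)


def sigma_for_snr(spec: PhantomSpec, params: AcquisitionParams, snr: float) -> float:
    """Channel noise sigma giving a target b0 SNR in the CSF compartment."""
    if snr <= 0:
        raise ParameterError("snr must be positive")
    csf = spec.compartment_table()[SUBARACHNOID]
    return steady_state_scale(csf.S0, params.TR, params.TE_eff, csf.T2) / snr


def simulate(
    spec: PhantomSpec, params: AcquisitionParams
) -> Tuple[DWIVolume, GroundTruth]:
    """Build geometry, apply the scenario and render: the full forward chain."""
    gt = apply_scenario(build_geometry(spec), spec)
    return render_dwi(gt, params, spec), gt


def roi_masks(gt: GroundTruth, spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Analysis ROIs derived from the ground-truth labels.

    Perivascular tracts are split into right/left hemisphere masks at the
    midline; subarachnoid and ventricle ROIs are the full labels.
    """
    x, _ = _grids(spec)
    pvs = gt.label_map == PVS
    return {
        "pvs_right": pvs & (x > 0),
        "pvs_left": pvs & (x < 0),
        "subarachnoid": gt.label_map == SUBARACHNOID,
        "ventricle": gt.label_map == VENTRICLE,
    }
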