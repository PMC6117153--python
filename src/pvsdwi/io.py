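"""NIfTI / FSL b-table / flat-config readers and writers.

DWI stacks are stored as NIfTI-1 4D volumes with FSL-dialect sidecars: a
``.bval`` file holding one whitespace-separated row of b-values and a
``.bvec`` file holding three rows (x, y, z components; zero columns mark b0
volumes).  Acquisition parameters travel as a flat key = value text config.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import nibabel as nib
import numpy as np

from .phantom import DWIVolume, GroundTruth
from .signal_model import AcquisitionParams, ParameterError

__all__ = [
    "read_dwi",
    "write_dwi",
    "write_ground_truth",
    "write_map",
    "read_map",
    "read_acquisition_config",
    "write_acquisition_config",
]

# flattened tensor component order in ground-truth / fit exports
_TENSOR_COMPONENTS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def _sidecar(path: Path, ext: str) -> Path:
    return path.with_suffix("").with_suffix(ext) if path.suffix == ".gz" else path.with_suffix(ext)


def write_dwi(vol: DWIVolume, path: Union[str, Path]) -> None:
    """Write a 4D NIfTI plus ``.bval``/``.bvec`` sidecars and a meta JSON."""
    path = Path(path)
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.data, affine), str(path))
    np.savetxt(_sidecar(path, ".bval"), vol.bvals[None], fmt="%.10g")
    np.savetxt(_sidecar(path, ".bvec"), vol.bvecs.T, fmt="%.10g")
    if vol.meta:
        _sidecar(path, ".json").write_text(json.dumps(vol.meta, indent=2, sort_keys=True))


def read_dwi(path: Union[str, Path]) -> DWIVolume:
    """Read a 4D NIfTI with FSL b-table sidecars back into a :class:`DWIVolume`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    for ext in (".bval", ".bvec"):
        sc = _sidecar(path, ext)
        if not sc.exists():
            raise FileNotFoundError(f"missing sidecar {sc} (expected next to {path.name})")
    bvals = np.atleast_1d(np.loadtxt(_sidecar(path, ".bval"), dtype=float)).ravel()
    bvecs = np.loadtxt(_sidecar(path, ".bvec"), dtype=float)
    bvecs = np.atleast_2d(bvecs)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL writes 3 rows x N columns
    if data.ndim != 4:
        raise ParameterError(f"{path.name}: expected 4D data, got {data.ndim}D")
    if data.shape[-1] != len(bvals) or data.shape[-1] != bvecs.shape[0]:
        raise ParameterError(
            f"{path.name}: volume count {data.shape[-1]} does not match b-table "
            f"({len(bvals)} bvals, {bvecs.shape[0]} bvecs)"
        )
    meta: Dict = {}
    meta_path = _sidecar(path, ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIVolume(data, bvals, bvecs, voxel, meta)


def write_map(data: np.ndarray, path: Union[str, Path], voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a scalar/vector map as NIfTI (bool maps are cast to uint8)."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float64) if data.dtype.kind == "f" else data, affine), str(Path(path)))


def read_map(path: Union[str, Path]) -> np.ndarray:
    return np.asarray(nib.load(str(Path(path))).dataobj)


def write_ground_truth(gt: GroundTruth, out_dir: Union[str, Path], voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Write label map, 6-component tensor map (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)
    and tangent map as NIfTI volumes in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_map(gt.label_map.astype(np.int16), out / "labels.nii", voxel_size_mm)
    six = np.stack([gt.tensor_map[..., i, j] for i, j in _TENSOR_COMPONENTS], axis=-1)
    write_map(six, out / "tensors.nii", voxel_size_mm)
    write_map(gt.tangent_map, out / "tangents.nii", voxel_size_mm)


# ---------------------------------------------------------------------------
# flat-text acquisition config

_SCALAR_FIELDS = {
    "TR": float, "TE_eff": float, "echo_train_length": int, "echo_spacing": float,
    "first_echo_time": float, "delta_small": float, "delta_big": float, "G": float,
    "b_nominal": float, "rwave_delay": float,
}

_UNIT_COMMENTS = {
    "TR": "ms", "TE_eff": "ms", "echo_train_length": "echoes", "echo_spacing": "ms",
    "first_echo_time": "ms", "delta_small": "ms (gradient pulse duration)",
    "delta_big": "ms (gradient pulse separation)", "G": "G/cm",
    "b_nominal": "s/mm^2 (externally calculated)", "rwave_delay": "ms",
}


def write_acquisition_config(params: AcquisitionParams, path: Union[str, Path]) -> None:
    """Serialise acquisition parameters as one ``key = value`` line each."""
    lines = []
    for key in _SCALAR_FIELDS:
        val = getattr(params, key)
        if val is None:
            continue
        lines.append(f"{key} = {val:g}  # {_UNIT_COMMENTS[key]}")
    for k, g in enumerate(params.directions, start=1):
        lines.append(f"direction.{k} = {g[0]:.12g},{g[1]:.12g},{g[2]:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_acquisition_config(path: Union[str, Path]) -> AcquisitionParams:
    """Parse a flat-text acquisition config back into :class:`AcquisitionParams`."""
    kwargs: Dict = {}
    directions = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith("direction."):
            idx = int(key.split(".", 1)[1])
            directions[idx] = tuple(float(c) for c in val.split(","))
        elif key in _SCALAR_FIELDS:
            kwargs[key] = _SCALAR_FIELDS[key](val)
        else:
            raise ParameterError(f"unknown config key {key!r}")
    if directions:
        kwargs["directions"] = tuple(directions[i] for i in sorted(directions))
    return AcquisitionParams(**kwargs)
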