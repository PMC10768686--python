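"""NIfTI / FSL gradient-table readers and writers.

Conventions: single-shell DWI as 4D NIfTI with b0 volumes identified by
b < 50; gradients as FSL-style ``bvec`` (3 rows) / ``bval`` (1 row) text
files; SH coefficient fields as 4D NIfTI plus a JSON sidecar recording the
basis (order, convention, kind), which readers validate.  Processing is in
voxel space: gradient directions are not reoriented by the NIfTI affine
(phantoms use identity affines).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import sh
from .errors import InvalidArgumentError
from .simulate import DWIVolume, GradientScheme

B0_THRESHOLD = 50.0


def write_dwi(dwi: DWIVolume, nifti_path: str | Path, bvec_path: str | Path,
              bval_path: str | Path, voxel_size: tuple[float, float, float] = (1, 1, 1)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(dwi.data, affine), str(nifti_path))
    np.savetxt(bvec_path, dwi.scheme.bvecs(), fmt="%.10f")
    np.savetxt(bval_path, dwi.scheme.bvals()[None, :], fmt="%.2f")


def read_dwi(nifti_path: str | Path, bvec_path: str | Path, bval_path: str | Path,
             wm_mask: np.ndarray | None = None) -> DWIVolume:
    """Load a single-shell DWI; rejects multi-shell or inconsistent inputs."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise InvalidArgumentError(f"expected 4D DWI, got shape {data.shape}")
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    if bvecs.shape[0] != 3:
        raise InvalidArgumentError(f"bvec must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size or bvals.size != data.shape[3]:
        raise InvalidArgumentError(
            f"gradient table ({bvecs.shape[1]} bvecs, {bvals.size} bvals) does not match "
            f"{data.shape[3]} volumes"
        )
    is_b0 = bvals < B0_THRESHOLD
    dw = ~is_b0
    if not np.any(dw):
        raise InvalidArgumentError("no diffusion-weighted volumes (all b < 50)")
    norms = np.linalg.norm(bvecs[:, dw], axis=0)
    if np.any(np.abs(norms - 1.0) > 0.01):
        raise InvalidArgumentError("diffusion-weighted bvec columns must be unit-norm (tol 0.01)")
    shell = bvals[dw]
    b_ref = float(np.median(shell))
    if np.any(np.abs(shell - b_ref) > 0.1 * b_ref):
        raise InvalidArgumentError(
            f"multi-shell input (b-values {sorted(set(np.round(shell, 1)))}); "
            "extract a single shell upstream"
        )
    # reorder to b0-first layout
    order = np.concatenate([np.flatnonzero(is_b0), np.flatnonzero(dw)])
    scheme = GradientScheme(bvecs[:, dw].T, b_ref, n_b0=int(is_b0.sum()))
    return DWIVolume(data[..., order], scheme, wm_mask=wm_mask)


def write_mask(mask: np.ndarray, path: str | Path,
               voxel_size: tuple[float, float, float] = (1, 1, 1)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_sh_field(field: sh.SHField, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(field.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(field.data, affine), str(path))
    sidecar = {"order": field.spec.max_order, "convention": field.spec.convention,
               "kind": field.kind, "n_coeffs": field.spec.n_coeffs}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_sh_field(path: str | Path, expect_order: int | None = None,
                  expect_kind: str | None = None) -> sh.SHField:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise InvalidArgumentError(f"missing SH basis sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if expect_order is not None and meta.get("order") != expect_order:
        raise InvalidArgumentError(
            f"sidecar order {meta.get('order')} does not match requested order {expect_order}"
        )
    if expect_kind is not None and meta.get("kind") != expect_kind:
        raise InvalidArgumentError(
            f"sidecar kind {meta.get('kind')!r} does not match requested kind {expect_kind!r}"
        )
    spec = sh.SHBasisSpec(meta["order"], meta.get("convention", sh.CONVENTION))
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return sh.SHField(data, spec, kind=meta.get("kind", "fodf"))
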