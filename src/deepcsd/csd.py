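"""Single-shell single-tissue constrained spherical deconvolution (CSD).

The deconvolution inverts the spherical convolution of the fODF with an
axially symmetric single-fiber response: in an orthonormal SH basis a
zonal kernel multiplies coefficient (k, m) by r_k * sqrt(4 pi / (2k+1)).
The non-negativity constraint follows the classic iterative hard-threshold
scheme: starting from an unconstrained solution truncated at order 4,
sphere points whose fODF amplitude falls below tau times the mean initial
amplitude are penalized with weight lambda until the active set stabilizes.

Full-direction CSD fields serve as the silver-standard training labels for
the learning modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import sh
from .errors import ConditioningError, InvalidArgumentError
from .simulate import DWIVolume, GradientScheme
from .sphere import rotation_aligning, symmetric_sphere

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResponseFunction:
    """Single-fiber deconvolution kernel: m=0 SH coefficients per even order.

    ``zonal`` holds r_k for k = 0, 2, ..., L of the z-aligned single-fiber
    signal profile (normalized signal scale); ``s0`` records the reference
    non-diffusion-weighted intensity.
    """

    zonal: np.ndarray
    s0: float = 1.0

    def __post_init__(self) -> None:
        z = np.asarray(self.zonal, dtype=np.float64)
        object.__setattr__(self, "zonal", z)
        if z.ndim != 1 or not np.all(np.isfinite(z)):
            raise InvalidArgumentError("zonal coefficients must be a finite 1D vector")
        if z[0] <= 0:
            raise InvalidArgumentError("r_0 must be positive")

    @property
    def max_order(self) -> int:
        return 2 * (self.zonal.shape[0] - 1)

    def kernel_scales(self, max_order: int) -> np.ndarray:
        """Per-coefficient convolution factor r_k sqrt(4 pi/(2k+1))."""
        if max_order > self.max_order:
            raise InvalidArgumentError(
                f"response of order {self.max_order} cannot serve order {max_order}"
            )
        k = sh.orders(max_order)
        return self.zonal[k // 2] * np.sqrt(4.0 * np.pi / (2 * k + 1.0))


@dataclass
class CSDParams:
    """Deconvolution settings (classic hard-threshold defaults)."""

    max_order: int = 8
    lambda_reg: float = 1.0
    tau: float = 0.1
    n_iter: int = 50
    n_constraint: int = 724
    init_order: int = 4
    #: relative floor the output must respect (min amplitude >= -floor * max)
    negativity_floor: float = 0.01
    #: penalty weight applied to points that still violate the floor after
    #: the ordinary iteration has converged
    lambda_floor: float = 100.0
    n_floor_iter: int = 10


def _tensor_principal_axes(signals: np.ndarray, scheme: GradientScheme, s0_floor: float = 1e-6) -> np.ndarray:
    """Principal diffusion axis per voxel from a log-linear tensor fit.

    ``signals`` is (n_vox, n_volumes) with b0 columns first.  Negative or
    tiny signals are clamped before the log.
    """
    nb0 = scheme.n_b0
    b0 = signals[:, :nb0].mean(axis=1) if nb0 > 0 else np.ones(signals.shape[0])
    s = np.maximum(signals[:, nb0:], s0_floor * np.maximum(b0, 1e-30)[:, None])
    y = -np.log(s / np.maximum(b0, 1e-30)[:, None]) / scheme.bvalue
    g = scheme.directions
    # design for the 6 unique tensor components
    G = np.stack([g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                  2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]], axis=1)
    coef, *_ = np.linalg.lstsq(G, y.T, rcond=None)
    axes = np.empty((signals.shape[0], 3))
    for i in range(signals.shape[0]):
        dxx, dyy, dzz, dxy, dxz, dyz = coef[:, i]
        D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
        w, v = np.linalg.eigh(D)
        axes[i] = v[:, np.argmax(w)]
    return axes


def estimate_response(dwi: DWIVolume, single_fiber_mask: np.ndarray,
                      max_order: int = 8) -> ResponseFunction:
    """Average z-aligned single-fiber profile fitted with m=0 even SH.

    Each masked voxel's signal is treated as a function on the gradient
    sphere, reoriented so the tensor principal axis maps to +z, and the
    normalized signals are pooled into one zonal least-squares fit.
    """
    mask = np.asarray(single_fiber_mask, dtype=bool)
    if mask.sum() == 0:
        raise InvalidArgumentError("single-fiber mask is empty")
    scheme = dwi.scheme
    signals = dwi.data[mask]
    axes = _tensor_principal_axes(signals, scheme)
    norm = dwi.normalized_dwi()[mask]

    thetas, values = [], []
    z = np.array([0.0, 0.0, 1.0])
    for i in range(signals.shape[0]):
        R = rotation_aligning(axes[i], z)
        rot = scheme.directions @ R.T
        thetas.append(np.arccos(np.clip(rot[:, 2], -1.0, 1.0)))
        values.append(norm[i])
    cos_t = np.cos(np.concatenate(thetas))
    vals = np.concatenate(values)

    # zonal design: m=0 columns only
    ks = np.arange(0, max_order + 1, 2)
    from scipy.special import lpmv
    Bz = np.stack([np.sqrt((2 * k + 1) / (4 * np.pi)) * lpmv(0, k, cos_t) for k in ks], axis=1)
    zonal, *_ = np.linalg.lstsq(Bz, vals, rcond=None)
    return ResponseFunction(zonal, s0=dwi.s0)


def forward_convolve(fodf_coeffs: np.ndarray, response: ResponseFunction) -> np.ndarray:
    """Spherical convolution of an fODF with the zonal response (signal SH)."""
    c = np.asarray(fodf_coeffs, dtype=np.float64)
    max_order = sh.order_from_ncoeffs(c.shape[-1])
    return c * response.kernel_scales(max_order)


def _constraint_matrix(params: CSDParams) -> np.ndarray:
    return sh.design_matrix(symmetric_sphere(params.n_constraint), params.max_order)


def csd_fit(signal_amplitudes: np.ndarray, scheme: GradientScheme,
            response: ResponseFunction, params: CSDParams | None = None,
            _cache: dict | None = None) -> np.ndarray:
    """Constrained deconvolution of one voxel's normalized DW signal.

    ``signal_amplitudes`` holds the diffusion-weighted samples (no b0
    entries), already divided by the voxel's mean b0.
    """
    if params is None:
        params = CSDParams()
    c = _cache if _cache is not None else {}
    if "A" not in c:
        B_sig = sh.design_matrix(scheme.directions, params.max_order)
        scales = response.kernel_scales(params.max_order)
        c["A"] = B_sig * scales
        c["B_con"] = _constraint_matrix(params)
        c["k"] = sh.orders(params.max_order)
        cond = np.linalg.cond(c["A"])
        if cond > sh.MAX_CONDITION:
            raise ConditioningError(f"deconvolution matrix condition number {cond:.3g}")
        c["A_pinv"] = np.linalg.pinv(c["A"])
        c["AtA"] = c["A"].T @ c["A"]
        # per-row outer products of the constraint matrix (flattened), so
        # the normal matrix of any active set is one mask-vector matmul
        # (the deconvolution matrix is mildly conditioned, cond ~1e2, so
        # normal equations are safe in float64 and much faster than tall
        # least squares)
        nc = c["B_con"].shape[1]
        c["B_outer"] = np.einsum("pi,pj->pij", c["B_con"], c["B_con"]).reshape(-1, nc * nc)
    A, B_con, A_pinv = c["A"], c["B_con"], c["A_pinv"]
    AtA, B_outer = c["AtA"], c["B_outer"]
    s = np.asarray(signal_amplitudes, dtype=np.float64)
    if s.shape[0] != A.shape[0]:
        raise InvalidArgumentError("signal length does not match scheme directions")
    Ats = A.T @ s

    x = A_pinv @ s
    x[c["k"] > params.init_order] = 0.0  # low-order bootstrap
    f_init = B_con @ x
    threshold = params.tau * float(f_init.mean())

    nc = AtA.shape[0]

    def solve(active_mask: np.ndarray, lam_sq: float,
              viol_mask: np.ndarray | None = None, lam_floor_sq: float = 0.0) -> np.ndarray:
        w = lam_sq * active_mask.astype(np.float64)
        if viol_mask is not None:
            w = w + lam_floor_sq * viol_mask.astype(np.float64)
        lhs = AtA + (w @ B_outer).reshape(nc, nc)
        return np.linalg.solve(lhs, Ats)

    active_prev: np.ndarray | None = None
    lam_sq = params.lambda_reg**2
    for _ in range(params.n_iter):
        f = B_con @ x
        active = f < threshold
        if active_prev is not None and np.array_equal(active, active_prev):
            break
        x = solve(active, lam_sq)
        active_prev = active

    # The fixed point above does not by itself bound residual negativity.
    # Enforce the advertised floor surgically: only points still violating
    # it receive an additional strong penalty (accumulated across passes),
    # leaving the legitimate small-positive region untouched.
    viol_mask = np.zeros(B_con.shape[0], dtype=bool)
    base_active = active_prev if active_prev is not None else np.zeros(B_con.shape[0], bool)
    for _ in range(params.n_floor_iter):
        f = B_con @ x
        new_viol = f < -params.negativity_floor * f.max()
        if not np.any(new_viol & ~viol_mask):
            break
        viol_mask |= new_viol
        x = solve(base_active, lam_sq, viol_mask, params.lambda_floor**2)
    return x


def fit_csd_volume(dwi: DWIVolume, mask: np.ndarray | None,
                   response: ResponseFunction, params: CSDParams | None = None) -> sh.SHField:
    """Voxelwise CSD inside a mask; zeros outside; deterministic."""
    if params is None:
        params = CSDParams()
    if mask is None:
        mask = dwi.wm_mask
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(dwi.data.shape[:3] + (sh.n_coeffs(params.max_order),))
    cache: dict = {}
    norm = dwi.normalized_dwi()
    n_failed = 0
    for ijk in np.argwhere(mask):
        i, j, k = ijk
        try:
            out[i, j, k] = csd_fit(norm[i, j, k], dwi.scheme, response, params, _cache=cache)
        except (ConditioningError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed:
        logger.warning("CSD failed in %d voxels (left zero)", n_failed)
    return sh.SHField(out, sh.SHBasisSpec(params.max_order), kind="fodf")


def peak_directions(fodf_coeffs: np.ndarray, rel_threshold: float = 0.25,
                    min_sep_deg: float = 25.0, n_grid: int = 724,
                    n_refine: int = 40) -> np.ndarray:
    """Dominant fODF peak directions (unit vectors, one per antipodal pair).

    Local maxima on a fixed symmetric probe sphere are refined by
    tangent-plane gradient ascent; maxima below ``rel_threshold`` times the
    global maximum are discarded and peaks closer than ``min_sep_deg`` are
    merged keeping the larger.
    """
    c = np.asarray(fodf_coeffs, dtype=np.float64)
    if np.allclose(c, 0.0):
        return np.zeros((0, 3))
    max_order = sh.order_from_ncoeffs(c.shape[0])
    grid = symmetric_sphere(n_grid)
    amp = sh.sh_to_amplitudes(c, grid, max_order)
    gmax = float(amp.max())
    if gmax <= 0:
        return np.zeros((0, 3))
    # a (near-)isotropic fODF has maxima everywhere and no peaks anywhere
    if amp.max() - amp.min() <= 1e-9 * max(abs(gmax), 1.0):
        return np.zeros((0, 3))

    # local maxima: amplitude >= every neighbor within ~1.5x grid spacing
    cos_neigh = np.cos(np.radians(12.0))
    dots = np.abs(grid @ grid.T)
    candidates = []
    for i in range(n_grid):
        neigh = dots[i] > cos_neigh
        if amp[i] >= amp[neigh].max() and amp[i] >= rel_threshold * gmax:
            candidates.append(i)
    if not candidates:
        return np.zeros((0, 3))

    refined = []
    for i in candidates:
        d = grid[i].copy()
        step = 0.05
        val = float(sh.sh_to_amplitudes(c, d[None], max_order)[0])
        for _ in range(n_refine):
            # numerical tangent gradient
            t1 = np.cross(d, [1.0, 0.0, 0.0])
            if np.linalg.norm(t1) < 1e-6:
                t1 = np.cross(d, [0.0, 1.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(d, t1)
            eps = 1e-4
            probe = np.stack([d + eps * t1, d - eps * t1, d + eps * t2, d - eps * t2])
            probe /= np.linalg.norm(probe, axis=1, keepdims=True)
            pv = sh.sh_to_amplitudes(c, probe, max_order)
            grad = (pv[0] - pv[1]) / (2 * eps) * t1 + (pv[2] - pv[3]) / (2 * eps) * t2
            cand = d + step * grad / (np.linalg.norm(grad) + 1e-30)
            cand /= np.linalg.norm(cand)
            cv = float(sh.sh_to_amplitudes(c, cand[None], max_order)[0])
            if cv > val:
                d, val = cand, cv
                step *= 1.2
            else:
                step *= 0.5
                if step < 1e-6:
                    break
        if d[2] < 0 or (d[2] == 0 and d[0] < 0):  # canonical hemisphere
            d = -d
        refined.append((val, d))

    refined.sort(key=lambda t: -t[0])
    gmax = max(gmax, refined[0][0])
    kept: list[tuple[float, np.ndarray]] = []
    cos_sep = np.cos(np.radians(min_sep_deg))
    for val, d in refined:
        if val < rel_threshold * gmax:
            continue
        if all(abs(float(d @ kd)) < cos_sep for _, kd in kept):
            kept.append((val, d))
    return np.array([d for _, d in kept]).reshape(-1, 3)
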