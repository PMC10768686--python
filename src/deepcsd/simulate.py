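"""Scan/rescan DWI phantom generator.

Desk-scale stand-in for paired multi-site HARDI cohorts: multi-tensor
single-shell signals on an electrostatically optimized gradient scheme,
analytic ground-truth fODFs built from antipodally symmetrized Watson
lobes, Rician noise, and a mild rescan perturbation (independent noise,
low-frequency multiplicative bias, small gradient-scheme rotation).  Every
generator is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sh
from .errors import InvalidArgumentError
from .sphere import angle_between, check_unit, rotation_about, symmetric_sphere

#: default single-fiber tensor eigenvalues (mm^2/s): prolate, lambda2 = lambda3
DEFAULT_EIGENVALUES = (1.7e-3, 0.2e-3, 0.2e-3)
#: free-water isotropic diffusivity (mm^2/s)
DEFAULT_D_ISO = 3.0e-3
#: default Watson concentration of the ground-truth fODF lobes
DEFAULT_KAPPA = 50.0


@dataclass(frozen=True)
class GradientScheme:
    """Single-shell acquisition geometry: unit directions, b-value, b0 count."""

    directions: np.ndarray
    bvalue: float
    n_b0: int = 1

    def __post_init__(self) -> None:
        d = check_unit(self.directions)
        object.__setattr__(self, "directions", d)
        if self.bvalue <= 0:
            raise InvalidArgumentError("bvalue must be positive")
        if self.n_b0 < 0:
            raise InvalidArgumentError("n_b0 must be non-negative")
        if d.shape[0] >= 2:
            ang = angle_between(d, d)
            np.fill_diagonal(ang, 180.0)
            if float(ang.min()) < 1.0:
                raise InvalidArgumentError(
                    f"directions closer than 1 degree after antipodal identification ({ang.min():.3f})"
                )

    @property
    def n_dirs(self) -> int:
        return self.directions.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.n_dirs

    def subset(self, indices: np.ndarray) -> "GradientScheme":
        return GradientScheme(self.directions[np.asarray(indices)], self.bvalue, self.n_b0)

    def rotated(self, rotation: np.ndarray) -> "GradientScheme":
        return GradientScheme(self.directions @ np.asarray(rotation).T, self.bvalue, self.n_b0)

    def bvals(self) -> np.ndarray:
        """FSL-style 1 x n_volumes b-value row (b0 volumes first)."""
        return np.concatenate([np.zeros(self.n_b0), np.full(self.n_dirs, self.bvalue)])

    def bvecs(self) -> np.ndarray:
        """FSL-style 3 x n_volumes gradient table (zero columns for b0)."""
        return np.concatenate([np.zeros((self.n_b0, 3)), self.directions]).T


@dataclass(frozen=True)
class FiberConfig:
    """Intra-voxel fiber populations: unit directions and volume fractions.

    The isotropic fraction is the remainder 1 - sum(fractions).
    """

    directions: np.ndarray  # (n_pop, 3)
    fractions: np.ndarray   # (n_pop,)

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.directions, dtype=np.float64))
        f = np.atleast_1d(np.asarray(self.fractions, dtype=np.float64))
        if d.shape[0] != f.shape[0]:
            raise InvalidArgumentError("one fraction per fiber population required")
        if d.shape[0] > 0:
            check_unit(d)
        if np.any(f < 0) or np.any(f > 1) or f.sum() > 1.0 + 1e-9:
            raise InvalidArgumentError("fractions must lie in [0, 1] and sum to at most 1")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "fractions", f)

    @property
    def f_iso(self) -> float:
        return float(max(0.0, 1.0 - self.fractions.sum()))


@dataclass(frozen=True)
class RescanPerturbation:
    """Scanner-variability model applied to the rescan of a pair.

    Emulates inter-session effects: different noise realizations and SNR,
    a low-frequency multiplicative intensity bias, and a small rigid
    rotation of the gradient scheme.
    """

    snr_scan: float = 30.0
    snr_rescan: float = 25.0
    bias_amplitude: float = 0.05
    scheme_rotation_deg: float = 3.0

    def __post_init__(self) -> None:
        if self.snr_scan <= 0 or self.snr_rescan <= 0:
            raise InvalidArgumentError("SNR values must be positive")
        if not 0.0 <= self.bias_amplitude <= 0.2:
            raise InvalidArgumentError("bias_amplitude must lie in [0, 0.2]")
        if not 0.0 <= self.scheme_rotation_deg <= 10.0:
            raise InvalidArgumentError("scheme_rotation_deg must lie in [0, 10]")


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition (b0 volumes first)."""

    data: np.ndarray
    scheme: GradientScheme
    wm_mask: np.ndarray | None = None
    s0: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[3] != self.scheme.n_volumes:
            raise InvalidArgumentError(
                f"data shape {self.data.shape} does not match scheme with {self.scheme.n_volumes} volumes"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise InvalidArgumentError("signals must be finite and non-negative")

    @property
    def b0(self) -> np.ndarray:
        return self.data[..., : self.scheme.n_b0]

    @property
    def dwi(self) -> np.ndarray:
        return self.data[..., self.scheme.n_b0:]

    def normalized_dwi(self, floor: float = 1e-12) -> np.ndarray:
        """Diffusion-weighted signal divided by the per-voxel mean b0."""
        if self.scheme.n_b0 == 0:
            return self.dwi / self.s0
        b0 = np.maximum(self.b0.mean(axis=-1, keepdims=True), floor)
        return self.dwi / b0


@dataclass
class Phantom:
    """Synthetic anatomy with known per-voxel fiber configurations."""

    shape: tuple[int, int, int]
    fiber_dirs: np.ndarray    # (X, Y, Z, 2, 3); zero rows for absent populations
    fiber_fracs: np.ndarray   # (X, Y, Z, 2)
    wm_mask: np.ndarray
    single_fiber_mask: np.ndarray
    crossing_mask: np.ndarray
    gt_fodf: sh.SHField
    eigenvalues: tuple[float, float, float] = DEFAULT_EIGENVALUES
    d_iso: float = DEFAULT_D_ISO
    kappa: float = DEFAULT_KAPPA
    background_iso_fraction: float = 1.0

    def config_at(self, x: int, y: int, z: int) -> FiberConfig:
        f = self.fiber_fracs[x, y, z]
        keep = f > 0
        return FiberConfig(self.fiber_dirs[x, y, z][keep].reshape(-1, 3), f[keep])


def make_gradient_scheme(n_dirs: int, bvalue: float = 2000.0, n_b0: int = 1,
                         seed: int = 0, n_iter: int = 400) -> GradientScheme:
    """Electrostatic-repulsion gradient scheme over antipodal pairs.

    Starts from a seeded random configuration and descends the Coulomb
    energy summed over both members of each antipodal pair, with an
    adaptive step; deterministic given the seed.
    """
    if n_dirs < 6:
        raise InvalidArgumentError("n_dirs must be at least 6")
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_dirs, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)

    def energy(p: np.ndarray) -> float:
        diff = p[:, None, :] - p[None, :, :]
        summ = p[:, None, :] + p[None, :, :]
        d2m = np.einsum("ijk,ijk->ij", diff, diff)
        d2p = np.einsum("ijk,ijk->ij", summ, summ)
        iu = np.triu_indices(p.shape[0], 1)
        return float(np.sum(1.0 / d2m[iu]) + np.sum(1.0 / d2p[iu]))

    step = 0.1
    e = energy(d)
    for _ in range(n_iter):
        diff = d[:, None, :] - d[None, :, :]
        summ = d[:, None, :] + d[None, :, :]
        d2m = np.einsum("ijk,ijk->ij", diff, diff)
        d2p = np.einsum("ijk,ijk->ij", summ, summ)
        np.fill_diagonal(d2m, np.inf)
        np.fill_diagonal(d2p, np.inf)
        force = 2.0 * np.einsum("ij,ijk->ik", 1.0 / d2m**2, diff)
        force += 2.0 * np.einsum("ij,ijk->ik", 1.0 / d2p**2, summ)
        # project onto the tangent plane and normalize scale
        force -= np.einsum("ik,ik->i", force, d)[:, None] * d
        fmax = np.max(np.linalg.norm(force, axis=1))
        if fmax < 1e-14:
            break
        cand = d + step * force / fmax
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        e_cand = energy(cand)
        if e_cand < e:
            d, e = cand, e_cand
            step *= 1.05
        else:
            step *= 0.5
            if step < 1e-9:
                break
    return GradientScheme(d, bvalue, n_b0)


def _tensor_attenuation(dirs_pop: np.ndarray, gradients: np.ndarray, bvalue: float,
                        eigenvalues: tuple[float, float, float]) -> np.ndarray:
    """exp(-b g^T D g) for prolate tensors: (..., n_pop, n_dirs)."""
    l1, l2, l3 = eigenvalues
    if not (l1 >= l2 == l3 > 0):
        raise InvalidArgumentError("eigenvalues must satisfy l1 >= l2 = l3 > 0")
    dots = np.einsum("...pi,gi->...pg", dirs_pop, gradients)
    return np.exp(-bvalue * (l2 + (l1 - l2) * dots**2))


def simulate_signal(config: FiberConfig, scheme: GradientScheme,
                    eigenvalues: tuple[float, float, float] = DEFAULT_EIGENVALUES,
                    d_iso: float = DEFAULT_D_ISO, s0: float = 1.0) -> np.ndarray:
    """Noiseless multi-tensor signal for one voxel (b0 entries first)."""
    att = _tensor_attenuation(config.directions, scheme.directions, scheme.bvalue, eigenvalues)
    dw = s0 * (config.fractions @ att + config.f_iso * np.exp(-scheme.bvalue * d_iso))
    return np.concatenate([np.full(scheme.n_b0, s0), dw])


def _watson_zonal_coeffs(kappa: float, max_order: int) -> np.ndarray:
    """m=0 SH coefficients f_k of the unit-mass Watson kernel at +z.

    The kernel exp(kappa t^2)/Z (t = cosine to the axis, Z its mass on the
    sphere) is zonal, so only m=0 terms survive; they are computed by
    Gauss-Legendre quadrature in t, which is exact to machine precision at
    64 nodes for the orders used here.
    """
    nodes, weights = np.polynomial.legendre.leggauss(64)
    w_t = np.exp(kappa * nodes * nodes)
    z_kappa = 2.0 * np.pi * np.sum(weights * w_t)
    ks = np.arange(0, max_order + 1, 2)
    out = np.empty(ks.size)
    for i, k in enumerate(ks):
        pk = np.polynomial.legendre.Legendre.basis(k)(nodes)
        nk = np.sqrt((2 * k + 1) / (4.0 * np.pi))
        out[i] = 2.0 * np.pi * np.sum(weights * w_t * pk) * nk / z_kappa
    return out


def _watson_mixture_coeffs(lobe_dirs: np.ndarray, fractions: np.ndarray,
                           f_iso: np.ndarray, kappa: float, max_order: int) -> np.ndarray:
    """Exact order-``max_order`` SH projection of a Watson-lobe mixture.

    A zonal kernel centered on mu has coefficients
    c_k^m = sqrt(4 pi/(2k+1)) f_k Y_k^m(mu) (spherical convolution of the
    kernel with a delta at mu), which makes the projection exact and
    rotation-invariant — no spherical-grid aliasing.  The isotropic
    remainder adds only to the (0,0) term.
    """
    from . import sh as _sh  # local import to avoid cycle at module load
    zonal = _watson_zonal_coeffs(kappa, max_order)
    k = _sh.orders(max_order)
    scale = np.sqrt(4.0 * np.pi / (2 * k + 1.0)) * zonal[k // 2]
    dirs2 = np.atleast_2d(lobe_dirs.reshape(-1, 3))
    Y = _sh.design_matrix(dirs2, max_order).reshape(lobe_dirs.shape[:-1] + (k.size,))
    coeffs = np.einsum("...p,...pj->...j", np.atleast_1d(fractions), Y * scale)
    coeffs[..., 0] += np.asarray(f_iso) / np.sqrt(4.0 * np.pi)
    return coeffs


def _lift_nonnegative(coeffs: np.ndarray, margin: float = 1e-3) -> np.ndarray:
    """Absorb truncation ringing into the isotropic term.

    An order-8 truncation of a sharp Watson lobe rings slightly negative.
    Adding a constant raises the floor without touching any order >= 2
    coefficient, so peak locations and all angular-correlation comparisons
    (which exclude order 0) are unchanged.  The offset is sized on a dense
    probe sphere so amplitudes stay nonnegative everywhere (up to the
    probe resolution).
    """
    c = np.atleast_2d(np.asarray(coeffs, dtype=np.float64)).copy()
    max_order = sh.order_from_ncoeffs(c.shape[-1])
    probe = symmetric_sphere(2000)
    amps = sh.sh_to_amplitudes(c, probe, max_order)
    deficit = np.maximum(0.0, -(amps.min(axis=-1) - margin))
    c[:, 0] += deficit * np.sqrt(4.0 * np.pi)  # constant Y00 = 1/sqrt(4 pi)
    return c.reshape(np.shape(coeffs))


def ground_truth_fodf(config: FiberConfig, max_order: int = 8,
                      sharpness: float = DEFAULT_KAPPA) -> np.ndarray:
    """Order-``max_order`` SH projection of the voxel's Watson-mixture fODF."""
    if sharpness <= 0:
        raise InvalidArgumentError("sharpness must be positive")
    if config.directions.shape[0] == 0:
        c = np.zeros(sh.n_coeffs(max_order))
        c[0] = config.f_iso / np.sqrt(4.0 * np.pi)
        return c
    coeffs = _watson_mixture_coeffs(config.directions, config.fractions,
                                    np.float64(config.f_iso), sharpness, max_order)
    return _lift_nonnegative(coeffs)


def add_rician_noise(signal: np.ndarray, snr: float, seed: int, s0: float = 1.0) -> np.ndarray:
    """Magnitude-MR (Rician) noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, s0/snr)."""
    if snr <= 0:
        raise InvalidArgumentError("snr must be positive")
    s = np.asarray(signal, dtype=np.float64)
    if np.any(s < 0):
        raise InvalidArgumentError("signal must be non-negative")
    if snr >= 1e12:
        return s.copy()
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    e1 = rng.normal(0.0, sigma, s.shape)
    e2 = rng.normal(0.0, sigma, s.shape)
    return np.sqrt((s + e1) ** 2 + e2**2)


def add_gaussian_noise(signal: np.ndarray, snr: float, seed: int, s0: float = 1.0) -> np.ndarray:
    """Additive Gaussian alternative kept for debugging (not the default)."""
    if snr <= 0:
        raise InvalidArgumentError("snr must be positive")
    s = np.asarray(signal, dtype=np.float64)
    if snr >= 1e12:
        return s.copy()
    rng = np.random.default_rng(seed)
    return np.clip(s + rng.normal(0.0, s0 / snr, s.shape), 0.0, None)


def make_phantom(shape: tuple[int, int, int] = (16, 16, 16), seed: int = 0,
                 kappa: float = DEFAULT_KAPPA,
                 eigenvalues: tuple[float, float, float] = DEFAULT_EIGENVALUES,
                 d_iso: float = DEFAULT_D_ISO) -> Phantom:
    """Deterministic phantom with a single-fiber and a 90-degree-crossing region.

    Layout: white matter occupies a central slab.  The left block holds one
    coherent fiber population (mostly +z, orientation bending smoothly with
    y); the right block holds two orthogonal populations (near +x and +y,
    co-rotating smoothly with z); a one-voxel gap and the remaining
    background are isotropic non-WM.  Orientation changes between
    neighboring voxels stay below 15 degrees.
    """
    X, Y, Z = shape
    if min(X, Y, Z) < 8:
        raise InvalidArgumentError("each phantom dimension must be at least 8")
    rng = np.random.default_rng(seed)

    fiber_dirs = np.zeros((X, Y, Z, 2, 3))
    fiber_fracs = np.zeros((X, Y, Z, 2))
    wm = np.zeros(shape, dtype=bool)
    single = np.zeros(shape, dtype=bool)
    crossing = np.zeros(shape, dtype=bool)

    z0, z1 = max(1, Z // 2 - 3), min(Z - 1, Z // 2 + 3)
    y0, y1 = 1, Y - 1
    mid = X // 2
    # smooth orientation modulations; small random phases make phantoms
    # differ across seeds while preserving smoothness
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    for x in range(1, mid - 1):
        for y in range(y0, y1):
            bend = 10.0 * np.sin(2 * np.pi * y / Y + ph1)
            d = rotation_about([1.0, 0.0, 0.0], bend) @ np.array([0.0, 0.0, 1.0])
            for z in range(z0, z1):
                fiber_dirs[x, y, z, 0] = d
                fiber_fracs[x, y, z, 0] = 0.75
                wm[x, y, z] = single[x, y, z] = True
    for x in range(mid, X - 1):
        for z in range(z0, z1):
            twist = 8.0 * np.sin(2 * np.pi * z / Z + ph2)
            R = rotation_about([0.0, 0.0, 1.0], twist)
            d1, d2 = R @ np.array([1.0, 0.0, 0.0]), R @ np.array([0.0, 1.0, 0.0])
            for y in range(y0, y1):
                fiber_dirs[x, y, z, 0] = d1
                fiber_dirs[x, y, z, 1] = d2
                fiber_fracs[x, y, z] = (0.4, 0.4)
                wm[x, y, z] = crossing[x, y, z] = True

    gt = np.zeros(shape + (sh.n_coeffs(8),))
    dirs_v = fiber_dirs[wm]          # (n, 2, 3)
    fracs_v = fiber_fracs[wm]        # (n, 2)
    # zero-fraction populations contribute nothing; give them a valid axis
    safe_dirs = np.where(np.linalg.norm(dirs_v, axis=-1, keepdims=True) > 0, dirs_v, [0.0, 0.0, 1.0])
    f_iso = 1.0 - fracs_v.sum(axis=1)
    gt[wm] = _lift_nonnegative(_watson_mixture_coeffs(safe_dirs, fracs_v, f_iso, kappa, 8))

    return Phantom(shape=(X, Y, Z), fiber_dirs=fiber_dirs, fiber_fracs=fiber_fracs,
                   wm_mask=wm, single_fiber_mask=single, crossing_mask=crossing,
                   gt_fodf=sh.SHField(gt, sh.SHBasisSpec(8), kind="fodf"),
                   eigenvalues=eigenvalues, d_iso=d_iso, kappa=kappa)


def _noiseless_volume(phantom: Phantom, scheme: GradientScheme, s0: float) -> np.ndarray:
    X, Y, Z = phantom.shape
    data = np.empty((X, Y, Z, scheme.n_volumes))
    data[..., : scheme.n_b0] = s0
    dirs = phantom.fiber_dirs.reshape(-1, 2, 3)
    fracs = phantom.fiber_fracs.reshape(-1, 2)
    safe = np.where(np.linalg.norm(dirs, axis=-1, keepdims=True) > 0, dirs, [0.0, 0.0, 1.0])
    att = _tensor_attenuation(safe, scheme.directions, scheme.bvalue, phantom.eigenvalues)
    iso = np.exp(-scheme.bvalue * phantom.d_iso)
    dw = s0 * (np.einsum("vp,vpg->vg", fracs, att) + (1.0 - fracs.sum(axis=1))[:, None] * iso)
    data[..., scheme.n_b0:] = dw.reshape(X, Y, Z, scheme.n_dirs)
    return data


def _bias_field(shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 - a, 1 + a] (one spatial period)."""
    X, Y, Z = shape
    px, py, pz = rng.uniform(0, 2 * np.pi, 3)
    gx = np.sin(2 * np.pi * np.arange(X) / X + px)
    gy = np.sin(2 * np.pi * np.arange(Y) / Y + py)
    gz = np.sin(2 * np.pi * np.arange(Z) / Z + pz)
    g = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return 1.0 + amplitude * g


def make_scan_rescan(phantom: Phantom, scheme: GradientScheme,
                     perturbation: RescanPerturbation | None = None,
                     seed: int = 0, s0: float = 1.0,
                     share_noise_seed: bool = False) -> tuple[DWIVolume, DWIVolume]:
    """Paired acquisitions of the same anatomy with independent noise.

    The scan uses the given scheme at ``snr_scan``; the rescan uses a
    slightly rotated scheme at ``snr_rescan`` with a low-frequency
    multiplicative bias field.  Both are voxelwise aligned by
    construction.  ``share_noise_seed`` forces both members onto one noise
    stream, so a fully degenerate perturbation yields identical volumes.
    """
    if perturbation is None:
        perturbation = RescanPerturbation()
    rng = np.random.default_rng(seed)
    noise_seed_a, noise_seed_b = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
    if share_noise_seed:
        noise_seed_b = noise_seed_a

    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    scheme_b = (scheme.rotated(rotation_about(axis, perturbation.scheme_rotation_deg))
                if perturbation.scheme_rotation_deg > 0 else scheme)

    clean_a = _noiseless_volume(phantom, scheme, s0)
    clean_b = _noiseless_volume(phantom, scheme_b, s0)
    clean_b = clean_b * _bias_field(phantom.shape, perturbation.bias_amplitude, rng)[..., None]

    scan = add_rician_noise(clean_a, perturbation.snr_scan, noise_seed_a, s0)
    rescan = add_rician_noise(clean_b, perturbation.snr_rescan, noise_seed_b, s0)
    return (DWIVolume(scan, scheme, phantom.wm_mask, s0),
            DWIVolume(rescan, scheme_b, phantom.wm_mask, s0))
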