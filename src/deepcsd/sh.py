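"""Real antipodally symmetric spherical-harmonic basis.

Every spherical function in this package (the normalized diffusion signal
and the fiber orientation distribution function, fODF) is represented by
coefficients of the real, even-order spherical harmonics.  The convention,
labelled ``"real-sym-orthonormal"``, is fully orthonormal on the sphere:

.. math::

    Y_k^m(\\theta, \\phi) =
    \\begin{cases}
      \\sqrt{2}\\, N_k^{|m|} P_k^{|m|}(\\cos\\theta) \\sin(|m|\\phi) & m < 0 \\\\
      N_k^0 P_k^0(\\cos\\theta)                                      & m = 0 \\\\
      \\sqrt{2}\\, N_k^{m} P_k^{m}(\\cos\\theta) \\cos(m\\phi)        & m > 0
    \\end{cases}

with :math:`N_k^m = \\sqrt{\\tfrac{2k+1}{4\\pi}\\tfrac{(k-m)!}{(k+m)!}}` and
:math:`P_k^m` the associated Legendre functions including the
Condon-Shortley phase (scipy's ``lpmv``).  Only even orders k appear, so the
basis spans exactly the antipodally symmetric band-limited functions; at
maximum order L = 8 it has (L+1)(L+2)/2 = 45 elements.  Coefficients are
ordered by increasing even order k, then degree m from -k to +k.

All results in this package are internal to this one documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, lpmv

from .errors import ConditioningError, InvalidArgumentError
from .sphere import check_unit, to_spherical

CONVENTION = "real-sym-orthonormal"

#: condition-number ceiling above which least-squares fits are refused
MAX_CONDITION = 1e6


def n_coeffs(max_order: int) -> int:
    """Number of even-order real SH basis functions up to ``max_order``.

    For L = 8 this is 45, the coefficient count used throughout the model.
    """
    if max_order < 0 or max_order % 2 != 0:
        raise InvalidArgumentError(f"max_order must be even and >= 0, got {max_order}")
    L = int(max_order)
    return (L + 1) * (L + 2) // 2


def index_table(max_order: int) -> list[tuple[int, int]]:
    """Ordered (order k, degree m) pairs: even k ascending, m from -k to k."""
    if max_order < 0 or max_order % 2 != 0:
        raise InvalidArgumentError(f"max_order must be even and >= 0, got {max_order}")
    return [(k, m) for k in range(0, max_order + 1, 2) for m in range(-k, k + 1)]


def orders(max_order: int) -> np.ndarray:
    """Per-coefficient order k as an int array of length n_coeffs."""
    return np.array([k for k, _ in index_table(max_order)], dtype=int)


@dataclass(frozen=True)
class SHBasisSpec:
    """Basis descriptor: maximum even order and the convention label."""

    max_order: int = 8
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        n_coeffs(self.max_order)  # validates evenness / sign
        if self.convention != CONVENTION:
            raise InvalidArgumentError(
                f"unknown SH convention {self.convention!r}; this package implements {CONVENTION!r}"
            )

    @property
    def n_coeffs(self) -> int:
        return n_coeffs(self.max_order)


def _normalization(k: np.ndarray, m: np.ndarray) -> np.ndarray:
    # sqrt((2k+1)/(4 pi) * (k-m)!/(k+m)!) via log-gammas for stability
    logn = 0.5 * (
        np.log(2 * k + 1.0) - np.log(4 * np.pi) + gammaln(k - m + 1.0) - gammaln(k + m + 1.0)
    )
    return np.exp(logn)


def design_matrix(directions: np.ndarray, max_order: int) -> np.ndarray:
    """Evaluate every basis function at every direction: (n_dirs, n_coeffs).

    Rows are invariant under direction negation because only even orders
    enter the basis.
    """
    d = check_unit(np.atleast_2d(directions))
    theta, phi = to_spherical(d)
    cos_t = np.cos(theta)
    table = index_table(max_order)
    B = np.empty((d.shape[0], len(table)), dtype=np.float64)
    for j, (k, m) in enumerate(table):
        am = abs(m)
        col = _normalization(np.float64(k), np.float64(am)) * lpmv(am, k, cos_t)
        if m < 0:
            col = np.sqrt(2.0) * col * np.sin(am * phi)
        elif m > 0:
            col = np.sqrt(2.0) * col * np.cos(m * phi)
        B[:, j] = col
    return B


def fit_sh(
    amplitudes: np.ndarray,
    directions: np.ndarray,
    max_order: int,
    ridge: float = 0.0,
    laplace_beltrami: bool = False,
) -> np.ndarray:
    """Least-squares SH coefficients of sampled amplitudes.

    Parameters
    ----------
    amplitudes
        Function samples, shape (n_dirs,) or (n_samples, n_dirs); fits are
        solved jointly for the batched form.
    ridge
        Non-negative Tikhonov weight.  With ``laplace_beltrami=True`` the
        penalty on coefficient (k, m) is weighted by (k(k+1))^2, the
        standard smoothness prior for low-direction fits; otherwise it is a
        plain ridge.  Default 0 (>= 45 well-spread directions make the L=8
        fit well-posed without it).
    """
    if ridge < 0:
        raise InvalidArgumentError("ridge must be non-negative")
    a = np.asarray(amplitudes, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError("amplitudes must be finite")
    B = design_matrix(directions, max_order)
    nc = B.shape[1]
    squeeze = a.ndim == 1
    a2 = np.atleast_2d(a)
    if a2.shape[1] != B.shape[0]:
        raise InvalidArgumentError(
            f"amplitude count {a2.shape[1]} does not match direction count {B.shape[0]}"
        )
    if ridge == 0.0:
        if B.shape[0] < nc:
            raise ConditioningError(
                f"{B.shape[0]} directions cannot determine {nc} coefficients without regularization"
            )
        cond = np.linalg.cond(B)
        if cond > MAX_CONDITION:
            raise ConditioningError(f"design matrix condition number {cond:.3g} exceeds {MAX_CONDITION:.0e}")
        coeffs, *_ = np.linalg.lstsq(B, a2.T, rcond=None)
    else:
        if laplace_beltrami:
            k = orders(max_order).astype(np.float64)
            w = (k * (k + 1.0)) ** 2
        else:
            w = np.ones(nc)
        reg = np.sqrt(ridge) * np.sqrt(w)
        Baug = np.vstack([B, np.diag(reg)])
        rhs = np.vstack([a2.T, np.zeros((nc, a2.shape[0]))])
        coeffs, *_ = np.linalg.lstsq(Baug, rhs, rcond=None)
    out = coeffs.T
    return out[0] if squeeze else out


def sh_to_amplitudes(coeffs: np.ndarray, directions: np.ndarray, max_order: int | None = None) -> np.ndarray:
    """Evaluate an SH expansion at directions (linear in the coefficients)."""
    c = np.asarray(coeffs, dtype=np.float64)
    nc = c.shape[-1]
    if max_order is None:
        max_order = order_from_ncoeffs(nc)
    B = design_matrix(directions, max_order)
    if nc != B.shape[1]:
        raise InvalidArgumentError(f"coefficient length {nc} does not match order {max_order}")
    return c @ B.T


def order_from_ncoeffs(nc: int) -> int:
    """Inverse of :func:`n_coeffs`; errors if nc is not a valid count."""
    for L in range(0, 65, 2):
        if n_coeffs(L) == nc:
            return L
        if n_coeffs(L) > nc:
            break
    raise InvalidArgumentError(f"{nc} is not an even-order SH coefficient count")


@dataclass
class SHField:
    """A 3D lattice of SH coefficient vectors (X, Y, Z, n_coeffs)."""

    data: np.ndarray
    spec: SHBasisSpec = field(default_factory=SHBasisSpec)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "fodf"  # "signal" or "fodf"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InvalidArgumentError(f"SHField data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] != self.spec.n_coeffs:
            raise InvalidArgumentError(
                f"coefficient axis {self.data.shape[3]} != n_coeffs({self.spec.max_order}) = {self.spec.n_coeffs}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]
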