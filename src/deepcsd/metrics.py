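"""Evaluation metrics for fODF fields.

The workhorse is the angular correlation coefficient (ACC): the cosine
similarity of two SH coefficient vectors over orders k >= 1, i.e.
excluding the isotropic (0,0) term.  In this real basis conjugation is the
identity, so the complex-basis definition reduces to a plain inner
product.  ACC is 1 for identical fODF shapes, -1 for anti-aligned ones,
and undefined (0/0) when either voxel has no energy above order zero —
such voxels are reported as NaN and counted, never silently set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError, UndefinedACCError
from .sh import SHField


@dataclass
class ACCMap:
    """Voxelwise ACC values (NaN outside mask or where undefined)."""

    values: np.ndarray
    mask: np.ndarray
    n_undefined: int = 0


def acc(u: np.ndarray, v: np.ndarray) -> float:
    """Angular correlation coefficient of two SH coefficient vectors.

    Normalized inner product of the order >= 1 blocks; invariant to
    positive rescaling of either argument and symmetric in (u, v).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise InvalidArgumentError("u and v must be 1D coefficient vectors of equal length")
    uk, vk = u[1:], v[1:]  # index 0 is the sole k=0 coefficient
    nu, nv = np.linalg.norm(uk), np.linalg.norm(vk)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedACCError("ACC is undefined for a purely isotropic fODF (zero k>=1 energy)")
    return float(np.clip(uk @ vk / (nu * nv), -1.0, 1.0))


def acc_map(field_u: SHField, field_v: SHField, mask: np.ndarray) -> ACCMap:
    """Voxelwise ACC of two aligned fields inside a mask."""
    if field_u.data.shape != field_v.data.shape:
        raise InvalidArgumentError("fields must share shape and order")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field_u.shape:
        raise InvalidArgumentError("mask shape does not match fields")
    out = np.full(mask.shape, np.nan)
    u = field_u.data[mask][:, 1:]
    v = field_v.data[mask][:, 1:]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    defined = (nu > 0) & (nv > 0)
    vals = np.full(u.shape[0], np.nan)
    vals[defined] = np.clip(
        np.einsum("ij,ij->i", u[defined], v[defined]) / (nu[defined] * nv[defined]), -1.0, 1.0
    )
    out[mask] = vals
    return ACCMap(out, mask, n_undefined=int(np.sum(~defined)))


def mean_acc(m: ACCMap) -> tuple[float, float, int]:
    """NaN-excluding (mean, sd, n) of an ACC map over its mask."""
    vals = m.values[m.mask]
    vals = vals[~np.isnan(vals)]
    n = vals.size
    if n == 0:
        return float("nan"), float("nan"), 0
    return float(vals.mean()), float(vals.std(ddof=0)), n


def zeroth_coeff_map(field: SHField) -> np.ndarray:
    """Per-voxel (0,0) SH coefficient (the "MD" map of the ablation plots).

    This is the isotropic component of the fODF in this basis, not a
    diffusivity in physical units; ``md_map`` is kept as an alias for the
    field's customary name.
    """
    return field.data[..., 0].copy()


md_map = zeroth_coeff_map


def _exact_signed_rank_pvalue(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p-value with mid-ranks for ties.

    Enumerates the null distribution of W+ over all 2^n equally likely
    sign assignments by polynomial (dynamic-programming) convolution.
    Mid-ranks are doubled so every achievable sum is an integer.
    """
    ranks2 = np.asarray(2.0 * stats.rankdata(np.abs(d)), dtype=np.int64)
    w_plus = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** d.size
    p_low = float(counts[: w_plus + 1].sum())
    p_high = float(counts[w_plus:].sum())
    p = min(1.0, 2.0 * min(p_low, p_high))
    w_minus = total / 2.0 - w_plus / 2.0  # back to mid-rank units
    return float(min(w_plus / 2.0, w_minus)), p


def paired_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  For n <= 25 the exact null distribution
    is enumerated (mid-ranks for ties); larger samples use the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 6:
        raise InvalidArgumentError("paired samples must be equal-length 1D vectors with n >= 6")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        raise InvalidArgumentError("all paired differences are zero; the test is degenerate")
    if d.size <= 25:
        return _exact_signed_rank_pvalue(d)
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)
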