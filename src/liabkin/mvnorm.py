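"""Deterministic multivariate-normal rectangle probabilities in 1-4 dimensions.

Liability-threshold likelihoods need orthant probabilities of a correlated
Gaussian vector (one liability per trait per sibling) evaluated thousands of
times inside an optimiser, so the integrator here is deterministic and fast:
the bivariate CDF uses Genz's Gauss-Legendre reduction of the Drezner-
Wesolowsky integral (absolute accuracy ~1e-14), and the 3- and 4-dimensional
CDFs condition on the leading one or two variables and integrate the exact
conditional bivariate rectangle over a tensor Gauss-Legendre grid in
probability scale.  Cell probabilities over all sign patterns are assembled
by subset inclusion-exclusion from the CDF values, so they sum to one by
construction.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import ndtr

__all__ = [
    "bvn_upper",
    "bvn_rect",
    "mvn_cdf",
    "mvn_rect",
    "orthant_probability",
    "cell_probabilities",
]

_TWOPI = 2.0 * np.pi

# Gauss-Legendre half-rules used by Genz's BVN algorithm (weights, +nodes).
_GL_RULES = {
    6: (
        np.array([0.1713244923791705, 0.3607615730481384, 0.4679139345726904]),
        np.array([0.9324695142031522, 0.6612093864662647, 0.2386191860831970]),
    ),
    12: (
        np.array(
            [
                0.04717533638651177, 0.1069393259953183, 0.1600783285433464,
                0.2031674267230659, 0.2334925365383547, 0.2491470458134029,
            ]
        ),
        np.array(
            [
                0.9815606342467191, 0.9041172563704750, 0.7699026741943050,
                0.5873179542866171, 0.3678314989981802, 0.1252334085114692,
            ]
        ),
    ),
    20: (
        np.array(
            [
                0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
                0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
                0.1527533871307259,
            ]
        ),
        np.array(
            [
                0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
                0.07652652113349733,
            ]
        ),
    ),
}


def _gl_rule(r: float):
    ar = abs(r)
    if ar < 0.3:
        n = 6
    elif ar < 0.75:
        n = 12
    else:
        n = 20
    w, x = _GL_RULES[n]
    return np.concatenate([w, w]), np.concatenate([1.0 - x, 1.0 + x])


def bvn_upper(h, k, r: float):
    """P(X > h, Y > k) for a standard bivariate normal with correlation ``r``.

    ``h`` and ``k`` broadcast; ``r`` is scalar.  Vectorised translation of
    Genz's BVND algorithm.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    shape = h.shape
    h = h.ravel().copy()
    k = k.ravel().copy()
    r = float(r)
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")

    out = np.empty(h.shape)
    # infinite limits resolved exactly
    inf_mask = ~(np.isfinite(h) & np.isfinite(k))
    if inf_mask.any():
        hi, ki = h[inf_mask], k[inf_mask]
        res = np.where(
            (hi == np.inf) | (ki == np.inf),
            0.0,
            np.where(
                hi == -np.inf,
                np.where(ki == -np.inf, 1.0, ndtr(-ki)),
                ndtr(-hi),
            ),
        )
        out[inf_mask] = res
    fin = ~inf_mask
    if fin.any():
        out[fin] = _bvn_upper_finite(h[fin], k[fin], r)
    return out.reshape(shape)


def _bvn_upper_finite(h: np.ndarray, k: np.ndarray, r: float) -> np.ndarray:
    w, xx = _gl_rule(r)
    if abs(r) < 0.925:
        if r == 0.0:
            bvn = ndtr(-h) * ndtr(-k)
        else:
            hk = h * k
            hs = (h * h + k * k) / 2.0
            asr = np.arcsin(r) / 2.0
            sn = np.sin(asr * xx)  # (m,)
            expo = (sn[:, None] * hk[None, :] - hs[None, :]) / (
                1.0 - sn[:, None] ** 2
            )
            bvn = (w[:, None] * np.exp(expo)).sum(axis=0)
            bvn = bvn * asr / _TWOPI + ndtr(-h) * ndtr(-k)
        return np.clip(bvn, 0.0, 1.0)

    # |r| >= 0.925: Drezner-Wesolowsky tail expansion + correction integral
    kk = -k if r < 0 else k.copy()
    hk = h * kk
    bvn = np.zeros_like(h)
    if abs(r) < 1.0:
        as_ = (1.0 - r) * (1.0 + r)
        a = np.sqrt(as_)
        bs = (h - kk) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 80.0
        asr0 = -(bs / as_ + hk) / 2.0
        m0 = asr0 > -100.0
        with np.errstate(over="ignore"):
            term0 = a * np.exp(np.where(m0, asr0, -np.inf)) * (
                1.0 - c * (bs - as_) * (1.0 - d * bs) / 3.0 + c * d * as_ * as_
            )
        bvn = np.where(m0, term0, 0.0)
        m1 = hk > -100.0
        b = np.sqrt(bs)
        sp = np.sqrt(_TWOPI) * ndtr(-b / a)
        corr = np.exp(np.where(m1, -hk / 2.0, 0.0)) * sp * b * (
            1.0 - c * bs * (1.0 - d * bs) / 3.0
        )
        bvn = np.where(m1, bvn - corr, bvn)
        ah = a / 2.0
        for wi, xi in zip(w, xx):
            xs = (ah * xi) ** 2
            asr1 = -(bs / xs + hk) / 2.0
            rs = np.sqrt(1.0 - xs)
            sp1 = 1.0 + c * xs * (1.0 + 5.0 * d * xs)
            ep = np.exp(-(hk / 2.0) * xs / (1.0 + rs) ** 2) / rs
            add = ah * wi * np.exp(np.where(asr1 > -100.0, asr1, -np.inf)) * (
                ep - sp1
            )
            bvn = bvn + np.where(asr1 > -100.0, add, 0.0)
        bvn = -bvn / _TWOPI
    if r > 0:
        p = bvn + ndtr(-np.maximum(h, kk))
    else:
        p = -bvn + np.maximum(0.0, ndtr(-h) - ndtr(-kk))
    return np.clip(p, 0.0, 1.0)


def bvn_rect(l1, u1, l2, u2, r: float):
    """P(l1 < X < u1, l2 < Y < u2), vectorised over limits with scalar r."""
    return (
        bvn_upper(l1, l2, r)
        - bvn_upper(l1, u2, r)
        - bvn_upper(u1, l2, r)
        + bvn_upper(u1, u2, r)
    )


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    evals = np.linalg.eigvalsh(corr)
    if evals[0] < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {evals[0]:.3g})")
    return corr


_GL_CACHE: dict = {}


def _full_gl(n: int):
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


_ZMAX = 8.5  # standard-normal mass beyond +/-8.5 is ~< 1e-17

_SQRT_TWOPI = np.sqrt(2.0 * np.pi)


def _adaptive(quad, n_nodes: int, smooth: float, tol: float = 3e-8) -> float:
    """Run ``quad`` with node doubling until two refinements agree.

    ``smooth`` is an a-priori smoothness score (small conditional variances
    or a near-singular conditional correlation mean sharp or kinked
    integrands); well-conditioned problems take the single-pass fast path.
    """
    if smooth > 0.25:
        return quad(n_nodes)
    n = max(n_nodes, 48)
    prev = quad(n)
    while n < 512:
        n *= 2
        cur = quad(n)
        if abs(cur - prev) < tol:
            return cur
        prev = cur
    return prev


def _cdf3(upper: np.ndarray, corr: np.ndarray, n_nodes: int) -> float:
    """P(X1<u1, X2<u2, X3<u3) by conditioning on X1.

    The outer integral runs in z-space over the truncated support
    [-_ZMAX, min(u1, _ZMAX)] with the Gaussian density folded into the
    Gauss-Legendre weights; the integrand is then analytic and convergence
    is exponential in the node count.
    """
    if np.any(upper == -np.inf):
        return 0.0
    # condition on the variable leaving the inner pair most weakly coupled,
    # so the conditional bivariate CDF absorbs strong correlations exactly
    best, best_score = 0, -np.inf
    for i in range(3):
        rest = [j for j in range(3) if j != i]
        score = min(
            1.0 - corr[i, rest[0]] ** 2, 1.0 - corr[i, rest[1]] ** 2
        )
        if upper[i] == np.inf:
            score = np.inf  # integrates out exactly
        if score > best_score:
            best, best_score = i, score
    order = [best] + [j for j in range(3) if j != best]
    upper = upper[order]
    corr = corr[np.ix_(order, order)]
    u1, u2, u3 = upper
    if u1 == np.inf:
        return float(bvn_upper(-u2, -u3, corr[1, 2]))
    r12, r13, r23 = corr[0, 1], corr[0, 2], corr[1, 2]
    sd2 = np.sqrt(max(1.0 - r12 * r12, 1e-14))
    sd3 = np.sqrt(max(1.0 - r13 * r13, 1e-14))
    rc = np.clip((r23 - r12 * r13) / (sd2 * sd3), -1.0, 1.0)
    a1, b1 = -_ZMAX, min(u1, _ZMAX)
    if b1 <= a1:
        return 0.0

    def quad(n: int) -> float:
        x, w = _full_gl(n)
        z = (b1 - a1) / 2.0 * x + (a1 + b1) / 2.0
        wz = (b1 - a1) / 2.0 * w * np.exp(-z * z / 2.0) / _SQRT_TWOPI
        a2 = (u2 - r12 * z) / sd2 if u2 != np.inf else np.full_like(z, np.inf)
        a3 = (u3 - r13 * z) / sd3 if u3 != np.inf else np.full_like(z, np.inf)
        return float(np.dot(wz, bvn_upper(-a2, -a3, rc)))

    smooth = min(1.0 - rc * rc, sd2 * sd2, sd3 * sd3)
    return _adaptive(quad, n_nodes, smooth)


def _cdf4(upper: np.ndarray, corr: np.ndarray, n_nodes: int) -> float:
    """P(X1<u1,...,X4<u4) by conditioning on (X1, X2); same z-space
    Gauss-Legendre scheme as `_cdf3`, tensorised over the first two
    coordinates with sequential (Cholesky) conditioning."""
    if np.any(upper == -np.inf):
        return 0.0
    inf_mask = upper == np.inf
    if inf_mask.any():
        idx = [i for i in range(4) if not inf_mask[i]]
        sub_u = upper[idx]
        sub_c = corr[np.ix_(idx, idx)]
        if len(idx) <= 2:
            return mvn_cdf(sub_u, sub_c, n_nodes) if len(idx) else 1.0
        return _cdf3(sub_u, sub_c, n_nodes)
    # pick the outer/inner 2+2 partition whose inner pair retains the most
    # conditional variance: sharp conditional limits are what slows the
    # outer quadrature down
    best_order, best_score = None, -np.inf
    for inner in ((2, 3), (1, 3), (1, 2)):
        outer = tuple(i for i in range(4) if i not in inner)
        S11_ = corr[np.ix_(outer, outer)]
        S21_ = corr[np.ix_(inner, outer)]
        Sc_ = corr[np.ix_(inner, inner)] - S21_ @ np.linalg.solve(
            S11_ + 1e-12 * np.eye(2), S21_.T
        )
        score = min(Sc_[0, 0], Sc_[1, 1])
        if score > best_score:
            best_order, best_score = outer + inner, score
    order = list(best_order)
    upper = upper[order]
    corr = corr[np.ix_(order, order)]
    r12 = corr[0, 1]
    S11 = corr[:2, :2]
    S21 = corr[2:, :2]
    S22 = corr[2:, 2:]
    B = S21 @ np.linalg.inv(S11 + 1e-12 * np.eye(2))
    Sc = S22 - B @ S21.T
    sd = np.sqrt(np.maximum(np.diag(Sc), 1e-14))
    rc = np.clip(Sc[0, 1] / (sd[0] * sd[1]), -1.0, 1.0)

    l21 = r12
    l22 = np.sqrt(max(1.0 - r12 * r12, 1e-14))
    a1, b1 = -_ZMAX, min(upper[0], _ZMAX)
    if b1 <= a1:
        return 0.0

    def quad(n: int) -> float:
        x, w = _full_gl(n)
        z1 = (b1 - a1) / 2.0 * x + (a1 + b1) / 2.0
        w1 = (b1 - a1) / 2.0 * w * np.exp(-z1 * z1 / 2.0) / _SQRT_TWOPI
        # inner variable u2 = (x2 - l21*z1)/l22 truncated at its limit
        b2 = np.minimum((upper[1] - l21 * z1) / l22, _ZMAX)
        z2 = (
            (b2[:, None] + _ZMAX) / 2.0 * x[None, :]
            + (b2[:, None] - _ZMAX) / 2.0
        )
        w2 = (
            (b2[:, None] + _ZMAX)
            / 2.0
            * w[None, :]
            * np.exp(-z2 * z2 / 2.0)
            / _SQRT_TWOPI
        )
        w2 = np.where((b2 > -_ZMAX)[:, None], w2, 0.0)
        x1 = np.broadcast_to(z1[:, None], z2.shape)
        x2 = l21 * x1 + l22 * z2
        m3 = B[0, 0] * x1 + B[0, 1] * x2
        m4 = B[1, 0] * x1 + B[1, 1] * x2
        a3 = (
            (upper[2] - m3) / sd[0]
            if upper[2] != np.inf
            else np.full_like(m3, np.inf)
        )
        a4 = (
            (upper[3] - m4) / sd[1]
            if upper[3] != np.inf
            else np.full_like(m4, np.inf)
        )
        return float(np.einsum("i,ij,ij->", w1, w2, bvn_upper(-a3, -a4, rc)))

    smooth = min(1.0 - rc * rc, sd[0] ** 2, sd[1] ** 2)
    return _adaptive(quad, n_nodes, smooth)


def mvn_cdf(upper, corr, n_nodes: int = 24) -> float:
    """P(X_i < upper_i for all i) for a zero-mean Gaussian with correlation
    matrix ``corr`` (dimension 1-4).  Deterministic."""
    upper = np.asarray(upper, dtype=float)
    corr = _check_corr(corr)
    d = len(upper)
    if corr.shape != (d, d):
        raise ValueError("dimension mismatch between limits and matrix")
    if d == 1:
        return float(ndtr(upper[0]))
    if d == 2:
        return float(bvn_upper(-upper[0], -upper[1], corr[0, 1]))
    if d == 3:
        return _cdf3(upper, corr, n_nodes)
    if d == 4:
        return _cdf4(upper, corr, n_nodes)
    raise ValueError("only dimensions 1-4 are supported")


def mvn_rect(lower, upper, corr, n_nodes: int = 24) -> float:
    """P(lower_i < X_i < upper_i for all i), by inclusion-exclusion over
    the rectangle corners."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    corr = _check_corr(corr)
    d = len(lower)
    if np.any(lower >= upper):
        return 0.0
    total = 0.0
    for corner in itertools.product((0, 1), repeat=d):
        pt = np.where(np.asarray(corner, bool), lower, upper)
        sign = (-1) ** sum(corner)
        total += sign * mvn_cdf(pt, corr, n_nodes=n_nodes)
    return float(max(total, 0.0))


def orthant_probability(corr, thresholds, signs, n_nodes: int = 24) -> float:
    """Probability that each coordinate falls on the given side of its
    threshold: sign ``+`` means above (affected), ``-`` means below.

    ``signs`` is a sequence of '+'/'-' characters or of +1/-1 integers.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    sgn = np.array([1 if s in ("+", 1) else -1 for s in signs])
    if len(sgn) != len(thresholds):
        raise ValueError("signs and thresholds must have equal length")
    lower = np.where(sgn > 0, thresholds, -np.inf)
    upper = np.where(sgn > 0, np.inf, thresholds)
    return mvn_rect(lower, upper, corr, n_nodes=n_nodes)


def cell_probabilities(corr, thresholds, n_nodes: int = 24) -> np.ndarray:
    """All 2^d orthant probabilities of the thresholded Gaussian, indexed by
    the affection pattern bitmask (bit i set = coordinate i above threshold).

    Assembled by inclusion-exclusion from the 2^d CDF evaluations, so the
    cells sum to one up to integration error.
    """
    corr = _check_corr(corr)
    thresholds = np.asarray(thresholds, dtype=float)
    d = len(thresholds)
    if corr.shape != (d, d):
        raise ValueError("dimension mismatch")
    # G[mask] = P(X_j < t_j for all j in mask)
    G = np.empty(2 ** d)
    for mask in range(2 ** d):
        idx = [i for i in range(d) if mask & (1 << i)]
        k = len(idx)
        if k == 0:
            G[mask] = 1.0
        elif k == 1:
            G[mask] = ndtr(thresholds[idx[0]])
        elif k == 2:
            i, j = idx
            G[mask] = bvn_upper(
                -thresholds[i], -thresholds[j], corr[i, j]
            )
        elif k == 3:
            G[mask] = _cdf3(
                thresholds[idx], corr[np.ix_(idx, idx)], n_nodes
            )
        else:
            G[mask] = _cdf4(thresholds, corr, n_nodes)
    cells = np.zeros(2 ** d)
    full = 2 ** d - 1
    for s_mask in range(2 ** d):  # bits set = affected (above threshold)
        comp = full & ~s_mask
        p = 0.0
        sub = s_mask
        # iterate over subsets V of s_mask
        while True:
            p += (-1) ** bin(sub).count("1") * G[sub | comp]
            if sub == 0:
                break
            sub = (sub - 1) & s_mask
        cells[s_mask] = max(p, 0.0)
    return cells
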