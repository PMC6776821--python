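"""Liability-threshold quantitative genetics for sibling pair data.

Binary disorders are modelled as thresholded standard-normal liabilities.
A pair of relatives measured on two disorders has a 4-dimensional Gaussian
liability vector (trait X and Y in each member) whose correlation matrix is
assembled from variance components A (additive genetic), D (dominant
genetic), C (shared environment) and E (unique environment) weighted by the
sharing coefficients of the relative class.  This module provides

* tetrachoric correlation maximum likelihood on 2x2 pair tables,
* the expected 4x4 pair correlation matrix for a component set,
* univariate and bivariate ACE/ADE/AE model fits by multinomial maximum
  likelihood over pair contingency cells, with AIC model selection,
* a weighted least-squares solution of the bivariate AE system directly
  from tetrachoric correlations, for published-summary reproduction.

Component matrices are parameterised by per-trait variance fractions
(softmax over the model's components, so they are positive and sum to one)
and cross-trait component correlations (tanh), which keeps every 2x2
component matrix positive semi-definite; the 4x4 pair matrix is then PSD
for any sharing coefficients in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtri

from .mvnorm import cell_probabilities, orthant_probability  # noqa: F401
from .relatedness import RelatednessClass

__all__ = [
    "threshold_from_prevalence",
    "orthant_probability",
    "TetrachoricResult",
    "tetrachoric_mle",
    "VarianceComponents",
    "pair_model_matrix",
    "BivariateFit",
    "fit_bivariate",
    "fit_univariate",
    "select_model",
    "ClassCorrelations",
    "solve_ae_from_correlations",
]

_MODELS = ("ACE", "ADE", "AE")


def threshold_from_prevalence(prevalence: float) -> float:
    """Standard-normal liability threshold with the given tail mass above it."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    return float(ndtri(1.0 - prevalence))


# ---------------------------------------------------------------------------
# tetrachoric correlation


@dataclass
class TetrachoricResult:
    r: float
    se: float
    ci: tuple[float, float]
    thresholds: tuple[float, float]
    loglik: float
    n: float
    boundary: bool = False

    def __repr__(self) -> str:  # compact, table-friendly
        lo, hi = self.ci
        flag = " [boundary]" if self.boundary else ""
        return f"tetrachoric r={self.r:.3f} (95% CI {lo:.3f}, {hi:.3f}){flag}"


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(getattr(table, "counts", table), dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return t


def _bvn_cells(t1: float, t2: float, r: float) -> np.ndarray:
    """2x2 cell probabilities, cell[i, j] = P(X status i, Y status j),
    status 1 meaning liability above threshold."""
    p = cell_probabilities(np.array([[1.0, r], [r, 1.0]]), [t1, t2])
    # bitmask: bit0 = first variable affected, bit1 = second affected
    return np.array([[p[0], p[2]], [p[1], p[3]]])


def tetrachoric_mle(table, r_bound: float = 0.999) -> TetrachoricResult:
    """Tetrachoric correlation of a 2x2 pair table by maximum likelihood.

    ``table[i, j]`` counts pairs with first-margin status ``i`` and
    second-margin status ``j`` (1 = affected).  Thresholds are estimated
    from the margins (their maximum-likelihood values under the bivariate
    normal with free correlation); the correlation then maximises the
    multinomial likelihood.  Fractional counts are accepted so tables
    reconstructed from published concordant/discordant summaries can be
    used directly.
    """
    t = _as_2x2(table)
    n = t.sum()
    m1 = t[1].sum()  # first margin affected
    m2 = t[:, 1].sum()
    if n <= 0 or min(m1, m2) <= 0 or min(n - m1, n - m2) <= 0:
        raise ValueError("tetrachoric MLE requires all margins nonzero")
    th1 = threshold_from_prevalence(m1 / n)
    th2 = threshold_from_prevalence(m2 / n)

    def negll(r: float) -> float:
        p = np.clip(_bvn_cells(th1, th2, r), 1e-300, 1.0)
        return -float((t * np.log(p)).sum())

    res = minimize_scalar(
        negll, bounds=(-r_bound, r_bound), method="bounded",
        options={"xatol": 1e-10},
    )
    r_hat = float(res.x)
    boundary = abs(r_hat) >= r_bound - 1e-6
    # observed information from the profile likelihood curvature
    h = 1e-4
    if boundary:
        se = np.nan
        ci = (np.nan, np.nan)
    else:
        d2 = (negll(r_hat + h) - 2.0 * negll(r_hat) + negll(r_hat - h)) / h**2
        se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
        ci = (r_hat - 1.959964 * se, r_hat + 1.959964 * se)
    return TetrachoricResult(
        r=r_hat, se=se, ci=ci, thresholds=(th1, th2),
        loglik=-negll(r_hat), n=float(n), boundary=boundary,
    )


# ---------------------------------------------------------------------------
# variance components and the pair model matrix


@dataclass
class VarianceComponents:
    """A/D/C/E liability variance fractions for two traits plus the
    cross-trait covariance carried by each component.

    ``a2`` etc. are length-2 arrays (fractions of unit liability variance
    per trait); ``cov_a`` etc. are scalars in liability covariance units.
    """

    a2: np.ndarray
    d2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    cov_a: float = 0.0
    cov_d: float = 0.0
    cov_c: float = 0.0
    cov_e: float = 0.0
    thresholds: np.ndarray = field(default_factory=lambda: np.zeros(2))
    traits: tuple[str, str] = ("X", "Y")

    def __post_init__(self) -> None:
        for name in ("a2", "d2", "c2", "e2", "thresholds"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        total = self.a2 + self.d2 + self.c2 + self.e2
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError(f"per-trait fractions must sum to 1, got {total}")
        if np.any(
            np.concatenate([self.a2, self.d2, self.c2, self.e2]) < -1e-12
        ):
            raise ValueError("variance fractions must be non-negative")
        for comp, cov in (
            ("a2", self.cov_a), ("d2", self.cov_d),
            ("c2", self.cov_c), ("e2", self.cov_e),
        ):
            bound = np.sqrt(np.prod(getattr(self, comp))) + 1e-12
            if abs(cov) > bound:
                raise ValueError(
                    f"cross-trait covariance {cov:.4f} exceeds the geometric "
                    f"mean bound {bound:.4f} for component {comp}"
                )

    @property
    def phenotypic_cov(self) -> float:
        return self.cov_a + self.cov_d + self.cov_c + self.cov_e

    @property
    def rg(self) -> float:
        denom = np.sqrt(self.a2[0] * self.a2[1])
        return self.cov_a / denom if denom > 0 else np.nan

    @property
    def re(self) -> float:
        denom = np.sqrt(self.e2[0] * self.e2[1])
        return self.cov_e / denom if denom > 0 else np.nan

    @property
    def coheritability_a(self) -> float:
        return self.cov_a / self.phenotypic_cov

    @property
    def coheritability_e(self) -> float:
        return self.cov_e / self.phenotypic_cov


def pair_model_matrix(
    vc: VarianceComponents, cls: RelatednessClass
) -> np.ndarray:
    """Expected 4x4 liability correlation matrix for (X1, Y1, X2, Y2):
    trait X and Y in member 1 then member 2 of a pair of the given class."""
    ka, kd, kc = cls.coeff_a, cls.coeff_d, cls.coeff_c
    within = vc.phenotypic_cov
    cross_x = ka * vc.a2[0] + kd * vc.d2[0] + kc * vc.c2[0]
    cross_y = ka * vc.a2[1] + kd * vc.d2[1] + kc * vc.c2[1]
    cross_xy = ka * vc.cov_a + kd * vc.cov_d + kc * vc.cov_c
    R = np.array(
        [
            [1.0, within, cross_x, cross_xy],
            [within, 1.0, cross_xy, cross_y],
            [cross_x, cross_xy, 1.0, within],
            [cross_xy, cross_y, within, 1.0],
        ]
    )
    evals = np.linalg.eigvalsh(R)
    if evals[0] < -1e-8:
        raise ValueError(
            f"implied pair matrix not PSD for class {cls.label} "
            f"(min eigenvalue {evals[0]:.3g})"
        )
    return R


# ---------------------------------------------------------------------------
# maximum-likelihood model fits


def _model_components(model: str) -> str:
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    return {"ACE": "C", "ADE": "D", "AE": ""}[model]


def _unpack_bivariate(
    theta: np.ndarray, model: str, n_classes: int, share_thresholds: bool
) -> tuple[VarianceComponents, np.ndarray]:
    """Map unconstrained parameters to a valid component set.

    Layout: [thresholds..., uA_X, uA_Y, (uM_X, uM_Y), zA, (zM), zE] where u
    are softmax logits relative to E and z are atanh component correlations.
    M is the model's middle component (C or D), absent for AE.  Thresholds
    are per relative class (two per class, trait X then Y) unless shared.
    Returns the components and a (n_classes, 2) threshold array.
    """
    extra = _model_components(model)
    nt = 2 if share_thresholds else 2 * n_classes
    th = theta[:nt].reshape(-1, 2)
    if share_thresholds:
        th = np.repeat(th, n_classes, axis=0)
    rest = theta[nt:]
    if extra:
        ua = rest[0:2]
        um = rest[2:4]
        za, zm, ze = rest[4], rest[5], rest[6]
        den = 1.0 + np.exp(ua) + np.exp(um)
        a2 = np.exp(ua) / den
        m2 = np.exp(um) / den
        e2 = 1.0 / den
    else:
        ua = rest[0:2]
        za, zm, ze = rest[2], 0.0, rest[3]
        den = 1.0 + np.exp(ua)
        a2 = np.exp(ua) / den
        m2 = np.zeros(2)
        e2 = 1.0 / den
    ra, rm, re_ = np.tanh([za, zm, ze])
    cov_a = ra * np.sqrt(a2[0] * a2[1])
    cov_m = rm * np.sqrt(m2[0] * m2[1])
    cov_e = re_ * np.sqrt(e2[0] * e2[1])
    zeros = np.zeros(2)
    vc = VarianceComponents(
        a2=a2,
        d2=m2 if extra == "D" else zeros,
        c2=m2 if extra == "C" else zeros,
        e2=e2,
        cov_a=cov_a,
        cov_d=cov_m if extra == "D" else 0.0,
        cov_c=cov_m if extra == "C" else 0.0,
        cov_e=cov_e,
        thresholds=th[0],
    )
    return vc, th


def _counts16(table) -> np.ndarray:
    c = np.asarray(getattr(table, "counts", table), dtype=float)
    if c.shape != (2, 2, 2, 2):
        raise ValueError(f"expected 2x2x2x2 pair counts, got shape {c.shape}")
    return c


def _bivariate_negll(
    theta: np.ndarray, tables: dict, model: str, share_thresholds: bool
) -> float:
    vc, th = _unpack_bivariate(theta, model, len(tables), share_thresholds)
    total = 0.0
    for k, (cls, table) in enumerate(tables.items()):
        counts = _counts16(table)
        try:
            R = pair_model_matrix(vc, cls)
        except ValueError:
            return 1e10
        cells = cell_probabilities(R, th[k][[0, 1, 0, 1]])
        # bitmask order: bit0=X1, bit1=Y1, bit2=X2, bit3=Y2
        p = cells.reshape(2, 2, 2, 2, order="F")  # p[x1, y1, x2, y2]
        # unordered pairs: average the two sister orderings (the model
        # matrix is exchangeable, so this equals the one-orientation value)
        p_sym = 0.5 * (p + p.transpose(2, 3, 0, 1))
        total -= float(
            (counts * np.log(np.clip(p_sym, 1e-300, 1.0))).sum()
        )
    return total


@dataclass
class BivariateFit:
    model: str
    components: VarianceComponents
    loglik: float
    aic: float
    n_params: int
    n_pairs: float
    param_cov: np.ndarray | None = None
    derived: dict = field(default_factory=dict)
    converged: bool = True
    classes: tuple[str, ...] = ()

    def summary(self) -> dict:
        vc = self.components
        out = {
            "model": self.model,
            "loglik": self.loglik,
            "aic": self.aic,
            "a2": list(vc.a2),
            "c2": list(vc.c2),
            "d2": list(vc.d2),
            "e2": list(vc.e2),
            "cov_a": vc.cov_a,
            "cov_e": vc.cov_e,
            "thresholds": list(vc.thresholds),
        }
        out.update(self.derived)
        return out


def _margin_threshold(p: float) -> float:
    return threshold_from_prevalence(float(np.clip(p, 1e-5, 1 - 1e-5)))


def _start_values(
    tables: dict, model: str, share_thresholds: bool
) -> np.ndarray:
    """Moment-style starting point: per-class margin thresholds and a
    class-weighted within-trait tetrachoric solve for the additive part."""
    ths = []
    for t in tables.values():
        counts = _counts16(t)
        n = counts.sum()
        # pool both pair members for the margin
        pX = (counts.sum(axis=(1, 2, 3))[1] + counts.sum(axis=(0, 1, 3))[1]) / (2 * n)
        pY = (counts.sum(axis=(0, 2, 3))[1] + counts.sum(axis=(0, 1, 2))[1]) / (2 * n)
        ths.extend([_margin_threshold(pX), _margin_threshold(pY)])
    if share_thresholds:
        ths = [np.mean(ths[0::2]), np.mean(ths[1::2])]
    num = den = 0.0
    for cls, t in tables.items():
        counts = _counts16(t)
        w = counts.sum()
        cross = tetrachoric_mle(counts.sum(axis=(1, 3))).r
        num += w * cls.coeff_a * cross
        den += w * cls.coeff_a**2
    a2_0 = float(np.clip(num / den if den > 0 else 0.3, 0.05, 0.9))
    e2_0 = 1.0 - a2_0
    u = np.log(a2_0 / e2_0)
    extra = _model_components(model)
    if extra:
        # split the familial part between A and the middle component
        uh = np.log((a2_0 / 2) / e2_0)
        rest = [uh, uh, uh - 0.5, uh - 0.5, 0.1, 0.1, 0.1]
    else:
        rest = [u, u, 0.1, 0.1]
    return np.array(ths + rest)


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def _delta_ci(
    f_derived, theta: np.ndarray, cov: np.ndarray, h: float = 1e-5
) -> dict:
    """95% delta-method CIs for every key of ``f_derived(theta)``."""
    base = f_derived(theta)
    keys = list(base)
    J = np.empty((len(keys), len(theta)))
    for j in range(len(theta)):
        e = np.zeros(len(theta)); e[j] = h
        up = f_derived(theta + e)
        dn = f_derived(theta - e)
        for i, k in enumerate(keys):
            J[i, j] = (up[k] - dn[k]) / (2 * h)
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    se = np.sqrt(np.maximum(var, 0.0))
    out = {}
    for i, k in enumerate(keys):
        out[k] = base[k]
        out[k + "_ci"] = (
            base[k] - 1.959964 * se[i], base[k] + 1.959964 * se[i]
        )
        out[k + "_se"] = se[i]
    return out


def _bivariate_derived(
    theta: np.ndarray, model: str, n_classes: int, share_thresholds: bool
) -> dict:
    vc, _ = _unpack_bivariate(theta, model, n_classes, share_thresholds)
    return {
        "h2_x": vc.a2[0],
        "h2_y": vc.a2[1],
        "cov_a": vc.cov_a,
        "rg": vc.rg,
        "re": vc.re,
        "coheritability_a": vc.coheritability_a,
        "coheritability_e": vc.coheritability_e,
    }


def fit_bivariate(
    tables: dict,
    model: str = "AE",
    seed: int = 0,
    n_restarts: int = 3,
    compute_ci: bool = True,
    share_thresholds: bool = False,
) -> BivariateFit:
    """Fit a bivariate ACE/ADE/AE liability model to 16-cell pair tables.

    ``tables`` maps :class:`RelatednessClass` to 2x2x2x2 counts indexed
    ``[x1, y1, x2, y2]`` (1 = affected).  At least two classes with
    different sharing coefficients are required for identification.
    Thresholds are estimated per relative class by default because the
    disorder margins genuinely differ between, say, full-sister and
    half-sister families; set ``share_thresholds`` to constrain them equal.
    """
    _model_components(model)
    if len(tables) < 2:
        raise ValueError(
            "bivariate components are not identified from a single "
            "relative class; supply at least two"
        )
    coeffs = {(c.coeff_a, c.coeff_d, c.coeff_c) for c in tables}
    if len(coeffs) < 2:
        raise ValueError("relative classes must differ in sharing coefficients")

    nc = len(tables)
    x0 = _start_values(tables, model, share_thresholds)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_restarts)):
        start = x0 if k == 0 else x0 + rng.normal(scale=0.3, size=x0.shape)
        res = minimize(
            _bivariate_negll, start, args=(tables, model, share_thresholds),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    theta = best.x
    loglik = -float(best.fun)
    k_params = len(theta)
    n_pairs = float(sum(_counts16(t).sum() for t in tables.values()))
    vc, _ = _unpack_bivariate(theta, model, nc, share_thresholds)
    fit = BivariateFit(
        model=model,
        components=vc,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k_params,
        n_params=k_params,
        n_pairs=n_pairs,
        converged=bool(best.success),
        classes=tuple(c.label for c in tables),
    )
    if compute_ci:
        H = _num_hessian(
            lambda th: _bivariate_negll(th, tables, model, share_thresholds),
            theta,
        )
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        fit.param_cov = cov
        fit.derived = _delta_ci(
            lambda th: _bivariate_derived(th, model, nc, share_thresholds),
            theta,
            cov,
        )
    else:
        fit.derived = _bivariate_derived(theta, model, nc, share_thresholds)
    return fit


def _univariate_negll(
    theta: np.ndarray, tables: dict, model: str, share_thresholds: bool
) -> float:
    extra = _model_components(model)
    nt = 1 if share_thresholds else len(tables)
    ts = theta[:nt]
    if share_thresholds:
        ts = np.repeat(ts, len(tables))
    rest = theta[nt:]
    if extra:
        den = 1.0 + np.exp(rest[0]) + np.exp(rest[1])
        a2, m2 = np.exp(rest[0]) / den, np.exp(rest[1]) / den
    else:
        den = 1.0 + np.exp(rest[0])
        a2, m2 = np.exp(rest[0]) / den, 0.0
    total = 0.0
    for k, (cls, table) in enumerate(tables.items()):
        counts = _as_2x2(table)
        km = cls.coeff_d if extra == "D" else cls.coeff_c
        r = cls.coeff_a * a2 + (km * m2 if extra else 0.0)
        t = ts[k]
        p = np.clip(_bvn_cells(t, t, min(r, 0.9999)), 1e-300, 1.0)
        sym = 0.5 * (p + p.T)
        total -= float((counts * np.log(sym)).sum())
    return total


def fit_univariate(
    tables: dict,
    model: str = "AE",
    compute_ci: bool = True,
    share_thresholds: bool = False,
) -> BivariateFit:
    """Joint univariate liability fit to one trait's 2x2 pair tables across
    relative classes.  Each class gets its own threshold by default (the
    trait's prevalence may differ between family types); within a class the
    two pair members share one threshold."""
    extra = _model_components(model)
    if len(tables) < 2 and extra:
        raise ValueError(f"{model} is not identified from a single class")
    ths = []
    for t in tables.values():
        c = _as_2x2(t)
        n = c.sum()
        ths.append(_margin_threshold((c[1].sum() + c[:, 1].sum()) / (2 * n)))
    if share_thresholds:
        ths = [float(np.mean(ths))]
    nt = len(ths)
    x0 = np.array(ths + [0.5] + ([-1.5] if extra else []))
    res = minimize(
        _univariate_negll, x0, args=(tables, model, share_thresholds),
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    theta = res.x

    def derived(th: np.ndarray) -> dict:
        rest = th[nt:]
        if extra:
            den = 1.0 + np.exp(rest[0]) + np.exp(rest[1])
            a2, m2 = np.exp(rest[0]) / den, np.exp(rest[1]) / den
        else:
            den = 1.0 + np.exp(rest[0])
            a2, m2 = np.exp(rest[0]) / den, 0.0
        out = {"h2": a2, "e2": 1.0 - a2 - m2}
        if extra == "C":
            out["c2"] = m2
        elif extra == "D":
            out["d2"] = m2
        return out

    d = derived(theta)
    a2 = d["h2"]
    m2 = d.get("c2", d.get("d2", 0.0))
    zeros = np.zeros(2)
    vc = VarianceComponents(
        a2=np.full(2, a2),
        d2=np.full(2, m2) if extra == "D" else zeros,
        c2=np.full(2, m2) if extra == "C" else zeros,
        e2=np.full(2, 1.0 - a2 - m2),
        thresholds=np.full(2, theta[0]),
    )
    loglik = -float(res.fun)
    fit = BivariateFit(
        model=model,
        components=vc,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * len(theta),
        n_params=len(theta),
        n_pairs=float(sum(_as_2x2(t).sum() for t in tables.values())),
        converged=bool(res.success),
        classes=tuple(c.label for c in tables),
    )
    if compute_ci:
        H = _num_hessian(
            lambda th: _univariate_negll(th, tables, model, share_thresholds),
            theta,
        )
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        fit.param_cov = cov
        fit.derived = _delta_ci(derived, theta, cov)
    else:
        fit.derived = d
    return fit


def select_model(fits: list[BivariateFit]) -> BivariateFit:
    """Lowest-AIC fit; ties broken toward the model with fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (round(f.aic, 9), f.n_params))


# ---------------------------------------------------------------------------
# AE solution from published tetrachoric correlations


@dataclass
class ClassCorrelations:
    """Printed tetrachoric correlations for one relative class."""

    cls: RelatednessClass
    r_x: float  # within-trait cross-sibling, trait X
    r_y: float  # within-trait cross-sibling, trait Y
    r_pheno: float  # cross-trait within-individual
    r_cross: float  # cross-trait cross-sibling
    n_pairs: float  # weight


@dataclass
class AESolution:
    a2: np.ndarray
    e2: np.ndarray
    cov_a: float
    cov_e: float
    cov_p: float
    rg: float
    re: float
    coheritability_a: float
    coheritability_e: float
    clipped: bool = False

    def as_components(self) -> VarianceComponents:
        return VarianceComponents(
            a2=self.a2, d2=np.zeros(2), c2=np.zeros(2), e2=self.e2,
            cov_a=self.cov_a, cov_e=self.cov_e,
        )


def solve_ae_from_correlations(
    correlations: list[ClassCorrelations],
) -> AESolution:
    """Pair-count-weighted least squares for the bivariate AE system.

    Under AE, the within-trait cross-sibling correlation of class k equals
    ``kappa_A(k) * a2`` and the cross-trait cross-sibling correlation equals
    ``kappa_A(k) * cov_A``; the within-individual cross-trait correlation
    equals ``cov_A + cov_E``.  Each equation is weighted by its class's
    pair count.  Negative implied components are clipped to zero and
    flagged.
    """
    if len(correlations) < 2:
        raise ValueError("at least two relative classes are required")
    w = np.array([c.n_pairs for c in correlations], dtype=float)
    ka = np.array([c.cls.coeff_a for c in correlations])

    def wls_slope(y: np.ndarray) -> float:
        return float((w * ka * y).sum() / (w * ka * ka).sum())

    a2x = wls_slope(np.array([c.r_x for c in correlations]))
    a2y = wls_slope(np.array([c.r_y for c in correlations]))
    cov_a = wls_slope(np.array([c.r_cross for c in correlations]))
    cov_p = float(
        (w * np.array([c.r_pheno for c in correlations])).sum() / w.sum()
    )
    clipped = False
    if a2x < 0 or a2y < 0 or a2x > 1 or a2y > 1:
        clipped = True
        a2x, a2y = float(np.clip(a2x, 0, 1)), float(np.clip(a2y, 0, 1))
    cov_e = cov_p - cov_a
    a2 = np.array([a2x, a2y])
    e2 = 1.0 - a2
    denom_a = np.sqrt(a2x * a2y)
    denom_e = np.sqrt(e2[0] * e2[1])
    return AESolution(
        a2=a2,
        e2=e2,
        cov_a=cov_a,
        cov_e=cov_e,
        cov_p=cov_p,
        rg=cov_a / denom_a if denom_a > 0 else np.nan,
        re=cov_e / denom_e if denom_e > 0 else np.nan,
        coheritability_a=cov_a / cov_p if cov_p != 0 else np.nan,
        coheritability_e=cov_e / cov_p if cov_p != 0 else np.nan,
        clipped=clipped,
    )
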