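"""Familial coaggregation: odds ratios of one disorder in relatives of
probands with another disorder, with covariate adjustment and
cluster-robust (sandwich) standard errors.

Pairs enter double-entered (both orientations), so each individual serves
once as index and once as relative; the induced dependence, together with
familial clustering, is absorbed by clustering the sandwich variance on
the family id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohortio import PedigreeTable, RelativePairSet

__all__ = ["LogisticFit", "fit_logistic", "coaggregation_or", "forest_table"]

_Z = 1.959963984540054


@dataclass
class LogisticFit:
    """Logistic regression result for one exposure coefficient of interest."""

    params: pd.Series  # log-odds scale
    se_robust: pd.Series
    se_model: pd.Series
    cov_robust: np.ndarray
    exposure: str
    n_obs: int
    n_clusters: int
    separation: bool = False
    converged: bool = True

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.params[self.exposure]))

    @property
    def or_ci(self) -> tuple[float, float]:
        b = self.params[self.exposure]
        s = self.se_robust[self.exposure]
        return float(np.exp(b - _Z * s)), float(np.exp(b + _Z * s))

    @property
    def p_value(self) -> float:
        from scipy.stats import norm

        z = self.params[self.exposure] / self.se_robust[self.exposure]
        return float(2.0 * norm.sf(abs(z)))


def fit_logistic(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    clusters=None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on a
    binary exposure plus covariates, with the sandwich variance clustered
    on ``clusters`` (singleton clusters give the heteroskedasticity-robust
    estimator).

    Separation is flagged when any fitted probability converges to within
    1e-8 of 0 or 1; the point estimate is then unreliable.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0} or set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("outcome and exposure must be binary 0/1")
    if x.sum() == 0 or x.sum() == len(x):
        raise ValueError("empty exposure stratum")
    X = pd.DataFrame({"const": 1.0, "exposure": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            X[str(c)] = cov[c].to_numpy(dtype=float)
    if clusters is None:
        clusters = np.arange(len(y))
    clusters = pd.Series(clusters).reset_index(drop=True)
    if len(clusters) != len(y):
        raise ValueError("clusters must cover all rows")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(over="ignore"):
        res = model.fit(maxiter=100, tol=1e-10)
        robust = model.fit(
            maxiter=100,
            tol=1e-10,
            cov_type="cluster",
            cov_kwds={"groups": np.asarray(clusters)},
        )
    fitted = np.asarray(res.fittedvalues)
    separation = bool(np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8))
    se_rob = pd.Series(np.asarray(robust.bse), index=X.columns)
    return LogisticFit(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        se_robust=se_rob,
        se_model=pd.Series(np.asarray(res.bse), index=X.columns),
        cov_robust=np.asarray(robust.cov_params()),
        exposure="exposure",
        n_obs=len(y),
        n_clusters=int(clusters.nunique()),
        separation=separation,
        converged=bool(res.converged),
    )


def coaggregation_or(
    ped: PedigreeTable,
    pairs: RelativePairSet,
    index_trait: str = "ADHD",
    relative_trait: str = "anyED",
    adjust_relative_index_trait: bool = False,
) -> LogisticFit:
    """OR of the relative's disorder given the index person's disorder.

    Pairs are double-entered; the regression of the relative's diagnosis on
    the index person's diagnosis adjusts for both members' birth years
    (centered, continuous) and sexes, clustering the sandwich variance on
    the family.  ``adjust_relative_index_trait`` adds the relative's own
    index-trait status (the sensitivity adjustment for the relative's own
    disorder).
    """
    d = pairs.double_entered()
    meta = ped.df.set_index("iid")
    exp = meta.loc[d["index_iid"], f"dx_{index_trait}"].to_numpy(float)
    out = meta.loc[d["rel_iid"], f"dx_{relative_trait}"].to_numpy(float)
    by_i = meta.loc[d["index_iid"], "birth_year"].to_numpy(float)
    by_r = meta.loc[d["rel_iid"], "birth_year"].to_numpy(float)
    covs = pd.DataFrame(
        {
            "by_index": by_i - by_i.mean(),
            "by_rel": by_r - by_r.mean(),
            "sex_index": (
                meta.loc[d["index_iid"], "sex"].to_numpy() == "F"
            ).astype(float),
            "sex_rel": (
                meta.loc[d["rel_iid"], "sex"].to_numpy() == "F"
            ).astype(float),
        }
    )
    # drop constant covariates (e.g. sex in all-female designs)
    covs = covs.loc[:, covs.nunique() > 1]
    if adjust_relative_index_trait:
        covs["rel_index_trait"] = meta.loc[
            d["rel_iid"], f"dx_{index_trait}"
        ].to_numpy(float)
    ok = ~(np.isnan(exp) | np.isnan(out) | covs.isna().any(axis=1).to_numpy())
    fit = fit_logistic(
        out[ok], exp[ok], covs[ok], clusters=d.loc[ok, "fid"]
    )
    return fit


def forest_table(fits: dict) -> pd.DataFrame:
    """Ordered OR summary over (relative class, disorder definition).

    ``fits`` maps (class label, disorder) to a LogisticFit; rows keep the
    insertion order of the classes (closest relatives first).
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for (cls_label, disorder), fit in fits.items():
        lo, hi = fit.or_ci
        rows.append(
            {
                "relative_class": cls_label,
                "disorder": disorder,
                "odds_ratio": fit.odds_ratio,
                "ci_low": lo,
                "ci_high": hi,
                "p": fit.p_value,
                "n_obs": fit.n_obs,
                "n_clusters": fit.n_clusters,
                "separation": fit.separation,
            }
        )
    return pd.DataFrame(rows)
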