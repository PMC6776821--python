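"""Polygenic risk scores: QC filtering of GWAS summary statistics, greedy
LD clumping against a reference panel, allele-aware scoring at p-value
thresholds, and association with symptom scales under clustered sampling.

Scores follow the standard clumping + thresholding recipe: after filtering
on minor allele frequency and imputation INFO, the most significant
variant in each LD neighbourhood (squared dosage correlation above
``r2_max`` within ``window_kb``) is kept as index variant; the score is
the effect-size-weighted effect-allele dosage sum over index variants
passing the p-value threshold, standardized in the target sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GenotypeMatrix",
    "PRSResult",
    "GEEResult",
    "qc_filter",
    "ld_clump",
    "score",
    "gee_linear",
    "cronbach_alpha",
    "genotype_pcs",
    "P_THRESHOLDS",
]

# thresholds used for the primary (p < 1) and sensitivity analyses
P_THRESHOLDS = (1e-5, 1e-3, 0.01, 0.05, 0.10, 0.50, 1.00)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeMatrix:
    """Diallelic dosage panel: variants (snp, chr, pos, a1=effect/ALT,
    a2=other/REF) and an (n_samples, n_variants) ALT-dosage matrix."""

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        need = {"snp", "chr", "pos", "a1", "a2"}
        missing = need - set(self.variants.columns)
        if missing:
            raise ValueError(f"variants missing columns {sorted(missing)}")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape mismatch")

    def __len__(self) -> int:
        return len(self.sample_ids)


def qc_filter(
    ss: pd.DataFrame,
    maf_min: float = 0.05,
    info_min: float = 0.80,
    drop_ambiguous: bool = True,
) -> pd.DataFrame:
    """Variant QC on summary statistics: keep variants with minor-allele
    frequency >= ``maf_min`` (inclusive) and INFO >= ``info_min``
    (inclusive).  Strand-ambiguous A/T and C/G variants are dropped by
    default because their orientation cannot be resolved from alleles.
    """
    need = {"freq", "p", "beta", "a1", "a2"}
    missing = need - set(ss.columns)
    if missing:
        raise ValueError(f"sumstats missing columns {sorted(missing)}")
    out = ss.copy()
    maf = np.minimum(out["freq"], 1.0 - out["freq"])
    keep = maf >= maf_min
    if "info" in out.columns:
        keep &= out["info"] >= info_min
    else:
        import warnings

        warnings.warn("no INFO column; INFO filter skipped", stacklevel=2)
    if drop_ambiguous:
        amb = np.fromiter(
            ((a1, a2) in _AMBIGUOUS for a1, a2 in zip(out["a1"], out["a2"])),
            dtype=bool,
            count=len(out),
        )
        keep &= ~amb
    return out[keep].reset_index(drop=True)


def ld_clump(
    ss: pd.DataFrame,
    reference: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> pd.DataFrame:
    """Greedy LD clumping: repeatedly take the smallest-p unclumped variant
    as index and remove every variant within ``window_kb`` of it whose
    squared dosage correlation in the reference exceeds ``r2_max``.
    Variants absent from the reference are dropped.
    """
    ref_idx = {s: j for j, s in enumerate(reference.variants["snp"])}
    present = ss["snp"].isin(ref_idx).to_numpy()
    ss = ss[present].reset_index(drop=True)
    if not len(ss):
        return ss
    X = reference.dosages
    cols = np.array([ref_idx[s] for s in ss["snp"]])
    pos = ss["pos"].to_numpy(dtype=float)
    chrom = ss["chr"].astype(str).to_numpy()
    order = np.argsort(ss["p"].to_numpy(), kind="stable")
    window = window_kb * 1000.0

    removed = np.zeros(len(ss), dtype=bool)
    is_index = np.zeros(len(ss), dtype=bool)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    for i in order:
        if removed[i] or is_index[i]:
            continue
        is_index[i] = True
        near = (
            (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
            & ~removed
            & ~is_index
        )
        cand = np.nonzero(near)[0]
        if len(cand) == 0:
            continue
        xi = Xc[:, cols[i]]
        denom = sd[cols[cand]] * sd[cols[i]] * len(xi)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc[:, cols[cand]].T @ xi) / denom
        r2 = np.where(np.isfinite(r), r * r, 0.0)
        removed[cand[r2 > r2_max]] = True
    return ss[is_index].reset_index(drop=True)


@dataclass
class PRSResult:
    """Per-individual polygenic scores at one p-value threshold."""

    raw: np.ndarray
    standardized: np.ndarray
    n_variants: int
    p_threshold: float
    n_flipped: int = 0
    n_dropped: int = 0


def _align(ss: pd.DataFrame, target: GenotypeMatrix):
    """Match sumstats rows to target columns, allowing allele swaps and
    strand flips; returns (ss row idx, target col idx, sign) where sign -1
    means the target ALT is the sumstats other allele (dosage reversed)."""
    tvar = target.variants
    t_idx = {s: j for j, s in enumerate(tvar["snp"])}
    rows, cols, signs = [], [], []
    dropped = 0
    for i, (snp, a1, a2) in enumerate(zip(ss["snp"], ss["a1"], ss["a2"])):
        j = t_idx.get(snp)
        if j is None:
            dropped += 1
            continue
        b1, b2 = tvar["a1"].iat[j], tvar["a2"].iat[j]
        c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
        if (a1, a2) == (b1, b2) or (c1, c2) == (b1, b2):
            sign = 1
        elif (a1, a2) == (b2, b1) or (c1, c2) == (b2, b1):
            sign = -1
        else:
            dropped += 1
            continue
        rows.append(i)
        cols.append(j)
        signs.append(sign)
    return (
        np.asarray(rows, int),
        np.asarray(cols, int),
        np.asarray(signs, int),
        dropped,
    )


def score(
    ss: pd.DataFrame,
    target: GenotypeMatrix,
    p_threshold: float = 1.00,
) -> PRSResult:
    """Effect-size-weighted effect-allele dosage sum over variants with
    p below the (strict) threshold.

    Alleles are reconciled by identity or strand complement; swapped
    labelling reverses the dosage (2 - d); irreconcilable variants are
    dropped.  Missing dosages are imputed to twice the effect-allele
    frequency.  The standardized copy has zero mean and unit variance in
    the target sample.
    """
    keep = ss["p"].to_numpy() < p_threshold
    sub = ss[keep].reset_index(drop=True)
    rows, cols, signs, dropped = _align(sub, target)
    n = len(target.sample_ids)
    if len(rows) == 0:
        raise ValueError("no variants pass the threshold after alignment")
    beta = sub["beta"].to_numpy()[rows]
    D = target.dosages[:, cols].astype(float).copy()
    freq = sub["freq"].to_numpy()[rows]
    if np.isnan(D).any():
        eaf = np.where(signs > 0, freq, 1.0 - freq)
        fill = np.broadcast_to(2.0 * eaf, D.shape)
        D = np.where(np.isnan(D), fill, D)
    D = np.where(signs[None, :] > 0, D, 2.0 - D)
    raw = D @ beta
    sd = raw.std()
    standardized = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    return PRSResult(
        raw=raw,
        standardized=standardized,
        n_variants=len(rows),
        p_threshold=p_threshold,
        n_flipped=int((signs < 0).sum()),
        n_dropped=dropped,
    )


@dataclass
class GEEResult:
    beta: float
    se: float
    p: float
    ci: tuple[float, float]
    delta_r2: float
    n_obs: int
    n_clusters: int


def gee_linear(
    outcome,
    prs,
    covariates: pd.DataFrame | None = None,
    clusters=None,
) -> GEEResult:
    """Linear association of a symptom score with a standardized PRS under
    an independence working correlation: point estimates equal OLS and the
    standard errors are cluster-robust (twin pairs as clusters).  The
    variance explained is the difference in OLS R^2 between the model with
    and without the PRS; ``beta`` is in outcome units per SD of PRS.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(prs, dtype=float)
    X = pd.DataFrame({"const": 1.0, "prs": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            X[str(c)] = cov[c].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"covariate matrix is rank deficient ({rank} < {X.shape[1]})"
        )
    if clusters is None:
        clusters = np.arange(len(y))
    clusters = pd.Series(clusters).reset_index(drop=True)
    full = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": clusters})
    nested = sm.OLS(y, X.drop(columns="prs")).fit()
    from scipy.stats import norm

    b = float(full.params["prs"])
    se = float(full.bse["prs"])
    z = b / se
    return GEEResult(
        beta=b,
        se=se,
        p=float(2.0 * norm.sf(abs(z))),
        ci=(b - 1.959964 * se, b + 1.959964 * se),
        delta_r2=float(full.rsquared - nested.rsquared),
        n_obs=int(full.nobs),
        n_clusters=int(clusters.nunique()),
    )


def cronbach_alpha(items: pd.DataFrame, standardized: bool = True) -> float:
    """Internal consistency of a set of items.

    The standardized variant uses the mean inter-item correlation r:
    alpha = k r / (1 + (k - 1) r); the raw variant uses variances.
    Zero-variance items are excluded (with a warning) in the standardized
    variant because their correlations are undefined.
    """
    X = pd.DataFrame(items).dropna()
    if X.shape[1] < 2:
        raise ValueError("at least two items are required")
    variances = X.var(axis=0, ddof=1)
    if standardized:
        keep = variances > 0
        if not keep.all():
            import warnings

            warnings.warn(
                f"excluding {int((~keep).sum())} zero-variance item(s)",
                stacklevel=2,
            )
            X = X.loc[:, keep]
        k = X.shape[1]
        C = np.corrcoef(X.to_numpy(), rowvar=False)
        r_bar = (C.sum() - k) / (k * (k - 1))
        return float(k * r_bar / (1.0 + (k - 1) * r_bar))
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    return float(k / (k - 1) * (1.0 - variances.sum() / total_var))


def genotype_pcs(geno: GenotypeMatrix, n_components: int = 5) -> np.ndarray:
    """Top principal components of the centred, scaled dosage matrix.

    A convenience for simulated panels (ancestry covariates are consumed,
    not validated, by the association stage).
    """
    X = geno.dosages.astype(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    X = X / np.where(sd > 0, sd, 1.0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_components] * S[:n_components]
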