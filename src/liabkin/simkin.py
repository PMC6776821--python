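"""Synthetic cohorts with known genetic architecture.

Generates register-like pedigrees (sister, half-sibling and cousin pair
structures), latent liabilities drawn family-block-wise from the joint
normal implied by A/D/C/E variance components and relatedness coefficients,
thresholded binary diagnoses, a diallelic genotype panel with block LD
(discovery GWAS + independent target cohort), and item-level ordinal
symptom scales.  Every stochastic operation takes an explicit seed;
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtri
from scipy.stats import norm

from .cohortio import PedigreeTable
from .mvnorm import bvn_upper
from .relatedness import RelatednessClass

__all__ = [
    "ArchitectureSpec",
    "GenoPanelSpec",
    "ScaleSpec",
    "ATAC_SCALE",
    "EDI2_SCALE",
    "simulate_pedigree",
    "simulate_liabilities",
    "threshold_diagnose",
    "simulate_cohort",
    "simulate_genotypes_and_sumstats",
    "simulate_symptom_scales",
    "scale_score",
]

DEFAULT_SEED = 20191015


# ---------------------------------------------------------------------------
# architecture


@dataclass
class ArchitectureSpec:
    """Liability variance decomposition for one or two binary traits.

    Fractions are of unit liability variance and must sum to one per
    trait; ``r_*`` are cross-trait correlations of the corresponding
    component and are ignored for single-trait specs.
    """

    traits: tuple[str, ...]
    prevalence: np.ndarray
    a2: np.ndarray
    d2: np.ndarray = None
    c2: np.ndarray = None
    e2: np.ndarray = None
    r_a: float = 0.0
    r_d: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        t = len(self.traits)
        self.prevalence = np.atleast_1d(np.asarray(self.prevalence, float))
        self.a2 = np.atleast_1d(np.asarray(self.a2, float))
        for name in ("d2", "c2"):
            v = getattr(self, name)
            setattr(
                self,
                name,
                np.zeros(t) if v is None else np.atleast_1d(np.asarray(v, float)),
            )
        if self.e2 is None:
            self.e2 = 1.0 - self.a2 - self.d2 - self.c2
        self.e2 = np.atleast_1d(np.asarray(self.e2, float))
        for name in ("prevalence", "a2", "d2", "c2", "e2"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} must have one entry per trait")
        total = self.a2 + self.d2 + self.c2 + self.e2
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError(f"variance fractions must sum to 1, got {total}")
        if np.any(np.concatenate([self.a2, self.d2, self.c2, self.e2]) < 0):
            raise ValueError("variance fractions must be non-negative")
        if np.any((self.prevalence <= 0) | (self.prevalence >= 1)):
            raise ValueError("prevalences must lie in (0, 1)")
        for r in (self.r_a, self.r_d, self.r_c, self.r_e):
            if abs(r) > 1:
                raise ValueError("component correlations must be in [-1, 1]")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def component_matrix(self, comp: str) -> np.ndarray:
        """Per-component trait covariance matrix (T x T)."""
        v = {"A": self.a2, "D": self.d2, "C": self.c2, "E": self.e2}[comp]
        r = {"A": self.r_a, "D": self.r_d, "C": self.r_c, "E": self.r_e}[comp]
        if self.n_traits == 1:
            return np.array([[v[0]]])
        off = r * np.sqrt(v[0] * v[1])
        return np.array([[v[0], off], [off, v[1]]])

    @property
    def thresholds(self) -> np.ndarray:
        return ndtri(1.0 - self.prevalence)

    def validate_for_class(self, cls: RelatednessClass) -> None:
        """Check the implied pair-liability matrix is PSD for a class."""
        T = self.n_traits
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        cov = np.zeros((2 * T, 2 * T))
        for comp, k in (
            ("A", cls.coeff_a), ("D", cls.coeff_d), ("C", cls.coeff_c),
        ):
            K_pair = np.array([[1.0, k], [k, 1.0]])
            cov += np.kron(K_pair, self.component_matrix(comp))
        cov += np.kron(K, self.component_matrix("E"))
        if np.linalg.eigvalsh(cov)[0] < -1e-9:
            raise ValueError(
                f"implied pair matrix not PSD for class {cls.label}"
            )


# ---------------------------------------------------------------------------
# pedigree structures

# each builder returns rows (iid suffix, sex or None for random, generation,
# mother suffix, father suffix, study flag)
_STRUCTURES = {
    # two children sharing both parents
    "full_sibling_pair": {
        "parents": [("m", "F"), ("f", "M")],
        "children": [(None, "m", "f"), (None, "m", "f")],
    },
    "full_sisters": {
        "parents": [("m", "F"), ("f", "M")],
        "children": [("F", "m", "f"), ("F", "m", "f")],
    },
    "full_sisters_trio": {
        "parents": [("m", "F"), ("f", "M")],
        "children": [("F", "m", "f")] * 3,
    },
    "maternal_half_pair": {
        "parents": [("m", "F"), ("f1", "M"), ("f2", "M")],
        "children": [(None, "m", "f1"), (None, "m", "f2")],
    },
    "maternal_half_sisters": {
        "parents": [("m", "F"), ("f1", "M"), ("f2", "M")],
        "children": [("F", "m", "f1"), ("F", "m", "f2")],
    },
    "paternal_half_pair": {
        "parents": [("f", "M"), ("m1", "F"), ("m2", "F")],
        "children": [(None, "m1", "f"), (None, "m2", "f")],
    },
    # two sisters (daughters of shared grandparents) each with one child
    "cousin_pair": {
        "grandparents": [("gm", "F"), ("gf", "M")],
        "parents": [
            ("p1", "F", "gm", "gf"),
            ("p2", "F", "gm", "gf"),
            ("s1", "M"),
            ("s2", "M"),
        ],
        "children": [(None, "p1", "s1"), (None, "p2", "s2")],
    },
    "twin_sisters": {
        "parents": [("m", "F"), ("f", "M")],
        "children": [("F", "m", "f"), ("F", "m", "f")],
        "twins": True,
    },
}


def simulate_pedigree(
    n_families: int,
    pattern="full_sisters",
    seed: int = DEFAULT_SEED,
    birth_year_range: tuple[int, int] = (1970, 2005),
) -> PedigreeTable:
    """Generate a pedigree of independent families.

    ``pattern`` is a structure name or a dict mapping structure names to
    sampling probabilities.  Children's sexes are Bernoulli(1/2) unless the
    structure forces them; birth years are uniform over
    ``birth_year_range`` (twin structures share one birth year).  The
    ``study`` column flags the offspring generation carrying phenotypes.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if isinstance(pattern, str):
        pattern = {pattern: 1.0}
    names = list(pattern)
    unknown = [n for n in names if n not in _STRUCTURES]
    if unknown:
        raise ValueError(f"unknown family structures {unknown}")
    probs = np.array([pattern[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(names), size=n_families, p=probs)
    y_lo, y_hi = birth_year_range

    frames = []
    for s_idx, name in enumerate(names):
        fams = np.nonzero(draws == s_idx)[0]
        if len(fams) == 0:
            continue
        st = _STRUCTURES[name]
        fids = [f"f{i}" for i in fams]
        nf = len(fams)
        is_twin = st.get("twins", False)
        twin_year = rng.integers(y_lo, y_hi + 1, size=nf)
        for suffix, sex in st.get("grandparents", []):
            frames.append(
                pd.DataFrame(
                    {
                        "iid": [f"{f}_{suffix}" for f in fids],
                        "fid": fids,
                        "mid": None,
                        "pid": None,
                        "sex": sex,
                        "birth_year": y_lo - 55,
                        "study": False,
                    }
                )
            )
        for entry in st["parents"]:
            suffix, sex = entry[0], entry[1]
            gm, gf = (entry[2], entry[3]) if len(entry) == 4 else (None, None)
            frames.append(
                pd.DataFrame(
                    {
                        "iid": [f"{f}_{suffix}" for f in fids],
                        "fid": fids,
                        "mid": [f"{f}_{gm}" for f in fids] if gm else None,
                        "pid": [f"{f}_{gf}" for f in fids] if gf else None,
                        "sex": sex,
                        "birth_year": y_lo - 28,
                        "study": False,
                    }
                )
            )
        for k, (sex, msfx, fsfx) in enumerate(st["children"]):
            sexes = (
                np.full(nf, sex)
                if sex
                else np.where(rng.random(nf) < 0.5, "F", "M")
            )
            years = (
                twin_year if is_twin else rng.integers(y_lo, y_hi + 1, size=nf)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "iid": [f"{f}_c{k}" for f in fids],
                        "fid": fids,
                        "mid": [f"{f}_{msfx}" for f in fids],
                        "pid": [f"{f}_{fsfx}" for f in fids],
                        "sex": sexes,
                        "birth_year": years,
                        "study": True,
                    }
                )
            )
    df = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["fid", "study", "iid"], kind="stable")
        .reset_index(drop=True)
    )
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# liabilities

# component-sharing coefficients by derived pair class; C sharing for
# paternal half-siblings and cousins is not identified by the designs here
# and defaults to zero (configurable via the c_sharing argument)
_DEFAULT_C_SHARING = {
    "full_sibling": 1.0,
    "maternal_half_sibling": 1.0,
    "paternal_half_sibling": 0.0,
    "cousin": 0.0,
}
_A_COEFF = {
    "full_sibling": 0.50,
    "maternal_half_sibling": 0.25,
    "paternal_half_sibling": 0.25,
    "cousin": 0.125,
}
_D_COEFF = {
    "full_sibling": 0.25,
    "maternal_half_sibling": 0.0,
    "paternal_half_sibling": 0.0,
    "cousin": 0.0,
}


def _classify_pairs_vectorised(
    df: pd.DataFrame, two: pd.DataFrame
) -> np.ndarray:
    """Pair class label per two-offspring family, from parent links only."""
    g1 = two.groupby("fid", sort=False).nth(0)
    g2 = two.groupby("fid", sort=False).nth(1)
    m1, p1 = g1["mid"].to_numpy(), g1["pid"].to_numpy()
    m2, p2 = g2["mid"].to_numpy(), g2["pid"].to_numpy()
    links = df.set_index("iid")[["mid", "pid"]]

    def grand(parent_ids, col):
        return links.reindex(pd.Index(parent_ids))[col].to_numpy()

    same_m = pd.notna(m1) & (m1 == m2)
    same_p = pd.notna(p1) & (p1 == p2)
    labels = np.full(len(m1), "unrelated", dtype=object)
    cous = np.zeros(len(m1), dtype=bool)
    for pa in (m1, p1):
        gma, gpa = grand(pa, "mid"), grand(pa, "pid")
        for pb in (m2, p2):
            gmb, gpb = grand(pb, "mid"), grand(pb, "pid")
            cous |= (
                pd.notna(gma) & (gma == gmb) & pd.notna(gpa) & (gpa == gpb)
            )
    labels[cous] = "cousin"
    labels[same_p & ~same_m] = "paternal_half_sibling"
    labels[same_m & ~same_p] = "maternal_half_sibling"
    labels[same_m & same_p] = "full_sibling"
    return labels


def _family_kinships(fam_df: pd.DataFrame, c_sharing: dict) -> tuple:
    """(study iids, K_A, K_D, K_C) for one family from parent links."""
    from .cohortio import classify_pair

    study = fam_df[fam_df["study"]] if "study" in fam_df else fam_df
    iids = list(study["iid"])
    n = len(iids)
    KA, KD, KC = np.eye(n), np.eye(n), np.eye(n)
    idx = fam_df.set_index("iid")
    for i in range(n):
        for j in range(i + 1, n):
            label = classify_pair(idx, iids[i], iids[j])
            if label is None:
                continue
            # same parents and same birth year = twin pair; dizygotic
            # sharing is that of full siblings, which classify gives us
            KA[i, j] = KA[j, i] = _A_COEFF[label]
            KD[i, j] = KD[j, i] = _D_COEFF[label]
            KC[i, j] = KC[j, i] = c_sharing.get(label, 0.0)
    return iids, KA, KD, KC


def simulate_liabilities(
    ped: PedigreeTable,
    spec: ArchitectureSpec,
    seed: int = DEFAULT_SEED,
    c_sharing: dict | None = None,
) -> pd.DataFrame:
    """Draw per-individual latent liabilities for the study generation.

    Families are independent; within a family the liabilities of all study
    members across traits are jointly normal with covariance assembled
    from the architecture's component matrices and the pairwise sharing
    coefficients derived from parent links.  Returns a DataFrame indexed
    by iid with one column per trait.
    """
    sharing = dict(_DEFAULT_C_SHARING)
    if c_sharing:
        sharing.update(c_sharing)
    T = spec.n_traits
    comp = {c: spec.component_matrix(c) for c in "ADCE"}
    df = ped.df

    # group families by kinship signature so each distinct structure is
    # factorised once and sampled in a single batch; two-offspring
    # families (the overwhelming case) are classified vectorised
    groups: dict = {}
    study = df[df["study"]] if "study" in df.columns else df
    sizes = study.groupby("fid", sort=False)["iid"].transform("size")
    two = study[sizes == 2]
    if len(two):
        labels = _classify_pairs_vectorised(df, two)
        first = two.groupby("fid", sort=False).nth(0)
        second = two.groupby("fid", sort=False).nth(1)
        for label in pd.unique(labels):
            sel = labels == label
            iid_lists = np.column_stack(
                [
                    first.loc[sel, "iid"].to_numpy(),
                    second.loc[sel, "iid"].to_numpy(),
                ]
            )
            ka = _A_COEFF.get(label, 0.0)
            kd = _D_COEFF.get(label, 0.0)
            kc = sharing.get(label, 0.0)
            KA = np.array([[1.0, ka], [ka, 1.0]])
            KD = np.array([[1.0, kd], [kd, 1.0]])
            KC = np.array([[1.0, kc], [kc, 1.0]])
            key = (KA.tobytes(), KD.tobytes(), KC.tobytes())
            groups.setdefault(key, (KA, KD, KC, []))[3].extend(
                iid_lists.tolist()
            )
    other_fids = set(study.loc[sizes != 2, "fid"])
    for fid in other_fids:
        fam_df = df[df["fid"] == fid]
        iids, KA, KD, KC = _family_kinships(fam_df, sharing)
        if not iids:
            continue
        key = (KA.tobytes(), KD.tobytes(), KC.tobytes())
        groups.setdefault(key, (KA, KD, KC, []))[3].append(iids)

    rng = np.random.default_rng(seed)
    out_iids: list = []
    out_vals: list = []
    for KA, KD, KC, fam_lists in groups.values():
        n = KA.shape[0]
        cov = (
            np.kron(KA, comp["A"])
            + np.kron(KD, comp["D"])
            + np.kron(KC, comp["C"])
            + np.kron(np.eye(n), comp["E"])
        )
        evals = np.linalg.eigvalsh(cov)
        if evals[0] < -1e-9:
            raise ValueError(
                "implied family liability covariance is not PSD; "
                "check the architecture and sharing coefficients"
            )
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        z = rng.standard_normal((len(fam_lists), n * T)) @ L.T
        out_vals.append(z.reshape(-1, T))
        for iids in fam_lists:
            out_iids.extend(iids)
    values = np.vstack(out_vals) if out_vals else np.empty((0, T))
    liab = pd.DataFrame(values, columns=list(spec.traits), index=out_iids)
    liab.index.name = "iid"
    return liab


def threshold_diagnose(liabilities, prevalence: float) -> np.ndarray:
    """Binary diagnosis: 1 iff liability exceeds the standard-normal
    quantile at (1 - prevalence)."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    t = ndtri(1.0 - prevalence)
    return (np.asarray(liabilities, dtype=float) > t).astype(np.int8)


def simulate_cohort(
    n_families: int,
    spec: ArchitectureSpec,
    pattern="full_sisters",
    seed: int = DEFAULT_SEED,
    birth_year_range: tuple[int, int] = (1970, 2005),
    c_sharing: dict | None = None,
) -> PedigreeTable:
    """Pedigree + thresholded diagnoses in one call.

    Non-study rows (parents, grandparents) get NA diagnoses.
    """
    ped = simulate_pedigree(
        n_families, pattern, seed=seed, birth_year_range=birth_year_range
    )
    liab = simulate_liabilities(ped, spec, seed=seed + 1, c_sharing=c_sharing)
    df = ped.df.set_index("iid")
    for k, trait in enumerate(spec.traits):
        dx = pd.Series(
            threshold_diagnose(liab[trait].to_numpy(), spec.prevalence[k]),
            index=liab.index,
            dtype="float",
        )
        df[f"dx_{trait}"] = dx
        df[f"liab_{trait}"] = liab[trait]
    return PedigreeTable(df.reset_index())


# ---------------------------------------------------------------------------
# genotype panel + discovery GWAS


@dataclass
class GenoPanelSpec:
    """Diallelic panel with block LD and a discovery/target split."""

    n_variants: int = 800
    block_len: int = 10
    block_rho: float = 0.6  # target adjacent-dosage correlation in a block
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_causal: int = 40
    h2_panel: float = 0.3  # discovery-trait variance explained by the panel
    n_discovery: int = 8000
    n_target: int = 3000
    info_range: tuple[float, float] = (0.7, 1.0)
    pos_step: int = 20_000  # bp between adjacent variants
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.n_variants:
            raise ValueError("causal count exceeds panel size")


@dataclass
class SimulatedPanel:
    """Everything the PRS stages consume, with ground truth attached."""

    variants: pd.DataFrame  # snp chr pos a1 a2 freq info
    sumstats: pd.DataFrame  # SumStats columns
    target_dosages: np.ndarray  # (n_target, m) ALT dosages
    target_ids: list
    true_beta: np.ndarray
    true_genetic_value: np.ndarray  # per target individual, standardized scale
    discovery_dosages: np.ndarray = None
    discovery_phenotype: np.ndarray = None


_AMBIGUOUS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONAMBIG = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


def _latent_rho_for_dosage_corr(target: float, f1: float, f2: float) -> float:
    """Latent-Gaussian correlation giving a target Pearson correlation
    between the thresholded Bernoulli haplotype indicators."""
    if target <= 0.0:
        return 0.0
    t1, t2 = ndtri(1.0 - f1), ndtri(1.0 - f2)
    s = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))

    def phi(rho):
        return (float(bvn_upper(t1, t2, rho)) - f1 * f2) / s

    hi = 0.999999
    if phi(hi) <= target:
        return hi
    return brentq(lambda r: phi(r) - target, 0.0, hi, xtol=1e-10)


def _simulate_haplotypes(
    rng, n: int, freqs: np.ndarray, block_len: int, latent_rhos: np.ndarray
) -> np.ndarray:
    """One haplotype per row: thresholded latent Gaussian AR(1) blocks."""
    m = len(freqs)
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    for j in range(1, m):
        if j % block_len == 0:
            z[:, j] = rng.standard_normal(n)
        else:
            a = latent_rhos[j - 1]
            z[:, j] = a * z[:, j - 1] + np.sqrt(1 - a * a) * rng.standard_normal(n)
    return (z < ndtri(freqs)[None, :]).astype(np.int8)


def simulate_genotypes_and_sumstats(
    spec: GenoPanelSpec, seed: int = DEFAULT_SEED
) -> SimulatedPanel:
    """Simulate a target genotype panel plus GWAS summary statistics from
    an independent discovery sample of the same population.

    Dosages are Hardy-Weinberg sums of two haplotypes; within a block,
    haplotype indicators follow a thresholded latent Gaussian AR(1) whose
    step correlations are calibrated so the realised adjacent-dosage
    correlation matches ``spec.block_rho``.  Marginal per-variant OLS on
    the discovery sample yields effect sizes, p-values, allele frequencies
    and simulated imputation INFO scores.
    """
    rng = np.random.default_rng(seed)
    m = spec.n_variants
    # one allele frequency per LD block: tightly linked variants share
    # frequency, which also makes any adjacent-dosage correlation in [0, 1)
    # attainable by the latent-threshold construction
    n_blocks = int(np.ceil(m / spec.block_len))
    block_freq = rng.uniform(*spec.maf_range, size=n_blocks)
    freqs = np.repeat(block_freq, spec.block_len)[:m]
    latent = np.array(
        [
            _latent_rho_for_dosage_corr(spec.block_rho, freqs[j], freqs[j + 1])
            for j in range(m - 1)
        ]
    )

    def draw_dosages(n):
        h1 = _simulate_haplotypes(rng, n, freqs, spec.block_len, latent)
        h2 = _simulate_haplotypes(rng, n, freqs, spec.block_len, latent)
        return (h1 + h2).astype(np.float64)

    X_disc = draw_dosages(spec.n_discovery)
    X_targ = draw_dosages(spec.n_target)

    beta = np.zeros(m)
    if spec.n_causal > 0:
        causal = rng.choice(m, size=spec.n_causal, replace=False)
        beta[causal] = rng.standard_normal(spec.n_causal)

    def genetic_value(X):
        g = (X - 2 * freqs[None, :]) @ beta
        sd = g.std()
        return g / sd if sd > 0 else g

    g_disc = genetic_value(X_disc)
    y = np.sqrt(spec.h2_panel) * g_disc + np.sqrt(
        1 - spec.h2_panel
    ) * rng.standard_normal(spec.n_discovery)

    # marginal per-variant OLS, vectorised
    n = spec.n_discovery
    xc = X_disc - X_disc.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    bhat = (xc * yc[:, None]).sum(axis=0) / np.maximum(sxx, 1e-12)
    resid_ss = (yc * yc).sum() - bhat * bhat * sxx
    se = np.sqrt(np.maximum(resid_ss / (n - 2), 1e-300) / np.maximum(sxx, 1e-12))
    zstat = bhat / se
    pvals = np.clip(2.0 * norm.sf(np.abs(zstat)), 1e-300, 1.0)

    allele_idx = rng.choice(len(_NONAMBIG), size=m)
    alleles = np.array(_NONAMBIG, dtype=object)[allele_idx]
    amb = rng.random(m) < 0.05  # a few strand-ambiguous pairs
    alleles[amb] = np.array(_AMBIGUOUS, dtype=object)[
        rng.choice(len(_AMBIGUOUS), size=int(amb.sum()))
    ]
    info = rng.uniform(*spec.info_range, size=m)
    variants = pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(m)],
            "chr": spec.chrom,
            "pos": 1 + np.arange(m) * spec.pos_step,
            "a1": [a[0] for a in alleles],
            "a2": [a[1] for a in alleles],
            "freq": X_targ.mean(axis=0) / 2.0,
            "info": info,
        }
    )
    sumstats = pd.DataFrame(
        {
            "snp": variants["snp"],
            "chr": variants["chr"],
            "pos": variants["pos"],
            "a1": variants["a1"],
            "a2": variants["a2"],
            "beta": bhat,
            "p": pvals,
            "freq": X_disc.mean(axis=0) / 2.0,
            "info": info,
        }
    )
    return SimulatedPanel(
        variants=variants,
        sumstats=sumstats,
        target_dosages=X_targ,
        target_ids=[f"t{i}" for i in range(spec.n_target)],
        true_beta=beta,
        true_genetic_value=genetic_value(X_targ),
        discovery_dosages=X_disc,
        discovery_phenotype=y,
    )


# ---------------------------------------------------------------------------
# symptom scales


@dataclass
class ScaleSpec:
    """Ordinal symptom scale: item names, legal response values, shared
    response category probabilities and a target internal consistency."""

    name: str
    subscales: dict  # subscale -> list of item names
    values: np.ndarray  # legal responses, ascending
    category_probs: np.ndarray
    target_alpha: float = 0.9

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.category_probs = np.asarray(self.category_probs, dtype=float)
        if len(self.values) != len(self.category_probs):
            raise ValueError("one probability per response category")
        if not np.isclose(self.category_probs.sum(), 1.0):
            raise ValueError("category probabilities must sum to 1")

    @property
    def items(self) -> list[str]:
        return [i for sub in self.subscales.values() for i in sub]

    @property
    def k(self) -> int:
        return len(self.items)

    @property
    def cuts(self) -> np.ndarray:
        """Latent thresholds between response categories."""
        cum = np.cumsum(self.category_probs)[:-1]
        return ndtri(cum)


# parent-rated ADHD inventory: 19 yes/partly/no items, scored 0/0.5/1 and
# summed; responses are heavily skewed toward "no" in the general population
ATAC_SCALE = ScaleSpec(
    name="atac",
    subscales={
        "inattention": [f"atac_ia{i}" for i in range(1, 10)],
        "hyperactivity": [f"atac_hi{i}" for i in range(1, 11)],
    },
    values=np.array([0.0, 0.5, 1.0]),
    category_probs=np.array([0.85, 0.11, 0.04]),
    target_alpha=0.95,
)

# self-rated eating-disorder inventory: 22 six-point items, scored by mean
EDI2_SCALE = ScaleSpec(
    name="edi2",
    subscales={
        "drive_for_thinness": [f"edi_dt{i}" for i in range(1, 8)],
        "bulimia": [f"edi_b{i}" for i in range(1, 8)],
        "body_dissatisfaction": [f"edi_bd{i}" for i in range(1, 9)],
    },
    values=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
    category_probs=np.array([0.42, 0.25, 0.14, 0.09, 0.06, 0.04]),
    target_alpha=0.9,
)


def _ordinal_corr(rho: float, cuts: np.ndarray, values: np.ndarray,
                  probs: np.ndarray) -> float:
    """Pearson correlation between two identically discretized standard
    normals with latent correlation ``rho``."""
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    lo = edges[:-1]
    hi = edges[1:]
    P = (
        bvn_upper(lo[:, None], lo[None, :], rho)
        - bvn_upper(lo[:, None], hi[None, :], rho)
        - bvn_upper(hi[:, None], lo[None, :], rho)
        + bvn_upper(hi[:, None], hi[None, :], rho)
    )
    mean = float((values * probs).sum())
    var = float((values**2 * probs).sum() - mean**2)
    exy = float(values @ P @ values)
    return (exy - mean * mean) / var


def _latent_interitem_rho(scale: ScaleSpec) -> float:
    """Latent inter-item correlation whose discretized items reach the
    scale's target standardized alpha."""
    k = scale.k
    a = scale.target_alpha
    r_bar = a / (k - a * (k - 1))
    cuts, values, probs = scale.cuts, scale.values, scale.category_probs

    def f(rho):
        return _ordinal_corr(rho, cuts, values, probs) - r_bar

    if f(0.999) < 0:
        return 0.999
    return brentq(f, 0.0, 0.999, xtol=1e-8)


def simulate_symptom_scales(
    genetic_value: np.ndarray,
    scale: ScaleSpec,
    effect: float = 0.2,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Item-level ordinal responses driven by a common factor.

    The common factor is ``effect`` times the standardized genetic value
    plus independent noise; each item loads on the factor with the latent
    inter-item correlation calibrated (through the discretization) to the
    scale's target Cronbach's alpha.  Returns one column per item.
    """
    if abs(effect) > 1:
        raise ValueError("effect is a correlation and must be in [-1, 1]")
    g = np.asarray(genetic_value, dtype=float)
    sd = g.std()
    g = (g - g.mean()) / sd if sd > 0 else g * 0.0
    rng = np.random.default_rng(seed)
    n = len(g)
    rho = _latent_interitem_rho(scale)
    factor = effect * g + np.sqrt(1 - effect**2) * rng.standard_normal(n)
    lam = np.sqrt(rho)
    latent = lam * factor[:, None] + np.sqrt(1 - rho) * rng.standard_normal(
        (n, scale.k)
    )
    codes = np.searchsorted(scale.cuts, latent)
    resp = scale.values[codes]
    return pd.DataFrame(resp, columns=scale.items)


def scale_score(items: pd.DataFrame, scale: ScaleSpec,
                subscale: str | None = None) -> pd.Series:
    """Scale scoring: sum for the ADHD inventory, mean for the
    eating-disorder inventory (full scale or one subscale)."""
    cols = scale.items if subscale is None else scale.subscales[subscale]
    missing = [c for c in cols if c not in items.columns]
    if missing:
        raise KeyError(f"missing item columns {missing[:3]}")
    vals = items[cols]
    bad = ~vals.isin(scale.values) & vals.notna()
    if bad.any().any():
        raise ValueError("responses outside the legal response set")
    if scale.name == "atac":
        return vals.sum(axis=1)
    return vals.mean(axis=1)
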