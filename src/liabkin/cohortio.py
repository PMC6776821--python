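"""Cohort data model, TSV/VCF readers and writers, and relative-pair
enumeration.

The pedigree is a flat table with one row per individual (including parent
and grandparent rows), identified by ``iid`` with family ``fid``, parent
links ``mid``/``pid`` (missing encoded as NA), ``sex`` ('F'/'M'),
``birth_year``, binary diagnosis columns prefixed ``dx_`` and any number of
symptom-item or covariate columns.  Relative classes are always derived
from the parent links, never from stored labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .relatedness import RelatednessClass, get_class

__all__ = [
    "PedigreeTable",
    "RelativePairSet",
    "PairCountTable",
    "read_pedigree",
    "write_pedigree",
    "read_sumstats",
    "write_sumstats",
    "enumerate_pairs",
    "tabulate_pairs",
    "prevalence_summary",
    "write_vcf",
    "read_vcf",
]

_REQUIRED = ["iid", "fid", "mid", "pid", "sex", "birth_year"]


@dataclass
class PedigreeTable:
    """Pedigree/phenotype table wrapper with link validation."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"pedigree is missing columns {missing}")
        if self.df["iid"].duplicated().any():
            dup = self.df.loc[self.df["iid"].duplicated(), "iid"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def dx_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("dx_")]

    def validate_links(self) -> None:
        ids = set(self.df["iid"])
        for col in ("mid", "pid"):
            known = self.df[col].dropna()
            stray = set(known) - ids
            if stray:
                raise ValueError(
                    f"{col} refers to unknown individuals, e.g. "
                    f"{sorted(stray)[:3]}"
                )

    def trait(self, name: str) -> pd.Series:
        col = name if name in self.df.columns else f"dx_{name}"
        if col not in self.df.columns:
            raise KeyError(f"trait {name!r} not in pedigree")
        return self.df.set_index("iid")[col]


@dataclass
class RelativePairSet:
    """Unordered relative pairs of one class, derived from parent links."""

    cls: RelatednessClass
    pairs: pd.DataFrame  # columns iid1, iid2, fid

    def __len__(self) -> int:
        return len(self.pairs)

    def double_entered(self) -> pd.DataFrame:
        """Both orientations of every pair (for coaggregation regressions)."""
        fwd = self.pairs.rename(columns={"iid1": "index_iid", "iid2": "rel_iid"})
        rev = self.pairs.rename(columns={"iid2": "index_iid", "iid1": "rel_iid"})
        return pd.concat([fwd, rev], ignore_index=True)


@dataclass
class PairCountTable:
    """Pair contingency counts for one trait (2x2) or two traits (16 cells).

    One-trait cells are indexed ``counts[s1, s2]`` (status of each member);
    two-trait cells ``counts[x1, y1, x2, y2]``.  Counts may be fractional:
    tables reconstructed from published concordant/discordant summaries
    split the discordant count evenly between the two orientations.
    """

    traits: tuple[str, ...]
    counts: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape not in ((2, 2), (2, 2, 2, 2)):
            raise ValueError(f"bad cell shape {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("cell counts must be non-negative")

    @property
    def n_pairs(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_concordant_discordant(
        cls, trait: str, both_affected: float, both_unaffected: float,
        discordant: float,
    ) -> "PairCountTable":
        """Symmetric 2x2 reconstruction from a published summary: the
        orientation split of the discordant pairs is not published, so each
        off-diagonal cell receives half."""
        c = np.array(
            [[both_unaffected, discordant / 2.0],
             [discordant / 2.0, both_affected]]
        )
        return cls(traits=(trait,), counts=c)

    def collapse(self, trait: str) -> "PairCountTable":
        """One-trait 2x2 marginal of a two-trait 16-cell table."""
        if self.counts.shape != (2, 2, 2, 2):
            raise ValueError("collapse requires a two-trait table")
        if trait == self.traits[0]:
            c = self.counts.sum(axis=(1, 3))
        elif trait == self.traits[1]:
            c = self.counts.sum(axis=(0, 2))
        else:
            raise KeyError(f"trait {trait!r} not in {self.traits}")
        return PairCountTable(
            traits=(trait,), counts=c, n_dropped=self.n_dropped
        )

    def concordant_discordant(self) -> tuple[float, float, float]:
        if self.counts.shape != (2, 2):
            raise ValueError("summary requires a one-trait table")
        c = self.counts
        return float(c[1, 1]), float(c[0, 0]), float(c[0, 1] + c[1, 0])


# ---------------------------------------------------------------------------
# TSV / VCF io (TSV dialect: UTF-8, tab-separated, header, NA for missing)


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"iid": str, "fid": str, "mid": str, "pid": str},
    )
    return PedigreeTable(df)


SUMSTATS_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "beta", "p", "freq", "info"]


def write_sumstats(ss: pd.DataFrame, path) -> None:
    missing = [c for c in SUMSTATS_COLUMNS if c not in ss.columns]
    if missing:
        raise ValueError(f"sumstats missing columns {missing}")
    ss[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"snp": str, "chr": str, "a1": str, "a2": str},
    )
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sumstats missing columns {missing}")
    return df


def write_vcf(path, variants: pd.DataFrame, dosages: np.ndarray,
              sample_ids) -> None:
    """Write a diallelic panel as VCF v4.2 with GT and DS fields.

    ``variants`` needs columns snp, chr, pos, a1 (ALT/effect), a2 (REF);
    ``dosages`` is (n_samples, n_variants) ALT-allele dosage in [0, 2].
    """
    n, m = dosages.shape
    if m != len(variants) or n != len(sample_ids):
        raise ValueError("dosage matrix does not match variants/samples")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(variants["chr"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in sample_ids)
            + "\n"
        )
        for j, row in enumerate(variants.itertuples(index=False)):
            ds = dosages[:, j]
            cells = [
                f"{gt_codes[int(round(min(max(d, 0), 2)))]}:{d:.3f}"
                for d in ds
            ]
            fh.write(
                f"{row.chr}\t{row.pos}\t{row.snp}\t{row.a2}\t{row.a1}\t.\t"
                f"PASS\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a diallelic VCF back into (variants, ALT dosages, sample ids).

    Prefers the DS field and falls back to GT allele counts.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is an optional reader
        return _read_vcf_plain(path)
    v = VCF(str(path))
    samples = list(v.samples)
    rows, cols = [], []
    for rec in v:
        rows.append(
            {
                "snp": rec.ID,
                "chr": rec.CHROM,
                "pos": rec.POS,
                "a1": rec.ALT[0],
                "a2": rec.REF,
            }
        )
        ds = rec.format("DS")
        if ds is not None:
            cols.append(np.asarray(ds, dtype=float).ravel())
        else:
            gts = np.asarray(rec.genotypes)[:, :2]
            cols.append(gts.sum(axis=1).astype(float))
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return variants, dosages, samples


def _read_vcf_plain(path):
    rows, cols, samples = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            ds_idx = fmt.index("DS") if "DS" in fmt else None
            gt_idx = fmt.index("GT") if "GT" in fmt else None
            vals = []
            for cell in parts[9:]:
                sub = cell.split(":")
                if ds_idx is not None:
                    vals.append(float(sub[ds_idx]))
                else:
                    gt = sub[gt_idx].replace("|", "/").split("/")
                    vals.append(float(sum(int(a) for a in gt)))
            rows.append({"snp": vid, "chr": chrom, "pos": int(pos),
                         "a1": alt, "a2": ref})
            cols.append(np.array(vals))
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return variants, dosages, samples


# ---------------------------------------------------------------------------
# pair enumeration


def _sibling_pairs(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Unordered within-family sibling pairs of one kind among all rows
    with the needed parent links present (merge-based, vectorised)."""
    sub = df.loc[
        df["mid"].notna() & df["pid"].notna(), ["iid", "fid", "mid", "pid"]
    ]
    if kind == "full":
        on = ["mid", "pid"]
    elif kind == "maternal_half":
        on = ["mid"]
    elif kind == "paternal_half":
        on = ["pid"]
    else:
        raise ValueError(kind)
    m = sub.merge(sub, on=on, suffixes=("1", "2"))
    m = m[m["iid1"] < m["iid2"]]
    if kind == "maternal_half":
        m = m[m["pid1"] != m["pid2"]]
    elif kind == "paternal_half":
        m = m[m["mid1"] != m["mid2"]]
    out = m.rename(columns={"fid1": "fid"})[["iid1", "iid2", "fid"]]
    return out.reset_index(drop=True)


def _cousin_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Pairs whose linking parents are full siblings and who are not
    themselves siblings or half-siblings."""
    parent_sibs = _sibling_pairs(df, "full")
    if not len(parent_sibs):
        return pd.DataFrame(columns=["iid1", "iid2", "fid"])
    # child -> parent edge list (one row per known parent link)
    edges = pd.concat(
        [
            df.loc[df["mid"].notna(), ["iid", "fid", "mid"]].rename(
                columns={"mid": "parent"}
            ),
            df.loc[df["pid"].notna(), ["iid", "fid", "pid"]].rename(
                columns={"pid": "parent"}
            ),
        ],
        ignore_index=True,
    )
    meta = df.set_index("iid")[["mid", "pid"]]
    # both orientations of the parent sibling pair
    psibs = pd.concat(
        [
            parent_sibs.rename(columns={"iid1": "pa", "iid2": "pb"}),
            parent_sibs.rename(columns={"iid2": "pa", "iid1": "pb"}),
        ],
        ignore_index=True,
    )[["pa", "pb"]]
    ca = psibs.merge(edges, left_on="pa", right_on="parent")[
        ["pa", "pb", "iid", "fid"]
    ].rename(columns={"iid": "c1"})
    pairs = ca.merge(
        edges.rename(columns={"iid": "c2"}).drop(columns="fid"),
        left_on="pb",
        right_on="parent",
    )[["c1", "c2", "fid"]]
    pairs = pairs[pairs["c1"] < pairs["c2"]]
    if not len(pairs):
        return pd.DataFrame(columns=["iid1", "iid2", "fid"])
    # drop pairs that share a parent (siblings or half-siblings)
    m1 = meta.reindex(pairs["c1"]).to_numpy()
    m2 = meta.reindex(pairs["c2"]).to_numpy()
    share = np.zeros(len(pairs), dtype=bool)
    for i in range(2):
        for j in range(2):
            a, b = m1[:, i], m2[:, j]
            share |= pd.notna(a) & (a == b)
    pairs = pairs[~share]
    pairs = pairs.drop_duplicates(subset=["c1", "c2"])
    return (
        pairs.rename(columns={"c1": "iid1", "c2": "iid2"})[
            ["iid1", "iid2", "fid"]
        ].reset_index(drop=True)
    )


def classify_pair(df_indexed: pd.DataFrame, iid1, iid2) -> str | None:
    """Relative class of one pair from parent links (None if unrelated or
    closer than sibling, e.g. parent-offspring)."""
    r1, r2 = df_indexed.loc[iid1], df_indexed.loc[iid2]
    same_m = pd.notna(r1.mid) and r1.mid == r2.mid
    same_p = pd.notna(r1.pid) and r1.pid == r2.pid
    if same_m and same_p:
        return "full_sibling"
    if same_m:
        return "maternal_half_sibling"
    if same_p:
        return "paternal_half_sibling"
    # cousins: any pair of linking parents are full siblings
    for pa in (r1.mid, r1.pid):
        for pb in (r2.mid, r2.pid):
            if pd.isna(pa) or pd.isna(pb) or pa not in df_indexed.index or pb not in df_indexed.index:
                continue
            ra, rb = df_indexed.loc[pa], df_indexed.loc[pb]
            if (
                pd.notna(ra.mid) and ra.mid == rb.mid
                and pd.notna(ra.pid) and ra.pid == rb.pid
            ):
                return "cousin"
    return None


def enumerate_pairs(
    ped: PedigreeTable,
    cls: RelatednessClass | str,
    sex_filter: str | None = None,
    one_per_family: bool = False,
    exclude_twins: bool = False,
    seed: int = 0,
) -> RelativePairSet:
    """Enumerate unordered relative pairs of one class from parent links.

    ``sex_filter`` restricts both members ('F' or 'M').  ``exclude_twins``
    drops full-sibling pairs born in the same year (same birth event).
    With ``one_per_family`` one pair per family is kept, chosen uniformly
    at random under ``seed``.
    """
    if isinstance(cls, str):
        cls = get_class(cls)
    df = ped.df
    base = cls.label.replace("_sister", "_sibling").replace("sister", "sibling")
    if base == "full_sibling":
        pairs = _sibling_pairs(df, "full")
    elif base == "maternal_half_sibling":
        pairs = _sibling_pairs(df, "maternal_half")
    elif base == "paternal_half_sibling":
        pairs = _sibling_pairs(df, "paternal_half")
    elif base == "cousin":
        pairs = _cousin_pairs(df)
    else:
        raise ValueError(f"unknown relatedness class {cls.label!r}")

    if "study" in df.columns and len(pairs):
        study = set(df.loc[df["study"].astype(bool), "iid"])
        keep = pairs["iid1"].isin(study) & pairs["iid2"].isin(study)
        pairs = pairs[keep].reset_index(drop=True)

    meta = df.set_index("iid")
    if "sister" in cls.label and sex_filter is None:
        sex_filter = "F"
    if sex_filter is not None and len(pairs):
        keep = (
            meta.loc[pairs["iid1"], "sex"].to_numpy() == sex_filter
        ) & (meta.loc[pairs["iid2"], "sex"].to_numpy() == sex_filter)
        pairs = pairs[keep].reset_index(drop=True)
    if exclude_twins and len(pairs) and base == "full_sibling":
        same_year = (
            meta.loc[pairs["iid1"], "birth_year"].to_numpy()
            == meta.loc[pairs["iid2"], "birth_year"].to_numpy()
        )
        pairs = pairs[~same_year].reset_index(drop=True)
    if one_per_family and len(pairs):
        rng = np.random.default_rng(seed)
        pairs = (
            pairs.assign(_u=rng.random(len(pairs)))
            .sort_values("_u")
            .groupby("fid", sort=False)
            .head(1)
            .drop(columns="_u")
            .sort_index()
            .reset_index(drop=True)
        )
    return RelativePairSet(cls=cls, pairs=pairs)


def tabulate_pairs(
    pairs: RelativePairSet, ped: PedigreeTable, traits
) -> PairCountTable:
    """Pair contingency counts for one or two traits.

    One trait gives the symmetric 2x2 (orientation-free: discordant pairs
    contribute half to each off-diagonal cell); two traits give the 16-cell
    table averaged over the two pair orientations, so cells come in
    symmetric halves and may be fractional.  Pairs with any missing trait
    value are dropped and counted in ``n_dropped``.
    """
    if isinstance(traits, str):
        traits = (traits,)
    traits = tuple(traits)
    if len(traits) not in (1, 2):
        raise ValueError("tabulate_pairs takes one or two traits")
    vals = {t: pairs_trait_values(pairs, ped, t) for t in traits}
    ok = np.ones(len(pairs.pairs), dtype=bool)
    for v1, v2 in vals.values():
        ok &= ~(np.isnan(v1) | np.isnan(v2))
    n_dropped = int((~ok).sum())
    if len(traits) == 1:
        (v1, v2) = vals[traits[0]]
        v1, v2 = v1[ok].astype(int), v2[ok].astype(int)
        c = np.zeros((2, 2))
        np.add.at(c, (v1, v2), 0.5)
        np.add.at(c, (v2, v1), 0.5)
        return PairCountTable(traits=traits, counts=c, n_dropped=n_dropped)
    (x1, x2) = (v[ok].astype(int) for v in vals[traits[0]])
    (y1, y2) = (v[ok].astype(int) for v in vals[traits[1]])
    c = np.zeros((2, 2, 2, 2))
    np.add.at(c, (x1, y1, x2, y2), 0.5)
    np.add.at(c, (x2, y2, x1, y1), 0.5)
    return PairCountTable(traits=traits, counts=c, n_dropped=n_dropped)


def pairs_trait_values(
    pairs: RelativePairSet, ped: PedigreeTable, trait: str
) -> tuple[np.ndarray, np.ndarray]:
    s = ped.trait(trait)
    v1 = s.reindex(pairs.pairs["iid1"]).to_numpy(dtype=float)
    v2 = s.reindex(pairs.pairs["iid2"]).to_numpy(dtype=float)
    return v1, v2


# ---------------------------------------------------------------------------
# descriptive prevalence table


def round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_summary(
    ped: PedigreeTable | pd.DataFrame,
    stratify_trait: str = "dx_ADHD",
    by_sex: bool = True,
) -> pd.DataFrame:
    """Counts and percentages of each diagnosis within strata defined by
    sex and status on ``stratify_trait`` (the descriptive table layout).

    Percentages are affected/stratum-size, rounded half-up to one decimal;
    an empty stratum yields NaN with ``undefined`` flagged.
    """
    if isinstance(ped, PedigreeTable):
        df = ped.df
        dx_cols = ped.dx_columns
    else:
        df = ped
        dx_cols = [c for c in df.columns if c.startswith("dx_")]
    strata: list[tuple[str, pd.DataFrame]] = [("total", df)]
    if by_sex:
        strata += [
            ("female", df[df["sex"] == "F"]),
            ("male", df[df["sex"] == "M"]),
        ]
    rows = []
    for name, sub in strata:
        for status, label in ((1, "with"), (0, "without")):
            grp = sub[sub[stratify_trait] == status]
            n = len(grp)
            for dx in dx_cols:
                if dx == stratify_trait:
                    continue
                count = int(grp[dx].sum()) if n else 0
                rows.append(
                    {
                        "stratum": name,
                        stratify_trait: label,
                        "n_stratum": n,
                        "diagnosis": dx,
                        "n_affected": count,
                        "percent": round_half_up(100.0 * count / n)
                        if n
                        else np.nan,
                        "undefined": n == 0,
                    }
                )
    return pd.DataFrame(rows)
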