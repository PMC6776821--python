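"""Simulate the study cohorts: a register-like relative-pair population, an
all-female sister cohort for the biometric models, and a genotyped
twin-like target sample with discovery GWAS summary statistics.

Writes pedigree/phenotype TSVs, a target VCF and a sumstats TSV under
results/data/ for the downstream analysis scripts.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import numpy as np
import pandas as pd

from liabkin.cohortio import write_pedigree, write_sumstats, write_vcf
from liabkin.prs import genotype_pcs, GenotypeMatrix
from liabkin.simkin import (
    ArchitectureSpec,
    EDI2_SCALE,
    GenoPanelSpec,
    simulate_cohort,
    simulate_genotypes_and_sumstats,
    simulate_symptom_scales,
)

SEED = 20191015
OUT = ROOT / "scratch" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# architecture shared by both register-like cohorts: an ADHD-like trait
# (prevalence 3.1%, heritability .82) and a composite eating-disorder-like
# trait (2%, heritability .45), genetic correlation .37
ARCH = ArchitectureSpec(
    traits=("ADHD", "anyED"),
    prevalence=[0.031, 0.02],
    a2=[0.82, 0.45],
    r_a=0.37,
    r_e=0.2,
)

print("== simulating register-like relative-pair cohort ==")
registry = simulate_cohort(
    150_000,
    ARCH,
    {
        "full_sibling_pair": 0.30,
        "maternal_half_pair": 0.20,
        "paternal_half_pair": 0.20,
        "cousin_pair": 0.30,
    },
    seed=SEED,
)
write_pedigree(registry, OUT / "registry.tsv")
study = registry.df[registry.df["study"]]
print(
    f"  {len(registry.df):,} individuals ({len(study):,} in the study "
    f"generation); ADHD prevalence "
    f"{study['dx_ADHD'].mean():.3f}, ED prevalence "
    f"{study['dx_anyED'].mean():.3f}"
)

print("== simulating all-female sister cohort ==")
sisters = simulate_cohort(
    80_000,
    ARCH,
    {"full_sisters": 0.85, "maternal_half_sisters": 0.15},
    seed=SEED + 1,
)
write_pedigree(sisters, OUT / "sisters.tsv")
print(f"  {len(sisters.df):,} individuals")

print("== simulating genotype panel, discovery GWAS and symptom scales ==")
panel = simulate_genotypes_and_sumstats(
    GenoPanelSpec(
        n_variants=600,
        block_len=10,
        block_rho=0.6,
        n_causal=50,
        h2_panel=0.3,
        n_discovery=10_000,
        n_target=5_000,
    ),
    seed=SEED + 2,
)
write_vcf(OUT / "target.vcf", panel.variants, panel.target_dosages,
          panel.target_ids)
write_sumstats(panel.sumstats, OUT / "sumstats.tsv")

items = simulate_symptom_scales(
    panel.true_genetic_value, EDI2_SCALE, effect=0.06, seed=SEED + 3
)
pcs = genotype_pcs(
    GenotypeMatrix(panel.variants, panel.target_dosages, panel.target_ids),
    n_components=5,
)
rng = np.random.default_rng(SEED + 4)
pheno = pd.DataFrame({"iid": panel.target_ids})
pheno["pair_id"] = np.arange(len(pheno)) // 2  # twin-pair clusters
pheno["sex"] = rng.integers(0, 2, len(pheno))
pheno["birth_year"] = rng.integers(1992, 2006, len(pheno))
for k in range(5):
    pheno[f"pc{k + 1}"] = pcs[:, k]
pheno = pd.concat([pheno, items], axis=1)
pheno.to_csv(OUT / "target_pheno.tsv", sep="\t", index=False, na_rep="NA")
print(
    f"  {len(pheno):,} genotyped individuals, {panel.sumstats.shape[0]} "
    f"variants in the discovery GWAS"
)
print(f"inputs written to {OUT}")
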