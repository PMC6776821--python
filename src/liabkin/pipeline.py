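"""Config-driven orchestration of the three analysis arms on a simulated
cohort, plus a reproduction mode that regenerates every worked number from
the packaged published summary counts.

``run_all`` writes four report tables (prevalence, coaggregation ORs,
biometric model fits, PRS associations) and a provenance log; all
randomness flows from one seed tree.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coaggregation import coaggregation_or, forest_table
from .cohortio import (
    PairCountTable,
    enumerate_pairs,
    prevalence_summary,
    round_half_up,
    tabulate_pairs,
)
from .liability import (
    ClassCorrelations,
    fit_bivariate,
    fit_univariate,
    select_model,
    solve_ae_from_correlations,
    tetrachoric_mle,
)
from .prs import GenotypeMatrix, gee_linear, ld_clump, qc_filter, score
from .relatedness import FULL_SISTER, MATERNAL_HALF_SISTER, get_class
from .simkin import (
    ArchitectureSpec,
    EDI2_SCALE,
    GenoPanelSpec,
    scale_score,
    simulate_cohort,
    simulate_genotypes_and_sumstats,
    simulate_symptom_scales,
)

__all__ = ["RunConfig", "run_all", "paper_fixtures", "reproduce_paper"]


@dataclass
class RunConfig:
    """Declarative configuration of a full simulated run."""

    seed: int = 20191015
    out_dir: str = "results/run"
    # registry-like arm
    n_registry_families: int = 20000
    registry_pattern: dict = field(
        default_factory=lambda: {
            "full_sibling_pair": 0.45,
            "maternal_half_pair": 0.10,
            "paternal_half_pair": 0.10,
            "cousin_pair": 0.35,
        }
    )
    # sister cohort for the biometric arm
    n_sister_families: int = 40000
    sister_pattern: dict = field(
        default_factory=lambda: {
            "full_sisters": 0.85,
            "maternal_half_sisters": 0.15,
        }
    )
    traits: tuple = ("ADHD", "anyED")
    prevalence: tuple = (0.031, 0.02)
    a2: tuple = (0.82, 0.45)
    r_a: float = 0.37
    r_e: float = 0.2
    biometric_models: tuple = ("ACE", "ADE", "AE")
    coagg_classes: tuple = (
        "full_sibling",
        "maternal_half_sibling",
        "paternal_half_sibling",
        "cousin",
    )
    # PRS arm
    panel: dict = field(default_factory=dict)
    prs_thresholds: tuple = (1e-5, 1e-3, 0.01, 0.05, 0.10, 0.50, 1.00)
    prs_effect: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def architecture(self) -> ArchitectureSpec:
        return ArchitectureSpec(
            traits=self.traits,
            prevalence=np.asarray(self.prevalence),
            a2=np.asarray(self.a2),
            r_a=self.r_a,
            r_e=self.r_e,
        )


def _seed_tree(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_all(config: RunConfig) -> dict:
    """Run the three analysis arms on freshly simulated cohorts and write
    the report bundle under ``config.out_dir``.  Deterministic given the
    config seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_tree(config.seed, 6)
    spec = config.architecture()

    # --- registry arm: prevalence + coaggregation --------------------------
    registry = simulate_cohort(
        config.n_registry_families,
        spec,
        config.registry_pattern,
        seed=seeds[0],
    )
    prev = prevalence_summary(registry, stratify_trait=f"dx_{spec.traits[0]}")
    prev.to_csv(out / "table_prevalence.tsv", sep="\t", index=False)

    fits = {}
    for label in config.coagg_classes:
        cls = get_class(label)
        pairs = enumerate_pairs(registry, cls)
        try:
            fits[(label, spec.traits[1])] = coaggregation_or(
                registry,
                pairs,
                index_trait=spec.traits[0],
                relative_trait=spec.traits[1],
            )
        except ValueError:
            continue
    forest = forest_table(fits)
    forest.to_csv(out / "table_coaggregation.tsv", sep="\t", index=False)

    # --- biometric arm -----------------------------------------------------
    sisters = simulate_cohort(
        config.n_sister_families,
        spec,
        config.sister_pattern,
        seed=seeds[1],
        c_sharing=None,
    )
    tables = {}
    for cls in (FULL_SISTER, MATERNAL_HALF_SISTER):
        pairs = enumerate_pairs(
            sisters, cls, one_per_family=True, exclude_twins=True,
            seed=seeds[2],
        )
        tables[cls] = tabulate_pairs(pairs, sisters, spec.traits).counts
    model_fits = [
        fit_bivariate(tables, model=m, seed=seeds[3], n_restarts=1)
        for m in config.biometric_models
    ]
    best = select_model(model_fits)
    bio_rows = []
    for f in model_fits:
        row = {
            "model": f.model,
            "loglik": f.loglik,
            "aic": f.aic,
            "selected": f is best,
        }
        row.update(
            {
                k: v
                for k, v in f.summary().items()
                if not isinstance(v, (list, tuple))
            }
        )
        bio_rows.append(row)
    bio = pd.DataFrame(bio_rows)
    bio.to_csv(out / "table_biometric.tsv", sep="\t", index=False)

    # --- PRS arm -----------------------------------------------------------
    panel_spec = GenoPanelSpec(**config.panel)
    panel = simulate_genotypes_and_sumstats(panel_spec, seed=seeds[4])
    target = GenotypeMatrix(
        panel.variants, panel.target_dosages, panel.target_ids
    )
    ss = qc_filter(panel.sumstats)
    clumped = ld_clump(ss, target)
    items = simulate_symptom_scales(
        panel.true_genetic_value,
        EDI2_SCALE,
        effect=config.prs_effect,
        seed=seeds[5],
    )
    outcome = scale_score(items, EDI2_SCALE)
    n = len(outcome)
    clusters = np.arange(n) // 2  # simulated twin pairs
    rng = np.random.default_rng(seeds[5])
    covs = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n).astype(float),
            "birth_year": rng.integers(1992, 2006, n).astype(float),
        }
    )
    prs_rows = []
    for thr in config.prs_thresholds:
        try:
            res = score(clumped, target, p_threshold=thr)
        except ValueError:
            continue
        g = gee_linear(outcome, res.standardized, covs, clusters)
        prs_rows.append(
            {
                "p_threshold": thr,
                "n_variants": res.n_variants,
                "beta": g.beta,
                "se": g.se,
                "ci_low": g.ci[0],
                "ci_high": g.ci[1],
                "p": g.p,
                "delta_r2": g.delta_r2,
            }
        )
    prs_table = pd.DataFrame(prs_rows)
    prs_table.to_csv(out / "table_prs.tsv", sep="\t", index=False)

    provenance = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return {
        "prevalence": prev,
        "coaggregation": forest,
        "biometric": bio,
        "prs": prs_table,
        "provenance": provenance,
    }


# ---------------------------------------------------------------------------
# reproduction mode from the packaged printed counts


def paper_fixtures() -> dict:
    """The packaged published summary counts and correlations."""
    with resources.files("liabkin.data").joinpath(
        "printed_counts.json"
    ).open() as fh:
        return json.load(fh)


def _reconstructed_table(entry: dict) -> np.ndarray:
    return PairCountTable.from_concordant_discordant(
        "t", entry["both_affected"], entry["both_unaffected"],
        entry["discordant"],
    ).counts


def reproduce_paper(seed: int = 0) -> dict:
    """Regenerate the in-paper worked numbers from the printed counts.

    Returns prevalence percentages recomputed from the descriptive-table
    counts, tetrachoric correlations from the reconstructed 2x2 pair
    tables, the joint univariate AE heritability of ADHD, and the
    correlation-based bivariate AE solutions for each disorder pair.
    """
    fx = paper_fixtures()
    out: dict = {}

    t1 = fx["table1"]
    pop = fx["population"]
    prev = {
        "adhd_total_pct": round_half_up(
            100.0 * t1["total"]["n_adhd"] / pop["n_total"]
        ),
        "adhd_female_pct": round_half_up(
            100.0 * t1["female"]["n_adhd"] / pop["n_female"]
        ),
        "adhd_male_pct": round_half_up(
            100.0 * t1["male"]["n_adhd"] / pop["n_male"]
        ),
    }
    for stratum in ("total", "female", "male"):
        for dx, cnt in t1[stratum]["counts_adhd"].items():
            prev[f"{dx}_in_adhd_{stratum}_pct"] = round_half_up(
                100.0 * cnt / t1[stratum]["n_adhd"]
            )
        for dx, cnt in t1[stratum]["counts_no_adhd"].items():
            prev[f"{dx}_in_no_adhd_{stratum}_pct"] = round_half_up(
                100.0 * cnt / t1[stratum]["n_no_adhd"]
            )
    out["prevalence"] = prev

    t2 = fx["table2"]["pair_counts"]
    tetra = {}
    for trait, by_class in t2.items():
        for cls_label, entry in by_class.items():
            res = tetrachoric_mle(_reconstructed_table(entry))
            tetra[f"{trait}_{cls_label}"] = {
                "r": res.r,
                "se": res.se,
                "ci": list(res.ci),
            }
    out["tetrachoric"] = tetra

    adhd_tables = {
        FULL_SISTER: _reconstructed_table(t2["ADHD"]["full_sister"]),
        MATERNAL_HALF_SISTER: _reconstructed_table(
            t2["ADHD"]["maternal_half_sister"]
        ),
    }
    uni = fit_univariate(adhd_tables, model="AE")
    out["adhd_heritability"] = {
        "h2": uni.derived["h2"],
        "h2_ci": list(uni.derived["h2_ci"]),
        "aic": uni.aic,
    }

    corr = fx["table2"]["correlations"]
    n_full = fx["quantitative_genetic_pairs"]["full_sister"]
    n_half = fx["quantitative_genetic_pairs"]["maternal_half_sister"]
    ae = {}
    for trait in ("AN", "OED", "BN"):
        cl = corr[trait]
        sol = solve_ae_from_correlations(
            [
                ClassCorrelations(
                    FULL_SISTER,
                    r_x=corr["ADHD"]["full_sister"]["within"],
                    r_y=cl["full_sister"]["within"],
                    r_pheno=cl["full_sister"]["phenotypic"],
                    r_cross=cl["full_sister"]["cross"],
                    n_pairs=n_full,
                ),
                ClassCorrelations(
                    MATERNAL_HALF_SISTER,
                    r_x=corr["ADHD"]["maternal_half_sister"]["within"],
                    r_y=cl["maternal_half_sister"]["within"],
                    r_pheno=cl["maternal_half_sister"]["phenotypic"],
                    r_cross=cl["maternal_half_sister"]["cross"],
                    n_pairs=n_half,
                ),
            ]
        )
        ae[f"ADHD_{trait}"] = {
            "a2_adhd": sol.a2[0],
            "a2_ed": sol.a2[1],
            "cov_a": sol.cov_a,
            "rg": sol.rg,
            "coheritability_a": sol.coheritability_a,
            "coheritability_e": sol.coheritability_e,
        }
    out["bivariate_ae"] = ae
    return out
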