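"""Synthetic cohort generator: pedigrees, liabilities, genotypes, scales."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from liabkin.cohortio import classify_pair, enumerate_pairs, write_pedigree
from liabkin.prs import cronbach_alpha
from liabkin.relatedness import (
    COUSIN,
    FULL_SIBLING,
    FULL_SISTER,
    MATERNAL_HALF_SIBLING,
    PATERNAL_HALF_SIBLING,
)
from liabkin.simkin import (
    ATAC_SCALE,
    EDI2_SCALE,
    ArchitectureSpec,
    GenoPanelSpec,
    scale_score,
    simulate_cohort,
    simulate_genotypes_and_sumstats,
    simulate_liabilities,
    simulate_pedigree,
    simulate_symptom_scales,
    threshold_diagnose,
)


class TestPedigree:
    def test_full_sisters_share_both_parents(self):
        ped = simulate_pedigree(1, "full_sisters", seed=1)
        kids = ped.df[ped.df["study"]]
        assert len(kids) == 2
        assert kids["mid"].nunique() == 1
        assert kids["pid"].nunique() == 1
        assert set(kids["sex"]) == {"F"}

    def test_maternal_half_sisters_share_mother_only(self):
        ped = simulate_pedigree(1, "maternal_half_sisters", seed=1)
        kids = ped.df[ped.df["study"]]
        assert kids["mid"].nunique() == 1
        assert kids["pid"].nunique() == 2

    def test_rejects_nonpositive_family_count(self):
        with pytest.raises(ValueError):
            simulate_pedigree(0, "full_sisters")

    def test_enumeration_matches_brute_force_pair_scan(self):
        # exhaustive O(n^2) scan over every individual pair as the oracle
        ped = simulate_pedigree(
            150,
            {
                "full_sibling_pair": 0.3,
                "maternal_half_pair": 0.2,
                "paternal_half_pair": 0.2,
                "cousin_pair": 0.3,
            },
            seed=1,
        )
        df = ped.df
        idx = df.set_index("iid")
        study = df[df["study"]]["iid"].tolist()
        brute = Counter()
        for a, b in itertools.combinations(study, 2):
            label = classify_pair(idx, a, b)
            if label:
                brute[label] += 1
        for cls in (
            FULL_SIBLING, MATERNAL_HALF_SIBLING, PATERNAL_HALF_SIBLING, COUSIN,
        ):
            enum = enumerate_pairs(ped, cls, sex_filter=None)
            assert len(enum) == brute[cls.label]

    def test_classes_mutually_exclusive_per_pair(self):
        ped = simulate_pedigree(
            300,
            {"full_sibling_pair": 0.5, "cousin_pair": 0.5},
            seed=5,
        )
        seen = {}
        for cls in (
            FULL_SIBLING, MATERNAL_HALF_SIBLING, PATERNAL_HALF_SIBLING, COUSIN,
        ):
            for t in enumerate_pairs(ped, cls, sex_filter=None).pairs.itertuples():
                key = tuple(sorted((t.iid1, t.iid2)))
                assert key not in seen, "pair assigned to two classes"
                seen[key] = cls.label

    def test_identical_seed_reproduces_bytes(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_pedigree(simulate_pedigree(200, "full_sisters", seed=9), a)
        write_pedigree(simulate_pedigree(200, "full_sisters", seed=9), b)
        assert a.read_bytes() == b.read_bytes()


class TestLiabilities:
    def _cross_sister_corr(self, spec, n_fam, seed, pattern="full_sisters"):
        ped = simulate_pedigree(n_fam, pattern, seed=seed)
        liab = simulate_liabilities(ped, spec, seed=seed + 1)
        cls = FULL_SIBLING if "full" in pattern else MATERNAL_HALF_SIBLING
        p = enumerate_pairs(ped, cls, sex_filter=None).pairs
        v1 = liab.loc[p["iid1"], spec.traits[0]].to_numpy()
        v2 = liab.loc[p["iid2"], spec.traits[0]].to_numpy()
        return np.corrcoef(v1, v2)[0, 1]

    def test_pure_environment_gives_independent_sisters(self):
        spec = ArchitectureSpec(traits=("X",), prevalence=[0.5], a2=[0.0])
        r = self._cross_sister_corr(spec, 20000, seed=2)
        assert abs(r) < 3 / np.sqrt(20000)

    def test_fully_additive_gives_half_correlation(self):
        spec = ArchitectureSpec(
            traits=("X",), prevalence=[0.5], a2=[1.0], e2=[0.0]
        )
        r = self._cross_sister_corr(spec, 20000, seed=3)
        assert r == pytest.approx(0.5, abs=3 * 0.75 / np.sqrt(20000))

    def test_heritable_trait_hits_closed_form_covariance(self):
        # .5 x .82 = .41 expected for full sisters
        spec = ArchitectureSpec(traits=("X",), prevalence=[0.5], a2=[0.82])
        r = self._cross_sister_corr(spec, 50000, seed=7)
        assert r == pytest.approx(0.41, abs=3 * (1 - 0.41**2) / np.sqrt(50000))

    def test_component_grid_recovery_across_classes(self):
        # coefficient-weighted component sums within 3 Monte-Carlo SEs
        cases = [
            (dict(a2=[0.6], c2=[0.2]), "full_sisters", 0.5 * 0.6 + 0.2),
            (dict(a2=[0.6], c2=[0.2]), "maternal_half_sisters", 0.25 * 0.6 + 0.2),
            (dict(a2=[0.4], d2=[0.3]), "full_sisters", 0.5 * 0.4 + 0.25 * 0.3),
            (dict(a2=[0.4], d2=[0.3]), "maternal_half_sisters", 0.25 * 0.4),
        ]
        for comps, pattern, expect in cases:
            spec = ArchitectureSpec(traits=("X",), prevalence=[0.5], **comps)
            r = self._cross_sister_corr(spec, 20000, seed=13, pattern=pattern)
            se = (1 - expect**2) / np.sqrt(20000)
            assert r == pytest.approx(expect, abs=3 * se)

    def test_cross_trait_cross_sister_covariance(self):
        spec = ArchitectureSpec(
            traits=("X", "Y"), prevalence=[0.5, 0.5],
            a2=[0.8, 0.5], r_a=0.6, r_e=0.0,
        )
        ped = simulate_pedigree(30000, "full_sisters", seed=21)
        liab = simulate_liabilities(ped, spec, seed=22)
        p = enumerate_pairs(ped, FULL_SISTER).pairs
        x1 = liab.loc[p["iid1"], "X"].to_numpy()
        y2 = liab.loc[p["iid2"], "Y"].to_numpy()
        expect = 0.5 * 0.6 * np.sqrt(0.8 * 0.5)
        assert np.cov(x1, y2)[0, 1] == pytest.approx(
            expect, abs=3 / np.sqrt(30000)
        )

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ArchitectureSpec(
                traits=("X",), prevalence=[0.1], a2=[0.6], e2=[0.6]
            )


class TestThresholdDiagnose:
    def test_median_threshold_splits_at_zero(self):
        assert list(threshold_diagnose([-1.0, 1.0], 0.5)) == [0, 1]

    def test_prevalence_near_one_diagnoses_everyone(self):
        z = np.array([-3.0, 0.0, 3.0])
        assert threshold_diagnose(z, 1 - 1e-12).all()

    def test_empirical_prevalence_converges(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(1_000_000)
        frac = threshold_diagnose(z, 0.019).mean()
        assert frac == pytest.approx(0.019, abs=3 * np.sqrt(0.019 / 1e6) + 1e-4)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            threshold_diagnose([0.0], 0.0)


class TestGenotypes:
    def test_null_panel_gives_uniform_pvalues(self):
        spec = GenoPanelSpec(
            n_variants=300, n_causal=0, n_discovery=2000, n_target=200
        )
        panel = simulate_genotypes_and_sumstats(spec, seed=3)
        p = panel.sumstats["p"].to_numpy()
        assert p.mean() == pytest.approx(0.5, abs=0.06)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.035)

    def test_single_causal_variant_tops_the_association(self):
        spec = GenoPanelSpec(
            n_variants=120, n_causal=1, n_discovery=20000, n_target=200,
            h2_panel=0.3, block_rho=0.5, block_len=5,
        )
        panel = simulate_genotypes_and_sumstats(spec, seed=8)
        causal = int(np.nonzero(panel.true_beta)[0][0])
        top = int(panel.sumstats["p"].idxmin())
        # the winner is the causal variant or an LD proxy in its block
        assert abs(top - causal) < spec.block_len

    def test_block_rho_sets_adjacent_dosage_r2(self):
        spec = GenoPanelSpec(
            n_variants=60, block_len=60, block_rho=0.9, n_causal=0,
            n_discovery=200, n_target=6000, maf_range=(0.2, 0.5),
        )
        panel = simulate_genotypes_and_sumstats(spec, seed=12)
        X = panel.target_dosages
        r2 = [
            np.corrcoef(X[:, j], X[:, j + 1])[0, 1] ** 2 for j in range(40)
        ]
        assert np.mean(r2) == pytest.approx(0.81, abs=0.03)

    def test_causal_count_cannot_exceed_panel(self):
        with pytest.raises(ValueError, match="causal"):
            GenoPanelSpec(n_variants=10, n_causal=11)

    def test_discovery_and_target_are_disjoint_draws(self):
        spec = GenoPanelSpec(n_variants=50, n_discovery=500, n_target=500)
        panel = simulate_genotypes_and_sumstats(spec, seed=4)
        assert not np.array_equal(
            panel.discovery_dosages[:500], panel.target_dosages
        )


class TestSymptomScales:
    def test_scale_floors(self):
        g = np.zeros(5)
        items = simulate_symptom_scales(g, ATAC_SCALE, effect=0.0, seed=1)
        floor = items * 0.0
        assert scale_score(floor, ATAC_SCALE).eq(0.0).all()
        edi_floor = simulate_symptom_scales(g, EDI2_SCALE, seed=1) * 0 + 1.0
        assert scale_score(edi_floor, EDI2_SCALE).eq(1.0).all()

    def test_responses_on_legal_sets(self):
        g = np.random.default_rng(2).standard_normal(500)
        atac = simulate_symptom_scales(g, ATAC_SCALE, seed=3)
        assert atac.isin([0.0, 0.5, 1.0]).all().all()
        edi = simulate_symptom_scales(g, EDI2_SCALE, seed=3)
        assert edi.isin([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]).all().all()
        assert atac.shape[1] == 19 and edi.shape[1] == 22

    def test_emitted_items_hit_target_alpha(self):
        g = np.random.default_rng(4).standard_normal(5000)
        items = simulate_symptom_scales(g, EDI2_SCALE, effect=0.1, seed=5)
        assert cronbach_alpha(items) == pytest.approx(
            EDI2_SCALE.target_alpha, abs=0.02
        )

    def test_scores_track_genetic_value(self):
        g = np.random.default_rng(6).standard_normal(4000)
        items = simulate_symptom_scales(g, EDI2_SCALE, effect=0.4, seed=7)
        score = scale_score(items, EDI2_SCALE)
        assert np.corrcoef(score, g)[0, 1] > 0.2

    def test_subscale_partition(self):
        g = np.zeros(10)
        items = simulate_symptom_scales(g, EDI2_SCALE, seed=8)
        subs = [
            scale_score(items, EDI2_SCALE, sub) for sub in EDI2_SCALE.subscales
        ]
        assert len(subs) == 3


class TestCohortDiagnoses:
    def test_diagnosis_prevalence_matches_spec(self):
        spec = ArchitectureSpec(
            traits=("ADHD",), prevalence=[0.05], a2=[0.8]
        )
        ped = simulate_cohort(20000, spec, "full_sisters", seed=31)
        dx = ped.df.loc[ped.df["study"], "dx_ADHD"]
        assert dx.mean() == pytest.approx(0.05, abs=0.006)

    def test_identical_seed_identical_cohort(self):
        spec = ArchitectureSpec(traits=("X",), prevalence=[0.1], a2=[0.5])
        a = simulate_cohort(300, spec, "full_sisters", seed=77).df
        b = simulate_cohort(300, spec, "full_sisters", seed=77).df
        pd.testing.assert_frame_equal(a, b)
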