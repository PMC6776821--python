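"""PRS construction: QC, LD clumping, scoring, association, scale scoring."""

import numpy as np
import pandas as pd
import pytest

from liabkin.prs import (
    GenotypeMatrix,
    cronbach_alpha,
    gee_linear,
    genotype_pcs,
    ld_clump,
    qc_filter,
    score,
)
from liabkin.simkin import (
    ATAC_SCALE,
    EDI2_SCALE,
    GenoPanelSpec,
    scale_score,
    simulate_genotypes_and_sumstats,
    simulate_symptom_scales,
)


def make_sumstats(rows):
    cols = ["snp", "chr", "pos", "a1", "a2", "beta", "p", "freq", "info"]
    return pd.DataFrame(rows, columns=cols)


def make_panel(variants_rows, dosages):
    v = pd.DataFrame(
        variants_rows, columns=["snp", "chr", "pos", "a1", "a2"]
    )
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(v, d, [f"s{i}" for i in range(d.shape[0])])


class TestQcFilter:
    def _base(self, **over):
        row = {
            "snp": "rs1", "chr": "1", "pos": 100, "a1": "A", "a2": "G",
            "beta": 0.1, "p": 0.5, "freq": 0.3, "info": 0.95,
        }
        row.update(over)
        return row

    def test_low_maf_removed(self):
        ss = pd.DataFrame([self._base(freq=0.04)])
        assert len(qc_filter(ss)) == 0

    def test_boundaries_inclusive(self):
        # the filter keeps variants at exactly MAF .05 and INFO .80
        ss = pd.DataFrame([self._base(freq=0.05, info=0.80)])
        assert len(qc_filter(ss)) == 1

    def test_high_frequency_alleles_use_minor_side(self):
        ss = pd.DataFrame([self._base(freq=0.97)])
        assert len(qc_filter(ss)) == 0

    def test_ambiguous_strand_dropped_by_default(self):
        ss = pd.DataFrame(
            [self._base(), self._base(snp="rs2", a1="A", a2="T")]
        )
        out = qc_filter(ss)
        assert out["snp"].tolist() == ["rs1"]
        kept = qc_filter(ss, drop_ambiguous=False)
        assert len(kept) == 2

    def test_empty_input_empty_output(self):
        ss = make_sumstats([])
        assert len(qc_filter(ss)) == 0

    def test_missing_info_column_warns_and_passes(self):
        ss = pd.DataFrame([self._base()]).drop(columns="info")
        with pytest.warns(UserWarning, match="INFO"):
            out = qc_filter(ss)
        assert len(out) == 1


def brute_force_clump(ss, r2, r2_max=0.1, window=1_000_000):
    """Independent re-implementation of the greedy rule on a precomputed
    r2 matrix, used as the oracle."""
    order = np.argsort(ss["p"].to_numpy(), kind="stable")
    removed, kept = set(), []
    pos = ss["pos"].to_numpy()
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in range(len(ss)):
            if j == i or j in removed or j in kept:
                continue
            if abs(pos[j] - pos[i]) <= window and r2[i, j] > r2_max:
                removed.add(j)
    return sorted(kept)


class TestLdClump:
    def _correlated_panel(self, n_var, seed, rho=0.5):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((400, 1))
        z = rho * base + np.sqrt(1 - rho**2) * rng.standard_normal((400, n_var))
        d = (z > 0).astype(float) + (
            rho * base + np.sqrt(1 - rho**2)
            * rng.standard_normal((400, n_var)) > 0
        ).astype(float)
        rows = [
            (f"rs{j}", "1", 1000 + j * 10_000, "A", "G") for j in range(n_var)
        ]
        return make_panel(rows, d)

    def test_most_significant_of_correlated_trio_survives(self):
        panel = self._correlated_panel(3, seed=1, rho=0.85)
        ss = make_sumstats(
            [
                ("rs0", "1", 1000, "A", "G", 0.3, 1e-8, 0.5, 1.0),
                ("rs1", "1", 11000, "A", "G", 0.2, 1e-4, 0.5, 1.0),
                ("rs2", "1", 21000, "A", "G", 0.1, 1e-2, 0.5, 1.0),
            ]
        )
        out = ld_clump(ss, panel, r2_max=0.1, window_kb=1000)
        assert out["snp"].tolist() == ["rs0"]

    def test_uncorrelated_panel_keeps_everything(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(300, 5)).astype(float)
        rows = [(f"rs{j}", "1", 1000 + j * 5000, "A", "G") for j in range(5)]
        panel = make_panel(rows, d)
        ss = make_sumstats(
            [
                (f"rs{j}", "1", 1000 + j * 5000, "A", "G", 0.1,
                 10 ** -(j + 2), 0.5, 1.0)
                for j in range(5)
            ]
        )
        assert len(ld_clump(ss, panel)) == 5

    def test_matches_brute_force_oracle_on_random_panels(self):
        rng = np.random.default_rng(3)
        for rep in range(60):
            spec = GenoPanelSpec(
                n_variants=10, block_len=5, block_rho=rng.uniform(0.2, 0.8),
                n_causal=0, n_discovery=100, n_target=250,
                pos_step=int(rng.integers(10_000, 600_000)),
            )
            panel_sim = simulate_genotypes_and_sumstats(spec, seed=1000 + rep)
            panel = GenotypeMatrix(
                panel_sim.variants, panel_sim.target_dosages,
                panel_sim.target_ids,
            )
            ss = panel_sim.sumstats.copy()
            ss["p"] = rng.random(len(ss))
            out = ld_clump(ss, panel, r2_max=0.1, window_kb=1000)
            r2 = np.corrcoef(panel.dosages, rowvar=False) ** 2
            expect = brute_force_clump(ss, r2)
            assert sorted(
                int(s[2:]) - 1 for s in out["snp"]
            ) == expect, f"mismatch in replicate {rep}"

    def test_variants_missing_from_reference_dropped(self):
        panel = self._correlated_panel(2, seed=4)
        ss = make_sumstats(
            [
                ("rs0", "1", 1000, "A", "G", 0.3, 1e-8, 0.5, 1.0),
                ("rsX", "1", 5000, "A", "G", 0.2, 1e-4, 0.5, 1.0),
            ]
        )
        out = ld_clump(ss, panel)
        assert "rsX" not in set(out["snp"])


class TestScore:
    def test_single_variant_weighted_dosage(self):
        panel = make_panel([("rs1", "1", 100, "A", "G")], [[2.0], [0.0]])
        ss = make_sumstats([("rs1", "1", 100, "A", "G", 0.5, 0.01, 0.3, 1.0)])
        res = score(ss, panel, p_threshold=1.0)
        assert res.raw[0] == pytest.approx(1.0)
        assert res.raw[1] == pytest.approx(0.0)

    def test_standardized_scores_unit_variance(self):
        rng = np.random.default_rng(5)
        panel = make_panel(
            [(f"rs{j}", "1", j * 1000, "A", "G") for j in range(6)],
            rng.integers(0, 3, size=(50, 6)),
        )
        ss = make_sumstats(
            [
                (f"rs{j}", "1", j * 1000, "A", "G", rng.normal(), 0.5,
                 0.4, 1.0)
                for j in range(6)
            ]
        )
        res = score(ss, panel)
        assert res.standardized.mean() == pytest.approx(0.0, abs=1e-9)
        assert res.standardized.std() == pytest.approx(1.0, abs=1e-9)

    def test_allele_relabeling_leaves_scores_unchanged(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(40, 2)).astype(float)
        rows = [("rs1", "1", 100, "A", "G"), ("rs2", "1", 200, "C", "T")]
        panel = make_panel(rows, d)
        ss = make_sumstats(
            [
                ("rs1", "1", 100, "A", "G", 0.4, 0.01, 0.3, 1.0),
                ("rs2", "1", 200, "C", "T", -0.2, 0.02, 0.4, 1.0),
            ]
        )
        base = score(ss, panel)
        # relabel rs1's effect allele as the other allele: the equivalent
        # sumstats row has the opposite beta and complementary frequency;
        # raw scores shift by a constant, standardized scores are unchanged
        swapped = ss.copy()
        swapped.loc[0, ["a1", "a2"]] = ["G", "A"]
        swapped.loc[0, "beta"] = -0.4
        swapped.loc[0, "freq"] = 0.7
        res = score(swapped, panel)
        np.testing.assert_allclose(res.raw, base.raw - 0.8, atol=1e-12)
        np.testing.assert_allclose(
            res.standardized, base.standardized, atol=1e-12
        )
        # strand flip (complement labels): same orientation, same score
        flipped = ss.copy()
        flipped.loc[1, ["a1", "a2"]] = ["G", "A"]
        np.testing.assert_allclose(
            score(flipped, panel).raw, base.raw, atol=1e-12
        )

    def test_concatenated_panels_add_scores(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(30, 4)).astype(float)
        rows = [(f"rs{j}", "1", j * 1000 + 10, "A", "G") for j in range(4)]
        panel = make_panel(rows, d)
        ss = make_sumstats(
            [
                (f"rs{j}", "1", j * 1000 + 10, "A", "G", rng.normal(),
                 0.5, 0.4, 1.0)
                for j in range(4)
            ]
        )
        whole = score(ss, panel).raw
        left = score(ss.iloc[:2], panel).raw
        right = score(ss.iloc[2:], panel).raw
        np.testing.assert_allclose(whole, left + right, atol=1e-12)

    def test_variant_counts_non_increasing_with_threshold(self):
        spec = GenoPanelSpec(
            n_variants=200, n_causal=10, n_discovery=2000, n_target=500
        )
        sim = simulate_genotypes_and_sumstats(spec, seed=8)
        panel = GenotypeMatrix(sim.variants, sim.target_dosages, sim.target_ids)
        counts = []
        for thr in (1.0, 0.5, 0.1, 0.05, 0.01):
            counts.append(score(sim.sumstats, panel, thr).n_variants)
        assert counts == sorted(counts, reverse=True)

    def test_missing_dosages_imputed_to_expected_count(self):
        panel = make_panel(
            [("rs1", "1", 100, "A", "G")], [[np.nan], [1.0]]
        )
        ss = make_sumstats([("rs1", "1", 100, "A", "G", 1.0, 0.01, 0.3, 1.0)])
        res = score(ss, panel)
        assert res.raw[0] == pytest.approx(2 * 0.3)

    def test_no_passing_variants_rejected(self):
        panel = make_panel([("rs1", "1", 100, "A", "G")], [[1.0]])
        ss = make_sumstats([("rs1", "1", 100, "A", "G", 0.5, 0.9, 0.3, 1.0)])
        with pytest.raises(ValueError):
            score(ss, panel, p_threshold=1e-5)


class TestGeeLinear:
    def test_null_prs_gives_null_slope(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(10000)
        prs = rng.standard_normal(10000)
        res = gee_linear(y, prs, clusters=np.arange(10000) // 2)
        assert res.beta == pytest.approx(0.0, abs=0.03)
        assert res.delta_r2 < 1e-3

    def test_recovers_symptom_scale_effect_size(self):
        # outcome = .03 x PRS + noise at the self-report scale's SD
        rng = np.random.default_rng(10)
        n = 40000
        prs = rng.standard_normal(n)
        y = 0.03 * prs + 0.77 * rng.standard_normal(n)
        res = gee_linear(y, prs, clusters=np.arange(n) // 2)
        assert res.beta == pytest.approx(0.03, abs=3 * 0.77 / np.sqrt(n))
        assert res.delta_r2 == pytest.approx(
            0.03**2 / (0.03**2 + 0.77**2), rel=0.5
        )

    def test_singleton_clusters_match_ols_robust(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 400
        prs = rng.standard_normal(n)
        y = 0.2 * prs + rng.standard_normal(n)
        res = gee_linear(y, prs, clusters=np.arange(n))
        X = pd.DataFrame({"const": 1.0, "prs": prs})
        hc1 = sm.OLS(y, X).fit(cov_type="HC1")
        assert res.beta == pytest.approx(float(hc1.params["prs"]), rel=1e-10)
        assert res.se == pytest.approx(float(hc1.bse["prs"]), rel=0.01)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(12)
        prs = rng.standard_normal(100)
        covs = pd.DataFrame({"a": np.ones(100), "b": np.ones(100)})
        with pytest.raises(ValueError, match="rank"):
            gee_linear(rng.standard_normal(100), prs, covs)


class TestScaleScores:
    def test_adhd_inventory_all_yes_sums_to_19(self):
        items = pd.DataFrame(
            [[1.0] * 19], columns=ATAC_SCALE.items
        )
        assert scale_score(items, ATAC_SCALE).iloc[0] == 19.0

    def test_edi_all_never_floors_at_one(self):
        items = pd.DataFrame([[1.0] * 22], columns=EDI2_SCALE.items)
        assert scale_score(items, EDI2_SCALE).iloc[0] == 1.0

    def test_partial_yes_answers_sum_in_halves(self):
        row = [0.5] * 9 + [0.0] * 10
        items = pd.DataFrame([row], columns=ATAC_SCALE.items)
        assert scale_score(items, ATAC_SCALE).iloc[0] == 4.5

    def test_subscale_ranges(self):
        row = [1.0] * 19
        items = pd.DataFrame([row], columns=ATAC_SCALE.items)
        assert scale_score(items, ATAC_SCALE, "inattention").iloc[0] == 9.0
        assert scale_score(items, ATAC_SCALE, "hyperactivity").iloc[0] == 10.0

    def test_out_of_range_response_rejected(self):
        items = pd.DataFrame([[7.0] * 22], columns=EDI2_SCALE.items)
        with pytest.raises(ValueError, match="legal"):
            scale_score(items, EDI2_SCALE)


class TestCronbachAlpha:
    def test_perfectly_correlated_pair_gives_one(self):
        x = np.arange(50, dtype=float)
        items = pd.DataFrame({"i1": x, "i2": 2 * x + 3})
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_give_near_zero(self):
        rng = np.random.default_rng(13)
        items = pd.DataFrame(rng.standard_normal((5000, 4)))
        assert cronbach_alpha(items) == pytest.approx(0.0, abs=0.1)

    def test_closed_form_three_items_half_correlation(self):
        # alpha = k r / (1 + (k-1) r) = 3 * .5 / 2 = .75
        rng = np.random.default_rng(14)
        n = 200000
        common = rng.standard_normal(n)
        items = pd.DataFrame(
            {
                f"i{j}": np.sqrt(0.5) * common
                + np.sqrt(0.5) * rng.standard_normal(n)
                for j in range(3)
            }
        )
        assert cronbach_alpha(items) == pytest.approx(0.75, abs=0.01)

    def test_zero_variance_item_excluded_with_warning(self):
        rng = np.random.default_rng(15)
        items = pd.DataFrame(
            {
                "a": rng.standard_normal(100),
                "b": rng.standard_normal(100),
                "flat": np.ones(100),
            }
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            val = cronbach_alpha(items)
        assert np.isfinite(val)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"only": [1.0, 2.0]}))


class TestGenotypePcs:
    def test_orthogonal_components_capture_structure(self):
        rng = np.random.default_rng(16)
        # two artificial subpopulations with shifted frequencies
        a = rng.binomial(2, 0.2, size=(100, 50))
        b = rng.binomial(2, 0.6, size=(100, 50))
        d = np.vstack([a, b]).astype(float)
        rows = [(f"rs{j}", "1", j * 100, "A", "G") for j in range(50)]
        panel = make_panel(rows, d)
        pcs = genotype_pcs(panel, n_components=2)
        labels = np.r_[np.zeros(100), np.ones(100)]
        assert abs(np.corrcoef(pcs[:, 0], labels)[0, 1]) > 0.9
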