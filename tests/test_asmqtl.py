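"""Association engine: INT, cis scan, secondary scan, phase 2, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import haplomethyl as hm
from haplomethyl.simulate import simulate_qtl_panel


class TestInverseNormalTransform:
    def test_three_values(self):
        # Phi^-1 at 5/6, 1/6, 1/2
        out = hm.inverse_normal_transform([5, 1, 3])
        assert out == pytest.approx([0.9674, -0.9674, 0.0], abs=1e-4)

    def test_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z = hm.inverse_normal_transform(x)
        assert np.all(np.diff(z[np.argsort(x)]) >= 0)

    def test_tie_at_median(self):
        assert hm.inverse_normal_transform([2, 2]) == pytest.approx([0.0, 0.0])

    def test_missing_preserved(self):
        out = hm.inverse_normal_transform([1.0, np.nan, 3.0])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(stats.norm.ppf(0.25))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            hm.inverse_normal_transform([1.0])


class TestCisScan:
    def test_agrees_with_statsmodels_ols(self):
        """Betas, SEs and p-values match a full multivariate OLS fit."""
        import statsmodels.api as sm

        rates, pos, geno, covar = simulate_qtl_panel(
            n_individuals=80, n_variants=5, causal_index=2, beta=0.5, seed=3
        )
        res = hm.cis_scan(rates, pos, geno, covar, min_obs=50)
        obs = rates.set_index(["sample", "haplotype"]).join(covar, how="inner")
        y = hm.inverse_normal_transform(obs["rate"].to_numpy())
        for _, row in res.associations.iterrows():
            g = geno.allele_matrix([row["variant_id"]], obs.index)[:, 0]
            X = sm.add_constant(
                np.column_stack([g, obs[covar.columns].to_numpy(dtype=float)])
            )
            fit = sm.OLS(y, X).fit()
            assert row["beta"] == pytest.approx(fit.params[1], rel=1e-8)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-8)
            assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_min_obs_skip(self):
        rates, pos, geno, covar = simulate_qtl_panel(n_individuals=49, n_variants=5,
                                                     seed=4)
        res = hm.cis_scan(rates, pos, geno, covar, min_obs=100)
        assert len(res.associations) == 0
        assert len(res.skipped) == 1
        assert "n_obs=98<100" in res.skipped["reason"].iloc[0]

    def test_window_excludes_distant_variants(self):
        rates, pos, geno, covar = simulate_qtl_panel(n_individuals=60, n_variants=8,
                                                     seed=5)
        geno.variants.loc[0, "pos"] = 10_000_000  # push one variant far away
        res = hm.cis_scan(rates, pos, geno, covar, min_obs=50)
        assert res.n_tests == 7

    def test_haplotype_label_swap_invariance(self):
        """Swapping P/M labels with the parental covariate updated leaves p unchanged."""
        rates, pos, geno, covar = simulate_qtl_panel(
            n_individuals=100, n_variants=4, causal_index=1, beta=0.4, seed=6
        )
        res1 = hm.cis_scan(rates, pos, geno, covar, min_obs=50)
        swapped = rates.copy()
        swapped["haplotype"] = swapped["haplotype"].map({"P": "M", "M": "P"})
        geno_sw = hm.HaplotypeGenotypes(
            geno.alleles[:, :, ::-1], geno.variants, geno.samples
        )
        res2 = hm.cis_scan(swapped, pos, geno_sw, covar, min_obs=50)
        a1 = res1.associations.set_index("variant_id")["p"]
        a2 = res2.associations.set_index("variant_id")["p"]
        assert np.allclose(a1, a2.loc[a1.index], rtol=1e-9)

    def test_int_absorbs_monotone_transform(self):
        rates, pos, geno, covar = simulate_qtl_panel(
            n_individuals=100, n_variants=4, causal_index=0, beta=0.5, seed=7
        )
        res1 = hm.cis_scan(rates, pos, geno, covar, min_obs=50)
        cubed = rates.assign(rate=rates["rate"] ** 3)  # monotone on any sign
        res2 = hm.cis_scan(cubed, pos, geno, covar, min_obs=50)
        assert np.allclose(
            res1.associations["beta"], res2.associations["beta"], rtol=1e-9
        )


class TestSecondaryScan:
    def test_recovers_second_variant(self):
        """Two independent planted effects: the secondary finds the second."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(1700 + rep)
            n = 400
            samples = [f"S{i}" for i in range(n)]
            alleles = (rng.random((10, n, 2)) < 0.35).astype(np.int8)
            variants = pd.DataFrame({
                "variant_id": [f"v{i}" for i in range(10)],
                "chrom": "chr1", "pos": np.arange(10) * 5000 + 20_000, "maf": 0.35,
            })
            geno = hm.HaplotypeGenotypes(alleles, variants, samples)
            pheno = pd.DataFrame({"age": rng.normal(50, 10, n)},
                                 index=pd.Index(samples, name="sample"))
            covar = hm.build_covariate_frame(pheno)
            idx = covar.index
            g2 = geno.allele_matrix(["v2", "v7"], idx)
            y = 0.6 * g2[:, 0] + 0.5 * g2[:, 1] + rng.normal(0, 1, len(idx))
            rates = pd.DataFrame({
                "target_id": "T0",
                "sample": idx.get_level_values("sample"),
                "haplotype": idx.get_level_values("haplotype"),
                "rate": y,
            })
            pos = pd.DataFrame([{"target_id": "T0", "chrom": "chr1",
                                 "start": 30_000, "end": 31_000}])
            scan = hm.cis_scan(rates, pos, geno, covar, min_obs=100)
            if len(scan.primaries) == 0:
                continue
            primary = scan.primaries.iloc[0]["variant_id"]
            sec = hm.secondary_scan("T0", primary, rates, pos, geno, covar,
                                    min_obs=100, alpha=scan.alpha)
            expected = {"v2", "v7"} - {primary}
            if sec is not None and sec.variant_id in expected:
                hits += 1
        assert hits >= 16  # >= 80% of reps

    def test_no_secondary_for_single_effect(self):
        rates, pos, geno, covar = simulate_qtl_panel(
            n_individuals=300, n_variants=8, causal_index=3, beta=0.6, seed=21
        )
        scan = hm.cis_scan(rates, pos, geno, covar)
        primary = scan.primaries.iloc[0]["variant_id"]
        sec = hm.secondary_scan("T0", primary, rates, pos, geno, covar,
                                alpha=scan.alpha)
        assert sec is None or sec.variant_id != primary

    def test_restriction_below_min_obs_returns_none(self):
        rates, pos, geno, covar = simulate_qtl_panel(
            n_individuals=80, n_variants=4, causal_index=0, beta=1.0, seed=22
        )
        sec = hm.secondary_scan("T0", "v0000", rates, pos, geno, covar, min_obs=150)
        assert sec is None


class TestPhase2Filter:
    def test_bh_hand_example(self):
        """BH at q=0.005 on [1e-6, 0.003, 0.8] keeps the first two."""
        from statsmodels.stats.multitest import multipletests

        rej, *_ = multipletests([1e-6, 0.003, 0.8], alpha=0.005, method="fdr_bh")
        assert list(rej) == [True, True, False]

    def test_empty_subset_all_fail(self):
        rates, pos, geno, covar = simulate_qtl_panel(
            n_individuals=150, n_variants=4, causal_index=0, beta=0.8, seed=23
        )
        scan = hm.cis_scan(rates, pos, geno, covar)
        cells = pd.DataFrame(columns=["neutrophils"])
        out = hm.phase2_filter(scan.primaries, rates, geno, covar, cells)
        assert not out["phase2_pass"].any()

    def test_true_effect_survives(self):
        rates, pos, geno, covar = simulate_qtl_panel(
            n_individuals=300, n_variants=5, causal_index=2, beta=0.8, seed=24
        )
        scan = hm.cis_scan(rates, pos, geno, covar)
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(
            {"neutrophils": rng.normal(4, 1, 150)},
            index=pd.Index([f"S{i:04d}" for i in range(150)], name="sample"),
        )
        out = hm.phase2_filter(scan.primaries, rates, geno, covar, cells)
        assert out["phase2_pass"].all()


class TestEffectConsistency:
    def test_equal_betas(self):
        table, frac = hm.effect_consistency([0.5], [0.3], [0.5], [0.4], n_ox=45)
        assert table["t"].iloc[0] == 0.0
        assert table["p"].iloc[0] == 1.0
        assert frac == 1.0

    def test_arithmetic(self):
        table, _ = hm.effect_consistency([0.5], [0.3], [0.0], [0.4], n_ox=45)
        assert table["t"].iloc[0] == pytest.approx(0.5 / np.sqrt(0.25))

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            hm.effect_consistency([0.5], [0.0], [0.5], [0.1], n_ox=45)

    def test_identical_truth_high_consistency(self):
        """Two cohorts estimating the same effects agree ~95% of the time."""
        rng = np.random.default_rng(23)
        n_pairs, true_beta = 300, rng.normal(0, 0.5, 300)
        se_a, se_b = 0.08, 0.03
        beta_a = true_beta + rng.normal(0, se_a, n_pairs)
        beta_b = true_beta + rng.normal(0, se_b, n_pairs)
        _, frac = hm.effect_consistency(
            beta_a, np.full(n_pairs, se_a), beta_b, np.full(n_pairs, se_b), n_ox=45
        )
        assert frac == pytest.approx(0.95, abs=0.04)
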