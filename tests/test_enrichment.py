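"""Distance thinning, LD proxies, matched resampling, GWA enrichment likelihood."""

import numpy as np
import pandas as pd
import pytest

import haplomethyl as hm
from haplomethyl.simulate import simulate_gwa_dataset


class TestThinByDistance:
    def test_hand_trace(self):
        variants = pd.DataFrame({
            "variant_id": ["a", "b", "c"],
            "chrom": "chr1",
            "pos": [1_000_000, 1_500_000, 2_500_000],
            "p": [1e-20, 1e-15, 1e-12],
        })
        out = hm.thin_by_distance(variants)
        assert list(out["variant_id"]) == ["a", "c"]

    def test_all_within_1mb_keeps_single_best(self):
        variants = pd.DataFrame({
            "variant_id": ["a", "b", "c"],
            "chrom": "chr1", "pos": [100, 200_000, 900_000],
            "p": [1e-5, 1e-9, 1e-7],
        })
        out = hm.thin_by_distance(variants)
        assert list(out["variant_id"]) == ["b"]

    def test_chromosomes_independent(self):
        variants = pd.DataFrame({
            "variant_id": ["a", "b"], "chrom": ["chr1", "chr2"],
            "pos": [100, 100], "p": [1e-5, 1e-5],
        })
        assert len(hm.thin_by_distance(variants)) == 2


class TestLdProxies:
    def make_geno(self, n=2000, seed=43):
        rng = np.random.default_rng(seed)
        lead = (rng.random((1, n, 2)) < 0.4).astype(np.int8)
        dup = lead.copy()
        flip = (1 - lead).astype(np.int8)
        indep = (rng.random((1, n, 2)) < 0.4).astype(np.int8)
        alleles = np.concatenate([lead, dup, flip, indep], axis=0)
        variants = pd.DataFrame({
            "variant_id": ["lead", "dup", "flip", "indep"],
            "chrom": "chr1", "pos": [100, 200, 300, 400], "maf": 0.4,
        })
        return hm.HaplotypeGenotypes(alleles, variants, [f"s{i}" for i in range(n)])

    def test_duplicate_and_flip_included_independent_excluded(self):
        geno = self.make_geno()
        proxies = hm.ld_proxies(geno, "lead")
        assert set(proxies) == {"lead", "dup", "flip"}

    def test_monomorphic_excluded(self):
        geno = self.make_geno()
        geno.alleles[3] = 0
        proxies = hm.ld_proxies(geno, "lead")
        assert "indep" not in proxies


class TestMatchedSampling:
    def make_pool(self, n, p_annot, rng):
        return pd.DataFrame({
            "variant_id": [f"p{i}" for i in range(n)],
            "chrom": rng.choice([f"chr{c}" for c in range(1, 8)], n),
            "pos": rng.integers(0, 240_000_000, n),
            "n_proxies": rng.integers(1, 40, n),
            "annotated": rng.random(n) < p_annot,
        })

    def test_whole_pool_annotation_fold_one(self):
        rng = np.random.default_rng(1)
        pool = self.make_pool(500, 1.0, rng)
        obs = self.make_pool(15, 1.0, rng)
        res = hm.matched_sampling_enrichment(obs, pool, n_resamples=300, seed=1)
        assert res.fold == 1.0
        assert res.p_value == 1.0

    def test_zero_overlap(self):
        rng = np.random.default_rng(2)
        pool = self.make_pool(500, 0.05, rng)
        obs = self.make_pool(15, 0.0, rng).assign(annotated=False)
        res = hm.matched_sampling_enrichment(obs, pool, n_resamples=300, seed=2)
        assert res.fold == 0.0
        assert res.p_value == 1.0

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(47)
        pool = self.make_pool(4000, 0.01, rng)
        obs = self.make_pool(30, 0.0, rng)
        obs["annotated"] = np.arange(len(obs)) < 3  # 10% vs 1% background
        res = hm.matched_sampling_enrichment(obs, pool, n_resamples=2000, seed=47)
        assert 5.0 <= res.fold <= 20.0
        assert res.p_value < 0.05

    def test_binomial_fallback_when_no_resample_reaches_x(self):
        rng = np.random.default_rng(3)
        pool = self.make_pool(2000, 0.001, rng)
        obs = self.make_pool(20, 0.0, rng)
        obs["annotated"] = np.arange(len(obs)) < 10
        res = hm.matched_sampling_enrichment(obs, pool, n_resamples=200, seed=3)
        assert res.p_value_method == "binomial"
        assert res.p_value < 1e-6


def toy_q(p_a=0.05, p_b=0.10, n_bins=5):
    return pd.DataFrame(
        {f: [1 - p_a - p_b, p_a, p_b] for f in range(n_bins)},
        index=["intronic", "A", "B"],
    )


class TestGwaEnrichmentFit:
    def test_likelihood_matches_product_formula(self):
        """Simplified per-signal log-likelihood equals the direct product form
        up to a constant, on tiny signals with small chi-squares."""
        q = toy_q()
        signals, background = simulate_gwa_dataset(
            q, {"intronic": 1.0, "A": 3.0, "B": 1.0}, n_signals=10,
            variants_per_signal=4, seed=11,
        )
        signals = signals.assign(chi2=signals["chi2"] / 10.0)  # keep exp() finite
        fit = hm.fit_gwa_enrichment(signals, background, n_bins=5)
        bins = hm.assign_frequency_bins(signals, 5)
        annotations = fit.annotations
        a_index = {a: i for i, a in enumerate(annotations)}
        q_hat = fit.q_hat.to_numpy()

        def direct_loglik(e_vec):
            total = 0.0
            for sid, grp in signals.groupby("signal_id"):
                f = int(bins.loc[sid])
                denom = float(q_hat[:, f] @ e_vec)
                qs = np.array([q_hat[a_index[a], f] for a in grp["annotation"]])
                es = np.array([e_vec[a_index[a]] for a in grp["annotation"]])
                chi2 = grp["chi2"].to_numpy()
                prod_all_q = np.prod(qs)
                s = sum(
                    np.exp(c) * (e * qv / denom) * prod_all_q / qv
                    for c, e, qv in zip(chi2, es, qs)
                )
                total += np.log(s)
            return total

        def simplified(e_vec):
            total = 0.0
            for sid, grp in signals.groupby("signal_id"):
                f = int(bins.loc[sid])
                chi2 = grp["chi2"].to_numpy()
                w = np.exp(chi2 - chi2.max())
                es = np.array([e_vec[a_index[a]] for a in grp["annotation"]])
                total += np.log(w @ es) - np.log(q_hat[:, f] @ e_vec)
            return total

        e1 = np.array([1.0, 2.0, 0.5])
        e2 = np.array([1.0, 1.0, 1.0])
        # likelihood *differences* must agree exactly (constants cancel)
        assert direct_loglik(e1) - direct_loglik(e2) == pytest.approx(
            simplified(e1) - simplified(e2), abs=1e-10
        )

    def test_chi2_shift_invariance(self):
        q = toy_q()
        signals, background = simulate_gwa_dataset(
            q, {"intronic": 1.0, "A": 4.0, "B": 1.0}, n_signals=200, seed=13
        )
        fit1 = hm.fit_gwa_enrichment(signals, background)
        shifted = signals.copy()
        shifted["chi2"] = shifted.groupby("signal_id")["chi2"].transform(
            lambda s: s + 500.0
        )
        fit2 = hm.fit_gwa_enrichment(shifted, background)
        assert np.allclose(fit1.e_hat, fit2.e_hat, rtol=1e-6)

    def test_signal_order_invariance(self):
        q = toy_q()
        signals, background = simulate_gwa_dataset(
            q, {"intronic": 1.0, "A": 4.0, "B": 1.0}, n_signals=100, seed=17
        )
        fit1 = hm.fit_gwa_enrichment(signals, background)
        fit2 = hm.fit_gwa_enrichment(
            signals.sample(frac=1.0, random_state=5), background
        )
        assert np.allclose(fit1.e_hat, fit2.e_hat, rtol=1e-6)

    def test_baseline_fixed_at_one(self):
        q = toy_q()
        signals, background = simulate_gwa_dataset(
            q, {"intronic": 1.0, "A": 2.0, "B": 0.5}, n_signals=100, seed=19
        )
        fit = hm.fit_gwa_enrichment(signals, background)
        assert fit.e_hat["intronic"] == 1.0
        assert fit.baseline == "intronic"

    def test_recovery_and_null(self):
        q = toy_q()
        sig, bg = simulate_gwa_dataset(q, {"intronic": 1, "A": 5.0, "B": 1.0},
                                       n_signals=600, seed=53)
        fit = hm.fit_gwa_enrichment(sig, bg)
        assert 3.0 <= fit.e_hat["A"] <= 7.0
        sig0, bg0 = simulate_gwa_dataset(q, {"intronic": 1, "A": 1.0, "B": 1.0},
                                         n_signals=600, seed=59)
        fit0 = hm.fit_gwa_enrichment(sig0, bg0)
        assert 0.7 <= fit0.e_hat["A"] <= 1.4


class TestSimulateGwaDataset:
    def test_single_annotation_all_causal(self):
        q = pd.DataFrame({f: [1.0] for f in range(5)}, index=["only"])
        signals, _ = simulate_gwa_dataset(q, {"only": 1.0}, n_signals=20, seed=1)
        assert set(signals["annotation"]) == {"only"}

    def test_neutral_enrichment_matches_background(self):
        """All E = 1: causal annotations distributed as q-hat (chi2 GoF)."""
        from scipy import stats

        q = toy_q(0.2, 0.3)
        signals, _ = simulate_gwa_dataset(
            q, {"intronic": 1.0, "A": 1.0, "B": 1.0}, n_signals=2000, seed=3
        )
        causal = signals[signals["is_lead"]]["annotation"].value_counts()
        observed = np.array([causal.get(a, 0) for a in q.index])
        expected = q[0].to_numpy() * len(signals[signals["is_lead"]])
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_analytic_causal_fraction(self):
        """E_A = 10, q_A = 0.01: causal fraction ~ 0.1/(0.1+0.99) = 0.092."""
        q = pd.DataFrame({f: [0.99, 0.01] for f in range(5)},
                         index=["base", "A"])
        signals, _ = simulate_gwa_dataset(q, {"base": 1.0, "A": 10.0},
                                          n_signals=2000, seed=5)
        frac = (signals[signals["is_lead"]]["annotation"] == "A").mean()
        expected = 10 * 0.01 / (10 * 0.01 + 0.99)
        se = np.sqrt(expected * (1 - expected) / 2000)
        assert abs(frac - expected) < 4 * se

    def test_too_few_signals_rejected(self):
        q = toy_q()
        with pytest.raises(ValueError):
            simulate_gwa_dataset(q, {"intronic": 1, "A": 1, "B": 1}, n_signals=3)
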