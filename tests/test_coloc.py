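"""Wakefield ABFs, coloc posterior enumeration, SMR and HEIDI."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from proxygwas.coloc import (coloc_posteriors, heidi_test, smr_heidi_screen,
                             smr_test, wakefield_log_abf, weighted_chi2_sf)
from proxygwas.simulate import simulate_summary_region


class TestWakefield:
    def test_null_effect_shrinks_evidence(self):
        se, W = 0.1, 0.15 ** 2
        r = W / (se ** 2 + W)
        labf = wakefield_log_abf(0.0, se)
        assert labf == pytest.approx(0.5 * np.log(1 - r))
        assert labf < 0

    def test_point_null_prior_limit(self):
        assert wakefield_log_abf(0.3, 0.1, prior_sd=1e-9) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_extended_precision_formula(self):
        beta, se, prior_sd = 0.042, 0.0137, 0.15
        W = np.longdouble(prior_sd) ** 2
        se_l = np.longdouble(se)
        r = W / (se_l ** 2 + W)
        z2 = (np.longdouble(beta) / se_l) ** 2
        oracle = 0.5 * (np.log1p(-r) + r * z2)
        assert wakefield_log_abf(beta, se, prior_sd) == pytest.approx(float(oracle), abs=1e-12)

    def test_non_positive_se_rejected(self):
        with pytest.raises(ValueError):
            wakefield_log_abf(0.1, 0.0)


def _coloc_oracle(l1, l2, p1, p2, p12):
    """Exhaustive enumeration over causal-placement pairs for tiny regions."""
    m = len(l1)
    w = {h: 0.0 for h in ("H0", "H1", "H2", "H3", "H4")}
    w["H0"] = 1.0
    for i in range(m):
        w["H1"] += p1 * np.exp(l1[i])
        w["H2"] += p2 * np.exp(l2[i])
        w["H4"] += p12 * np.exp(l1[i] + l2[i])
    for i, j in itertools.product(range(m), repeat=2):
        if i != j:
            w["H3"] += p1 * p2 * np.exp(l1[i] + l2[j])
    total = sum(w.values())
    return {h: v / total for h, v in w.items()}


class TestColocPosteriors:
    def test_flat_evidence_favours_null(self):
        res = coloc_posteriors(np.zeros(100), np.zeros(100))
        assert max(res.pp, key=res.pp.get) == "H0"
        assert res.pp["H0"] > 0.9

    def test_single_strong_shared_snp_colocalises(self):
        l1 = np.zeros(20)
        l2 = np.zeros(20)
        l1[7] = l2[7] = 30.0
        res = coloc_posteriors(l1, l2)
        assert res.pp["H4"] > 0.75
        assert res.colocalised

    def test_three_snp_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            l1 = rng.normal(0, 5, 3)
            l2 = rng.normal(0, 5, 3)
            res = coloc_posteriors(l1, l2)
            oracle = _coloc_oracle(l1, l2, 1e-4, 1e-4, 1e-5)
            for h in res.pp:
                assert res.pp[h] == pytest.approx(oracle[h], abs=1e-10)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        res = coloc_posteriors(rng.normal(0, 10, 50), rng.normal(0, 10, 50))
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_common_prior_scaling_preserves_alternative_ratios(self):
        rng = np.random.default_rng(2)
        l1, l2 = rng.normal(0, 3, 10), rng.normal(0, 3, 10)
        a = coloc_posteriors(l1, l2, 1e-4, 1e-4, 1e-5)
        b = coloc_posteriors(l1, l2, 3e-4, 3e-4, 3e-5)
        for h1, h2 in itertools.combinations(("H1", "H2", "H4"), 2):
            assert a.pp[h1] / a.pp[h2] == pytest.approx(b.pp[h1] / b.pp[h2], rel=1e-6)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            coloc_posteriors(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            coloc_posteriors(np.array([]), np.array([]))

    def test_scenario_simulations_recover_each_hypothesis(self):
        expect = {"shared-causal": "H4", "distinct-causal": "H3", "null": "H0",
                  "gwas-only": "H1"}
        for scenario, hyp in expect.items():
            wins = 0
            for seed in range(10):
                region = simulate_summary_region(50, 3.0, scenario, seed=seed)
                labf1 = wakefield_log_abf(region.gwas["beta"].to_numpy(),
                                          region.gwas["se"].to_numpy())
                labf2 = wakefield_log_abf(region.eqtl["beta"].to_numpy(),
                                          region.eqtl["se"].to_numpy())
                res = coloc_posteriors(labf1, labf2)
                wins += max(res.pp, key=res.pp.get) == hyp
            assert wins >= 9, scenario


class TestSmr:
    def test_symmetric_z_halves_the_chi_square(self):
        res = smr_test(3.0, 3.0, 0.3, 0.2)
        assert res.stat == pytest.approx(4.5)
        assert res.p == pytest.approx(stats.chi2.sf(4.5, 1))
        assert res.b_xy == pytest.approx(1.5)

    def test_strong_instrument_limit(self):
        res = smr_test(4.0, 1e6, 0.1, 1.0)
        assert res.stat == pytest.approx(16.0, rel=1e-6)

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    def test_harmonic_mean_bound(self, zg, ze):
        res = smr_test(zg, ze, 1.0, 1.0)
        assert res.stat <= min(zg ** 2, ze ** 2) + 1e-12

    def test_zero_eqtl_z_rejected(self):
        with pytest.raises(ValueError):
            smr_test(1.0, 0.0, 0.1, 0.0)


class TestWeightedChi2:
    @pytest.mark.parametrize("k", [1, 3, 6])
    @pytest.mark.parametrize("x", [0.5, 4.0, 20.0])
    def test_equal_weights_reduce_to_chi2(self, k, x):
        assert weighted_chi2_sf(x, np.ones(k)) == pytest.approx(
            stats.chi2.sf(x, k), abs=1e-6)

    def test_zero_weight_vector_and_zero_x(self):
        assert weighted_chi2_sf(4.0, np.zeros(3)) == 1.0
        assert weighted_chi2_sf(0.0, np.ones(3)) == 1.0


class TestHeidi:
    def _region(self, n=30, decay=20.0, scenario="shared-causal", seed=0):
        return simulate_summary_region(n, decay, scenario, seed=seed)

    def test_proportional_effects_are_perfectly_homogeneous(self):
        region = self._region()
        b_e = region.eqtl["beta"].to_numpy()
        b_g = 2.0 * b_e  # exact shared mediation, no noise in the ratio
        top = int(np.argmax(np.abs(b_e / region.eqtl["se"])))
        res = heidi_test(b_g, region.gwas["se"].to_numpy(), b_e,
                         region.eqtl["se"].to_numpy(), region.ld, top)
        assert res.tested
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_distinct_causal_variants_in_moderate_ld_rejected(self):
        """Two distinct causal variants whose LD (r^2 ~ 0.2) places discordant
        instruments inside the eligibility window: HEIDI should reject
        homogeneity in >= 90% of seeds at the simulated effect scale."""
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            region = self._region(scenario="distinct-causal", seed=seed)
            z_e = (region.eqtl["beta"] / region.eqtl["se"]).to_numpy()
            top = int(np.argmax(np.abs(z_e)))
            res = heidi_test(region.gwas["beta"].to_numpy(),
                             region.gwas["se"].to_numpy(),
                             region.eqtl["beta"].to_numpy(),
                             region.eqtl["se"].to_numpy(), region.ld, top)
            rejections += res.tested and res.p < 0.05
        assert rejections >= 0.9 * n_seeds

    def test_too_few_eligible_snps_yields_no_test(self):
        region = simulate_summary_region(4, 0.2, "shared-causal", seed=1)
        z_e = (region.eqtl["beta"] / region.eqtl["se"]).to_numpy()
        top = int(np.argmax(np.abs(z_e)))
        res = heidi_test(region.gwas["beta"].to_numpy(), region.gwas["se"].to_numpy(),
                         region.eqtl["beta"].to_numpy(), region.eqtl["se"].to_numpy(),
                         region.ld, top)
        assert not res.tested
        assert np.isnan(res.p)


class TestJointScreen:
    def test_smr_heidi_rule_separates_pleiotropy_from_linkage(self):
        """FDR-corrected SMR < 5% AND HEIDI > 5% flags shared-causal regions
        and spares distinct-causal regions with separated variants."""
        regions = {}
        for seed in range(10):
            r = simulate_summary_region(50, 3.0, "shared-causal", seed=seed)
            regions[f"shared_{seed}"] = (r.gwas, r.eqtl, r.ld)
            r = simulate_summary_region(50, 3.0, "distinct-causal", seed=seed)
            regions[f"distinct_{seed}"] = (r.gwas, r.eqtl, r.ld)
        df = smr_heidi_screen(regions).set_index("region")
        shared_rate = np.mean([df.loc[f"shared_{s}", "pleiotropic"] for s in range(10)])
        distinct_rate = np.mean([df.loc[f"distinct_{s}", "pleiotropic"] for s in range(10)])
        assert shared_rate >= 0.9
        assert distinct_rate <= 0.1
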