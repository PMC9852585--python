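"""Replication power formulas, one-sided FDR replication and the sign test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from proxygwas.datasets import REPLICATION_PANEL_N, load_replication_panel
from proxygwas.replication import (benjamini_hochberg, expected_replication_pvalue,
                                   one_sided_replication_pvalue,
                                   predicted_replication_se, select_replicable,
                                   sign_test)
from proxygwas.replication import test_replication as run_replication


class TestPredictedSe:
    def test_panel_lead_snp_value(self):
        # freq 0.58 in 17,787 directly measured participants -> 0.011 at 3 dp
        se = predicted_replication_se(0.58, REPLICATION_PANEL_N)
        assert se == pytest.approx(0.0107, abs=5e-5)
        assert round(se, 3) == 0.011

    def test_tiny_sample_closed_form(self):
        assert predicted_replication_se(0.5, 2) == pytest.approx(1.0)

    @pytest.mark.parametrize("freq", [0.0, 1.0])
    def test_fixed_allele_rejected(self, freq):
        with pytest.raises(ValueError):
            predicted_replication_se(freq, 1000)

    @given(st.floats(0.01, 0.99), st.integers(10, 10**6))
    def test_symmetry_and_monotonicity(self, freq, n):
        assert predicted_replication_se(freq, n) == \
            pytest.approx(predicted_replication_se(1 - freq, n), rel=1e-12)
        assert predicted_replication_se(freq, 2 * n) < predicted_replication_se(freq, n)


class TestExpectedPvalue:
    def test_zero_effect_is_half(self):
        assert expected_replication_pvalue(0.0, 0.1) == pytest.approx(0.5)

    def test_normal_quantile_identity(self):
        assert expected_replication_pvalue(1.6449, 1.0) == pytest.approx(0.05, abs=1e-4)

    def test_composition_with_predicted_se(self):
        se = predicted_replication_se(0.58, 18_000)
        assert expected_replication_pvalue(0.022, se) == pytest.approx(0.0197, abs=5e-4)

    def test_non_positive_se_rejected(self):
        with pytest.raises(ValueError):
            expected_replication_pvalue(0.1, 0.0)


class TestSelectReplicable:
    def _records(self):
        return pd.DataFrame({"rsid": ["a", "b"], "beta_disc": [0.022, 0.001],
                             "freq1": [0.58, 0.3]})

    def test_pmax_limits(self):
        assert len(select_replicable(self._records(), 18_000, 1.0)) == 2
        assert len(select_replicable(self._records(), 18_000, 0.0)) == 0

    def test_strong_record_selected_weak_not(self):
        out = select_replicable(self._records(), 18_000, 0.05)
        assert list(out["rsid"]) == ["a"]


class TestOneSidedPvalue:
    def test_zero_replication_effect_is_half(self):
        assert one_sided_replication_pvalue(0.5, 0.0, 0.1) == pytest.approx(0.5)

    def test_concordant_negative_pair(self):
        # z = 3.18 in the discovery direction
        p = one_sided_replication_pvalue(-0.018, -0.035, 0.011)
        assert p == pytest.approx(7.3e-4, rel=0.05)

    def test_opposite_sign_symmetry(self):
        p = one_sided_replication_pvalue(1.0, -0.2, 0.1)
        assert p == pytest.approx(stats.norm.cdf(2.0), abs=1e-12)

    @given(st.floats(1e-4, 0.1), st.floats(1e-4, 0.1),
           st.sampled_from([1, -1]), st.sampled_from([1, -1]))
    def test_below_half_iff_directions_agree(self, bd, br, sd, sr):
        bd, br = sd * bd, sr * br
        p = one_sided_replication_pvalue(bd, br, 0.05)
        assert (p < 0.5) == (np.sign(bd) == np.sign(br))


def _bh_oracle(p):
    """q_i = min over thresholds t in {p_j >= p_i} of t * m / #{p <= t}."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [t * m / np.sum(p <= t) for t in p if t >= pi]
        q[i] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_passthrough(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), _bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_q_dominates_p_and_is_monotone(self, p):
        q = benjamini_hochberg(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        np.testing.assert_allclose(benjamini_hochberg(p),
                                   multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestSignTest:
    def test_nineteen_of_twentyseven(self):
        p = sign_test(19, 27)
        assert p == pytest.approx(0.0261, abs=5e-5)
        assert round(p, 2) == 0.03

    def test_all_consistent(self):
        assert sign_test(27, 27) == pytest.approx(2.0 ** -27, rel=1e-9)

    def test_median_count_brute_force(self):
        from math import comb

        oracle = sum(comb(27, j) for j in range(14, 28)) / 2 ** 27
        assert sign_test(14, 27) == pytest.approx(oracle, rel=1e-12)
        assert sign_test(14, 27) == pytest.approx(0.5, abs=1e-4)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            sign_test(28, 27)


class TestTestReplication:
    def test_zero_replication_effects_nothing_replicates(self):
        disc = pd.DataFrame({"rsid": ["a", "b"], "beta_disc": [0.1, -0.2]})
        repl = pd.DataFrame({"rsid": ["a", "b"], "beta_repl": [0.0, 0.0],
                             "se_repl": [0.05, 0.05]})
        out = run_replication(disc, repl)
        assert out.n_replicated == 0
        assert out.n_consistent == 0          # zero betas are strict ties
        assert out.sign_test_p == pytest.approx(1.0)

    def test_panel_recount_gives_nineteen_consistent(self):
        panel = load_replication_panel()
        out = run_replication(panel[["rsid", "beta_disc"]],
                               panel[["rsid", "beta_repl", "se_repl"]])
        assert out.n_tested == 27
        assert out.n_consistent == 19

    def test_unmatched_records_listed(self):
        disc = pd.DataFrame({"rsid": ["a", "b"], "beta_disc": [0.1, 0.2]})
        repl = pd.DataFrame({"rsid": ["a"], "beta_repl": [0.2], "se_repl": [0.1]})
        out = run_replication(disc, repl)
        assert out.unmatched == ["b"]
        assert out.n_tested == 1

    def test_large_replication_cohort_replicates_causal_records(self):
        """Power -> 1: with truth-level effects and a big replication panel,
        every causal record replicates and effects are attenuation-free."""
        from proxygwas.assoc import preprocess_phenotype, run_gwas
        from proxygwas.simulate import (SimulationConfig, simulate_cohort,
                                        simulate_replication_cohort)

        cfg = SimulationConfig(n_total=200, n_measured=100, m_variants=12,
                               n_causal=2, effect_sizes=(0.35, 0.35),
                               n_replication=15_000, seed=23)
        _, _, truth = simulate_cohort(cfg)
        repl, geno = simulate_replication_cohort(cfg, truth)
        pheno = preprocess_phenotype(
            repl.table["fat_mass"].to_numpy(), repl.table[repl.covariate_cols],
            repl.table["sex"].to_numpy())
        table, _ = run_gwas(geno, pheno)
        disc = pd.DataFrame({
            "rsid": truth.causal_ids,
            "beta_disc": truth.std_marginal_target("fat_mass", "F"),
        })
        stats_tab = table.rename(columns={"beta1": "beta_repl", "se": "se_repl"})
        out = run_replication(disc, stats_tab[["rsid", "beta_repl", "se_repl"]])
        assert out.n_replicated == out.n_tested == 2


class TestAttenuation:
    def test_partial_mediation_shrinks_discovery_effects(self):
        """With delta < 1 the imputed-trait discovery effect is attenuated
        relative to the directly measured replication effect."""
        from proxygwas.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_total=100, n_measured=50, m_variants=10,
                               n_causal=3, effect_sizes=(0.3, 0.3, 0.3),
                               mediation_fractions=(0.3, 0.5, 0.7), seed=31)
        _, _, truth = simulate_cohort(cfg)
        for sex in ("F", "M"):
            imputed = np.abs(truth.std_marginal_imputed("fat_mass", sex))
            measured = np.abs(truth.std_marginal_target("fat_mass", sex))
            assert np.all(imputed < measured)
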