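"""Tests of the comparative statistics and the MCMC machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecmscreen import (
    EffectsTableSpec,
    HierarchicalModelSpec,
    fit_hierarchical_growth_model,
    fit_ic50_difference_model,
    gen_effects_table,
    sign_test_two_sided,
    welch_t_test,
)
from ecmscreen.sampler import sample_mwg
from ecmscreen.simulation import gen_ic50_replicates

CONTRAST = ("plate", "Softwell 2 kPa", "Softwell 0.2 kPa")
CONTRAST_KEY = "contrast[plate:Softwell 2 kPa-Softwell 0.2 kPa]"
FAST = dict(chains=2, warmup=300, draws=600)


def enumerate_sign_test(n: int, k: int) -> float:
    """Oracle: exact p by enumerating all 2^n equiprobable sign patterns."""
    counts = np.zeros(n + 1)
    for pattern in itertools.product([0, 1], repeat=n):
        counts[sum(pattern)] += 1
    probs = counts / 2**n
    return min(1.0, 2 * min(probs[: k + 1].sum(), probs[k:].sum()))


class TestSignTest:
    def test_eight_concordant_matches_study_headline(self):
        """8/8 comparisons in one direction: p = 2*(1/2)^8 = 0.0078125,
        i.e. 0.008 at three decimals."""
        res = sign_test_two_sided([0.1] * 8)
        assert res.n == 8 and res.k == 8
        assert res.p_two_sided == 0.0078125
        assert round(res.p_two_sided, 3) == 0.008

    def test_balanced_pair_capped_at_one(self):
        assert sign_test_two_sided([1.0, -1.0]).p_two_sided == 1.0

    def test_six_concordant_closed_form(self):
        assert sign_test_two_sided([-1] * 6).p_two_sided == pytest.approx(0.03125)

    def test_ties_dropped_and_all_ties_rejected(self):
        res = sign_test_two_sided([1, 0, 0, -1, 1])
        assert res.n == 3 and res.k == 2
        with pytest.raises(ValueError, match="ties"):
            sign_test_two_sided([0.0, 0.0])

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 12])
    def test_agrees_with_pattern_enumeration(self, n):
        for k in range(n + 1):
            deltas = [1.0] * k + [-1.0] * (n - k)
            assert sign_test_two_sided(deltas).p_two_sided == pytest.approx(
                enumerate_sign_test(n, k), abs=1e-12
            )


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p_two_sided == 1.0

    def test_hand_computed_equal_variance_case(self):
        """(1..5) vs (2..6): s^2 = 2.5 each, t = -1/sqrt(1) = -1, df = 8."""
        res = welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.t == pytest.approx(-1.0)
        assert res.df == pytest.approx(8.0)
        assert res.p_two_sided == pytest.approx(0.3466, abs=1e-4)

    def test_antisymmetric_in_arguments(self):
        a, b = [1.0, 2.5, 3.1], [0.2, 0.9, 4.0, 5.5]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_reduces_to_pooled_t_when_variances_equal(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 11.0, 12.0, 13.0]
        res = welch_t_test(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_t_test([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match=">= 2"):
            welch_t_test([1.0], [1.0, 2.0])


class TestSampler:
    def gaussian_logpost(self, mean, sd):
        mean, sd = np.asarray(mean), np.asarray(sd)

        def logpost(X):
            return -0.5 * np.sum(((X - mean) / sd) ** 2, axis=1)

        return logpost

    def test_recovers_gaussian_moments(self):
        res = sample_mwg(
            self.gaussian_logpost([1.0, -2.0], [0.5, 2.0]), np.zeros(2),
            n_chains=4, warmup=500, draws=2000, seed=0,
        )
        flat = res.samples.reshape(-1, 2)
        np.testing.assert_allclose(flat.mean(axis=0), [1.0, -2.0], atol=0.1)
        np.testing.assert_allclose(flat.std(axis=0), [0.5, 2.0], rtol=0.1)

    def test_seed_determinism(self):
        kw = dict(n_chains=2, warmup=100, draws=200, seed=3)
        a = sample_mwg(self.gaussian_logpost([0.0], [1.0]), np.zeros(1), **kw)
        b = sample_mwg(self.gaussian_logpost([0.0], [1.0]), np.zeros(1), **kw)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            sample_mwg(self.gaussian_logpost([0.0], [1.0]), np.zeros(1), n_chains=1)


class TestHierarchicalModel:
    def test_recovers_planted_contrast_within_its_ci(self):
        table, truth = gen_effects_table(EffectsTableSpec(seed=3))
        true_contrast = (
            truth["plate_effects"]["Softwell 2 kPa"] - truth["plate_effects"]["Softwell 0.2 kPa"]
        )
        post = fit_hierarchical_growth_model(
            table, HierarchicalModelSpec(contrasts=(CONTRAST,), seed=5, **FAST)
        )
        row = post[CONTRAST_KEY]
        assert row["ci_lo"] <= true_contrast <= row["ci_hi"]

    def test_zero_noise_contrast_is_deterministic_difference(self):
        spec = EffectsTableSpec(
            exp_sd=0.0,
            residual_sd_by_plate={"Plastic": 0.0, "Softwell 0.2 kPa": 0.0, "Softwell 2 kPa": 0.0},
            seed=1,
        )
        table, truth = gen_effects_table(spec)
        post = fit_hierarchical_growth_model(
            table, HierarchicalModelSpec(contrasts=(CONTRAST,), seed=2, **FAST)
        )
        true_contrast = (
            truth["plate_effects"]["Softwell 2 kPa"] - truth["plate_effects"]["Softwell 0.2 kPa"]
        )
        assert post[CONTRAST_KEY]["mean"] == pytest.approx(true_contrast, abs=1e-4)

    def test_duplicate_seeded_runs_identical(self):
        table, _ = gen_effects_table(EffectsTableSpec(seed=0))
        spec = HierarchicalModelSpec(seed=9, **FAST)
        a = fit_hierarchical_growth_model(table, spec)
        b = fit_hierarchical_growth_model(table, spec)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_absent_contrast_level_named_in_error(self):
        table, _ = gen_effects_table(EffectsTableSpec(seed=0))
        with pytest.raises(ValueError, match="Softwell 20 kPa"):
            fit_hierarchical_growth_model(
                table,
                HierarchicalModelSpec(
                    contrasts=(("plate", "Softwell 20 kPa", "Plastic"),), **FAST
                ),
            )

    def test_missing_column_and_single_experiment_rejected(self):
        table, _ = gen_effects_table(EffectsTableSpec(seed=0))
        with pytest.raises(ValueError, match="missing required column"):
            fit_hierarchical_growth_model(table.drop(columns=["plate"]))
        single = table[table["experiment"] == "exp00"]
        with pytest.raises(ValueError, match="experiments"):
            fit_hierarchical_growth_model(single)

    def test_intercept_approaches_grand_mean_as_priors_widen(self):
        table, _ = gen_effects_table(EffectsTableSpec(seed=6))
        # the balanced design puts the likelihood peak of the reference-cell
        # mean structure at the data; with very wide priors the posterior
        # mean of mu must sit near the reference-group grand value
        wide = fit_hierarchical_growth_model(
            table, HierarchicalModelSpec(prior_scale_mult=100.0, seed=4, **FAST)
        )
        narrow = fit_hierarchical_growth_model(
            table, HierarchicalModelSpec(prior_scale_mult=1.0, seed=4, **FAST)
        )
        ref_mean = table[(table.cell == "HCT116") & (table.plate == "Plastic")]["rate"].mean()
        sd_y = table["rate"].std()
        assert abs(wide["mu"]["mean"] - ref_mean) < 0.5 * sd_y
        assert abs(wide["mu"]["mean"] - ref_mean) <= abs(narrow["mu"]["mean"] - ref_mean) + 0.1 * sd_y


class TestIC50DifferenceModel:
    def test_identical_ic50s_fold_change_near_one(self):
        rows = [{"cell": "HCT116", "o2": o2, "ic50_uM": 0.3}
                for o2 in ("21", "0.1") for _ in range(5)]
        post = fit_ic50_difference_model(pd.DataFrame(rows), seed=1, **FAST)
        fold = post["fold_change[HCT116:0.1-vs-21]"]
        assert fold["mean"] == pytest.approx(1.0, abs=0.05)

    def test_single_cell_two_o2_levels_one_delta(self):
        table = gen_ic50_replicates(seed=3)
        post = fit_ic50_difference_model(table, seed=3, **FAST)
        deltas = [n for n in post.summary.index if n.startswith("delta[")]
        assert deltas == ["delta[HCT116:0.1-vs-21]"]

    def test_planted_fold_change_recovered(self):
        table = gen_ic50_replicates(fold_change=1.7, seed=12)
        post = fit_ic50_difference_model(table, seed=12, **FAST)
        fold = post["fold_change[HCT116:0.1-vs-21]"]
        assert fold["ci_lo"] <= 1.7 <= fold["ci_hi"]

    def test_censored_inputs_excluded_with_warning(self):
        table = gen_ic50_replicates(seed=5)
        table.loc[0, "ic50_uM"] = -1.0
        with pytest.warns(UserWarning, match="excluding"):
            fit_ic50_difference_model(table, seed=5, **FAST)

    def test_insufficient_replicates_rejected(self):
        rows = [
            {"cell": "HCT116", "o2": "21", "ic50_uM": 0.3},
            {"cell": "HCT116", "o2": "21", "ic50_uM": 0.4},
            {"cell": "HCT116", "o2": "0.1", "ic50_uM": 0.5},
        ]
        with pytest.raises(ValueError, match="replicates"):
            fit_ic50_difference_model(pd.DataFrame(rows))
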