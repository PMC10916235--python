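"""MR estimators against independent oracles, plus routing and FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from targetmr import mr
from targetmr.errors import (EstimationError, InsufficientInstrumentsError,
                             ParameterError, UsageError, ValidationError)
from targetmr.types import Instrument

from conftest import (random_instruments, weighted_median_oracle,
                      wls_intercept_oracle, wls_origin_oracle)


def _iv(bx, by, sx=0.05, so=0.04, snp="rs1"):
    return Instrument(gene="G", snp_id=snp, beta_exp=bx, se_exp=sx,
                      beta_out=by, se_out=so, eaf_exp=0.3, eaf_out=0.3,
                      n_exp=30_000, n_out=150_000)


class TestWaldRatio:
    def test_identity_case(self):
        est = mr.wald_ratio(_iv(0.4, 0.4, sx=0.05, so=0.05))
        assert est.beta == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        est = mr.wald_ratio(_iv(0.5, 0.13, sx=0.05, so=0.04))
        assert est.beta == pytest.approx(0.26)
        assert est.se == pytest.approx(0.08)

    def test_second_order_term_adds_variance(self):
        first = mr.wald_ratio(_iv(0.5, 0.13, sx=0.05, so=0.04))
        second = mr.wald_ratio(_iv(0.5, 0.13, sx=0.05, so=0.04),
                               second_order=True)
        expected = math.sqrt(0.04 ** 2 / 0.25 + 0.13 ** 2 * 0.05 ** 2 / 0.5 ** 4)
        assert second.se == pytest.approx(expected)
        assert second.se > first.se

    def test_zero_exposure_beta_is_degenerate(self):
        with pytest.raises(EstimationError):
            mr.wald_ratio(_iv(0.0, 0.1))


class TestIvw:
    def test_equal_weight_case_is_mean_of_ratios(self):
        ivs = [_iv(0.4, 0.08, so=0.03, snp="rs1"),
               _iv(0.4, 0.12, so=0.03, snp="rs2")]
        est = mr.ivw(ivs)
        assert est.beta == pytest.approx((0.2 + 0.3) / 2)

    def test_single_instrument_rejected(self):
        with pytest.raises(UsageError):
            mr.ivw([_iv(0.4, 0.1)])

    def test_matches_wls_origin_oracle_to_1e12(self, rng):
        for _ in range(50):
            ivs = random_instruments(rng, int(rng.integers(2, 10)))
            est = mr.ivw(ivs)
            beta, se = wls_origin_oracle([iv.beta_exp for iv in ivs],
                                         [iv.beta_out for iv in ivs],
                                         [iv.se_out for iv in ivs])
            assert est.beta == pytest.approx(beta, abs=1e-12)
            assert est.se == pytest.approx(se, abs=1e-12)

    def test_random_effects_never_deflates_se(self, rng):
        ivs = random_instruments(rng, 8)
        assert mr.ivw(ivs, model="random").se >= mr.ivw(ivs, model="fixed").se

    def test_duplicated_instrument_equals_wald_ratio(self):
        iv = _iv(0.5, 0.13)
        dup = _iv(0.5, 0.13, snp="rs2")
        assert mr.ivw([iv, dup]).beta == pytest.approx(mr.wald_ratio(iv).beta)


class TestEgger:
    def test_matches_normal_equations_oracle_to_1e12(self, rng):
        for _ in range(50):
            ivs = random_instruments(rng, int(rng.integers(3, 12)))
            slope, intercept = mr.mr_egger(ivs)
            bx = np.array([iv.beta_exp for iv in ivs])
            flip = np.where(bx < 0, -1.0, 1.0)
            coef, se = wls_intercept_oracle(
                bx * flip,
                np.array([iv.beta_out for iv in ivs]) * flip,
                [iv.se_out for iv in ivs])
            assert slope.beta == pytest.approx(coef[1], abs=1e-12)
            assert slope.se == pytest.approx(se[1], abs=1e-12)
            assert intercept.beta == pytest.approx(coef[0], abs=1e-12)

    def test_intercept_centered_on_zero_without_pleiotropy(self, rng):
        intercepts = []
        for _ in range(300):
            intercepts.append(mr.mr_egger(random_instruments(rng, 8))[1].beta)
        mcse = np.std(intercepts) / math.sqrt(len(intercepts))
        assert abs(np.mean(intercepts)) < 3 * mcse

    def test_collinear_design_is_singular(self):
        ivs = [_iv(0.4, 0.1, snp=f"rs{i}") for i in range(3)]
        with pytest.raises(EstimationError):
            mr.mr_egger(ivs)

    def test_needs_three_instruments(self, rng):
        with pytest.raises(InsufficientInstrumentsError):
            mr.mr_egger(random_instruments(rng, 2))


class TestWeightedMedian:
    def test_equal_weights_simple_median(self):
        ivs = [_iv(1.0, r, so=0.05, snp=f"rs{i}")
               for i, r in enumerate([0.1, 0.2, 0.9])]
        est = mr.weighted_median(ivs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_identical_ratios_give_tight_bootstrap(self):
        ivs = [_iv(0.5, 0.15, sx=1e-6, so=1e-6, snp=f"rs{i}") for i in range(4)]
        est = mr.weighted_median(ivs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 1e-4

    def test_matches_enumeration_oracle_to_1e12(self, rng):
        for _ in range(50):
            ivs = random_instruments(rng, int(rng.integers(3, 9)))
            est = mr.weighted_median(ivs, n_boot=10, seed=0)
            ratios = [iv.beta_out / iv.beta_exp for iv in ivs]
            weights = [iv.beta_exp ** 2 / iv.se_out ** 2 for iv in ivs]
            assert est.beta == pytest.approx(
                weighted_median_oracle(ratios, weights), abs=1e-12)

    def test_bootstrap_reproducible_for_fixed_seed(self, rng):
        ivs = random_instruments(rng, 5)
        a = mr.weighted_median(ivs, n_boot=100, seed=7)
        b = mr.weighted_median(ivs, n_boot=100, seed=7)
        assert a.se == b.se


class TestSteiger:
    def test_strong_exposure_weak_outcome_is_correct_direction(self):
        iv = _iv(0.3, 0.03, sx=0.01, so=0.01)  # z_exp=30, z_out=3
        correct, pval = mr.steiger_test(iv, 30_000, 30_000)
        assert correct is True
        assert pval < 1e-10

    def test_symmetric_case_has_pvalue_one(self):
        iv = _iv(0.1, 0.1, sx=0.02, so=0.02)
        correct, pval = mr.steiger_test(iv, 10_000, 10_000)
        assert correct is False
        assert pval == pytest.approx(1.0)

    def test_matches_independent_fisher_z_formula(self, rng):
        from scipy import stats
        for _ in range(100):
            iv = _iv(float(rng.normal(0, 0.3)) or 0.1,
                     float(rng.normal(0, 0.05)),
                     sx=float(rng.uniform(0.01, 0.05)),
                     so=float(rng.uniform(0.01, 0.05)))
            n1, n2 = int(rng.integers(100, 50_000)), int(rng.integers(100, 50_000))
            correct, pval = mr.steiger_test(iv, n1, n2)
            z1, z2 = iv.beta_exp / iv.se_exp, iv.beta_out / iv.se_out
            r1 = math.sqrt(z1 ** 2 / (z1 ** 2 + n1 - 2))
            r2 = math.sqrt(z2 ** 2 / (z2 ** 2 + n2 - 2))
            zdiff = (np.arctanh(r1) - np.arctanh(r2)) / math.sqrt(
                1 / (n1 - 3) + 1 / (n2 - 3))
            assert correct == (r1 > r2)
            assert pval == pytest.approx(
                min(1.0, 2 * stats.norm.sf(abs(zdiff))), rel=1e-9)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ParameterError):
            mr.steiger_test(_iv(0.3, 0.1), 3, 100)


class TestBhFdr:
    def test_hand_step_up_example(self):
        q = mr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert mr.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.all(mr.bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_agrees_with_statsmodels_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(1e-12, 1, size=int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mr.bh_fdr(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            mr.bh_fdr([0.0, 0.5])

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.uniform(0, 1, size=30))
        q = mr.bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)


class TestOrCi:
    def test_zero_beta(self):
        or_, lo, hi = mr.to_or_ci(0.0, 0.1)
        assert or_ == 1.0
        assert lo == pytest.approx(math.exp(-0.196))
        assert hi == pytest.approx(math.exp(0.196))

    def test_zero_se_degenerate_ci(self):
        or_, lo, hi = mr.to_or_ci(0.2, 0.0)
        assert lo == or_ == hi

    def test_reporting_shape_of_strong_risk_gene(self):
        or_, lo, hi = mr.to_or_ci(0.2624, 0.0451)
        assert round(or_, 2) == 1.30
        assert round(lo, 2) == 1.19
        assert round(hi, 2) == 1.42


class TestRouting:
    def test_one_instrument_routes_to_wald(self, rng):
        res = mr.run_gene_mr("G", random_instruments(rng, 1))
        assert res.method == "wald_ratio"
        assert res.sensitivity == {}

    def test_two_instruments_route_to_ivw_without_sensitivity(self, rng):
        res = mr.run_gene_mr("G", random_instruments(rng, 2))
        assert res.method == "ivw"
        assert "egger_beta" not in res.sensitivity

    def test_five_instruments_record_sensitivity(self, rng):
        res = mr.run_gene_mr("G", random_instruments(rng, 5), n_boot=50)
        assert res.method == "ivw"
        assert {"egger_beta", "egger_intercept_pval", "wm_beta"} <= set(res.sensitivity)

    def test_no_kept_instruments_skips_gene(self):
        iv = _iv(0.4, 0.1)
        iv.action = "dropped"
        iv.drop_reason = "allele-mismatch"
        assert mr.run_gene_mr("G", [iv]) is None

    def test_finalize_fdr_preserves_order_and_sets_q(self, rng):
        results = [mr.run_gene_mr(f"G{i}", random_instruments(rng, 1))
                   for i in range(10)]
        out = mr.finalize_fdr(results)
        expected = mr.bh_fdr([r.pval for r in results])
        assert [r.gene for r in out] == [f"G{i}" for i in range(10)]
        assert np.allclose([r.qval for r in out], expected)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_estimators_equivariant_under_exposure_sign_flip(seed):
    """Negating (beta_exp, beta_out) jointly leaves all estimates unchanged."""
    rng = np.random.default_rng(seed)
    ivs = random_instruments(rng, 5)
    flipped = [Instrument(gene=iv.gene, snp_id=iv.snp_id,
                          beta_exp=-iv.beta_exp, se_exp=iv.se_exp,
                          beta_out=-iv.beta_out, se_out=iv.se_out,
                          eaf_exp=iv.eaf_exp, eaf_out=iv.eaf_out,
                          n_exp=iv.n_exp, n_out=iv.n_out) for iv in ivs]
    assert mr.ivw(ivs).beta == pytest.approx(mr.ivw(flipped).beta, abs=1e-12)
    assert mr.mr_egger(ivs)[0].beta == pytest.approx(
        mr.mr_egger(flipped)[0].beta, abs=1e-12)
    assert mr.weighted_median(ivs, n_boot=5, seed=0).beta == pytest.approx(
        mr.weighted_median(flipped, n_boot=5, seed=0).beta, abs=1e-12)
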