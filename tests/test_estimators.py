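import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_inst
from mrscreen.estimators import (
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    to_odds_ratio,
    wald_ratio,
    weighted_median_value,
)
from mrscreen.exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    DomainError,
    InsufficientInstrumentsError,
)


def random_instruments(rng, j, theta=0.3):
    insts = []
    for i in range(j):
        bx = rng.uniform(0.05, 0.5) * rng.choice([-1, 1])
        insts.append(
            make_inst(
                f"rs{i}",
                beta_exp=bx,
                se_exp=rng.uniform(0.005, 0.02),
                beta_out=theta * bx + rng.normal(0, 0.02),
                se_out=rng.uniform(0.01, 0.1),
                pos=1_000_000 + i,
            )
        )
    return insts


class TestWaldRatio:
    def test_direct_arithmetic(self):
        r = wald_ratio(make_inst(beta_exp=1.0, beta_out=0.2, se_out=0.1))
        assert r.theta == 0.2
        assert r.se == 0.1
        assert r.weight == pytest.approx(100.0)

    def test_zero_outcome_effect(self):
        assert wald_ratio(make_inst(beta_out=0.0)).theta == 0.0

    def test_half_exposure_effect(self):
        r = wald_ratio(make_inst(beta_exp=0.5, beta_out=0.1, se_out=0.05))
        assert r.theta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)

    def test_negative_exposure_effect_se_positive(self):
        r = wald_ratio(make_inst(beta_exp=-0.5, beta_out=0.1, se_out=0.05))
        assert r.theta == pytest.approx(-0.2)
        assert r.se == pytest.approx(0.1)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(make_inst(beta_exp=0.0))


class TestIVW:
    def test_identical_ratios_degenerate(self):
        insts = [make_inst("a", beta_out=0.5, se_out=0.1),
                 make_inst("b", beta_out=0.5, se_out=0.2)]
        est, q = mr_ivw(insts)
        assert est.beta == pytest.approx(0.5)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert est.se == pytest.approx((0.1**-2 + 0.2**-2) ** -0.5)  # phi floored at 1

    def test_hand_computed_fixture(self, ivw_fixture_pair):
        est, q = mr_ivw(ivw_fixture_pair)
        assert est.beta == pytest.approx(0.28, abs=1e-12)
        assert q == pytest.approx(3.2, abs=1e-10)
        assert est.se == pytest.approx(0.16, abs=1e-10)
        assert est.pvalue == pytest.approx(0.080, abs=5e-4)

    def test_two_equal_precision_instruments_mean(self):
        insts = [make_inst("a", beta_out=0.2, se_out=0.1),
                 make_inst("b", beta_out=0.4, se_out=0.1)]
        est, _ = mr_ivw(insts)
        assert est.beta == pytest.approx(0.3)

    def test_below_minimum_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_ivw([make_inst()])

    def test_or_fields_consistent(self, ivw_fixture_pair):
        est, _ = mr_ivw(ivw_fixture_pair)
        assert est.or_value == pytest.approx(math.exp(est.beta))
        assert est.or_low == pytest.approx(math.exp(est.ci_low))
        assert est.or_high == pytest.approx(math.exp(est.ci_high))
        assert est.ci_low < est.beta < est.ci_high

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_wls_through_origin_oracle(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        insts = random_instruments(rng, int(rng.integers(3, 31)))
        est, _ = mr_ivw(insts)
        bx = np.array([i.beta_exp for i in insts])
        by = np.array([i.beta_out for i in insts])
        w = np.array([i.se_out for i in insts]) ** -2.0
        fit = sm.WLS(by, bx, weights=w).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        insts = random_instruments(rng, 12)
        est, q = mr_ivw(insts)
        perm = list(insts)
        rng.shuffle(perm)
        est2, q2 = mr_ivw(perm)
        assert est2.beta == pytest.approx(est.beta, abs=1e-12)
        assert q2 == pytest.approx(q, abs=1e-9)

    def test_q_nonnegative_zero_iff_equal(self):
        rng = np.random.default_rng(3)
        insts = random_instruments(rng, 8)
        _, q = mr_ivw(insts)
        assert q > 0
        equal = [make_inst(f"e{i}", beta_out=0.4, se_out=0.1 + 0.01 * i) for i in range(4)]
        _, q0 = mr_ivw(equal)
        assert q0 == pytest.approx(0.0, abs=1e-12)


class TestWeightedMedianValue:
    def test_simple_median(self):
        assert weighted_median_value([1, 2, 3], [1, 1, 1]) == 2.0

    def test_even_count_interpolates(self):
        assert weighted_median_value([1, 2, 3, 4], [1, 1, 1, 1]) == pytest.approx(2.5)

    def test_unequal_weights_interpolation(self):
        assert weighted_median_value([1, 2, 3], [3, 1, 1]) == pytest.approx(1.5)

    def test_order_of_values_irrelevant(self):
        assert weighted_median_value([3, 1, 2], [1, 3, 1]) == weighted_median_value([1, 2, 3], [3, 1, 1])

    def test_single_value(self):
        assert weighted_median_value([7.0], [2.0]) == 7.0

    def test_heavy_weight_pulls_toward_value(self):
        # p = (5/12, 10.5/12, 11.5/12); interpolate 0.5 between 1 and 2
        assert weighted_median_value([1, 2, 3], [10, 1, 1]) == pytest.approx(1 + 1 / 5.5)

    def test_errors(self):
        with pytest.raises(DomainError):
            weighted_median_value([], [])
        with pytest.raises(DomainError):
            weighted_median_value([1, 2], [1, 0])

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=20),
        st.data(),
    )
    def test_bounded_by_extremes(self, values, data):
        weights = data.draw(
            st.lists(st.floats(0.1, 10), min_size=len(values), max_size=len(values))
        )
        m = weighted_median_value(values, weights)
        assert min(values) <= m <= max(values)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=15))
    def test_equal_weights_odd_count_is_median(self, values):
        if len(values) % 2 == 0:
            values = values + [0.0]
        m = weighted_median_value(values, [1.0] * len(values))
        assert m == pytest.approx(float(np.median(values)), abs=1e-9)


class TestWeightedMedianEstimator:
    def test_identical_ratios(self):
        insts = [make_inst(f"r{i}", beta_out=0.5, se_out=0.1) for i in range(4)]
        est = mr_weighted_median(insts, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        insts = random_instruments(rng, 10)
        a = mr_weighted_median(insts, n_boot=500, seed=42)
        b = mr_weighted_median(insts, n_boot=500, seed=42)
        assert a.se == b.se and a.pvalue == b.pvalue

    def test_below_minimum_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_weighted_median([make_inst("a"), make_inst("b")], seed=0)

    def test_bootstrap_se_matches_independent_reimplementation(self):
        """Monte-Carlo oracle: plain-python bootstrap of the same scheme."""
        rng = np.random.default_rng(7)
        insts = random_instruments(rng, 12)
        est = mr_weighted_median(insts, n_boot=2000, seed=11)

        theta = np.array([wald_ratio(i).theta for i in insts])
        se = np.array([wald_ratio(i).se for i in insts])
        w = se ** -2.0
        oracle_rng = np.random.default_rng(999)  # independent stream
        reps = []
        for _ in range(2000):
            draw = oracle_rng.normal(theta, se)
            reps.append(weighted_median_value(draw, w))
        assert est.se == pytest.approx(float(np.std(reps, ddof=1)), rel=0.10)

    def test_equal_weights_odd_j_is_sample_median(self):
        insts = [make_inst(f"r{i}", beta_out=b, se_out=0.1)
                 for i, b in enumerate([0.1, 0.5, 0.3])]
        est = mr_weighted_median(insts, seed=0)
        assert est.beta == pytest.approx(0.3)


class TestEgger:
    def test_perfect_fit_fixture(self, egger_fixture_triplet):
        res = mr_egger(egger_fixture_triplet)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.1, abs=1e-10)
        assert res.slope.se == pytest.approx(0.0707, abs=5e-4)
        assert res.intercept_se == pytest.approx(0.1528, abs=5e-4)

    def test_zero_outcome_effects(self):
        insts = [make_inst(f"r{i}", beta_exp=float(i + 1), beta_out=0.0) for i in range(3)]
        res = mr_egger(insts)
        assert res.slope.beta == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_below_minimum_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger([make_inst("a"), make_inst("b", beta_exp=2.0)])

    def test_collinear_raises(self):
        insts = [make_inst(f"r{i}", beta_exp=1.0) for i in range(3)]
        with pytest.raises(CollinearityError):
            mr_egger(insts)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        insts = random_instruments(rng, int(rng.integers(3, 31)))
        res = mr_egger(insts)
        bx = np.array([i.beta_exp for i in insts])
        by = np.array([i.beta_out for i in insts])
        sy = np.array([i.se_out for i in insts])
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        # independent solver: scale rows by sqrt(w), ordinary lstsq
        sw = 1.0 / sy
        design = np.column_stack([sw, sw * bx])
        coef, *_ = np.linalg.lstsq(design, sw * by, rcond=None)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(coef[1], abs=1e-10)

    def test_slope_equals_ivw_on_noiseless_proportional_data(self):
        theta = 0.4
        insts = [make_inst(f"r{i}", beta_exp=bx, beta_out=theta * bx, se_out=0.1)
                 for i, bx in enumerate([0.1, 0.2, 0.35, 0.5])]
        res = mr_egger(insts)
        ivw, _ = mr_ivw(insts)
        assert res.slope.beta == pytest.approx(theta, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert ivw.beta == pytest.approx(res.slope.beta, abs=1e-10)

    def test_orientation_invariance(self):
        """Negating (beta_exp, beta_out) of any instrument leaves the fit
        unchanged thanks to the beta_exp >= 0 orientation step."""
        rng = np.random.default_rng(5)
        insts = random_instruments(rng, 8)
        res = mr_egger(insts)
        from dataclasses import replace

        flipped = [
            replace(i, beta_exp=-i.beta_exp, beta_out=-i.beta_out) if k % 2 else i
            for k, i in enumerate(insts)
        ]
        res2 = mr_egger(flipped)
        assert res2.slope.beta == pytest.approx(res.slope.beta, abs=1e-12)
        assert res2.intercept == pytest.approx(res.intercept, abs=1e-12)

    def test_pvalues_use_t_distribution(self, ivw_fixture_pair):
        rng = np.random.default_rng(9)
        insts = random_instruments(rng, 5)
        res = mr_egger(insts)
        expected = 2 * stats.t.sf(abs(res.slope.beta) / res.slope.se, 3)
        assert res.slope.pvalue == pytest.approx(expected, rel=1e-9)


class TestToOddsRatio:
    def test_zero_beta_symmetric_interval(self):
        or_v, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_v == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_published_row_shape(self):
        or_v, lo, hi = to_odds_ratio(math.log(1.14), 0.0448, 1.96)
        assert or_v == pytest.approx(1.14)
        assert lo == pytest.approx(1.04, abs=0.01)
        assert hi == pytest.approx(1.25, abs=0.01)

    def test_protective_row_shape(self):
        or_v, lo, hi = to_odds_ratio(math.log(0.82), 0.0911, 1.96)
        assert or_v == pytest.approx(0.82)
        assert lo == pytest.approx(0.69, abs=5e-3)
        assert hi == pytest.approx(0.98, abs=5e-3)

    def test_nonpositive_se_raises(self):
        with pytest.raises(DomainError):
            to_odds_ratio(0.1, 0.0)


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scaling_beta_exp_divides_estimates(self, c):
        from dataclasses import replace

        rng = np.random.default_rng(2)
        insts = random_instruments(rng, 9)
        scaled = [replace(i, beta_exp=c * i.beta_exp) for i in insts]
        ivw_a, _ = mr_ivw(insts)
        ivw_b, _ = mr_ivw(scaled)
        assert ivw_b.beta == pytest.approx(ivw_a.beta / c, rel=1e-10)
        wm_a = mr_weighted_median(insts, n_boot=100, seed=5)
        wm_b = mr_weighted_median(scaled, n_boot=100, seed=5)
        assert wm_b.beta == pytest.approx(wm_a.beta / c, rel=1e-10)
        eg_a, eg_b = mr_egger(insts), mr_egger(scaled)
        assert eg_b.slope.beta == pytest.approx(eg_a.slope.beta / c, rel=1e-10)

    def test_global_negation_leaves_estimates(self):
        from dataclasses import replace

        rng = np.random.default_rng(4)
        insts = random_instruments(rng, 9)
        negated = [replace(i, beta_exp=-i.beta_exp, beta_out=-i.beta_out) for i in insts]
        assert mr_ivw(negated)[0].beta == pytest.approx(mr_ivw(insts)[0].beta, abs=1e-12)
        assert mr_weighted_median(negated, n_boot=100, seed=6).beta == pytest.approx(
            mr_weighted_median(insts, n_boot=100, seed=6).beta, abs=1e-12
        )
        assert mr_egger(negated).slope.beta == pytest.approx(mr_egger(insts).slope.beta, abs=1e-12)


def test_estimators_invariant_to_harmonization_corrections():
    """End-to-end: estimates agree whether or not non-palindromic records
    needed swap/strand correction before harmonization."""
    from dataclasses import replace

    from mrscreen.harmonize import harmonize_all
    from mrscreen.synthetic_data import SimulationConfig, simulate_study

    study = simulate_study(SimulationConfig(n_snps=12, theta=0.25, seed=3))
    insts_a, _ = harmonize_all(study.exposure_stats, study.outcome_stats)

    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    mangled = []
    for k, rec in enumerate(study.outcome_stats):
        if k % 3 == 0:
            rec = replace(rec, effect_allele=rec.other_allele, other_allele=rec.effect_allele,
                          beta=-rec.beta, eaf=None if rec.eaf is None else 1 - rec.eaf)
        if k % 2 == 0 and not comp[rec.effect_allele] == rec.other_allele:
            rec = replace(rec, effect_allele=comp[rec.effect_allele],
                          other_allele=comp[rec.other_allele])
        mangled.append(rec)
    insts_b, _ = harmonize_all(study.exposure_stats, mangled)

    assert mr_ivw(insts_b)[0].beta == pytest.approx(mr_ivw(insts_a)[0].beta, abs=1e-12)
    assert mr_egger(insts_b).slope.beta == pytest.approx(mr_egger(insts_a).slope.beta, abs=1e-12)
    assert mr_weighted_median(insts_b, n_boot=100, seed=8).beta == pytest.approx(
        mr_weighted_median(insts_a, n_boot=100, seed=8).beta, abs=1e-12
    )
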