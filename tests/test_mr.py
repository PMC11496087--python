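import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrmediate.mr import (
    MRInputError,
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    mr_estimate,
    wald_ratio,
    wald_ratios,
    weighted_median,
)

from conftest import make_instruments, random_instruments


def two_ratio_set():
    # Wald ratios 0.2 (se 0.04) and 0.3 (se 0.06)
    return make_instruments([0.5, 0.5], [0.05, 0.05], [0.1, 0.15], [0.02, 0.03])


class TestWaldRatio:
    def test_hand_arithmetic(self):
        [inst] = make_instruments([0.5], [0.05], [0.1], [0.02])
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)
        assert est.method == "wald" and est.n_snp == 1
        assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se, abs=1e-10)
        assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se, abs=1e-10)

    def test_null_numerator(self):
        [inst] = make_instruments([0.5], [0.05], [0.0], [0.02])
        assert wald_ratio(inst).beta == 0.0

    def test_zero_exposure_beta_fails(self):
        [inst] = make_instruments([0.0], [0.05], [0.1], [0.02])
        with pytest.raises(MRInputError, match="v0"):
            wald_ratio(inst)

    def test_single_instrument_dispatch(self):
        """One cis-pQTL instrument yields a Wald estimate with n_snp = 1."""
        insts = make_instruments([0.25], [0.01], [0.07], [0.02])
        est = mr_estimate(insts)
        assert est.method == "wald" and est.n_snp == 1


class TestIVW:
    def test_closed_form_two_ratios(self):
        est = ivw(two_ratio_set(), random_effects=False)
        assert est.beta == pytest.approx(0.230769, abs=1e-5)
        assert est.se == pytest.approx(0.033282, abs=1e-5)

    def test_homogeneous_ratios(self):
        insts = make_instruments([0.2, 0.4, 0.5], [0.02] * 3, [0.05, 0.1, 0.125], [0.01] * 3)
        fixed = ivw(insts, random_effects=False)
        mre = ivw(insts)
        assert fixed.beta == pytest.approx(0.25)
        assert cochran_q(insts).q_stat == pytest.approx(0.0, abs=1e-20)
        assert mre.se == pytest.approx(fixed.se)  # Q=0 -> no inflation

    def test_equals_zero_intercept_wls_slope(self, rng):
        """IVW beta equals the no-intercept WLS slope with weights 1/se_out^2."""
        for _ in range(10):
            insts = random_instruments(rng, 8)
            be = np.array([h.beta_exp for h in insts])
            bo = np.array([h.beta_out for h in insts])
            w = np.array([1 / h.se_out**2 for h in insts])
            slope = sm.WLS(bo, be, weights=w).fit().params[0]
            assert ivw(insts).beta == pytest.approx(slope, abs=1e-10)

    def test_requires_two_instruments(self):
        with pytest.raises(MRInputError):
            ivw(make_instruments([0.5], [0.05], [0.1], [0.02]))


class TestCochranQ:
    def test_hand_arithmetic(self):
        res = cochran_q(two_ratio_set())
        assert res.q_stat == pytest.approx(1.9231, abs=1e-3)
        assert res.df == 1

    def test_null_calibration(self):
        """Q rejects at ~5% under a correctly specified homogeneous model."""
        master = np.random.default_rng(97)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            be = master.uniform(0.15, 0.3, 12)
            se_o = np.full(12, 0.02)
            bo = 0.1 * be + se_o * master.standard_normal(12)
            insts = make_instruments(be, np.full(12, 1e-6), bo, se_o)
            rej += cochran_q(insts).pval < 0.05
        assert 0.02 < rej / n_rep < 0.08


class TestEgger:
    def test_collinear_points_exact(self):
        insts = make_instruments([1, 2, 3], [0.01] * 3, [0.5, 1.0, 1.5], [0.05] * 3)
        res = mr_egger(insts, n_boot=0)
        assert res.estimate.beta == pytest.approx(0.5, abs=1e-12)
        assert res.pleiotropy.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_intercept_shift_equivariance(self, rng):
        insts = random_instruments(rng, 10)
        res0 = mr_egger(insts, n_boot=0)
        shifted = make_instruments(
            [h.beta_exp for h in insts],
            [h.se_exp for h in insts],
            [h.beta_out + 0.07 for h in insts],
            [h.se_out for h in insts],
        )
        res1 = mr_egger(shifted, n_boot=0)
        assert res1.estimate.beta == pytest.approx(res0.estimate.beta, abs=1e-10)
        assert res1.pleiotropy.egger_intercept == pytest.approx(
            res0.pleiotropy.egger_intercept + 0.07, abs=1e-10
        )

    def test_matches_generic_wls_solver(self, rng):
        insts = random_instruments(rng, 20)
        res = mr_egger(insts, n_boot=0)
        be = np.array([abs(h.beta_exp) for h in insts])
        bo = np.array([h.beta_out * np.sign(h.beta_exp) for h in insts])
        w = np.array([1 / h.se_out**2 for h in insts])
        fit = sm.WLS(bo, sm.add_constant(be), weights=w).fit()
        assert res.pleiotropy.egger_intercept == pytest.approx(fit.params[0], abs=1e-8)
        assert res.estimate.beta == pytest.approx(fit.params[1], abs=1e-8)

    def test_bootstrap_se_deterministic(self, rng):
        insts = random_instruments(rng, 10)
        a = mr_egger(insts, n_boot=200, seed=5)
        b = mr_egger(insts, n_boot=200, seed=5)
        assert a.bootstrap_estimate.se == b.bootstrap_estimate.se
        assert a.bootstrap_estimate.beta == a.estimate.beta

    def test_requires_three(self):
        with pytest.raises(MRInputError):
            mr_egger(two_ratio_set())


class TestWeightedMedian:
    def test_symmetric_middle(self):
        insts = make_instruments([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        assert weighted_median(insts, n_boot=10, seed=0).beta == pytest.approx(0.2)

    @staticmethod
    def _brute_force(b, w):
        """Scan all interpolation intervals of the weighted empirical CDF."""
        order = np.argsort(b)
        b = np.asarray(b, dtype=float)[order]
        w = np.asarray(w, dtype=float)[order]
        w = w / w.sum()
        s = np.cumsum(w) - w / 2
        if 0.5 <= s[0]:
            return b[0]
        for j in range(len(b) - 1):
            if s[j] <= 0.5 <= s[j + 1]:
                frac = (0.5 - s[j]) / (s[j + 1] - s[j])
                return b[j] + frac * (b[j + 1] - b[j])
        return b[-1]

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            insts = random_instruments(rng, int(rng.integers(3, 15)))
            b, s = wald_ratios(insts)
            expected = self._brute_force(b, 1 / s**2)
            got = weighted_median(insts, n_boot=10, seed=0).beta
            assert got == pytest.approx(expected, abs=1e-10)

    def test_robust_to_minority_invalid(self):
        """With 40% of ratios shifted by +1 the median stays near truth
        while IVW is dragged away."""
        master = np.random.default_rng(11)
        wm_ok = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 20
            be = np.full(n, 0.3)
            se_o = np.full(n, 0.005)
            bo = 0.2 * be + se_o * master.standard_normal(n)
            bo[:8] += 1.0 * be[:8]  # 40% invalid, ratios shifted by +1
            insts = make_instruments(be, np.full(n, 1e-6), bo, se_o)
            wm = weighted_median(insts, n_boot=10, seed=0).beta
            b_ivw = ivw(insts).beta
            if abs(wm - 0.2) < 0.05 and abs(b_ivw - 0.2) > 0.05:
                wm_ok += 1
        assert wm_ok / n_rep > 0.9

    def test_requires_three(self):
        with pytest.raises(MRInputError):
            weighted_median(two_ratio_set())


class TestLeaveOneOut:
    def test_cardinality_and_labels(self, rng):
        insts = random_instruments(rng, 6)
        loo = leave_one_out(insts)
        assert [vid for vid, _ in loo] == [h.variant_id for h in insts]
        assert all(est.n_snp == 5 for _, est in loo)

    def test_homogeneous_estimates_equal_full(self):
        insts = make_instruments(
            [0.2, 0.4, 0.5, 0.3], [0.02] * 4, [0.05, 0.1, 0.125, 0.075], [0.01] * 4
        )
        full = ivw(insts)
        for _, est in leave_one_out(insts):
            assert est.beta == pytest.approx(full.beta, abs=1e-12)

    def test_outlier_omission_moves_most(self, rng):
        truth = 0.2
        insts = random_instruments(rng, 10, theta=truth)
        insts[3].beta_out += 15 * insts[3].se_out  # planted outlier
        full = ivw(insts).beta
        moves = {vid: abs(est.beta - truth) for vid, est in leave_one_out(insts)}
        assert min(moves, key=moves.get) == insts[3].variant_id
        assert moves[insts[3].variant_id] < abs(full - truth)


@settings(deadline=None, max_examples=30)
@given(c=st.floats(0.1, 10), seed=st.integers(0, 100))
def test_scale_equivariance(c, seed):
    """Scaling exposure betas and SEs by c divides causal estimates by c."""
    rng = np.random.default_rng(seed)
    insts = random_instruments(rng, 6)
    scaled = make_instruments(
        [h.beta_exp * c for h in insts],
        [h.se_exp * c for h in insts],
        [h.beta_out for h in insts],
        [h.se_out for h in insts],
    )
    assert ivw(scaled).beta * c == pytest.approx(ivw(insts).beta, rel=1e-9)
    assert mr_egger(scaled, n_boot=0).estimate.beta * c == pytest.approx(
        mr_egger(insts, n_boot=0).estimate.beta, rel=1e-9
    )
    assert weighted_median(scaled, n_boot=5, seed=1).beta * c == pytest.approx(
        weighted_median(insts, n_boot=5, seed=1).beta, rel=1e-9
    )
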