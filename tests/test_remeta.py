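import math

import numpy as np
import pytest
from scipy import optimize, stats

from hetaug import dataset_from_arrays, fit, fit_dl, fit_ml, fit_reml, qprofile_ci, wald_ci
from hetaug.remeta import generalized_q

from conftest import random_dataset


class TestToyOracles:
    """Hand-derivable equal-variance cases."""

    def test_homogeneous_data_all_methods(self):
        d = dataset_from_arrays([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        for method in ("dl", "ml", "reml"):
            r = fit(d, method=method)
            assert r.tau2 == pytest.approx(0.0, abs=1e-10)
            assert r.truncated
            assert r.mu == pytest.approx(1.0)
            assert r.mu_se == pytest.approx(1 / math.sqrt(3), rel=1e-10)
            assert r.I2 == 0.0

    def test_dl_moments_formula(self, two_study):
        # Q = 2, C = 1, df = 1 -> tau2 = 1; I2 = 1/2
        r = fit_dl(two_study)
        assert r.Q == pytest.approx(2.0)
        assert r.tau2 == pytest.approx(1.0)
        assert r.mu == pytest.approx(1.0)
        assert r.I2 == pytest.approx(0.5)

    def test_ml_equal_variance_closed_form(self):
        # tau2_ML = mean squared deviation - sigma^2, truncated at 0
        r0 = fit_ml(dataset_from_arrays([0.0, 2.0], [1.0, 1.0]))
        assert r0.tau2 == pytest.approx(0.0, abs=1e-8)
        r3 = fit_ml(dataset_from_arrays([0.0, 4.0], [1.0, 1.0]))
        assert r3.tau2 == pytest.approx(3.0, rel=1e-6)

    def test_reml_equal_variance_closed_form(self, two_study):
        # tau2_REML = sample variance - sigma^2 = 2/1 - 1 = 1
        r = fit_reml(two_study)
        assert r.tau2 == pytest.approx(1.0, rel=1e-6)

    def test_fixed_effect_se(self, two_study):
        # at tau2 = 0 the weighted SE is 1/sqrt(2)
        r = fit_ml(two_study)
        assert r.tau2 == pytest.approx(0.0, abs=1e-8)
        assert r.mu_se == pytest.approx(1 / math.sqrt(2), rel=1e-6)

    def test_ml_reml_converge_at_large_k(self):
        """REML's correction vanishes as K grows (checked at K = 200)."""
        rng = np.random.default_rng(11)
        v = np.full(200, 0.069)
        y = rng.normal(0.0, np.sqrt(v + 0.2))
        d = dataset_from_arrays(y, v)
        assert fit_ml(d).tau2 == pytest.approx(fit_reml(d).tau2, abs=5e-3)


class TestAgainstIndependentOracles:
    def test_matches_direct_objective_maximization(self):
        """All three fitters agree with brute-force optimization of their
        stated objective functions on 20 random datasets."""
        from conftest import direct_tau2_oracle

        rng = np.random.default_rng(314)
        for _ in range(20):
            d = random_dataset(rng)
            y, v = d.effects(), d.variances()
            for method, restricted in (("ml", False), ("reml", True)):
                oracle = direct_tau2_oracle(y, v, restricted)
                assert fit(d, method=method).tau2 == pytest.approx(oracle, abs=1e-6)

            # DL from the scalar moments formula
            w = 1.0 / v
            mu_fe = np.sum(w * y) / np.sum(w)
            Q = float(np.sum(w * (y - mu_fe) ** 2))
            C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
            oracle_dl = max(0.0, (Q - (d.n - 1)) / C)
            assert fit_dl(d).tau2 == pytest.approx(oracle_dl, abs=1e-10)

    def test_frozen_metafor_values(self, six_study):
        """Frozen expected values from metafor 4.8 (rma.uni, same model) on
        the fixed 6-study dataset."""
        expected = {
            "dl": (0.0363962752, 0.1430319881, 0.1351985829),
            "ml": (0.0102310045, 0.1379591948, 0.1157434550),
            "reml": (0.0327526130, 0.1424291957, 0.1327146550),
        }
        for method, (tau2, mu, se) in expected.items():
            r = fit(six_study, method=method)
            assert r.tau2 == pytest.approx(tau2, abs=1e-4)
            assert r.mu == pytest.approx(mu, abs=1e-4)
            assert r.mu_se == pytest.approx(se, abs=1e-4)
        # Q-profile interval frozen from metafor confint()
        lo, hi = qprofile_ci(six_study)
        assert lo == pytest.approx(0.0, abs=1e-10)
        assert hi == pytest.approx(0.6997974, abs=1e-4)


class TestQProfile:
    def test_two_study_closed_form(self, two_study):
        # Q(tau2) = 2/(1+tau2); Q(0)=2 < chi2_{1,0.975} so lo = 0;
        # hi solves 2/(1+t) = chi2_{1,0.025}
        lo, hi = qprofile_ci(two_study, level=0.95)
        assert lo == 0.0
        expected_hi = 2.0 / stats.chi2.ppf(0.025, 1) - 1.0
        assert hi == pytest.approx(expected_hi, rel=1e-6)
        assert hi == pytest.approx(2035.4, rel=1e-3)

    def test_homogeneous_truncates_to_zero(self):
        d = dataset_from_arrays([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        lo, _ = qprofile_ci(d)
        assert lo == 0.0

    def test_generalized_q_decreasing(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            d = random_dataset(rng)
            qs = [generalized_q(d, t) for t in np.linspace(0, 5, 40)]
            assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_scale_equivariance(self):
        """Scaling effects and SEs by c scales the tau2 interval by c^2."""
        rng = np.random.default_rng(5)
        d = random_dataset(rng, 6)
        c = 3.0
        scaled = dataset_from_arrays(c * d.effects(), c**2 * d.variances())
        lo, hi = qprofile_ci(d)
        slo, shi = qprofile_ci(scaled)
        assert slo == pytest.approx(c**2 * lo, abs=1e-8)
        assert shi == pytest.approx(c**2 * hi, rel=1e-6)

    def test_interval_ordering(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            d = random_dataset(rng)
            lo, hi = qprofile_ci(d)
            assert 0.0 <= lo <= hi


class TestWaldCI:
    def test_standard_normal_quantile(self):
        lo, hi = wald_ci(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.95996, abs=1e-5)
        assert hi == pytest.approx(1.95996, abs=1e-5)

    def test_degenerate_se(self):
        assert wald_ci(1.0, 0.0, 0.95) == (1.0, 1.0)

    def test_width_linearity(self):
        se = 0.37
        lo, hi = wald_ci(1.42, se, 0.95)
        assert hi - lo == pytest.approx(2 * stats.norm.ppf(0.975) * se, rel=1e-12)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, -1.0, 0.95)


class TestPreconditions:
    def test_n_equals_p_rejected(self):
        d = dataset_from_arrays([0.0, 1.0], [1.0, 1.0])
        # shrink to a single observed record artificially
        from hetaug import Dataset

        single = Dataset(d.records[:1])
        with pytest.raises(ValueError):
            fit_dl(single)

    def test_unknown_method_rejected(self, two_study):
        with pytest.raises(ValueError, match="unknown method"):
            fit(two_study, method="pm")
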