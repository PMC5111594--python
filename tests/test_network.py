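import numpy as np
import pytest

from hetaug import (
    ContrastRecord,
    InverseGammaPrior,
    NetworkSpec,
    augment,
    build_pseudo_data,
    derived_contrast,
    fit_reml,
    fit_dl,
    nma_design,
    split_multiarm,
    dataset_from_arrays,
)


def smoking_style_network(rng: np.random.Generator) -> NetworkSpec:
    """Synthetic 4-intervention network (A reference) with all six direct
    comparisons represented, loosely shaped like a smoking-cessation
    counselling network."""
    pairs = [("B", "A", 3), ("C", "A", 5), ("D", "A", 2),
             ("C", "B", 2), ("D", "B", 2), ("D", "C", 3)]
    truth = {"A": 0.0, "B": 0.3, "C": 0.6, "D": 0.9}
    contrasts = []
    i = 0
    for treat, ctl, n_st in pairs:
        for _ in range(n_st):
            i += 1
            v = float(rng.uniform(0.05, 0.3))
            eff = rng.normal(truth[treat] - truth[ctl], np.sqrt(v + 0.05))
            contrasts.append(ContrastRecord(f"s{i}", treat, ctl, float(eff), v))
    return NetworkSpec(("A", "B", "C", "D"), "A", tuple(contrasts))


class TestDesignMatrix:
    def test_reference_study_row(self):
        spec = NetworkSpec(
            ("A", "B", "C", "D"),
            "A",
            (
                ContrastRecord("s1", "B", "A", 0.5, 0.1),
                ContrastRecord("s2", "C", "B", 0.2, 0.1),
                ContrastRecord("s3", "D", "A", 0.1, 0.1),
                ContrastRecord("s4", "C", "A", 0.1, 0.1),
            ),
        )
        X = nma_design(spec).design()
        # columns ordered (B, C, D)
        np.testing.assert_array_equal(X[0], [1.0, 0.0, 0.0])  # AB study
        np.testing.assert_array_equal(X[1], [-1.0, 1.0, 0.0])  # BC study
        np.testing.assert_array_equal(X[2], [0.0, 0.0, 1.0])  # AD study

    def test_pseudo_rows_all_zero(self):
        rng = np.random.default_rng(0)
        data = nma_design(smoking_style_network(rng))
        aug = augment(data, build_pseudo_data(InverseGammaPrior(1.39, 0.13)))
        for r in aug.records:
            if r.is_pseudo:
                assert r.covariates == (0.0, 0.0, 0.0)

    def test_disconnected_network_names_unreachable(self):
        spec = NetworkSpec(
            ("A", "B", "C", "D"),
            "A",
            (
                ContrastRecord("s1", "B", "A", 0.5, 0.1),
                ContrastRecord("s2", "D", "C", 0.2, 0.1),
            ),
        )
        with pytest.raises(ValueError, match="C.*D|disconnected"):
            nma_design(spec)


class TestSplitMultiarm:
    def test_two_arm_equals_direct_conversion(self):
        from hetaug import logodds_from_2x2

        recs = split_multiarm("s", [("X", 10, 50), ("Y", 20, 50)], "X")
        assert len(recs) == 1
        eff, var = logodds_from_2x2(20, 30, 10, 40)
        assert recs[0].effect == pytest.approx(eff)
        assert recs[0].within_variance == pytest.approx(var)
        assert (recs[0].treat, recs[0].control) == ("Y", "X")

    def test_three_arm_gives_two_contrasts(self):
        recs = split_multiarm(
            "s", [("X", 5, 40), ("Y", 9, 40), ("Z", 12, 40)], "X"
        )
        assert [(r.treat, r.control) for r in recs] == [("Y", "X"), ("Z", "X")]

    def test_symmetric_counts_give_zero_effects(self):
        recs = split_multiarm(
            "s", [("X", 10, 40), ("Y", 10, 40), ("Z", 10, 40)], "X"
        )
        assert all(r.effect == pytest.approx(0.0) for r in recs)

    def test_zero_total_arm_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            split_multiarm("s", [("X", 0, 0), ("Y", 5, 10)], "X")


class TestDerivedContrasts:
    def test_basic_parameter_identity(self):
        rng = np.random.default_rng(1)
        spec = smoking_style_network(rng)
        r = fit_reml(nma_design(spec), compute_tau2_ci=False)
        est, se, _ = derived_contrast(r, spec, "A", "C")
        assert est == pytest.approx(r.coefficients[1])
        assert se == pytest.approx(np.sqrt(r.coef_cov[1, 1]))

    def test_same_intervention_zero(self):
        rng = np.random.default_rng(2)
        spec = smoking_style_network(rng)
        r = fit_reml(nma_design(spec), compute_tau2_ci=False)
        assert derived_contrast(r, spec, "B", "B") == (0.0, 0.0, (0.0, 0.0))

    def test_consistency_closure(self):
        """Derived BC + CD - BD = 0 exactly, by linearity."""
        rng = np.random.default_rng(3)
        spec = smoking_style_network(rng)
        r = fit_reml(nma_design(spec), compute_tau2_ci=False)
        bc = derived_contrast(r, spec, "B", "C")[0]
        cd = derived_contrast(r, spec, "C", "D")[0]
        bd = derived_contrast(r, spec, "B", "D")[0]
        assert bc + cd - bd == pytest.approx(0.0, abs=1e-12)

    def test_reference_change_invariance(self):
        """Re-referencing re-parameterizes the design but leaves every
        pairwise contrast and tau2 unchanged."""
        rng = np.random.default_rng(4)
        spec_a = smoking_style_network(rng)
        spec_b = NetworkSpec(
            ("B", "A", "C", "D"), "B", spec_a.contrasts
        )
        fa = fit_reml(nma_design(spec_a), compute_tau2_ci=False)
        fb = fit_reml(nma_design(spec_b), compute_tau2_ci=False)
        assert fa.tau2 == pytest.approx(fb.tau2, abs=1e-8)
        for j, k in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
            ea, sa, _ = derived_contrast(fa, spec_a, j, k)
            eb, sb, _ = derived_contrast(fb, spec_b, j, k)
            assert ea == pytest.approx(eb, abs=1e-8)
            assert sa == pytest.approx(sb, abs=1e-8)

    def test_single_pair_reduces_to_plain_meta_analysis(self):
        effs, vars_ = [0.4, 0.1, 0.6], [0.1, 0.2, 0.15]
        spec = NetworkSpec(
            ("A", "B"),
            "A",
            tuple(
                ContrastRecord(f"s{i}", "B", "A", e, v)
                for i, (e, v) in enumerate(zip(effs, vars_))
            ),
        )
        nma_fit = fit_dl(nma_design(spec))
        plain_fit = fit_dl(dataset_from_arrays(effs, vars_))
        assert nma_fit.mu == pytest.approx(plain_fit.mu, abs=1e-12)
        assert nma_fit.tau2 == pytest.approx(plain_fit.tau2, abs=1e-12)

    def test_augmented_nma_zero_bias_at_fixed_tau2(self):
        """Pseudo rows (all-zero covariates) never move fixed-tau2
        basic-parameter estimates."""
        rng = np.random.default_rng(6)
        data = nma_design(smoking_style_network(rng))
        aug = augment(data, build_pseudo_data(InverseGammaPrior(1.39, 0.13)))
        for tau2 in (0.0, 0.2):
            for ds_pair in ((data, aug),):
                d, a = ds_pair
                def coefs(ds):
                    X, y = ds.design(), ds.effects()
                    w = 1.0 / (ds.variances() + tau2)
                    return np.linalg.solve((X.T * w) @ X, (X.T * w) @ y)
                np.testing.assert_allclose(coefs(d), coefs(a), atol=1e-10)

    def test_unknown_intervention_rejected(self):
        rng = np.random.default_rng(8)
        spec = smoking_style_network(rng)
        r = fit_reml(nma_design(spec), compute_tau2_ci=False)
        with pytest.raises(ValueError, match="not in the network"):
            derived_contrast(r, spec, "A", "Z")
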