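"""AUC coupling ratios and operational-model bias quantification."""

import numpy as np
import pytest

from neurobias import (
    HillFit,
    OperationalTruth,
    bias_factor,
    compute_auc,
    coupling_ratios,
    delta_logR,
    fit_operational_global,
    generate_operational_dataset,
    operational_bias_table,
    operational_response,
    predict_curve,
)

FIT_KW = dict(converged=True, rss=0.0, n_points=9, window=(-12.0, -4.0))


def _hill(pec50=6.0, top=1.0, hill_n=1.0, basal=0.0, converged=True):
    kw = dict(FIT_KW)
    kw["converged"] = converged
    return HillFit(pec50=pec50, top=top, hill_n=hill_n, basal=basal, **kw)


class TestComputeAUC:
    def test_zero_top_zero_auc(self):
        assert compute_auc(_hill(top=0.0), (-9, -3)) == 0.0

    def test_linearity_in_top(self):
        a1 = compute_auc(_hill(top=1.0), (-9, -3))
        a2 = compute_auc(_hill(top=2.0), (-9, -3))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_matches_analytic_integral_for_unit_slope(self):
        # int 1/(1+10^(p-x)) dx = log10(1+10^(x-p)) evaluated over the window
        auc = compute_auc(_hill(pec50=6.0, top=1.0, hill_n=1.0), (-9, -3))
        analytic = np.log10(1 + 10.0 ** (-3 + 6)) - np.log10(1 + 10.0 ** (-9 + 6))
        assert auc == pytest.approx(analytic, rel=1e-4)

    def test_unconverged_fit_propagates_missing(self):
        assert np.isnan(compute_auc(_hill(converged=False), (-9, -3)))

    def test_basal_excluded_from_integral(self):
        a0 = compute_auc(_hill(basal=0.0), (-9, -3))
        a1 = compute_auc(_hill(basal=5.0), (-9, -3))
        assert a1 == pytest.approx(a0, rel=1e-12)


class TestCouplingRatios:
    PATHWAYS = ("GoB", "Gz", "Gi2", "barr2")

    def _aucs(self, per_agonist):
        return {
            (agonist, p): vals[i]
            for agonist, vals in per_agonist.items()
            for i, p in enumerate(self.PATHWAYS)
        }

    def test_reference_matrix_is_all_ones(self):
        aucs = self._aucs({"dopamine": [2.0, 1.5, 1.2, 0.8], "x": [1.0, 1.0, 0.4, 0.2]})
        profile = coupling_ratios(aucs, "dopamine")
        assert np.allclose(profile.normalized["dopamine"].to_numpy(), 1.0)

    def test_uniform_scaling_cancels(self):
        ref = [2.0, 1.5, 1.2, 0.8]
        aucs = self._aucs({"dopamine": ref, "x": [3 * v for v in ref]})
        profile = coupling_ratios(aucs, "dopamine")
        assert np.allclose(profile.normalized["x"].to_numpy(), 1.0)

    def test_halved_arrestin_auc_doubles_ratio(self):
        ref = [2.0, 1.5, 1.2, 0.8]
        halved = list(ref)
        halved[3] = ref[3] / 2
        profile = coupling_ratios(self._aucs({"dopamine": ref, "x": halved}), "dopamine")
        assert profile.normalized["x"].loc["GoB", "barr2"] == pytest.approx(2.0)

    def test_reciprocal_symmetry(self):
        aucs = self._aucs({"dopamine": [2.0, 1.5, 1.2, 0.8], "x": [1.7, 0.9, 0.6, 0.1]})
        m = coupling_ratios(aucs, "dopamine").normalized["x"].to_numpy()
        assert np.allclose(m * m.T, 1.0)

    def test_assay_scale_invariance(self):
        """Scaling one pathway's AUCs for all agonists leaves ratios unchanged."""
        base = {"dopamine": [2.0, 1.5, 1.2, 0.8], "x": [1.7, 0.9, 0.6, 0.1]}
        scaled = {a: [v * (5.0 if i == 3 else 1.0) for i, v in enumerate(vals)]
                  for a, vals in base.items()}
        m1 = coupling_ratios(self._aucs(base), "dopamine").normalized["x"]
        m2 = coupling_ratios(self._aucs(scaled), "dopamine").normalized["x"]
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_zero_reference_auc_names_pathway(self):
        aucs = self._aucs({"dopamine": [2.0, 0.0, 1.2, 0.8], "x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="Gz"):
            coupling_ratios(aucs, "dopamine")


def _two_pathway_truth(ddlog, ref_logr=7.0, test_logr_gob=7.44):
    return OperationalTruth(
        em=1.0,
        basal=0.0,
        n=1.0,
        log_ka={"ref": 0.0, "test": 0.0},
        log_r={
            "ref": {"GoB": ref_logr, "barr2": ref_logr},
            "test": {"GoB": test_logr_gob, "barr2": test_logr_gob - ddlog},
        },
    )


class TestOperationalGlobalFit:
    def test_noise_free_logr_recovery(self):
        truth = _two_pathway_truth(np.log10(274))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        for pathway in ("GoB", "barr2"):
            result = fit_operational_global(df, full_agonists=["ref", "test"], pathway=pathway)
            assert result.converged
            for agonist in ("ref", "test"):
                assert result.log_r[agonist] == pytest.approx(
                    truth.log_r[agonist][pathway], abs=0.02
                )

    def test_shared_system_parameters(self):
        truth = _two_pathway_truth(np.log10(12))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        result = fit_operational_global(df, full_agonists=["ref", "test"], pathway="GoB")
        assert result.em == pytest.approx(1.0, abs=0.02)
        assert result.basal == pytest.approx(0.0, abs=0.02)
        assert result.n == pytest.approx(1.0, abs=0.05)

    def test_full_agonist_half_max_at_reciprocal_tau(self):
        truth = _two_pathway_truth(np.log10(12))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        result = fit_operational_global(df, full_agonists=["ref", "test"], pathway="GoB")
        tau = 10.0 ** result.log_r["ref"]  # KA = 1 M so tau = R
        mid = operational_response(
            1.0 / tau, result.em, result.basal, result.n, 0.0, result.log_r["ref"]
        )
        assert mid == pytest.approx((result.em + result.basal) / 2, rel=1e-3)

    def test_single_agonist_rejected(self):
        truth = OperationalTruth(
            em=1.0, basal=0.0, n=1.0, log_ka={"a": 0.0}, log_r={"a": {"p": 7.0}}
        )
        df = generate_operational_dataset(truth, n_rep=1)
        with pytest.raises(ValueError):
            fit_operational_global(df, full_agonists=["a"], pathway="p")


class TestDeltaAndBiasFactor:
    def test_reference_delta_zero(self):
        truth = _two_pathway_truth(np.log10(12))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        result = fit_operational_global(df, full_agonists=["ref", "test"], pathway="GoB")
        assert delta_logR(result, "ref", "ref") == 0.0

    def test_delta_arithmetic_and_antisymmetry(self):
        truth = _two_pathway_truth(np.log10(12))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        result = fit_operational_global(df, full_agonists=["ref", "test"], pathway="GoB")
        d = delta_logR(result, "test", "ref")
        assert delta_logR(result, "ref", "test") == pytest.approx(-d)

    def test_missing_agonist_rejected(self):
        truth = _two_pathway_truth(np.log10(12))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        result = fit_operational_global(df, full_agonists=["ref", "test"], pathway="GoB")
        with pytest.raises(ValueError):
            delta_logR(result, "nope", "ref")

    def test_bias_factor_reciprocal_product_is_one(self):
        # reciprocal by construction; float rounding leaves at most 1 ulp
        assert bias_factor(0.31, -1.2) * bias_factor(-1.2, 0.31) == pytest.approx(1.0, rel=1e-14)

    @pytest.mark.parametrize("fold", [274.0, 12.0])
    def test_planted_fold_bias_recovered_noise_free(self, fold):
        truth = _two_pathway_truth(np.log10(fold))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        table = operational_bias_table(df, reference="ref", n_boot=0)
        row = table.bias.set_index("agonist").loc["test"]
        assert row["pathway_a"] == "GoB" and row["pathway_b"] == "barr2"
        assert row["bias_factor"] == pytest.approx(fold, rel=0.05)

    def test_reference_bias_factor_exactly_one(self):
        truth = _two_pathway_truth(np.log10(12))
        df = generate_operational_dataset(truth, n_rep=1, noise_sd=0.0, seed=2)
        table = operational_bias_table(df, reference="ref", n_boot=0)
        row = table.bias.set_index("agonist").loc["ref"]
        assert row["bias_factor"] == 1.0


def test_operational_recovery_median_error_small():
    """Median |logR error| < 0.05 over 50 noisy two-agonist datasets."""
    rng = np.random.default_rng(123)
    errors = []
    for _ in range(50):
        ref_logr = rng.uniform(6.0, 8.0)
        test_logr = rng.uniform(5.0, 8.0)
        truth = OperationalTruth(
            em=1.0, basal=0.0, n=1.0,
            log_ka={"ref": 0.0, "test": 0.0},
            log_r={"ref": {"p": ref_logr}, "test": {"p": test_logr}},
        )
        df = generate_operational_dataset(
            truth, n_rep=3, noise_sd=0.05, seed=int(rng.integers(2**31))
        )
        result = fit_operational_global(df, full_agonists=["ref", "test"], pathway="p")
        errors.append(abs(result.log_r["ref"] - ref_logr))
        errors.append(abs(result.log_r["test"] - test_logr))
    assert np.median(errors) < 0.05
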