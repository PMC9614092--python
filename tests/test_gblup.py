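"""Kernels, REML variance components, BLUP conditional-mean predictions."""

import numpy as np
import pandas as pd
import pytest

import sketchgs as sg
from sketchgs.gblup import MODEL_COMPONENTS, build_kernels, fit_mixed_model, predict_blup


def tiny_pheno():
    """3 lines x 2 environments, one replicate: 6 observations."""
    return pd.DataFrame(
        {
            "line": ["L0", "L1", "L2"] * 2,
            "env": ["A"] * 3 + ["B"] * 3,
            "rep": 1,
            "value": [1.0, 2.0, 0.5, 1.5, 2.5, 1.0],
        }
    )


def tiny_kernels():
    X = sg.MarkerMatrix(
        np.array([[1.0, -1.0], [-1.0, 1.0], [1.0, 1.0]]),
        line_ids=["L0", "L1", "L2"],
        standardized=True,
    )
    return build_kernels(X, tiny_pheno())


class TestKernels:
    def test_two_line_hand_example(self):
        X = sg.MarkerMatrix(np.array([[1.0, -1.0], [-1.0, 1.0]]),
                            line_ids=["L0", "L1"], standardized=True)
        ph = pd.DataFrame({"line": ["L0", "L1"], "env": ["A", "A"],
                           "rep": 1, "value": [0.0, 1.0]})
        K = build_kernels(X, ph)
        np.testing.assert_allclose(K.G, [[1, -1], [-1, 1]], atol=1e-12)

    def test_trace_identity_and_psd(self, small_trial, small_kernels):
        _, _, _, _, X = small_trial
        K = small_kernels
        assert np.trace(K.G) == pytest.approx(X.n_lines, abs=1e-8)
        for M in (K.K_E, K.K_L, K.K_g, K.K_gE):
            np.testing.assert_allclose(M, M.T, atol=1e-10)
            w = np.linalg.eigvalsh(M)
            assert w.min() > -1e-8

    def test_interaction_kernel_zero_across_environments(self):
        K = tiny_kernels()
        # (line L0, env A) vs (line L1, env B): environments differ
        assert K.K_gE[0, 4] == 0.0
        # same env pairs carry the genomic covariance
        assert K.K_gE[0, 1] == pytest.approx(K.G[0, 1])

    def test_missing_line_named(self):
        X = sg.MarkerMatrix(np.array([[1.0, -1.0], [-1.0, 1.0]]),
                            line_ids=["L0", "L1"], standardized=True)
        ph = pd.DataFrame({"line": ["L0", "LX"], "env": ["A", "A"],
                           "rep": 1, "value": [0.0, 1.0]})
        with pytest.raises(ValueError, match="LX"):
            build_kernels(X, ph)

    def test_projected_reduction_restandardized(self, small_trial):
        _, _, pheno, _, X = small_trial
        r = sg.reduce_random_projection(X, 30, seed=0)
        K = build_kernels(r, pheno)
        assert np.trace(K.G) == pytest.approx(X.n_lines, abs=1e-6)


class TestREML:
    def test_pure_noise_intercept_is_mean(self):
        rng = np.random.default_rng(0)
        ph = tiny_pheno().copy()
        ph = pd.concat([ph] * 4, ignore_index=True)
        ph["value"] = 2.0 + 0.1 * rng.standard_normal(len(ph))
        X = sg.MarkerMatrix(rng.standard_normal((3, 5)), line_ids=["L0", "L1", "L2"],
                            standardized=True)
        K = build_kernels(X, ph)
        fit = fit_mixed_model(ph, K, "GE")
        assert fit.mu_hat == pytest.approx(ph["value"].mean(), abs=0.05)

    def test_shift_invariance(self, small_trial, small_kernels):
        _, _, pheno, _, _ = small_trial
        f1 = fit_mixed_model(pheno, small_kernels, "GE")
        shifted = pheno.copy()
        shifted["value"] = shifted["value"] + 100.0
        f2 = fit_mixed_model(shifted, small_kernels, "GE")
        assert f2.mu_hat - f1.mu_hat == pytest.approx(100.0, abs=1e-4)
        for c in f1.var_hat:
            assert f2.var_hat[c] == pytest.approx(f1.var_hat[c], rel=1e-3, abs=1e-6)

    def test_gxe_model_improves_loglik_on_gxe_data(self):
        """Extra interaction component raises the restricted likelihood."""
        wins, diffs = 0, []
        for rep in range(20):
            cfg = sg.SimConfig(
                n_lines=50, n_markers=120, n_envs=3, block_size=20,
                within_block_rho=0.4, n_causal=30, seed=300 + rep,
                var_components=sg.TrueVariances(var_E=0.5, var_g=1.0,
                                                var_gE=1.0, var_eps=1.0),
            )
            g = sg.simulate_genotypes(cfg)
            ph, _ = sg.simulate_phenotypes(g, cfg)
            X = sg.standardize(sg.clean_markers(g)[0])
            K = build_kernels(X, ph)
            l_ge = fit_mixed_model(ph, K, "GE").reml_loglik
            l_gxe = fit_mixed_model(ph, K, "GExE").reml_loglik
            diffs.append(l_gxe - l_ge)
            wins += l_gxe > l_ge
        assert np.mean(diffs) > 0
        assert wins >= 15

    def test_empty_training_index_rejected(self, small_trial, small_kernels):
        _, _, pheno, _, _ = small_trial
        with pytest.raises(ValueError, match="empty"):
            fit_mixed_model(pheno, small_kernels, "GE", training_index=np.array([], int))
        with pytest.raises(ValueError, match="model"):
            fit_mixed_model(pheno, small_kernels, "bogus")


class TestPrediction:
    @pytest.mark.parametrize("model", ["EL", "GE", "GExE"])
    def test_matches_joint_gaussian_conditioning_oracle(self, model):
        """predict_blup equals dense conditional-mean computation."""
        K = tiny_kernels()
        ph = tiny_pheno()
        var_hat = {"var_eps": 0.7, "var_E": 0.9, "var_L": 0.4,
                   "var_g": 1.3, "var_gE": 0.6}
        train = np.array([0, 1, 2, 4])
        test = np.array([3, 5])
        fit = sg.FittedGSModel(
            model=model, mu_hat=1.2, var_hat=var_hat, kernels=K,
            training_index=train, y=ph["value"].to_numpy(), reml_loglik=0.0,
        )
        pred = predict_blup(fit, test)

        # independent oracle: build the full joint covariance and condition
        V = var_hat["var_eps"] * np.eye(6)
        for comp in MODEL_COMPONENTS[model]:
            V = V + var_hat[comp] * K.kernel(comp)
        resid = ph["value"].to_numpy()[train] - 1.2
        oracle = 1.2 + V[np.ix_(test, train)] @ np.linalg.solve(
            V[np.ix_(train, train)], resid
        )
        np.testing.assert_allclose(pred, oracle, atol=1e-8)

    def test_no_signal_predicts_intercept(self):
        K = tiny_kernels()
        ph = tiny_pheno()
        fit = sg.FittedGSModel(
            model="GExE", mu_hat=3.3,
            var_hat={"var_eps": 1.0, "var_E": 0.0, "var_g": 0.0, "var_gE": 0.0},
            kernels=K, training_index=np.array([0, 1, 2]),
            y=ph["value"].to_numpy(), reml_loglik=0.0,
        )
        np.testing.assert_allclose(predict_blup(fit, np.array([3, 4, 5])), 3.3)

    def test_unseen_environment_reduces_to_line_term(self):
        """EL predictions into a new environment are intercept + line BLUP."""
        K = tiny_kernels()
        ph = tiny_pheno()
        var_hat = {"var_eps": 0.5, "var_E": 1.0, "var_L": 0.8}
        train = np.array([0, 1, 2])       # all of env A
        test = np.array([3, 4, 5])        # env B unseen in training
        fit = sg.FittedGSModel(
            model="EL", mu_hat=1.0, var_hat=var_hat, kernels=K,
            training_index=train, y=ph["value"].to_numpy(), reml_loglik=0.0,
        )
        pred = predict_blup(fit, test)
        # the cross-environment covariance contributes nothing, so only the
        # line term moves predictions away from the intercept
        V = 0.5 * np.eye(6) + 1.0 * K.K_E + 0.8 * K.K_L
        resid = ph["value"].to_numpy()[train] - 1.0
        line_term = (0.8 * K.K_L)[np.ix_(test, train)] @ np.linalg.solve(
            V[np.ix_(train, train)], resid
        )
        np.testing.assert_allclose(pred, 1.0 + line_term, atol=1e-10)

    def test_overlap_rejected(self):
        K = tiny_kernels()
        ph = tiny_pheno()
        fit = sg.FittedGSModel(
            model="GE", mu_hat=0.0,
            var_hat={"var_eps": 1.0, "var_E": 0.0, "var_g": 0.0},
            kernels=K, training_index=np.array([0, 1, 2]),
            y=ph["value"].to_numpy(), reml_loglik=0.0,
        )
        with pytest.raises(ValueError, match="overlap"):
            predict_blup(fit, np.array([2, 3]))
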