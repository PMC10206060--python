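"""Genomic prediction models against closed-form and joint-solve oracles."""

import numpy as np
import pytest

from crosspred.io_qc import GenotypeMatrix, ValidationError
from crosspred.models import (
    additive_kernel,
    build_design,
    epistatic_kernel,
    fit_bayes,
    fit_egblup,
    fit_egblup_from_design,
    fit_rrblup,
    fitted_gebv,
    predict_gebv,
)
from conftest import random_genotypes


def simulate_additive(n, p, h2=0.7, seed=0, n_qtl=None):
    """Genotypes + phenotype from a purely additive architecture."""
    rng = np.random.default_rng(seed)
    G = random_genotypes(n, p, seed=seed)
    D = build_design(G)
    b = np.zeros(p)
    qtl = rng.choice(p, size=n_qtl or p, replace=False)
    b[qtl] = rng.standard_normal(len(qtl))
    g = (D.scores - D.scores.mean(0)) @ b
    vg = g.var()
    noise = rng.standard_normal(n) * np.sqrt(vg * (1 - h2) / h2) if h2 < 1 else 0.0
    return G, D, g + noise, g


class TestDesignAndKernels:
    def test_call_to_score_transform(self):
        G = GenotypeMatrix(["A"], ["m1", "m2", "m3"], np.array([[0, 1, 2]], dtype=np.int8))
        D = build_design(G)
        assert np.array_equal(D.scores[0], [-1.0, 0.0, 1.0])

    def test_missing_call_rejected(self):
        G = GenotypeMatrix(["A", "B"], ["m1"], np.array([[-1], [2]], dtype=np.int8))
        with pytest.raises(ValidationError, match="missing"):
            build_design(G)

    def test_additive_kernel_matches_hand_computation(self):
        G = random_genotypes(4, 3, seed=8)
        D = build_design(G)
        K = additive_kernel(D)
        Z = D.scores - D.scores.mean(0)
        raw = Z @ Z.T
        expected = raw / np.mean(np.diag(raw))
        assert np.allclose(K.values, expected)
        assert np.mean(np.diag(K.values)) == pytest.approx(1.0)

    def test_identical_lines_share_kernel_entries(self):
        calls = np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1]], dtype=np.int8)
        G = GenotypeMatrix(["A", "B", "C"], ["m1", "m2", "m3"], calls)
        K = additive_kernel(build_design(G))
        assert K.values[0, 1] == pytest.approx(K.values[0, 0])
        assert K.values[0, 1] == pytest.approx(K.values[1, 1])

    def test_epistatic_kernel_is_hadamard_square_rescaled(self):
        G = random_genotypes(6, 12, seed=4)
        K = additive_kernel(build_design(G))
        H = epistatic_kernel(K)
        raw = K.values * K.values
        assert np.allclose(H.values, raw / np.mean(np.diag(raw)))
        assert np.mean(np.diag(H.values)) == pytest.approx(1.0)

    def test_epistatic_kernel_stays_psd(self):
        for seed in range(5):
            K = additive_kernel(build_design(random_genotypes(10, 30, seed=seed)))
            H = epistatic_kernel(K)
            w = np.linalg.eigvalsh(H.values)
            assert w.min() > -1e-8


class TestRRBlup:
    def test_zero_markers_returns_intercept_only(self):
        G = GenotypeMatrix(["A", "B", "C"], [], np.empty((3, 0), dtype=np.int8))
        fit = fit_rrblup([1.0, 2.0, 3.0], build_design(G))
        assert fit.intercept == pytest.approx(2.0)
        assert fit.effects.size == 0

    def test_constant_response_gives_zero_effects(self):
        D = build_design(random_genotypes(10, 20, seed=1))
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_rrblup(np.full(10, 3.5), D)
        assert np.allclose(fit.effects, 0.0)
        assert fit.intercept == pytest.approx(3.5)

    def test_equivalence_with_gblup_at_matched_ratio(self):
        """RR-BLUP marker solutions reproduce GBLUP genetic values computed
        from the relationship matrix at the same variance ratio."""
        G, D, y, _ = simulate_additive(50, 200, h2=0.6, seed=2)
        fit = fit_rrblup(y, D)
        Z = D.scores - D.scores.mean(0)
        delta = fit.variance_components["delta"]
        K = Z @ Z.T
        g_oracle = K @ np.linalg.solve(K + delta * np.eye(50), y - fit.intercept)
        assert np.abs(Z @ fit.effects - g_oracle).max() < 1e-6

    def test_invariance_to_marker_permutation(self):
        G, D, y, _ = simulate_additive(30, 60, seed=3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(60)
        Gp = G.subset_markers(perm)
        f1 = fit_rrblup(y, D)
        f2 = fit_rrblup(y, build_design(Gp))
        gebv1 = fitted_gebv(f1, D)
        gebv2 = fitted_gebv(f2, build_design(Gp))
        for ln in G.line_ids:
            assert gebv1[ln] == pytest.approx(gebv2[ln], abs=1e-6)

    def test_shift_invariance(self):
        _, D, y, _ = simulate_additive(40, 80, seed=4)
        f1 = fit_rrblup(y, D)
        f2 = fit_rrblup(y + 100.0, D)
        g1 = np.array(list(fitted_gebv(f1, D).values()))
        g2 = np.array(list(fitted_gebv(f2, D).values()))
        assert np.allclose(g2 - g1, 100.0, atol=1e-6)

    def test_accuracy_increases_with_training_size(self):
        """Mean correlation with true genetic values rises with n over
        replicated draws at fixed h2."""
        mean_acc = {}
        for n in (50, 200, 500):
            accs = []
            for rep in range(10):
                _, D, y, g = simulate_additive(n, 100, h2=0.4, seed=1000 * n + rep, n_qtl=40)
                fit = fit_rrblup(y, D)
                gebv = (D.scores - D.scores.mean(0)) @ fit.effects
                accs.append(np.corrcoef(gebv, g)[0, 1])
            mean_acc[n] = np.mean(accs)
        assert mean_acc[50] < mean_acc[200] < mean_acc[500]


class TestBayes:
    def test_determinism_under_fixed_seed(self):
        _, D, y, _ = simulate_additive(25, 40, seed=5)
        a = fit_bayes(y, D, "BayesB", iterations=300, burn_in=100, seed=42)
        b = fit_bayes(y, D, "BayesB", iterations=300, burn_in=100, seed=42)
        assert a.intercept == b.intercept
        assert np.array_equal(a.effects, b.effects)

    def test_constant_response_effects_near_zero(self):
        D = build_design(random_genotypes(20, 30, seed=6))
        fit = fit_bayes(np.full(20, 1.0), D, "BayesRR", iterations=500, burn_in=100, seed=0)
        assert np.abs(fit.effects).max() < 0.05

    def test_fixed_variance_bayesrr_matches_closed_form_ridge(self):
        """With degenerate variance priors the BayesRR posterior mean is the
        ridge solution at lambda = sigma2_e / sigma2_b (MC tolerance)."""
        rng = np.random.default_rng(7)
        G = random_genotypes(30, 50, seed=7)
        D = build_design(G)
        y = rng.standard_normal(30)
        s2b, s2e = 0.02, 0.5
        fit = fit_bayes(y, D, "BayesRR", iterations=6000, burn_in=1000, seed=3,
                        fix_variances=(s2b, s2e))
        Z = D.scores - D.scores.mean(0)
        ridge = np.linalg.solve(Z.T @ Z + (s2e / s2b) * np.eye(50), Z.T @ (y - y.mean()))
        assert np.abs(fit.effects - ridge).max() < 0.02 * y.std()

    def test_iterations_must_exceed_burn_in(self):
        _, D, y, _ = simulate_additive(10, 10, seed=8)
        with pytest.raises(ValueError, match="exceed"):
            fit_bayes(y, D, "BayesRR", iterations=100, burn_in=100)

    def test_chain_length_stability(self):
        """Doubling the chain at fixed seed moves posterior-mean GEBVs by
        less than the spread between independent seeds."""
        _, D, y, _ = simulate_additive(30, 50, h2=0.5, seed=9)
        Z = D.scores - D.scores.mean(0)

        def gebv(iters, seed):
            f = fit_bayes(y, D, "BayesRR", iterations=iters, burn_in=500, seed=seed)
            return Z @ f.effects

        base = gebv(1500, 0)
        double = gebv(3000, 0)
        other_seeds = [gebv(1500, s) for s in (1, 2, 3)]
        seed_spread = max(np.abs(g - base).max() for g in other_seeds)
        assert np.abs(double - base).max() < seed_spread


class TestEGBlup:
    def test_constrained_epistasis_reduces_to_gblup(self):
        """With sigma2_aa pinned at 0 the fit equals single-kernel GBLUP
        computed by an independent spectral REML path."""
        _, D, y, _ = simulate_additive(50, 120, h2=0.6, seed=10)
        fit = fit_egblup_from_design(y, D, constrain_epistasis=True, precise=True)
        Gk = additive_kernel(D)
        d, U = np.linalg.eigh(Gk.values)
        n = len(y)
        ys, xs = U.T @ y, U.T @ np.ones(n)
        from scipy.optimize import minimize_scalar

        def nll(lt):
            t = np.exp(lt)
            w = 1.0 / (t * d + 1.0)
            xwx = np.sum(xs * xs * w)
            beta = np.sum(xs * ys * w) / xwx
            r = ys - xs * beta
            s2 = np.sum(r * r * w) / (n - 1)
            return 0.5 * ((n - 1) * np.log(s2) + np.sum(np.log(t * d + 1.0)) + np.log(xwx))

        res = minimize_scalar(nll, bounds=(-12, 12), method="bounded",
                              options={"xatol": 1e-12})
        t = np.exp(res.x)
        w = 1.0 / (t * d + 1.0)
        xwx = np.sum(xs * xs * w)
        beta = np.sum(xs * ys * w) / xwx
        r = ys - xs * beta
        g_oracle = t * Gk.values @ (U @ (w * r))
        assert np.abs(fit.train_gvalues - g_oracle).max() < 1e-6

    def test_constant_response_zero_genetic_values(self):
        D = build_design(random_genotypes(12, 20, seed=11))
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_egblup_from_design(np.full(12, 2.0), D)
        assert np.allclose(fit.train_gvalues, 0.0)

    def test_pure_additive_signal_keeps_epistatic_share_small(self):
        """On additive-only simulations the epistatic component should
        soak up little variance (median share < 0.2 over replicates)."""
        shares = []
        for rep in range(20):
            _, D, y, _ = simulate_additive(60, 80, h2=0.8, seed=200 + rep, n_qtl=40)
            fit = fit_egblup_from_design(y, D)
            vc = fit.variance_components
            shares.append(vc["sigma2_aa"] / (vc["sigma2_a"] + vc["sigma2_aa"] + 1e-12))
        assert np.median(shares) < 0.2


class TestPrediction:
    def test_marker_models_self_consistent_on_training_lines(self):
        G, D, y, _ = simulate_additive(30, 50, seed=12)
        for fit in (fit_rrblup(y, D),
                    fit_bayes(y, D, "BayesRR", iterations=300, burn_in=100, seed=0)):
            pred = predict_gebv(fit, G)
            fitted = fitted_gebv(fit, D)
            for ln in G.line_ids:
                assert pred[ln] == pytest.approx(fitted[ln], abs=1e-8)

    def test_duplicate_of_training_line_scores_identically(self):
        G, D, y, _ = simulate_additive(25, 40, seed=13)
        dup = GenotypeMatrix(["copy"], G.marker_ids, G.calls[[4]].copy())
        for fit in (fit_rrblup(y, D), fit_egblup_from_design(y, D)):
            fitted = (fitted_gebv(fit, D) if fit.model_tag != "EGBLUP"
                      else fitted_gebv(fit))
            pred = predict_gebv(fit, dup)
            assert pred["copy"] == pytest.approx(fitted[G.line_ids[4]], abs=1e-6)

    def test_marker_panel_mismatch_reported(self):
        G, D, y, _ = simulate_additive(20, 30, seed=14)
        fit = fit_rrblup(y, D)
        other = random_genotypes(3, 30, seed=15)
        other.marker_ids[0] = "rogue"
        with pytest.raises(ValidationError, match="rogue"):
            predict_gebv(fit, other)

    def test_egblup_projection_matches_joint_mixed_model(self):
        """Kernel projection for new lines equals solving one mixed model in
        which the new lines are unphenotyped (Henderson MME oracle)."""
        G, D, y, _ = simulate_additive(30, 60, h2=0.7, seed=16)
        new = random_genotypes(10, 60, seed=17)
        new.line_ids = [f"N{i}" for i in range(10)]
        fit = fit_egblup_from_design(y, D)
        pred = predict_gebv(fit, new)

        # oracle: joint kernels over train+new with training centering
        mu_cols = D.scores.mean(0)
        Zall = np.vstack([D.scores, new.calls.astype(float) - 1.0]) - mu_cols
        cA, cH = fit.kernel_scales
        Gj = (Zall @ Zall.T) / cA
        Hj = (Gj * Gj) / cH
        vc = fit.variance_components
        n_tr, n_all = 30, 40
        lam_a = vc["sigma2_e"] / max(vc["sigma2_a"], 1e-12)
        lam_aa = vc["sigma2_e"] / max(vc["sigma2_aa"], 1e-12)
        X = np.ones((n_tr, 1))
        Z = np.hstack([np.eye(n_tr), np.zeros((n_tr, 10))])
        jit = 1e-8 * n_all
        Gi = np.linalg.inv(Gj + jit * np.eye(n_all))
        Hi = np.linalg.inv(Hj + jit * np.eye(n_all))
        M = np.block([
            [X.T @ X, X.T @ Z, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam_a * Gi, Z.T @ Z],
            [Z.T @ X, Z.T @ Z, Z.T @ Z + lam_aa * Hi],
        ])
        rhs = np.concatenate([X.T @ y, Z.T @ y, Z.T @ y])
        sol = np.linalg.solve(M, rhs)
        mu = sol[0]
        u1 = sol[1:1 + n_all]
        u2 = sol[1 + n_all:]
        oracle = mu + u1[n_tr:] + u2[n_tr:]
        for i, ln in enumerate(new.line_ids):
            assert pred[ln] == pytest.approx(oracle[i], abs=1e-4)
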