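"""Genomic prediction models: RR-BLUP, BayesRR, BayesB and EGBLUP.

All four models regress training-line values on SNP scores coded
{-1, 0, +1} (call - 1) and centered by training-set column means; the same
centering is applied unchanged to any new genotypes scored later.

* RR-BLUP: ridge mixed model ``y = 1 mu + Z u + e`` with iid marker effects,
  variance ratio estimated by REML on the spectral decomposition of ZZ'.
* BayesRR / BayesB: single-site Gibbs samplers (numba-compiled).  BayesRR
  shrinks all markers under one effect variance with a scaled-inverse-chi-
  squared hyperprior; BayesB adds a per-marker variance and a prior point
  mass ``pi`` at zero effect.
* EGBLUP: genomic BLUP extended with an additive-by-additive epistatic
  kernel, the Hadamard square of the additive relationship matrix.  Both
  kernels are rescaled to mean diagonal 1 so their variance components are
  comparable.

Predictions for unphenotyped genotypes use the marker-effect vector
directly, or for EGBLUP the kernel projection
``g_new = K_new,train (K_train,train + eps I)^-1 g_train`` per kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize, minimize_scalar

from .io_qc import MISSING, GenotypeMatrix, ValidationError

__all__ = [
    "MarkerDesign",
    "KernelMatrix",
    "GPFit",
    "build_design",
    "additive_kernel",
    "epistatic_kernel",
    "fit_rrblup",
    "fit_bayes",
    "fit_egblup",
    "predict_gebv",
]

_PSD_TOL = 1e-8
_KERNEL_JITTER = 1e-8


@dataclass
class MarkerDesign:
    """Centered-ready marker score grid: score = call - 1 in {-1, 0, +1}."""

    line_ids: list[str]
    marker_ids: list[str]
    scores: np.ndarray  # n_lines x n_markers, float64

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over a line set."""

    line_ids: list[str]
    values: np.ndarray
    kind: str  # "additive" or "epistatic"
    center_means: np.ndarray | None = None  # training column means of scores
    scale: float = 1.0  # divisor applied to reach mean(diag) = 1

    def check_psd(self, tol: float = _PSD_TOL) -> None:
        # Cholesky probe with a tolerance-sized ridge: O(n^3/3) and cheap
        # compared to a full eigendecomposition at training-population sizes.
        n = self.values.shape[0]
        shift = tol * max(1.0, float(np.max(np.diag(self.values)))) * n
        try:
            np.linalg.cholesky(self.values + shift * np.eye(n))
        except np.linalg.LinAlgError:
            raise ValidationError("kernel is not PSD beyond tolerance") from None


@dataclass
class GPFit:
    """A trained genomic prediction model able to score new genotypes."""

    model_tag: str  # RRBLUP | BayesRR | BayesB | EGBLUP
    intercept: float
    marker_ids: list[str]
    center_means: np.ndarray  # training column means of scores
    effects: np.ndarray | None = None  # marker-effect models
    variance_components: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    # EGBLUP-only payload
    train_scores: np.ndarray | None = None  # centered training scores
    kernel_scales: tuple[float, float] | None = None  # (additive c, epistatic cH)
    kernel_weights: tuple[np.ndarray, np.ndarray] | None = None  # (K+eps)^-1 g per kernel
    train_gvalues: np.ndarray | None = None  # g1 + g2 on training lines
    train_line_ids: list[str] | None = None


def build_design(G: GenotypeMatrix) -> MarkerDesign:
    """Map calls {0,1,2} to scores {-1,0,+1}; refuses missing calls."""
    if G.has_missing():
        raise ValidationError("genotypes contain missing calls; impute before modelling")
    return MarkerDesign(
        list(G.line_ids), list(G.marker_ids), G.calls.astype(np.float64) - 1.0
    )


def design_to_calls(D: MarkerDesign) -> GenotypeMatrix:
    return GenotypeMatrix(
        list(D.line_ids), list(D.marker_ids), (D.scores + 1.0).astype(np.int8)
    )


def additive_kernel(D: MarkerDesign, center_means: np.ndarray | None = None) -> KernelMatrix:
    """VanRaden-style additive relationship matrix, mean diagonal scaled to 1."""
    if D.n_markers < 1:
        raise ValidationError("need at least one marker for a kernel")
    mu = D.scores.mean(axis=0) if center_means is None else np.asarray(center_means)
    Z = D.scores - mu
    raw = Z @ Z.T
    c = float(np.mean(np.diag(raw)))
    if c <= 0.0:
        warnings.warn("zero-variance marker panel; returning kernel of ones", stacklevel=2)
        return KernelMatrix(list(D.line_ids), np.ones_like(raw), "additive", mu, 1.0)
    return KernelMatrix(list(D.line_ids), raw / c, "additive", mu, c)


def epistatic_kernel(Gk: KernelMatrix) -> KernelMatrix:
    """Hadamard square of the additive kernel, rescaled to mean diagonal 1.

    PSD by the Schur product theorem.
    """
    if Gk.kind != "additive":
        raise ValidationError("epistatic kernel must be built from an additive kernel")
    raw = Gk.values * Gk.values
    c = float(np.mean(np.diag(raw)))
    if c <= 0.0:
        c = 1.0
    return KernelMatrix(list(Gk.line_ids), raw / c, "epistatic", Gk.center_means, c)


def _align_y(y, line_ids: list[str]) -> np.ndarray:
    """Accept a mapping/Series or an aligned array of training values."""
    if hasattr(y, "__getitem__") and not isinstance(y, np.ndarray):
        try:
            return np.array([float(y[i]) for i in line_ids])
        except (KeyError, TypeError, IndexError):
            pass
    arr = np.asarray(y, dtype=float)
    if arr.shape[0] != len(line_ids):
        raise ValidationError("y is not aligned with the training lines")
    return arr


# ---------------------------------------------------------------------------
# RR-BLUP


def fit_rrblup(y, D: MarkerDesign) -> GPFit:
    """Ridge-regression BLUP with the variance ratio estimated by REML.

    Works on the spectral decomposition of ZZ', so the cost is O(n^3) in the
    number of training lines regardless of marker count.
    """
    yv = _align_y(y, D.line_ids)
    n = D.n_lines
    if n < 2:
        raise ValidationError("RR-BLUP needs at least 2 training lines")
    mu_cols = D.scores.mean(axis=0)
    Z = D.scores - mu_cols
    if D.n_markers == 0:
        return GPFit(
            "RRBLUP", float(yv.mean()), [], mu_cols, effects=np.empty(0),
            variance_components={"sigma2_u": 0.0, "sigma2_e": float(yv.var(ddof=1))},
        )
    if np.allclose(yv, yv[0]):
        warnings.warn("constant response; RR-BLUP effects are zero", stacklevel=2)
        return GPFit(
            "RRBLUP", float(yv[0]), list(D.marker_ids), mu_cols,
            effects=np.zeros(D.n_markers),
            variance_components={"sigma2_u": 0.0, "sigma2_e": 0.0},
        )
    K = Z @ Z.T
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    ys = U.T @ yv
    xs = U.T @ np.ones(n)

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (d + delta)
        xwx = np.sum(xs * xs * w)
        beta = np.sum(xs * ys * w) / xwx
        r = ys - xs * beta
        s2 = np.sum(r * r * w) / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2) + np.sum(np.log(d + delta)) + np.log(xwx))

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    delta = float(np.exp(res.x))
    w = 1.0 / (d + delta)
    xwx = np.sum(xs * xs * w)
    beta = float(np.sum(xs * ys * w) / xwx)
    r = ys - xs * beta
    sigma2_u = float(np.sum(r * r * w) / (n - 1))
    sigma2_e = sigma2_u * delta
    # u = sigma2_u Z' V^-1 (y - X beta), with V = sigma2_u (K + delta I)
    effects = Z.T @ (U @ (r * w))
    return GPFit(
        "RRBLUP",
        beta,
        list(D.marker_ids),
        mu_cols,
        effects=effects,
        variance_components={"sigma2_u": sigma2_u, "sigma2_e": sigma2_e, "delta": delta},
    )


# ---------------------------------------------------------------------------
# Bayesian whole-genome regression (Gibbs)


@njit(cache=True)
def _gibbs_wgr(
    Z, y, iters, burn, seed, nu, s_b, nu_e, s_e, pi, bayesb,
    fix_variances, sigma2_b_fix, sigma2_e_fix,
):  # pragma: no cover - exercised through fit_bayes
    np.random.seed(seed)
    n, p = Z.shape
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        xtx[j] = s
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    b = np.zeros(p)
    sig_j = np.full(p, s_b * nu / max(nu - 2.0, 0.1))
    sigma2_b = s_b * nu / max(nu - 2.0, 0.1)
    sigma2_e = s_e * nu_e / max(nu_e - 2.0, 0.1)
    if fix_variances:
        sigma2_b = sigma2_b_fix
        sigma2_e = sigma2_e_fix
        for j in range(p):
            sig_j[j] = sigma2_b_fix
    e = y - mu
    mu_sum = 0.0
    b_sum = np.zeros(p)
    kept = 0
    for it in range(iters):
        # intercept
        for i in range(n):
            e[i] += mu
        m = 0.0
        for i in range(n):
            m += e[i]
        m /= n
        mu = m + np.random.normal() * np.sqrt(sigma2_e / n)
        for i in range(n):
            e[i] -= mu
        # marker effects
        ssb = 0.0
        n_in = 0
        for j in range(p):
            old = b[j]
            if old != 0.0:
                for i in range(n):
                    e[i] += Z[i, j] * old
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]
            if bayesb:
                vj = sig_j[j]
                if xtx[j] <= 0.0:
                    b[j] = 0.0
                else:
                    v0 = xtx[j] * sigma2_e
                    v1 = v0 + xtx[j] * xtx[j] * vj
                    log_bf = 0.5 * (np.log(v0 / v1) + rhs * rhs * (1.0 / v0 - 1.0 / v1))
                    if log_bf > 50.0:
                        prob = 1.0
                    else:
                        odds = ((1.0 - pi) / pi) * np.exp(log_bf)
                        prob = odds / (1.0 + odds)
                    if np.random.random() < prob:
                        cc = xtx[j] + sigma2_e / vj
                        b[j] = rhs / cc + np.random.normal() * np.sqrt(sigma2_e / cc)
                        n_in += 1
                    else:
                        b[j] = 0.0
                if not fix_variances:
                    # per-marker scaled-inv-chi2 update (prior draw when excluded)
                    if b[j] != 0.0:
                        sig_j[j] = (b[j] * b[j] + nu * s_b) / np.random.chisquare(nu + 1.0)
                    else:
                        sig_j[j] = nu * s_b / np.random.chisquare(nu)
            else:
                if xtx[j] <= 0.0:
                    b[j] = 0.0
                else:
                    cc = xtx[j] + sigma2_e / sigma2_b
                    b[j] = rhs / cc + np.random.normal() * np.sqrt(sigma2_e / cc)
                ssb += b[j] * b[j]
            if b[j] != 0.0:
                for i in range(n):
                    e[i] -= Z[i, j] * b[j]
        if not fix_variances:
            if not bayesb:
                sigma2_b = (ssb + nu * s_b) / np.random.chisquare(nu + p)
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma2_e = (sse + nu_e * s_e) / np.random.chisquare(nu_e + n)
        if it >= burn:
            kept += 1
            mu_sum += mu
            for j in range(p):
                b_sum[j] += b[j]
    return mu_sum / kept, b_sum / kept


def fit_bayes(
    y,
    D: MarkerDesign,
    model: str = "BayesRR",
    iterations: int = 1500,
    burn_in: int = 500,
    seed: int = 0,
    pi: float = 0.95,
    nu: float = 4.2,
    fix_variances: tuple[float, float] | None = None,
) -> GPFit:
    """Gibbs-sampled whole-genome regression (BayesRR or BayesB).

    Posterior means over the post-burn-in samples are returned as the
    intercept and effect vector.  ``fix_variances = (sigma2_b, sigma2_e)``
    freezes both variances (degenerate priors), which turns BayesRR into a
    Monte-Carlo ridge solver — useful for validation against the closed
    form.  ``pi`` is BayesB's prior mass at zero effect.
    """
    if model not in ("BayesRR", "BayesB"):
        raise ValueError(f"unknown Bayesian model {model!r}")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    yv = _align_y(y, D.line_ids)
    if D.n_lines < 2:
        raise ValidationError("need at least 2 training lines")
    mu_cols = D.scores.mean(axis=0)
    Z = np.ascontiguousarray(D.scores - mu_cols)
    vy = float(yv.var(ddof=1)) if len(yv) > 1 else 1.0
    if vy == 0.0:
        vy = 1e-12
    msx = float(np.sum(Z.var(axis=0))) or 1.0
    nu_e = nu
    # hyperprior scales: half the phenotypic variance to markers, half to noise
    frac = 0.5
    s_b_rr = vy * frac / msx * (nu - 2.0) / nu
    s_b_b = vy * frac / (msx * (1.0 - pi)) * (nu - 2.0) / nu  # spread over included markers
    s_e = vy * (1.0 - frac) * (nu_e - 2.0) / nu_e
    fix = fix_variances is not None
    sb_fix, se_fix = (fix_variances if fix else (0.0, 0.0))
    mu_hat, b_hat = _gibbs_wgr(
        Z, yv.astype(np.float64), int(iterations), int(burn_in), int(seed) & 0x7FFFFFFF,
        float(nu), float(s_b_b if model == "BayesB" else s_b_rr), float(nu_e), float(s_e),
        float(pi), model == "BayesB", fix, float(sb_fix), float(se_fix),
    )
    return GPFit(
        model,
        float(mu_hat),
        list(D.marker_ids),
        mu_cols,
        effects=np.asarray(b_hat),
        settings={
            "iterations": iterations, "burn_in": burn_in, "seed": int(seed),
            "pi": pi if model == "BayesB" else None, "nu": nu,
        },
    )


# ---------------------------------------------------------------------------
# EGBLUP


def _reml_neg_loglik(theta: np.ndarray, kernels: list[np.ndarray], y: np.ndarray):
    """Profiled REML negative log-likelihood at variance ratios theta.

    V = sigma2_e (sum_k theta_k K_k + I); sigma2_e and the intercept are
    profiled out analytically.
    """
    n = len(y)
    V0 = np.eye(n)
    for t, K in zip(theta, kernels):
        V0 += t * K
    L = np.linalg.cholesky(V0)
    X = np.ones((n, 1))
    a = np.linalg.solve(L, np.column_stack([y, X]))
    Vy, VX = a[:, 0], a[:, 1]
    xwx = VX @ VX
    beta = (VX @ Vy) / xwx
    r = Vy - VX * beta
    s2 = (r @ r) / (n - 1)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    nll = 0.5 * ((n - 1) * np.log(s2) + logdet + np.log(xwx))
    return nll, beta, s2, V0


def fit_egblup(
    y,
    Gk: KernelMatrix,
    Hk: KernelMatrix,
    constrain_epistasis: bool = False,
    max_iter: int = 1000,
    precise: bool = False,
) -> GPFit:
    """Two-kernel REML fit: y = 1 mu + g1 + g2 + e with g1 ~ (0, G sa2),
    g2 ~ (0, H saa2).

    The two variance ratios are found by direct maximization of the profiled
    restricted likelihood (Nelder-Mead on log ratios), which at a few
    hundred training lines converges far faster than component-wise EM.
    ``constrain_epistasis`` pins sigma2_aa at 0, reducing to single-kernel
    GBLUP.  ``precise`` tightens the optimizer and adds restarts; the
    default tolerances resolve GEBVs far below phenotypic noise while
    keeping large fits affordable.
    """
    if Gk.line_ids != Hk.line_ids:
        raise ValidationError("kernels are over different line sets")
    yv = _align_y(y, Gk.line_ids)
    n = len(yv)
    if n < 2:
        raise ValidationError("need at least 2 training lines")
    Gk.check_psd()
    Hk.check_psd()
    if np.allclose(yv, yv[0]):
        warnings.warn("constant response; EGBLUP genetic values are zero", stacklevel=2)
        zero = np.zeros(n)
        return GPFit(
            "EGBLUP", float(yv[0]), [], np.asarray(Gk.center_means),
            variance_components={"sigma2_a": 0.0, "sigma2_aa": 0.0, "sigma2_e": 0.0},
            kernel_weights=(zero, zero), train_gvalues=zero,
            train_line_ids=list(Gk.line_ids), kernel_scales=(Gk.scale, Hk.scale),
        )

    G = Gk.values
    H = Hk.values
    def _safe(theta_log, kernels):
        theta_v = np.exp(np.clip(theta_log, -30.0, 30.0))
        try:
            return _reml_neg_loglik(theta_v, kernels, yv)[0]
        except np.linalg.LinAlgError:
            return 1e30

    opts = (
        {"xatol": 1e-12, "fatol": 1e-14, "maxiter": max_iter}
        if precise
        else {"xatol": 1e-4, "fatol": 1e-9, "maxiter": max_iter}
    )
    if constrain_epistasis:
        def obj1(lt):
            return _safe([lt[0]], [G])
        res = minimize(obj1, x0=[0.0], method="Nelder-Mead", options=opts)
        theta = np.array([float(np.exp(np.clip(res.x[0], -30.0, 30.0))), 0.0])
        _, beta, s2, V0 = _reml_neg_loglik(theta[:1], [G], yv)
    else:
        def obj2(lt):
            return _safe(lt, [G, H])
        starts = ([0.0, 0.0], [1.0, -2.0], [-2.0, 1.0]) if precise else ([0.0, 0.0],)
        best = None
        for x0 in starts:
            res = minimize(obj2, x0=x0, method="Nelder-Mead", options=opts)
            if best is None or res.fun < best.fun:
                best = res
        res = best
        theta = np.exp(np.clip(res.x, -30.0, 30.0))
        _, beta, s2, V0 = _reml_neg_loglik(theta, [G, H], yv)
        theta = np.array([theta[0], theta[1]])
    if not np.isfinite(beta) or not np.isfinite(s2):
        raise RuntimeError("EGBLUP REML did not converge to a finite solution")

    sigma2_e = float(s2)
    sigma2_a = float(theta[0] * s2)
    sigma2_aa = float(theta[1] * s2)
    resid = yv - beta
    v0inv_r = np.linalg.solve(V0, resid)
    g1 = theta[0] * (G @ v0inv_r)
    g2 = theta[1] * (H @ v0inv_r)
    eps = _KERNEL_JITTER * n
    wG = np.linalg.solve(G + eps * np.eye(n), g1)
    wH = np.linalg.solve(H + eps * np.eye(n), g2)
    return GPFit(
        "EGBLUP",
        float(beta),
        [],
        np.asarray(Gk.center_means),
        variance_components={
            "sigma2_a": sigma2_a, "sigma2_aa": sigma2_aa, "sigma2_e": sigma2_e,
        },
        kernel_scales=(Gk.scale, Hk.scale),
        kernel_weights=(wG, wH),
        train_gvalues=g1 + g2,
        train_line_ids=list(Gk.line_ids),
    )


def fit_egblup_from_design(y, D: MarkerDesign, **kwargs) -> GPFit:
    """Convenience: build both kernels from a design, then fit, recording
    the training scores needed for later kernel projection."""
    Gk = additive_kernel(D)
    Hk = epistatic_kernel(Gk)
    fit = fit_egblup(y, Gk, Hk, **kwargs)
    fit.marker_ids = list(D.marker_ids)
    fit.center_means = np.asarray(Gk.center_means)
    fit.train_scores = D.scores - Gk.center_means
    return fit


# ---------------------------------------------------------------------------
# prediction


def _new_scores(fit: GPFit, newgeno: GenotypeMatrix) -> np.ndarray:
    if newgeno.has_missing():
        raise ValidationError("new genotypes contain missing calls")
    if list(newgeno.marker_ids) != list(fit.marker_ids):
        extra = set(newgeno.marker_ids) - set(fit.marker_ids)
        missing = set(fit.marker_ids) - set(newgeno.marker_ids)
        raise ValidationError(
            "marker panel mismatch between fit and new genotypes; "
            f"missing from new: {sorted(missing)[:5]}, unexpected: {sorted(extra)[:5]}"
        )
    return (newgeno.calls.astype(np.float64) - 1.0) - fit.center_means


def predict_gebv(fit: GPFit, newgeno: GenotypeMatrix) -> dict[str, float]:
    """Score new genotypes on the training marker panel.

    Marker-effect models: GEBV = mu + z . u with z centered by training
    means.  EGBLUP: additive and epistatic kernels are extended to the new
    lines with the training centering, and each genetic component is
    projected through its kernel.
    """
    if fit.model_tag in ("RRBLUP", "BayesRR", "BayesB"):
        Z = _new_scores(fit, newgeno)
        vals = fit.intercept + Z @ fit.effects
        return dict(zip(newgeno.line_ids, map(float, vals)))
    if fit.model_tag == "EGBLUP":
        if fit.train_scores is None:
            raise ValidationError(
                "EGBLUP fit lacks training scores; use fit_egblup_from_design"
            )
        Zn = _new_scores(fit, newgeno)
        cA, cH = fit.kernel_scales
        K_cross = (Zn @ fit.train_scores.T) / cA
        H_cross = (K_cross * K_cross) / cH
        wG, wH = fit.kernel_weights
        vals = fit.intercept + K_cross @ wG + H_cross @ wH
        return dict(zip(newgeno.line_ids, map(float, vals)))
    raise ValueError(f"unknown model tag {fit.model_tag!r}")


def fitted_gebv(fit: GPFit, D: MarkerDesign | None = None) -> dict[str, float]:
    """GEBVs of the training lines themselves."""
    if fit.model_tag == "EGBLUP":
        vals = fit.intercept + fit.train_gvalues
        return dict(zip(fit.train_line_ids, map(float, vals)))
    if D is None:
        raise ValueError("marker-effect models need the training design")
    Z = D.scores - fit.center_means
    vals = fit.intercept + Z @ fit.effects
    return dict(zip(D.line_ids, map(float, vals)))
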