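"""Multi-environment yield-trial analysis: entry BLUPs and heritability.

The trial model is

    y = mu + E + M + E(r) + G + E(G) + e

with environment E (year x location), the maturity covariate M (days from
planting to maturity, entered linearly) and replicate-within-environment
E(r) fixed, and genotype G and genotype-by-environment E(G) random.  The
variance components sigma2_G, sigma2_GxE and sigma2_R are estimated by
EM-REML on Henderson's mixed-model equations; negative iterates are floored
at zero (boundary REML).  Entry BLUPs are the solutions for G, reported on
the deviation scale.

Broad-sense heritability on an entry-mean basis:

    H2 = sigma2_G / (sigma2_G + sigma2_GxE / e + sigma2_R / (e r))

for a trial with e environments and r replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["VarianceComponents", "fit_pheno_model", "entry_mean_heritability"]


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_GxE: float
    sigma2_R: float
    converged: bool = True
    n_iter: int = 0
    gxe_confounded: bool = False  # single environment: GxE inestimable

    def __post_init__(self) -> None:
        if min(self.sigma2_G, self.sigma2_GxE, self.sigma2_R) < 0:
            raise ValueError("variance components must be non-negative")


def _incidence(labels: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(labels)
    Z = np.zeros((len(labels), len(cats.categories)))
    Z[np.arange(len(labels)), cats.codes] = 1.0
    return Z, list(cats.categories)


def fit_pheno_model(
    records: pd.DataFrame,
    max_iter: int = 500,
    tol: float = 1e-6,
    outlier_z: float = 4.0,
) -> tuple[pd.Series, VarianceComponents]:
    """EM-REML fit of the trial mixed model.

    ``records`` is long format with columns ``line_id``, ``year``,
    ``location`` (or a pre-built ``environment``), ``rep``,
    ``maturity_days`` and ``yield``.  Records lacking maturity are dropped
    with a logged count.  Returns (entry BLUPs as a Series indexed by
    line_id, variance components).
    """
    df = records.copy()
    if "environment" not in df.columns:
        df["environment"] = df["year"].astype(str) + "_" + df["location"].astype(str)
    n_before = len(df)
    df = df.dropna(subset=["maturity_days", "yield"])
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d records lacking maturity or yield", dropped)
    if df["line_id"].nunique() < 2:
        raise ValueError("need at least 2 distinct lines")
    if len(df) < 3:
        raise ValueError("too few records to fit the trial model")

    y = df["yield"].to_numpy(dtype=float)
    n = len(y)

    # fixed effects: intercept + environment + rep-within-environment + maturity
    env, env_levels = _incidence(df["environment"].astype(str))
    single_env = env.shape[1] == 1
    rep_in_env = df["environment"].astype(str) + "/" + df["rep"].astype(str)
    rep, _ = _incidence(rep_in_env)
    mat = df["maturity_days"].to_numpy(dtype=float)
    mat = (mat - mat.mean())[:, None]
    X = np.column_stack([np.ones(n), env[:, 1:], rep[:, 1:], mat])
    # drop linearly dependent fixed columns (rep nested coding overlaps env)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    X = X[:, keep]
    p_rank = X.shape[1]

    Z1, lines = _incidence(df["line_id"].astype(str))
    gxe_lab = df["line_id"].astype(str) + "@" + df["environment"].astype(str)
    Z2, _ = _incidence(gxe_lab)
    q1, q2 = Z1.shape[1], Z2.shape[1]

    vy = float(y.var(ddof=1)) or 1.0
    s2g, s2ge, s2e = vy / 3, vy / 3, vy / 3
    if single_env:
        s2ge = 0.0

    W = np.column_stack([X, Z1, Z2])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    i1 = slice(X.shape[1], X.shape[1] + q1)
    i2 = slice(X.shape[1] + q1, X.shape[1] + q1 + q2)

    floor = vy * 1e-10
    sol = None
    it = 0
    for it in range(1, max_iter + 1):
        lam1 = s2e / max(s2g, floor)
        lam2 = s2e / max(s2ge, floor) if not single_env else 1e12
        M = WtW.copy()
        M[i1, i1] += np.eye(q1) * lam1
        M[i2, i2] += np.eye(q2) * lam2
        Minv = np.linalg.inv(M)
        sol = Minv @ Wty
        u1 = sol[i1]
        u2 = sol[i2]
        s2e_new = (yty - sol @ Wty) / (n - p_rank)
        s2g_new = (u1 @ u1 + s2e_new * np.trace(Minv[i1, i1])) / q1
        if single_env:
            s2ge_new = 0.0
        else:
            s2ge_new = (u2 @ u2 + s2e_new * np.trace(Minv[i2, i2])) / q2
        s2g_new = max(s2g_new, 0.0)
        s2ge_new = max(s2ge_new, 0.0)
        s2e_new = max(s2e_new, floor)
        rel = max(
            abs(s2g_new - s2g) / max(s2g, floor),
            abs(s2ge_new - s2ge) / max(s2ge, floor) if not single_env else 0.0,
            abs(s2e_new - s2e) / max(s2e, floor),
        )
        s2g, s2ge, s2e = s2g_new, s2ge_new, s2e_new
        if rel < tol:
            break
    converged = it < max_iter
    if not converged:
        logger.warning("EM-REML hit max_iter=%d (last rel change %.2e)", max_iter, rel)

    # flag (not drop) extreme standardized residuals for the caller's log
    resid = y - W @ sol
    sd = resid.std(ddof=p_rank) or 1.0
    n_out = int((np.abs(resid / sd) > outlier_z).sum())
    if n_out:
        logger.warning("%d records exceed |standardized residual| > %g", n_out, outlier_z)

    blups = pd.Series(sol[i1], index=lines, name="entry_blup")
    vc = VarianceComponents(
        sigma2_G=float(s2g if s2g > floor * 10 else max(s2g, 0.0)),
        sigma2_GxE=float(s2ge),
        sigma2_R=float(s2e),
        converged=converged,
        n_iter=it,
        gxe_confounded=single_env,
    )
    return blups, vc


def entry_mean_heritability(vc: VarianceComponents, e: int, r: int) -> float:
    """H2 = s2G / (s2G + s2GxE/e + s2R/(e r)) for e environments, r reps."""
    if e < 1 or r < 1:
        raise ValueError("e and r must be at least 1")
    denom = vc.sigma2_G + vc.sigma2_GxE / e + vc.sigma2_R / (e * r)
    if denom == 0.0:
        raise ValueError("all variance components are zero; H2 undefined")
    return vc.sigma2_G / denom
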