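"""Validation of cross prediction against observed cross means.

The design mirrors a retrospective breeding-program test: crosses that were
actually made have phenotyped progeny, so each cross has an observed value
(the mean entry BLUP of its progeny).  Prediction accuracy is the Spearman
rank correlation between predicted cross values and these observed means,
measured across replicate tests that each sample a subset of the crosses.

Three training-set compositions probe the effect of relatedness:

* FTS — full training set, every line retained;
* WFS — all direct progeny of the predicted crosses removed (parents kept),
  the composition closest to real deployment where a cross is predicted
  before it is ever made;
* RTS — the same *number* of lines removed as WFS, but sampled from lines
  that are not progeny of the predicted crosses, separating the effect of
  training-set size from that of relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import GeneticMap, GenotypeMatrix
from .models import (
    build_design,
    fit_bayes,
    fit_egblup_from_design,
    fit_rrblup,
)
from .ocs import CrossSpec, evaluate_progeny_gebvs, simulate_cross_progeny

__all__ = [
    "TrainingComposition",
    "ValidationConfig",
    "ValidationResult",
    "build_training_set",
    "observed_cross_value",
    "spearman_accuracy",
    "run_validation",
]

MODEL_TAGS = ("RRBLUP", "BayesRR", "BayesB", "EGBLUP")


@dataclass
class TrainingComposition:
    tag: str  # FTS | WFS | RTS
    retained: list[str]
    removed: list[str]
    seed: int | None = None


@dataclass
class ValidationConfig:
    models: tuple[str, ...] = MODEL_TAGS
    criteria: tuple[float, ...] = (0.0, 0.1, 0.2)
    ts_tags: tuple[str, ...] = ("FTS", "WFS", "RTS")
    n_reps: int = 50
    sample_size: int = 40
    n_progeny: int = 500
    final_generation: int = 5
    bayes_iterations: int = 1500
    bayes_burn_in: int = 500
    seed: int = 0


@dataclass
class ValidationResult:
    grid: pd.DataFrame  # rep, ts, model, criterion, accuracy
    predictions: pd.DataFrame  # rep, ts, model, criterion, cross, predicted, observed
    config: ValidationConfig
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.summary = (
            self.grid.groupby(["ts", "model", "criterion"])["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def build_training_set(
    all_lines,
    predicted_crosses,
    pedigree: dict[str, tuple[str, str]],
    tag: str,
    seed=None,
) -> TrainingComposition:
    """Assemble a training composition; parents of predicted crosses are
    always retained."""
    all_lines = [str(x) for x in all_lines]
    cross_ids = {CrossSpec(*c).cross_id if not isinstance(c, CrossSpec) else c.cross_id
                 for c in predicted_crosses}
    parents = {p for cid in cross_ids for p in cid}
    progeny = {
        ln for ln in all_lines
        if ln in pedigree and tuple(pedigree[ln]) in cross_ids
    }
    if tag == "FTS":
        return TrainingComposition("FTS", list(all_lines), [])
    if tag == "WFS":
        removed = [ln for ln in all_lines if ln in progeny]
        retained = [ln for ln in all_lines if ln not in progeny]
        return TrainingComposition("WFS", retained, removed)
    if tag == "RTS":
        n_remove = sum(1 for ln in all_lines if ln in progeny)
        pool = [ln for ln in all_lines if ln not in progeny and ln not in parents]
        if len(pool) < n_remove:
            raise ValueError(
                f"RTS infeasible: need to remove {n_remove} lines but only "
                f"{len(pool)} non-progeny, non-parent lines exist"
            )
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        removed = set(rng.choice(pool, size=n_remove, replace=False).tolist())
        retained = [ln for ln in all_lines if ln not in removed]
        return TrainingComposition("RTS", retained, sorted(removed), seed=None)
    raise ValueError(f"unknown training-set tag {tag!r}")


def observed_cross_value(cross, progeny_blups, progeny_of: dict) -> float:
    """Mean entry BLUP of a cross's phenotyped progeny."""
    cid = cross.cross_id if isinstance(cross, CrossSpec) else tuple(map(str, cross))
    vals = [
        float(progeny_blups[ln])
        for ln, origin in progeny_of.items()
        if tuple(origin) == cid and ln in progeny_blups
    ]
    if not vals:
        raise ValueError(f"cross {cid} has no phenotyped progeny")
    return float(np.mean(vals))


def spearman_accuracy(predicted: dict, observed: dict) -> float:
    """Spearman rank correlation over a common cross set (average ranks for
    ties); raises on constant input where the correlation is undefined."""
    keys = sorted(predicted, key=str)
    if set(keys) != set(observed):
        raise ValueError("predicted and observed cover different crosses")
    if len(keys) < 3:
        raise ValueError("need at least 3 crosses for a rank correlation")
    p = np.array([predicted[k] for k in keys], dtype=float)
    o = np.array([observed[k] for k in keys], dtype=float)
    if np.allclose(p, p[0]) or np.allclose(o, o[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho = stats.spearmanr(p, o).statistic
    return float(rho)


def _fit_model(tag: str, y, design, cfg: ValidationConfig, seed: int):
    if tag == "RRBLUP":
        return fit_rrblup(y, design)
    if tag in ("BayesRR", "BayesB"):
        return fit_bayes(
            y, design, model=tag,
            iterations=cfg.bayes_iterations, burn_in=cfg.bayes_burn_in, seed=seed,
        )
    if tag == "EGBLUP":
        return fit_egblup_from_design(y, design)
    raise ValueError(f"unknown model tag {tag!r}")


def run_validation(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    blups,
    crosses,
    pedigree: dict[str, tuple[str, str]],
    config: ValidationConfig | None = None,
    observed: dict | None = None,
) -> ValidationResult:
    """Replicated cross-prediction test.

    Per replicate: sample ``sample_size`` crosses without replacement,
    build each requested training composition, fit each model on the
    retained lines, simulate each sampled cross's progeny once (shared
    across models and criteria), score the crosses, and record the Spearman
    accuracy of every (composition, model, criterion) combination.  Fully
    deterministic given ``config.seed``.
    """
    cfg = config or ValidationConfig()
    crosses = [c if isinstance(c, CrossSpec) else CrossSpec(*c) for c in crosses]
    if cfg.sample_size > len(crosses):
        raise ValueError(
            f"sample_size {cfg.sample_size} exceeds the {len(crosses)} available crosses"
        )
    for tag in cfg.models:
        if tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {tag!r}")
    if observed is None:
        observed = {c: observed_cross_value(c, blups, pedigree) for c in crosses}

    master = np.random.SeedSequence(cfg.seed)
    rep_seqs = master.spawn(cfg.n_reps)
    grid_rows = []
    pred_rows = []
    for rep, seq in enumerate(rep_seqs):
        rng = np.random.default_rng(seq)
        pick = rng.choice(len(crosses), size=cfg.sample_size, replace=False)
        sampled = [crosses[i] for i in sorted(pick)]
        # one progeny set per cross per replicate, shared everywhere
        progeny = {
            c: simulate_cross_progeny(
                c, geno, gmap, cfg.n_progeny, cfg.final_generation, seed=rng
            )
            for c in sampled
        }
        for ts_tag in cfg.ts_tags:
            comp = build_training_set(
                geno.line_ids, sampled, pedigree, ts_tag, seed=rng
            )
            train_geno = geno.subset_lines(comp.retained)
            design = build_design(train_geno)
            y = {ln: float(blups[ln]) for ln in comp.retained}
            for model in cfg.models:
                fit_seed = int(rng.integers(0, 2**31 - 1))
                fit = _fit_model(model, y, design, cfg, fit_seed)
                per_crit: dict[float, dict] = {float(i): {} for i in cfg.criteria}
                for c in sampled:
                    cv = evaluate_progeny_gebvs(c, fit, progeny[c], cfg.criteria)
                    for i in cfg.criteria:
                        per_crit[float(i)][c] = cv.uc[float(i)]
                for i, pred in per_crit.items():
                    obs_sub = {c: observed[c] for c in sampled}
                    acc = spearman_accuracy(pred, obs_sub)
                    grid_rows.append(
                        {"rep": rep, "ts": ts_tag, "model": model,
                         "criterion": i, "accuracy": acc}
                    )
                    for c in sampled:
                        pred_rows.append(
                            {"rep": rep, "ts": ts_tag, "model": model, "criterion": i,
                             "cross": str(c), "predicted": pred[c], "observed": obs_sub[c]}
                        )
    return ValidationResult(
        grid=pd.DataFrame(grid_rows),
        predictions=pd.DataFrame(pred_rows),
        config=cfg,
    )
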