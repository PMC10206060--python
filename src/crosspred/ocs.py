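"""Cross scoring and ranking by the usefulness criterion.

A cross is valued through the GEBVs of its simulated RIL progeny.  The
usefulness criterion at selection intensity ``i`` is classically
``UC = mu + i * sigma_g``; here it is operationalized as the mean of the
top-``i`` fraction of progeny GEBVs, with ``i = 0`` reducing to the plain
progeny mean (MV).  Dominance variance is absent in RILs and epistatic
variance is assumed minimal, so the SD of progeny GEBVs stands in for the
genetic SD and the top-fraction mean is the natural empirical counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import GeneticMap, GenotypeMatrix
from .meiosis import ProgenySet, simulate_ril_progeny
from .models import GPFit, predict_gebv

__all__ = [
    "CrossSpec",
    "CrossValue",
    "enumerate_crosses",
    "usefulness",
    "evaluate_cross",
    "rank_crosses",
]


@dataclass(frozen=True)
class CrossSpec:
    """An unordered pair of parents; (A, B) == (B, A)."""

    parent1_id: str
    parent2_id: str

    def __post_init__(self) -> None:
        a, b = str(self.parent1_id), str(self.parent2_id)
        if a > b:
            a, b = b, a
        object.__setattr__(self, "parent1_id", a)
        object.__setattr__(self, "parent2_id", b)

    @property
    def cross_id(self) -> tuple[str, str]:
        return (self.parent1_id, self.parent2_id)

    def __str__(self) -> str:
        return f"{self.parent1_id}x{self.parent2_id}"


@dataclass
class CrossValue:
    """Per-cross progeny GEBV summary."""

    cross: CrossSpec
    progeny_mean: float
    progeny_sd: float
    uc: dict[float, float]
    model_tag: str
    n_progeny: int
    seed: int | None = None
    gebvs: np.ndarray | None = field(default=None, repr=False)


def enumerate_crosses(parent_ids, allow_self: bool = False) -> list[CrossSpec]:
    """All unordered parent pairs in lexicographic order (selfs off by default)."""
    ids = [str(p) for p in parent_ids]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate parent ids: {dup}")
    if len(ids) < 2 and not allow_self:
        raise ValueError("need at least 2 parents")
    ids = sorted(ids)
    out = []
    for i, a in enumerate(ids):
        if allow_self:
            out.append(CrossSpec(a, a))
        for b in ids[i + 1:]:
            out.append(CrossSpec(a, b))
    return out


def usefulness(gebvs, i: float = 0.0) -> float:
    """Mean of the top-``i`` fraction of values; ``i = 0`` is the plain mean.

    The head count is ``k = max(1, round(i * n))`` with round-half-away-
    from-zero, so i = 0.1 or 0.2 of 500 progeny select exactly 50 or 100.
    """
    v = np.asarray(list(gebvs), dtype=float)
    if v.size == 0:
        raise ValueError("empty GEBV collection")
    if not 0.0 <= i < 1.0:
        raise ValueError("selection intensity must be in [0, 1)")
    if i == 0.0:
        return float(v.mean())
    k = max(1, int(np.floor(i * v.size + 0.5)))
    top = np.sort(v)[-k:]
    return float(top.mean())


def evaluate_progeny_gebvs(
    cross: CrossSpec,
    fit: GPFit,
    progeny: ProgenySet,
    intensities=(0.0, 0.1, 0.2),
    seed: int | None = None,
) -> CrossValue:
    """Score an already-simulated progeny set under one fitted model."""
    gebv_map = predict_gebv(fit, progeny.genotypes)
    g = np.array(list(gebv_map.values()))
    sd = float(g.std(ddof=1)) if g.size > 1 else 0.0
    return CrossValue(
        cross=cross,
        progeny_mean=float(g.mean()),
        progeny_sd=sd,
        uc={float(i): usefulness(g, float(i)) for i in intensities},
        model_tag=fit.model_tag,
        n_progeny=g.size,
        seed=seed,
        gebvs=g,
    )


def simulate_cross_progeny(
    cross: CrossSpec,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    n_progeny: int = 500,
    final_generation: int = 5,
    seed=None,
) -> ProgenySet:
    return simulate_ril_progeny(
        geno.row(cross.parent1_id),
        geno.row(cross.parent2_id),
        gmap,
        n=n_progeny,
        final_generation=final_generation,
        seed=seed,
        cross_id=cross.cross_id,
    )


def evaluate_cross(
    cross: CrossSpec,
    fit: GPFit,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    n_progeny: int = 500,
    intensities=(0.0, 0.1, 0.2),
    seed: int | None = None,
) -> CrossValue:
    """Simulate a cross's RIL progeny and summarize their predicted GEBVs."""
    progeny = simulate_cross_progeny(cross, geno, gmap, n_progeny, seed=seed)
    cv = evaluate_progeny_gebvs(cross, fit, progeny, intensities, seed=seed)
    cv.gebvs = None  # keep CrossValue light once summarized
    return cv


def rank_crosses(
    crosses,
    fit: GPFit,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    criterion: float = 0.0,
    n_progeny: int = 500,
    intensities=(0.0, 0.1, 0.2),
    seed: int | None = None,
) -> pd.DataFrame:
    """Evaluate and rank crosses, highest chosen criterion first.

    One progeny set is simulated per cross (seeded per cross off the master
    seed) and shared by every requested intensity.  Ties break on the
    lexicographic cross id for a deterministic table.
    """
    crosses = list(crosses)
    if not crosses:
        raise ValueError("no crosses to rank")
    if criterion not in [float(i) for i in intensities]:
        intensities = tuple(intensities) + (criterion,)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(crosses))
    rows = []
    for cs, sub in zip(crosses, child_seeds):
        cv = evaluate_cross(
            cs, fit, geno, gmap, n_progeny=n_progeny,
            intensities=intensities, seed=np.random.default_rng(sub),
        )
        row = {
            "parent1": cs.parent1_id,
            "parent2": cs.parent2_id,
            "mean": cv.progeny_mean,
            "sd": cv.progeny_sd,
        }
        for i in sorted(cv.uc):
            row[f"uc_{i:g}"] = cv.uc[i]
        rows.append(row)
    df = pd.DataFrame(rows)
    crit_col = f"uc_{float(criterion):g}"
    df = df.sort_values(
        [crit_col, "parent1", "parent2"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
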