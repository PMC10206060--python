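"""Fully synthetic breeding scenarios for end-to-end testing.

Emulates an elite inbred breeding program: homozygous founders on a
multi-chromosome genetic map, a quantitative trait with additive and
additive-by-additive QTL, a training population bred from the founders by
random crossing plus single seed descent, and a set of validation crosses
realized with phenotyped RIL progeny (whose cross-of-origin is recorded so
training sets of varying relatedness can be constructed).

Defaults mirror a soybean-sized program: 20 chromosomes of 125 cM,
~3,800 mapped SNPs, 35 founder parents, a 702-line training population,
42 validation crosses with 16 phenotyped progeny each, and an entry-mean
heritability of about 0.5 — the scale of trait determinism typical of
multi-environment yield trials.  The trait architecture (100 additive QTL,
30 additive-by-additive pairs drawn among them) is a generic polygenic
yield architecture; it is a modelling choice, not an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_qc import GeneticMap, GenotypeMatrix
from .meiosis import simulate_gametes, simulate_ril_progeny
from .ocs import CrossSpec

__all__ = [
    "ScenarioConfig",
    "BreedingScenario",
    "simulate_founders",
    "simulate_trait",
    "make_breeding_scenario",
    "true_genetic_values",
]


@dataclass
class ScenarioConfig:
    n_chromosomes: int = 20
    chromosome_length_cM: float = 125.0
    n_markers: int = 3762
    n_founders: int = 35
    n_training_lines: int = 702
    n_qtl_additive: int = 100
    n_qtl_epistatic_pairs: int = 30
    h2_target: float = 0.5
    n_validation_crosses: int = 42
    progeny_per_cross: int = 16
    final_generation: int = 5
    mask_qtl: bool = False  # drop QTL markers from the panel (marker-QTL LD regime)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        if self.n_markers < self.n_qtl_additive:
            raise ValueError("marker count must be at least the QTL count")
        if self.n_markers < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")


@dataclass
class BreedingScenario:
    """Everything a pipeline run needs, plus the generating truth."""

    config: ScenarioConfig
    geno: GenotypeMatrix  # training lines + realized progeny
    gmap: GeneticMap
    phenotypes: pd.Series  # entry-BLUP-like line values (deviation scale)
    true_values: pd.Series  # additive + epistatic QTL sum per line
    qtl_table: pd.DataFrame
    crosses: list[CrossSpec]
    pedigree: dict[str, tuple[str, str]]  # progeny line -> cross of origin
    parent_ids: list[str]
    training_line_ids: list[str] = field(default_factory=list)

    @property
    def all_line_ids(self) -> list[str]:
        return list(self.geno.line_ids)

    def observed_cross_values(self) -> dict[CrossSpec, float]:
        from .validation import observed_cross_value

        return {
            c: observed_cross_value(c, self.phenotypes, self.pedigree)
            for c in self.crosses
        }


def simulate_founders(cfg: ScenarioConfig, seed=None) -> tuple[GenotypeMatrix, GeneticMap]:
    """Homozygous founders with per-marker allele frequencies ~ U(0.1, 0.9).

    Markers are placed uniformly at random along each chromosome (then
    sorted); the U(0.1, 0.9) frequency spectrum keeps most markers
    polymorphic after QC, mimicking a chip designed for common variants.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    rows = []
    for c, k in enumerate(per_chrom, start=1):
        pos = np.sort(rng.uniform(0.0, cfg.chromosome_length_cM, size=k))
        for j, p in enumerate(pos, start=1):
            rows.append((f"chr{c:02d}_m{j:04d}", f"chr{c:02d}", float(p)))
    gmap = GeneticMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM"]))
    freqs = rng.uniform(0.1, 0.9, size=cfg.n_markers)
    calls = (rng.random((cfg.n_founders, cfg.n_markers)) < freqs).astype(np.int8) * 2
    ids = [f"FND{i + 1:03d}" for i in range(cfg.n_founders)]
    return GenotypeMatrix(ids, gmap.marker_ids, calls), gmap


def _draw_qtl(cfg: ScenarioConfig, marker_ids: list[str], rng) -> pd.DataFrame:
    qtl_idx = np.sort(rng.choice(len(marker_ids), size=cfg.n_qtl_additive, replace=False))
    add_eff = rng.standard_normal(cfg.n_qtl_additive)
    rows = [
        {"kind": "additive", "marker_i": int(i), "marker_j": -1, "effect": float(a)}
        for i, a in zip(qtl_idx, add_eff)
    ]
    n_pairs = cfg.n_qtl_epistatic_pairs
    if n_pairs > 0:
        if cfg.n_qtl_additive < 2:
            raise ValueError("epistatic pairs need at least 2 additive QTL")
        # pairs share loci with the additive QTL: additive-by-additive form
        pair_eff = rng.standard_normal(n_pairs)
        for e in pair_eff:
            i, j = rng.choice(qtl_idx, size=2, replace=False)
            rows.append(
                {"kind": "epistatic", "marker_i": int(i), "marker_j": int(j), "effect": float(e)}
            )
    return pd.DataFrame(rows)


def true_genetic_values(geno: GenotypeMatrix, qtl_table: pd.DataFrame) -> pd.Series:
    """Additive + additive-by-additive QTL sum on the {-1,0,+1} score scale."""
    S = geno.calls.astype(float) - 1.0
    g = np.zeros(geno.n_lines)
    for _, row in qtl_table.iterrows():
        if row["kind"] == "additive":
            g += row["effect"] * S[:, int(row["marker_i"])]
        else:
            g += row["effect"] * S[:, int(row["marker_i"])] * S[:, int(row["marker_j"])]
    return pd.Series(g, index=geno.line_ids, name="true_genetic_value")


def simulate_trait(
    geno: GenotypeMatrix, gmap: GeneticMap, cfg: ScenarioConfig, seed=None
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Draw a QTL architecture and phenotype every line at the target h2.

    Residual noise is centered and rescaled so the realized variance ratio
    var(g) / var(y) equals ``h2_target`` exactly (h2 = 1 gives y = g).
    Returns (phenotypes, true genetic values, qtl table).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed + 1 if seed is None else seed
    )
    qtl = _draw_qtl(cfg, geno.marker_ids, rng)
    g = true_genetic_values(geno, qtl)
    h2 = cfg.h2_target
    var_g = float(g.var(ddof=1))
    if h2 >= 1.0 or var_g == 0.0:
        noise = np.zeros(len(g))
        if var_g == 0.0 and h2 < 1.0:
            noise = rng.standard_normal(len(g))
    else:
        if h2 == 0.0:
            raise ValueError("h2_target = 0 leaves the residual variance undefined")
        noise = rng.standard_normal(len(g))
        noise = noise - noise.mean()
        sd_obs = noise.std(ddof=1)
        target_sd = np.sqrt(var_g * (1.0 - h2) / h2)
        noise = noise * (target_sd / sd_obs if sd_obs > 0 else 0.0)
    y = pd.Series(g.to_numpy() + noise, index=geno.line_ids, name="phenotype")
    return y, g, qtl


def _random_cross_lines(
    parents: GenotypeMatrix, gmap: GeneticMap, n_out: int,
    final_generation: int, rng, prefix: str
) -> GenotypeMatrix:
    """One F5-derived RIL from each of ``n_out`` random parent pairs.

    Vectorized across crosses: every output line is an independent row in a
    batched single-seed-descent, so this is cheap even for many lines.
    """
    n_par, m = parents.calls.shape
    i1 = rng.integers(0, n_par, size=n_out)
    shift = rng.integers(1, n_par, size=n_out)
    i2 = (i1 + shift) % n_par  # distinct mate for every cross
    P1 = parents.calls[i1]
    P2 = parents.calls[i2]
    # split each parent row into two haplotypes (residual hets phased in
    # coupling; arbitrary but harmless for near-homozygous material)
    A = simulate_gametes((P1 >= 1).astype(np.uint8), (P1 == 2).astype(np.uint8), gmap, rng)
    B = simulate_gametes((P2 >= 1).astype(np.uint8), (P2 == 2).astype(np.uint8), gmap, rng)
    H1, H2 = A, B
    for _ in range(final_generation - 1):
        g1 = simulate_gametes(H1, H2, gmap, rng)
        g2 = simulate_gametes(H1, H2, gmap, rng)
        H1, H2 = g1, g2
    calls = (H1 + H2).astype(np.int8)
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_out)]
    return GenotypeMatrix(ids, parents.marker_ids, calls)


def make_breeding_scenario(cfg: ScenarioConfig) -> BreedingScenario:
    """Build a complete scenario: founders -> training population ->
    validation crosses with realized, phenotyped progeny.

    The training population descends from the founders through two
    generations of random crossing, each followed by single seed descent to
    the configured generation.  Validation crosses are sampled among a
    founder-sized subset of training lines (the "parents"); their realized
    progeny are phenotyped and included in the line set, with the pedigree
    recording each progeny's cross of origin.
    """
    rng = np.random.default_rng(cfg.seed)
    founders, gmap = simulate_founders(cfg, rng)
    gen1 = _random_cross_lines(
        founders, gmap, cfg.n_training_lines, cfg.final_generation, rng, "G1_"
    )
    training = _random_cross_lines(
        gen1, gmap, cfg.n_training_lines, cfg.final_generation, rng, "TL"
    )
    n_parents = min(cfg.n_founders, cfg.n_training_lines)
    parent_ids = sorted(
        rng.choice(training.line_ids, size=n_parents, replace=False).tolist()
    )
    max_crosses = n_parents * (n_parents - 1) // 2
    if cfg.n_validation_crosses > max_crosses:
        raise ValueError(
            f"{cfg.n_validation_crosses} crosses requested but only "
            f"{max_crosses} unordered pairs exist among {n_parents} parents"
        )
    all_pairs = [(a, b) for k, a in enumerate(parent_ids) for b in parent_ids[k + 1:]]
    pick = rng.choice(len(all_pairs), size=cfg.n_validation_crosses, replace=False)
    crosses = [CrossSpec(*all_pairs[i]) for i in sorted(pick)]

    pedigree: dict[str, tuple[str, str]] = {}
    progeny_blocks = []
    for ci, cs in enumerate(crosses, start=1):
        ps = simulate_ril_progeny(
            training.row(cs.parent1_id),
            training.row(cs.parent2_id),
            gmap,
            n=cfg.progeny_per_cross,
            final_generation=cfg.final_generation,
            seed=rng,
            cross_id=cs.cross_id,
            line_prefix=f"VC{ci:02d}",
        )
        progeny_blocks.append(ps.genotypes)
        for lid in ps.genotypes.line_ids:
            pedigree[lid] = cs.cross_id

    all_ids = list(training.line_ids)
    all_calls = [training.calls]
    for blk in progeny_blocks:
        all_ids.extend(blk.line_ids)
        all_calls.append(blk.calls)
    geno = GenotypeMatrix(all_ids, gmap.marker_ids, np.vstack(all_calls))

    pheno, tgv, qtl = simulate_trait(geno, gmap, cfg, rng)

    if cfg.mask_qtl:
        qtl_cols = sorted(
            set(qtl["marker_i"].tolist()) | set(qtl.loc[qtl["marker_j"] >= 0, "marker_j"])
        )
        keep = np.setdiff1d(np.arange(geno.n_markers), np.array(qtl_cols, dtype=int))
        masked = geno.subset_markers(keep)
        from .io_qc import harmonize

        geno_out, gmap_out = harmonize(masked, gmap)
    else:
        geno_out, gmap_out = geno, gmap

    return BreedingScenario(
        config=cfg,
        geno=geno_out,
        gmap=gmap_out,
        phenotypes=pheno,
        true_values=tgv,
        qtl_table=qtl,
        crosses=crosses,
        pedigree=pedigree,
        parent_ids=parent_ids,
        training_line_ids=list(training.line_ids),
    )


def small_config(**overrides) -> ScenarioConfig:
    """A desk-scale configuration for tests and examples."""
    base = ScenarioConfig(
        n_chromosomes=4,
        chromosome_length_cM=100.0,
        n_markers=400,
        n_founders=12,
        n_training_lines=120,
        n_qtl_additive=30,
        n_qtl_epistatic_pairs=10,
        h2_target=0.5,
        n_validation_crosses=12,
        progeny_per_cross=10,
        seed=0,
    )
    return replace(base, **overrides)
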