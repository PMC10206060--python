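"""Meiosis and single-seed-descent simulation of F5-derived RIL progeny.

Crossovers follow the no-interference (Haldane) model: per chromosome the
crossover count is Poisson with mean equal to the chromosome's map length in
Morgans, and crossover positions are uniform on the map interval.  This is
the chi-squared interference model at m = 0.  No obligate chiasma is
enforced, so a meiosis may pass a chromosome through intact.

Progeny are produced by single seed descent: each progeny traces back to an
independent F1 meiosis, and each subsequent generation selfs a single plant
(two independent gametes) until the requested generation, F5 by default.
F5-derived lines keep their residual heterozygosity (about 1/16 per
originally segregating locus); calls of 1 are emitted as such.

All randomness flows through a single :class:`numpy.random.Generator`, so a
fixed seed yields bit-identical progeny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_qc import MISSING, GeneticMap, GenotypeMatrix, ValidationError

__all__ = [
    "Haplotype",
    "ProgenySet",
    "founder_haplotypes",
    "simulate_gamete",
    "simulate_gametes",
    "simulate_ril_progeny",
]

#: A haplotype is a 1-D uint8 array of allele counts in {0, 1}, one per
#: mapped marker, in map (storage) order.
Haplotype = np.ndarray


@dataclass
class ProgenySet:
    """Simulated progeny of one cross."""

    cross_id: tuple[str, str]
    genotypes: GenotypeMatrix
    generation: int = 5

    @property
    def n_progeny(self) -> int:
        return self.genotypes.n_lines


def _check_panel(row: np.ndarray, gmap: GeneticMap) -> None:
    if row.shape[0] != gmap.n_markers:
        raise ValidationError(
            f"genotype row has {row.shape[0]} markers but map has {gmap.n_markers}; "
            "harmonize genotypes and map first"
        )


def founder_haplotypes(
    parent_row: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> tuple[Haplotype, Haplotype]:
    """Split a 0/1/2 genotype row into two phased haplotypes.

    Homozygous calls split deterministically; heterozygous calls are phased
    by one coin flip per chromosome (adequate for the near-homozygous inbred
    parents this simulator targets — true phase is unknowable from single-
    site calls anyway).
    """
    row = np.asarray(parent_row)
    _check_panel(row, gmap)
    if (row == MISSING).any():
        raise ValidationError("parent genotype contains missing calls; impute first")
    h1 = (row >= 1).astype(np.uint8)
    h2 = (row == 2).astype(np.uint8)
    het = row == 1
    if het.any():
        for idx, _pos in gmap.blocks():
            if rng.integers(0, 2) == 1:
                block_het = het[idx]
                sel = idx[block_het]
                h1[sel], h2[sel] = h2[sel].copy(), h1[sel].copy()
    return h1, h2


def simulate_gametes(
    H1: np.ndarray, H2: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw one gamete per row from row-wise haplotype pairs.

    ``H1`` and ``H2`` are (n, m) arrays: row i holds the two haplotypes of
    individual i.  Chromosomes recombine independently; within a chromosome
    the returned gamete alternates source haplotype at each crossover point.
    Markers at identical positions always co-segregate.
    """
    H1 = np.atleast_2d(H1)
    H2 = np.atleast_2d(H2)
    n, m = H1.shape
    if m != gmap.n_markers:
        raise ValidationError("haplotypes are not aligned to the genetic map")
    out = np.empty((n, m), dtype=np.uint8)
    for idx, pos in gmap.blocks():
        lo, hi = pos[0], pos[-1]
        length_morgans = (hi - lo) / 100.0
        k = rng.poisson(length_morgans, size=n)
        start = rng.integers(0, 2, size=n)
        kmax = int(k.max()) if n else 0
        if kmax == 0 or length_morgans == 0.0:
            parity = np.zeros((n, len(pos)), dtype=np.int64)
        else:
            xo = rng.uniform(lo, hi, size=(n, kmax))
            live = np.arange(kmax)[None, :] < k[:, None]
            xo = np.where(live, xo, np.inf)
            # crossover at x switches source for all markers with position > x
            parity = (xo[:, :, None] < pos[None, None, :]).sum(axis=1)
        src = (start[:, None] + parity) % 2
        out[:, idx] = np.where(src == 0, H1[:, idx], H2[:, idx])
    return out


def simulate_gamete(
    h1: Haplotype, h2: Haplotype, gmap: GeneticMap, rng: np.random.Generator
) -> Haplotype:
    """Single-gamete convenience wrapper around :func:`simulate_gametes`."""
    return simulate_gametes(h1[None, :], h2[None, :], gmap, rng)[0]


def simulate_ril_progeny(
    p1_row: np.ndarray,
    p2_row: np.ndarray,
    gmap: GeneticMap,
    n: int = 500,
    final_generation: int = 5,
    seed: int | np.random.Generator | None = None,
    cross_id: tuple[str, str] = ("P1", "P2"),
    line_prefix: str | None = None,
) -> ProgenySet:
    """Simulate ``n`` independent F(final_generation)-derived RILs of a cross.

    Each progeny starts from its own F1 meiosis (one gamete from each
    parent) and is then selfed by single seed descent, drawing two
    independent gametes per generation, until the requested generation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if final_generation < 2:
        raise ValueError("final_generation must be at least 2 (F2 or later)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p1_row = np.asarray(p1_row)
    p2_row = np.asarray(p2_row)
    _check_panel(p1_row, gmap)
    _check_panel(p2_row, gmap)

    a1, a2 = founder_haplotypes(p1_row, gmap, rng)
    b1, b2 = founder_haplotypes(p2_row, gmap, rng)
    # F1: one gamete from each parent, independently per progeny
    H1 = simulate_gametes(np.tile(a1, (n, 1)), np.tile(a2, (n, 1)), gmap, rng)
    H2 = simulate_gametes(np.tile(b1, (n, 1)), np.tile(b2, (n, 1)), gmap, rng)
    # selfing F1 -> F2 -> ... -> F(final_generation)
    for _ in range(final_generation - 1):
        g1 = simulate_gametes(H1, H2, gmap, rng)
        g2 = simulate_gametes(H1, H2, gmap, rng)
        H1, H2 = g1, g2
    calls = (H1 + H2).astype(np.int8)
    prefix = line_prefix or f"{cross_id[0]}x{cross_id[1]}"
    ids = [f"{prefix}_{i + 1:04d}" for i in range(n)]
    geno = GenotypeMatrix(ids, gmap.marker_ids, calls)
    return ProgenySet(cross_id=tuple(map(str, cross_id)), genotypes=geno, generation=final_generation)
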