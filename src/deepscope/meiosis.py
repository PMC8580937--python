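"""Gamete formation, crossing and single-seed descent.

Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson with mean equal to the map length in Morgans, crossover positions are
uniform on the map and there is no interference and no mutation.  All
operations are vectorized over batches of parents; a cycle's worth of
offspring is produced by a handful of array passes per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout

__all__ = ["Couple", "CrossPlan", "gametes", "gamete", "cross", "single_seed_descent"]


@dataclass(frozen=True)
class Couple:
    """One planned cross: parent ids, offspring count and a block label."""

    p1: int
    p2: int
    n_offspring: int = 20
    label: str = "elite"


@dataclass
class CrossPlan:
    """Ordered crossing block for one breeding cycle.

    Default contract: 50 couples x 20 offspring = 1000 F1 hybrids.  The
    ``metadata`` dict carries audit information (e.g. pre-selection pool
    sizes used by the layered strategies).
    """

    couples: list[Couple]
    metadata: dict = field(default_factory=dict)

    @property
    def n_offspring(self) -> int:
        return sum(c.n_offspring for c in self.couples)

    def labels(self) -> list[str]:
        return [c.label for c in self.couples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.p1, c.p2, c.n_offspring, c.label) for c in self.couples],
            columns=["P1", "P2", "n_offspring", "label"],
        )


def gametes(
    haplotypes: np.ndarray, layout: GenomeLayout, rng: np.random.Generator
) -> np.ndarray:
    """Draw one recombinant gamete from each of a batch of parents.

    ``haplotypes`` has shape (n, 2, n_loci); the result has shape
    (n, n_loci).  Per chromosome and parent, the transmitted phase at a locus
    is the starting haplotype (fair coin) flipped once per crossover that
    falls below the locus position.
    """
    h = np.asarray(haplotypes)
    n = h.shape[0]
    out = np.empty((n, h.shape[2]), dtype=h.dtype)
    for c, sl in enumerate(layout.chromosome_slices()):
        pos = layout.positions[sl]
        length_m = layout.chrom_lengths[c] / 100.0  # cM -> Morgans
        start = rng.integers(0, 2, size=n)
        if length_m <= 0 or pos.size == 0:
            phase = np.repeat(start[:, None], pos.size, axis=1)
        else:
            k = rng.poisson(length_m, size=n)
            kmax = int(k.max())
            if kmax == 0:
                phase = np.repeat(start[:, None], pos.size, axis=1)
            else:
                xo = rng.uniform(0.0, layout.chrom_lengths[c], size=(n, kmax))
                xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
                below = (xo[:, :, None] < pos[None, None, :]).sum(axis=1)
                phase = (start[:, None] + below) % 2
        chrom = h[:, :, sl]
        out[:, sl] = np.where(phase == 0, chrom[:, 0, :], chrom[:, 1, :])
    return out


def gamete(
    parent_haplotypes: np.ndarray, layout: GenomeLayout, rng: np.random.Generator
) -> np.ndarray:
    """Single gamete from one parent given as a (2, n_loci) array."""
    return gametes(np.asarray(parent_haplotypes)[None], layout, rng)[0]


def cross(
    p1_haplotypes: np.ndarray,
    p2_haplotypes: np.ndarray,
    n_offspring: int,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """F1 offspring of one couple: one gamete from each parent per offspring."""
    h1 = np.repeat(np.asarray(p1_haplotypes)[None], n_offspring, axis=0)
    h2 = np.repeat(np.asarray(p2_haplotypes)[None], n_offspring, axis=0)
    return np.stack([gametes(h1, layout, rng), gametes(h2, layout, rng)], axis=1)


def cross_batch(
    parent_haps_1: np.ndarray,
    parent_haps_2: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """One offspring per row of the two aligned parent-haplotype batches."""
    return np.stack(
        [gametes(parent_haps_1, layout, rng), gametes(parent_haps_2, layout, rng)],
        axis=1,
    )


def single_seed_descent(
    haplotypes: np.ndarray,
    generations: int,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance each line by selfing, one seed per line per generation.

    Two generations take F1s to F3s; the expected heterozygous fraction at
    initially heterozygous loci halves each generation.
    """
    if generations < 0:
        raise ValueError("generations must be nonnegative")
    h = np.asarray(haplotypes)
    for _ in range(generations):
        h = np.stack([gametes(h, layout, rng), gametes(h, layout, rng)], axis=1)
    return h
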