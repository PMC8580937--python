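"""Genome coordinate system, trait architecture and population-level genetic metrics.

The simulated genome is a set of biallelic loci laid out on a genetic map
(centimorgan positions on a fixed number of chromosomes).  A subset of loci act
as QTLs carrying additive substitution effects drawn from a geometric series;
the complement is used as markers for genomic prediction.  True genetic values,
phenotypes over multiple environments, and the diversity metrics used to judge
breeding strategies (top-10 mean genetic value, polymorphic fraction, maximum
reachable genetic value) all live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "TraitArchitecture",
    "EnvironmentModel",
    "build_trait",
    "genetic_values",
    "genetic_value",
    "simulate_phenotypes",
    "max_reachable_gv",
    "population_metrics",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Coordinate frame for meiosis, prediction and segment windows.

    Loci carry a single global index (0-based internally; delimited I/O is
    1-based).  ``qtl_indices`` and ``marker_indices`` partition the loci:
    QTLs define the true genetic value, markers are what the prediction model
    and the selection scores see.

    Parameters
    ----------
    chrom_lengths : ndarray of float
        Genetic map length of each chromosome in centimorgans.
    loci_per_chromosome : ndarray of int
        Number of loci on each chromosome; sums to the total locus count.
    positions : ndarray of float
        Map position of each locus in cM, within-chromosome, nondecreasing.
    chrom_of : ndarray of int
        Chromosome index of each locus.
    qtl_indices, marker_indices : ndarray of int
        Complementary sorted subsets of ``arange(n_loci)``.
    """

    chrom_lengths: np.ndarray
    loci_per_chromosome: np.ndarray
    positions: np.ndarray
    chrom_of: np.ndarray
    qtl_indices: np.ndarray
    marker_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_lengths", np.asarray(self.chrom_lengths, dtype=float))
        object.__setattr__(self, "loci_per_chromosome", np.asarray(self.loci_per_chromosome, dtype=int))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "chrom_of", np.asarray(self.chrom_of, dtype=int))
        object.__setattr__(self, "qtl_indices", np.sort(np.asarray(self.qtl_indices, dtype=int)))
        object.__setattr__(self, "marker_indices", np.sort(np.asarray(self.marker_indices, dtype=int)))
        n = self.positions.size
        if self.loci_per_chromosome.sum() != n:
            raise ValueError("loci_per_chromosome must sum to the total locus count")
        merged = np.concatenate([self.qtl_indices, self.marker_indices])
        if not np.array_equal(np.sort(merged), np.arange(n)):
            raise ValueError("qtl_indices and marker_indices must partition all loci")
        for c in range(self.n_chromosomes):
            sel = self.chrom_of == c
            if sel.sum() != self.loci_per_chromosome[c]:
                raise ValueError("chromosome assignment inconsistent with loci_per_chromosome")
            pos = self.positions[sel]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions must be nondecreasing within chromosome {c}")
            if pos.size and (pos[0] < 0 or pos[-1] > self.chrom_lengths[c]):
                raise ValueError(f"positions outside chromosome {c} bounds")

    @property
    def n_loci(self) -> int:
        return int(self.positions.size)

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom_lengths.size)

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_indices.size)

    @property
    def n_markers(self) -> int:
        return int(self.marker_indices.size)

    def chromosome_slices(self) -> list[slice]:
        """Contiguous global-index slice of each chromosome."""
        ends = np.cumsum(self.loci_per_chromosome)
        starts = np.concatenate([[0], ends[:-1]])
        return [slice(int(s), int(e)) for s, e in zip(starts, ends)]

    @classmethod
    def default(
        cls,
        n_loci: int = 1590,
        n_chromosomes: int = 7,
        n_qtl: int = 100,
        chrom_length_cm: float = 150.0,
        rng: np.random.Generator | None = None,
    ) -> "GenomeLayout":
        """Evenly spaced loci on equally long chromosomes; QTLs sampled
        uniformly without replacement from all loci (seeded via ``rng``)."""
        if n_qtl >= n_loci:
            raise ValueError("n_qtl must be smaller than n_loci")
        rng = np.random.default_rng(rng)
        base, extra = divmod(n_loci, n_chromosomes)
        counts = np.array([base + (1 if c < extra else 0) for c in range(n_chromosomes)])
        positions = np.concatenate(
            [np.linspace(0.0, chrom_length_cm, m + 2)[1:-1] for m in counts]
        )
        chrom_of = np.repeat(np.arange(n_chromosomes), counts)
        qtl = np.sort(rng.choice(n_loci, size=n_qtl, replace=False))
        markers = np.setdiff1d(np.arange(n_loci), qtl)
        return cls(
            chrom_lengths=np.full(n_chromosomes, float(chrom_length_cm)),
            loci_per_chromosome=counts,
            positions=positions,
            chrom_of=chrom_of,
            qtl_indices=qtl,
            marker_indices=markers,
        )

    def to_frame(self) -> pd.DataFrame:
        """Genetic map as a tidy table (1-based locus ids)."""
        role = np.full(self.n_loci, "marker", dtype=object)
        role[self.qtl_indices] = "QTL"
        return pd.DataFrame(
            {
                "chromosome": self.chrom_of + 1,
                "locus_id": np.arange(1, self.n_loci + 1),
                "position_cM": self.positions,
                "role": role,
            }
        )

    def write_map(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_map(cls, path, chrom_lengths=None) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t")
        chrom = df["chromosome"].to_numpy(int) - 1
        counts = np.bincount(chrom)
        pos = df["position_cM"].to_numpy(float)
        if chrom_lengths is None:
            chrom_lengths = [pos[chrom == c].max() for c in range(counts.size)]
        qtl = np.flatnonzero(df["role"].to_numpy() == "QTL")
        markers = np.flatnonzero(df["role"].to_numpy() != "QTL")
        return cls(chrom_lengths, counts, pos, chrom, qtl, markers)


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive trait with geometric-series QTL effects.

    The k-th QTL (k = 1..L) has substitution effect ``a**k`` with
    ``a = (L-1)/(L+1)``: the favorable homozygote contributes ``+a**k``, the
    unfavorable homozygote ``-a**k`` and the heterozygote 0.
    ``favorable_allele[k]`` records which of the 0/1 codes is favorable.
    """

    L: int
    a: float
    qtl_effects: np.ndarray
    favorable_allele: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtl_effects", np.asarray(self.qtl_effects, dtype=float))
        object.__setattr__(self, "favorable_allele", np.asarray(self.favorable_allele, dtype=np.int8))
        if self.qtl_effects.size != self.L or self.favorable_allele.size != self.L:
            raise ValueError("effects and favorable-allele labels must have length L")


def build_trait(L: int, rng: np.random.Generator | None = None) -> TraitArchitecture:
    """Build the geometric-effects trait for ``L`` QTLs.

    The favorable allele at each QTL is the founder-coded '1' allele with
    probability 0.5 (seeded through ``rng``), recorded for reproducibility.
    """
    if L < 1:
        raise ValueError("trait needs at least one QTL (L >= 1)")
    rng = np.random.default_rng(rng)
    a = (L - 1) / (L + 1)
    if L == 1:
        warnings.warn("L=1 gives a=0: the single QTL has zero effect", stacklevel=2)
    effects = a ** np.arange(1, L + 1, dtype=float)
    favorable = (rng.random(L) < 0.5).astype(np.int8)
    return TraitArchitecture(L=L, a=a, qtl_effects=effects, favorable_allele=favorable)


def _qtl_dosage(haplotypes: np.ndarray, trait: TraitArchitecture, layout: GenomeLayout) -> np.ndarray:
    """Signed favorable-allele dosage at each QTL: -1, 0 or +1 per individual."""
    h = np.asarray(haplotypes)
    if h.ndim == 2:  # single individual (2, n_loci)
        h = h[None]
    q = h[:, :, layout.qtl_indices]
    if np.any(q < 0):
        raise ValueError("missing allele at a QTL locus")
    return (q == trait.favorable_allele[None, None, :]).sum(axis=1).astype(np.int64) - 1


def genetic_values(haplotypes: np.ndarray, trait: TraitArchitecture, layout: GenomeLayout) -> np.ndarray:
    """True genetic value of each individual: sum of signed QTL effects."""
    return _qtl_dosage(haplotypes, trait, layout) @ trait.qtl_effects


def genetic_value(haplotypes: np.ndarray, trait: TraitArchitecture, layout: GenomeLayout) -> float:
    """Genetic value of a single individual given as a (2, n_loci) array."""
    return float(genetic_values(haplotypes, trait, layout)[0])


@dataclass(frozen=True)
class EnvironmentModel:
    """Additive multi-environment phenotyping model.

    A phenotype is the mean over ``n_env`` environments of
    ``g_i + e_j + eps_ij`` where ``e_j ~ N(0, sigma_E2)`` is shared by every
    individual in environment j and ``eps_ij ~ N(0, sigma_e2)`` is the
    plot-level residual.  ``sigma_E2`` defaults to eight times the founder
    genetic variance and ``sigma_e2`` is scaled so plot-level heritability
    ``sigma_g2 / (sigma_g2 + sigma_e2)`` equals the target ``h2``.
    """

    n_env: int = 3
    sigma_E2: float = 0.0
    sigma_e2: float = 0.0
    h2: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_E2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")
        if self.n_env < 1:
            raise ValueError("need at least one environment")

    @classmethod
    def from_founders(
        cls,
        founder_gv: np.ndarray,
        h2: float = 0.5,
        env_scale: float = 8.0,
        n_env: int = 3,
    ) -> "EnvironmentModel":
        """Calibrate variance components on the founder population."""
        if not 0 < h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        sigma_g2 = float(np.var(founder_gv))
        return cls(
            n_env=n_env,
            sigma_E2=env_scale * sigma_g2,
            sigma_e2=sigma_g2 * (1 - h2) / h2,
            h2=h2,
        )


def simulate_phenotypes(
    gv: np.ndarray, env: EnvironmentModel, rng: np.random.Generator
) -> np.ndarray:
    """Phenotype each individual once across ``env.n_env`` environments.

    Environment effects are redrawn per phenotyping event (new trials each
    cycle); residuals are independent per individual x environment.
    """
    gv = np.asarray(gv, dtype=float)
    e = rng.normal(0.0, np.sqrt(env.sigma_E2), size=env.n_env)
    eps = rng.normal(0.0, np.sqrt(env.sigma_e2), size=(gv.size, env.n_env))
    return gv + e.mean() + eps.mean(axis=1)


def max_reachable_gv(haplotypes: np.ndarray, trait: TraitArchitecture, layout: GenomeLayout) -> float:
    """Best genetic value still attainable by the population.

    Per QTL: a fixed locus contributes its fixed homozygote value (+-a^k); a
    segregating locus optimistically contributes +a^k.  Non-increasing under
    truncation selection (alleles can only be lost) and never below the best
    individual in the population.
    """
    h = np.asarray(haplotypes)
    if h.ndim == 2:
        h = h[None]
    if h.shape[0] == 0:
        raise ValueError("population must be nonempty")
    q = h[:, :, layout.qtl_indices]
    fav = trait.favorable_allele[None, None, :]
    any_fav = np.any(q == fav, axis=(0, 1))
    any_unfav = np.any(q != fav, axis=(0, 1))
    # segregating or fixed-favorable -> +a^k ; fixed-unfavorable -> -a^k
    sign = np.where(any_fav, 1.0, -1.0)
    del any_unfav
    return float(sign @ trait.qtl_effects)


def polymorphic_fraction(haplotypes: np.ndarray) -> float:
    """Fraction of all loci at which both alleles are present."""
    h = np.asarray(haplotypes)
    if h.ndim == 2:
        h = h[None]
    flat = h.reshape(-1, h.shape[-1])
    return float(np.mean(flat.min(axis=0) != flat.max(axis=0)))


def population_metrics(
    haplotypes: np.ndarray, trait: TraitArchitecture, layout: GenomeLayout
) -> dict[str, float]:
    """Per-cycle summary record of a breeding population.

    ``top10_mean_gv`` is the mean true genetic value of the top
    ``min(10, n)`` individuals — the commercialization candidates.
    """
    h = np.asarray(haplotypes)
    if h.ndim == 2:
        h = h[None]
    if h.shape[0] == 0:
        raise ValueError("population must be nonempty")
    gv = genetic_values(h, trait, layout)
    top = np.sort(gv)[::-1][: min(10, gv.size)]
    return {
        "n": float(gv.size),
        "top10_mean_gv": float(top.mean()),
        "mean_gv": float(gv.mean()),
        "var_gv": float(np.var(gv)),
        "polymorphic_fraction": polymorphic_fraction(h),
        "max_reachable_gv": max_reachable_gv(h, trait, layout),
    }
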