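"""Population container, synthetic founder pools and gene-bank construction.

Founders emulate two differentiated panels of fully homozygous inbred lines
(two North American six-row spring barley breeding programs at default sizes
384 and 380 lines over 1590 SNP loci).  The gene bank is built by crossing a
random member of pool A with the pool-B partner that maximizes the S-score —
its members are heterozygous F1s carrying high allelic diversity but low
genetic value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout

__all__ = [
    "Individual",
    "Population",
    "GeneBank",
    "generate_founders",
    "build_gene_bank",
    "read_population",
    "write_population",
]


@dataclass(frozen=True)
class Individual:
    """Read-only view of one diploid individual."""

    id: int
    haplotypes: np.ndarray  # (2, n_loci) 0/1
    origin: str
    birth_cycle: int


class Population:
    """Ordered collection of diploid individuals, array-backed.

    ``haplotypes`` has shape (n, 2, n_loci) with alleles coded 0/1.  Origin
    tags record provenance (``poolA``, ``poolB``, ``elite``, ``layer0`` ..
    ``layer4``, ``genebank``).  Ids are unique within a population.
    """

    def __init__(
        self,
        haplotypes: np.ndarray,
        ids: np.ndarray | None = None,
        origins: np.ndarray | str = "unknown",
        birth_cycles: np.ndarray | int = 0,
        provenance: str = "",
    ) -> None:
        h = np.asarray(haplotypes, dtype=np.int8)
        if h.ndim != 3 or h.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if h.size and (h.min() < 0 or h.max() > 1):
            raise ValueError("alleles must be coded 0/1")
        n = h.shape[0]
        self.haplotypes = h
        self.ids = (
            np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids, dtype=np.int64)
        )
        if np.unique(self.ids).size != n:
            raise ValueError("ids must be unique within a population")
        if isinstance(origins, str):
            origins = np.full(n, origins, dtype=object)
        self.origins = np.asarray(origins, dtype=object)
        if np.isscalar(birth_cycles):
            birth_cycles = np.full(n, birth_cycles, dtype=np.int64)
        self.birth_cycles = np.asarray(birth_cycles, dtype=np.int64)
        if not (self.ids.size == self.origins.size == self.birth_cycles.size == n):
            raise ValueError("metadata arrays must match population size")
        self.provenance = provenance

    def __len__(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.haplotypes.shape[2])

    def __getitem__(self, i: int) -> Individual:
        return Individual(
            id=int(self.ids[i]),
            haplotypes=self.haplotypes[i],
            origin=str(self.origins[i]),
            birth_cycle=int(self.birth_cycles[i]),
        )

    def genotypes(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Genotype matrix coded -1/0/1 (allele-1 dosage minus one)."""
        g = self.haplotypes.sum(axis=1, dtype=np.int8) - 1
        return g if loci is None else g[:, loci]

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Frequency of the '1' allele per locus."""
        f = self.haplotypes.mean(axis=(0, 1))
        return f if loci is None else f[loci]

    def subset(self, index: np.ndarray, provenance: str | None = None) -> "Population":
        return Population(
            self.haplotypes[index],
            self.ids[index],
            self.origins[index],
            self.birth_cycles[index],
            self.provenance if provenance is None else provenance,
        )

    @classmethod
    def concat(cls, pops: list["Population"], provenance: str = "") -> "Population":
        return cls(
            np.concatenate([p.haplotypes for p in pops]),
            np.concatenate([p.ids for p in pops]),
            np.concatenate([p.origins for p in pops]),
            np.concatenate([p.birth_cycles for p in pops]),
            provenance,
        )


class GeneBank(Population):
    """Static external collection of accessions; fixed size after construction."""

    def __init__(self, *args, **kwargs) -> None:
        super().__init__(*args, **kwargs)
        self._size = len(self)

    @property
    def size(self) -> int:
        return self._size


def generate_founders(
    layout: GenomeLayout,
    n_per_pool: int | tuple[int, int] = (384, 380),
    differentiation: float = 0.1,
    fixed_locus_fraction: float = 0.075,
    freq_bounds: tuple[float, float] = (0.05, 0.95),
    rng: np.random.Generator | None = None,
    id_start: int = 0,
) -> tuple[Population, Population]:
    """Generate two differentiated pools of fully homozygous inbred lines.

    Per locus an ancestral '1'-allele frequency is drawn uniformly on
    ``freq_bounds``; with probability ``fixed_locus_fraction`` (default calibrated so the combined
    polymorphic fraction lands near 0.92) the locus is
    instead ancestrally fixed (monomorphic everywhere), which places the
    default combined polymorphic fraction near the 92% observed in the real
    panels.  Pool-specific frequencies are perturbed around the ancestral one
    with a Balding-Nichols beta kernel whose spread is set by
    ``differentiation`` (an F_ST-like parameter in [0, 1]); at 0 both pools
    share the ancestral spectrum exactly.  Every line is fully inbred: one
    allele draw per locus, copied to both haplotypes.
    """
    if isinstance(n_per_pool, (int, np.integer)):
        n_per_pool = (int(n_per_pool), int(n_per_pool))
    if min(n_per_pool) < 2:
        raise ValueError("each pool needs at least two lines")
    if not 0 <= differentiation <= 1:
        raise ValueError("differentiation must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    k = layout.n_loci

    anc = rng.uniform(freq_bounds[0], freq_bounds[1], size=k)
    fixed = rng.random(k) < fixed_locus_fraction
    anc[fixed] = rng.integers(0, 2, size=int(fixed.sum())).astype(float)

    pools = []
    for which, (n, tag) in enumerate(zip(n_per_pool, ("poolA", "poolB"))):
        if differentiation > 0:
            f = (1 - differentiation) / differentiation
            freq = np.where(
                (anc == 0) | (anc == 1),
                anc,
                rng.beta(np.clip(anc * f, 1e-12, None), np.clip((1 - anc) * f, 1e-12, None)),
            )
        else:
            freq = anc
        alleles = (rng.random((n, k)) < freq[None, :]).astype(np.int8)
        hap = np.repeat(alleles[:, None, :], 2, axis=1)
        ids = id_start + np.arange(n) if which == 0 else id_start + n_per_pool[0] + np.arange(n)
        pools.append(Population(hap, ids=ids, origins=tag, birth_cycles=0, provenance=tag))
    return pools[0], pools[1]


def build_gene_bank(
    poolA: Population,
    poolB: Population,
    layout: GenomeLayout,
    size: int = 500,
    rng: np.random.Generator | None = None,
    id_start: int = 1_000_000,
) -> GeneBank:
    """Cross pool-A members with S-score-maximizing pool-B partners.

    Repeats ``size`` times: draw a random pool-A parent, pick the pool-B
    partner maximizing the S-score over the marker loci (mask vector all
    ones — no parental set exists at this point), and keep one F1 of the
    cross.  For inbred x inbred the F1 is deterministic: haplotype 1 from A,
    haplotype 2 from B, heterozygous wherever the parents differ.  Ties in
    the S-score break by ascending pool-B position.
    """
    if len(poolA) == 0 or len(poolB) == 0:
        raise ValueError("founder pools must be nonempty")
    rng = np.random.default_rng(rng)
    m = layout.marker_indices
    za = poolA.genotypes(m).astype(np.int32)
    zb = poolB.genotypes(m).astype(np.int32)
    # S(i,j) with p=1 everywhere: sum_m (z_i - z_j)^2 / 2.  For fully inbred
    # parents this is twice the Hamming distance; a single matmul gives all
    # pairs at once: (z_i - z_j)^2 = z_i^2 + z_j^2 - 2 z_i z_j.
    sq_a = (za**2).sum(axis=1)
    sq_b = (zb**2).sum(axis=1)
    s = (sq_a[:, None] + sq_b[None, :] - 2 * (za @ zb.T)) / 2.0
    best_partner = np.argmax(s, axis=1)  # argmax takes the lowest index on ties

    picks = rng.integers(0, len(poolA), size=size)
    partners = best_partner[picks]
    hap = np.stack(
        [poolA.haplotypes[picks, 0, :], poolB.haplotypes[partners, 0, :]], axis=1
    )
    return GeneBank(
        hap,
        ids=id_start + np.arange(size),
        origins="genebank",
        birth_cycles=0,
        provenance="genebank",
    )


# ---------------------------------------------------------------------------
# Delimited haplotype-matrix I/O
#
# Format: tab-delimited; header "id origin birth_cycle" followed by 1-based
# locus ids; two rows per individual (haplotype 1 then haplotype 2), each
# starting with the id/origin/birth_cycle columns followed by 0/1 alleles.


def write_population(pop: Population, path) -> None:
    with open(path, "w") as fh:
        loci = "\t".join(f"L{i}" for i in range(1, pop.n_loci + 1))
        fh.write(f"id\torigin\tbirth_cycle\t{loci}\n")
        for i in range(len(pop)):
            meta = f"{pop.ids[i]}\t{pop.origins[i]}\t{pop.birth_cycles[i]}"
            for h in range(2):
                alleles = "\t".join(str(int(a)) for a in pop.haplotypes[i, h])
                fh.write(f"{meta}\t{alleles}\n")


def read_population(path) -> Population:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_loci = len(header) - 3
        if n_loci < 1:
            raise ValueError("haplotype matrix has no locus columns")
        rows, meta = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_loci + 3:
                raise ValueError(
                    f"line {ln}: expected {n_loci} alleles, found {len(parts) - 3}"
                )
            try:
                alleles = np.array(parts[3:], dtype=np.int8)
            except ValueError as err:
                raise ValueError(f"line {ln}: non-integer allele code") from err
            if alleles.size and (alleles.min() < 0 or alleles.max() > 1):
                raise ValueError(f"line {ln}: alleles must be coded 0/1")
            rows.append(alleles)
            meta.append((int(parts[0]), parts[1], int(parts[2])))
    if len(rows) % 2:
        raise ValueError("haplotype matrix must contain two rows per individual")
    n = len(rows) // 2
    for i in range(n):
        if meta[2 * i] != meta[2 * i + 1]:
            raise ValueError(f"individual {i}: metadata differs between haplotype rows")
    hap = np.stack(rows).reshape(n, 2, n_loci)
    ids = np.array([meta[2 * i][0] for i in range(n)])
    origins = np.array([meta[2 * i][1] for i in range(n)], dtype=object)
    cycles = np.array([meta[2 * i][2] for i in range(n)])
    return Population(hap, ids=ids, origins=origins, birth_cycles=cycles)


def read_genotype_matrix(path) -> Population:
    """Load a one-row-per-individual 0/1/2 genotype table (homozygotes only).

    Heterozygote code 1 is rejected with an explanatory error: haplotype
    phase is required downstream and cannot be reconstructed from dosages.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_loci = len(header) - 3
        haps, ids, origins, cycles = [], [], [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_loci + 3:
                raise ValueError(f"line {ln}: expected {n_loci} genotype columns")
            dose = np.array(parts[3:], dtype=np.int8)
            if np.any(dose == 1):
                raise ValueError(
                    f"line {ln}: heterozygote dosage code 1 cannot be phased; "
                    "provide the two-row haplotype format instead"
                )
            if dose.size and (dose.min() < 0 or dose.max() > 2):
                raise ValueError(f"line {ln}: genotype codes must be 0/1/2")
            hap1 = (dose == 2).astype(np.int8)
            haps.append(np.stack([hap1, hap1]))
            ids.append(int(parts[0]))
            origins.append(parts[1])
            cycles.append(int(parts[2]))
    return Population(
        np.stack(haps), ids=np.array(ids), origins=np.array(origins, dtype=object),
        birth_cycles=np.array(cycles),
    )
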