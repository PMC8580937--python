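"""Crossing-block construction for the three parental-selection strategies.

Every strategy turns the current breeding state into a 50-couple crossing
block (1000 planned offspring):

* truncation — top-100 GEBV parents, paired at random;
* deep scoping — a 500-member elite stream (25 couples) plus a layered
  pre-breeding stream: gene-bank donors enter through layer 0 and mature
  through layers 1-4, each layer pairing its 5 highest-H-score members with
  S-score-maximizing partners from a shrinking GEBV pre-selection;
* HUC with bridging — an 80-parent elite stream (40 couples) plus a
  10-couple bridging block pairing gene-bank donors with top-GEBV elites by
  maximizing the summed usefulness criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout, TraitArchitecture, EnvironmentModel
from .meiosis import Couple, CrossPlan, cross_batch, single_seed_descent
from .population import GeneBank, Population
from .prediction import RidgeBLUPResults, TrainingPanel
from .selection import (
    PVector,
    SegmentMap,
    hebv_matrix,
    h_scores,
    s_scores,
    usefulness,
)

__all__ = [
    "BreedingState",
    "truncation_block",
    "elite_pair_min_relationship",
    "deep_scoping_block",
    "huc_bridging_block",
    "elite_flow_counts",
]

LAYER_LABELS = ["layer0", "layer1", "layer2", "layer3", "layer4"]


@dataclass
class BreedingState:
    """Everything a strategy needs to build a crossing block."""

    layout: GenomeLayout
    trait: TraitArchitecture
    env: EnvironmentModel
    segmap: SegmentMap
    population: Population
    gene_bank: GeneBank
    panel: TrainingPanel
    results: RidgeBLUPResults
    cycle: int = 0
    strategy: str = "truncation"
    next_id: int = 2_000_000

    def layer_members(self, layer: int) -> np.ndarray:
        """Population indices whose origin tag is the given layer."""
        return np.flatnonzero(self.population.origins == f"layer{layer}")


def _rank_desc(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Indices sorted by descending value, ties broken by ascending id."""
    return np.lexsort((ids, -np.asarray(values, dtype=float)))


def truncation_block(
    gebvs: np.ndarray,
    ids: np.ndarray,
    rng: np.random.Generator,
    n_parents: int = 100,
    n_offspring: int = 20,
) -> CrossPlan:
    """Select the top ``n_parents`` GEBV individuals and pair them randomly
    into disjoint couples."""
    gebvs = np.asarray(gebvs, dtype=float)
    ids = np.asarray(ids)
    if gebvs.size < n_parents:
        raise ValueError(f"population of {gebvs.size} cannot supply {n_parents} parents")
    chosen = ids[_rank_desc(gebvs, ids)[:n_parents]]
    perm = rng.permutation(n_parents)
    couples = [
        Couple(int(chosen[perm[2 * i]]), int(chosen[perm[2 * i + 1]]), n_offspring, "elite")
        for i in range(n_parents // 2)
    ]
    return CrossPlan(couples, metadata={"elite_parent_ids": chosen.tolist()})


def _relationship_matrix(
    Z: np.ndarray, allele_freq: np.ndarray | None = None, method: str = "vanraden"
) -> np.ndarray:
    """Pairwise genomic relationship of the rows of Z (coded -1/0/1).

    ``vanraden`` centers by twice the reference allele frequency (taken from
    the current breeding population when supplied) and normalizes by
    2 * sum p(1-p); ``allele_share`` is the plain fraction of shared alleles.
    Only the ordering of values matters for pairing.
    """
    Z = np.asarray(Z, dtype=float)
    if method == "allele_share":
        k = Z.shape[1]
        # identical genotypes share both alleles; opposite homozygotes none
        d = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
        return 1.0 - d / (2.0 * k)
    if method != "vanraden":
        raise ValueError(f"unknown relationship method: {method}")
    if allele_freq is None:
        p = (Z.mean(axis=0) + 1.0) / 2.0
    else:
        p = np.asarray(allele_freq, dtype=float)
    W = Z - (2.0 * p - 1.0)[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        denom = 1.0
    return (W @ W.T) / denom


def elite_pair_min_relationship(
    elite_ids: np.ndarray,
    Z_elite: np.ndarray,
    gebvs: np.ndarray,
    allele_freq: np.ndarray | None = None,
    method: str = "vanraden",
) -> list[tuple[int, int]]:
    """Greedy minimum-relationship pairing of an even elite parent set.

    Repeatedly takes the highest-GEBV unpaired individual as P1 and pairs it
    with the unpaired individual minimizing their genomic relationship; all
    ties break by ascending id.
    """
    elite_ids = np.asarray(elite_ids)
    if elite_ids.size % 2:
        raise ValueError("elite parent count must be even")
    G = _relationship_matrix(Z_elite, allele_freq, method)
    order = _rank_desc(np.asarray(gebvs, dtype=float), elite_ids)
    unpaired = list(order)
    pairs: list[tuple[int, int]] = []
    while unpaired:
        p1 = unpaired.pop(0)
        rel = [(G[p1, q], elite_ids[q], q) for q in unpaired]
        rel.sort(key=lambda t: (t[0], t[1]))
        q = rel[0][2]
        unpaired.remove(q)
        pairs.append((int(elite_ids[p1]), int(elite_ids[q])))
    return pairs


def _population_hebv(state: BreedingState, haplotypes: np.ndarray) -> np.ndarray:
    """Per-individual segment maxima of a haplotype batch (n, 2, n_loci)."""
    X = haplotypes[:, :, state.layout.marker_indices].reshape(
        haplotypes.shape[0] * 2, -1
    )
    return hebv_matrix(X, state.results.u, state.segmap).segment_max()


def _scoping_pick(
    z_p1: np.ndarray,
    pool_idx: np.ndarray,
    Z: np.ndarray,
    ids: np.ndarray,
    pvec: PVector,
    divisor: float,
) -> int:
    """S-score-maximizing partner within the pre-selected pool (ties by id)."""
    s = s_scores(z_p1, Z[pool_idx], pvec.values, divisor)
    return int(pool_idx[_rank_desc(s, ids[pool_idx])[0]])


def deep_scoping_block(
    state: BreedingState,
    rng: np.random.Generator,
    n_elite_parents: int = 50,
    n_offspring: int = 20,
    donors_per_cycle: int = 5,
    n_layers: int = 5,
    layer_preselection: tuple[int, ...] = (400, 300, 200, 100),
    layer0_pool: int = 500,
    elite_set: str = "parents",
    relationship: str = "vanraden",
    s_divisor: float = 2.0,
) -> CrossPlan:
    """Build the deep-scoping crossing block.

    Elite stream: the top ``n_elite_parents`` GEBV individuals over the whole
    breeding population, paired by minimum genomic relationship.  Layer 0:
    the ``donors_per_cycle`` gene-bank members with the highest H-score
    versus the elite parental set, each paired with the S-score maximizer in
    the top-``layer0_pool`` GEBV subpopulation.  Layers 1..n_layers-1: the 5
    highest-H-score members of the previous layer, paired with the S-score
    maximizer within a shrinking GEBV pre-selection (400/300/200/100 at
    defaults) that excludes members of layers earlier than the P1 source
    layer.  The marker mask vector is reset at the start of the cycle and
    updated after every committed parent, elite couples first.

    Bootstrap: while a source layer is still empty (the first cycles after
    switching strategy) that layer's P1 parents are taken from the top of
    the GEBV ranking of the general breeding population.
    """
    pop = state.population
    ids = pop.ids
    Z = pop.genotypes(state.layout.marker_indices)
    gebv = state.results.gebv(Z)
    freqs = (Z.mean(axis=0) + 1.0) / 2.0

    rank = _rank_desc(gebv, ids)
    elite_pos = rank[:n_elite_parents]
    id_to_pos = {int(i): int(p) for p, i in zip(rank, ids[rank])}

    pairs = elite_pair_min_relationship(
        ids[elite_pos], Z[elite_pos], gebv[elite_pos], allele_freq=freqs, method=relationship
    )
    pvec = PVector(Z.shape[1])
    couples: list[Couple] = []
    for p1_id, p2_id in pairs:
        pvec.update(Z[id_to_pos[p1_id]])
        pvec.update(Z[id_to_pos[p2_id]])
        couples.append(Couple(p1_id, p2_id, n_offspring, "elite"))

    # per-individual segment maxima for H-scores
    B_pop = _population_hebv(state, pop.haplotypes)
    B_gb = _population_hebv(state, state.gene_bank.haplotypes)
    if elite_set == "parents":
        elite_ids_for_h = np.array([i for pair in pairs for i in pair])
        B_elite = B_pop[[id_to_pos[int(i)] for i in elite_ids_for_h]]
    elif elite_set == "subpopulation":
        B_elite = B_pop[rank[: min(layer0_pool, len(pop))]]
    else:
        raise ValueError(f"unknown elite_set: {elite_set}")
    lam = state.segmap.lam

    Z_gb = state.gene_bank.genotypes(state.layout.marker_indices)
    gb_ids = state.gene_bank.ids
    preselect_used: dict[str, int] = {}

    for layer in range(n_layers):
        label = f"layer{layer}"
        if layer == 0:
            h = h_scores(B_gb, B_elite, lam)
            n_p1 = min(donors_per_cycle, len(gb_ids))
            p1_rows = _rank_desc(h, gb_ids)[:n_p1]
            p1_ids = gb_ids[p1_rows]
            p1_Z = Z_gb[p1_rows]
            pool_n = min(layer0_pool, len(pop))
            pool_idx = rank[:pool_n]
        else:
            members = state.layer_members(layer - 1)
            if members.size == 0:
                # bootstrap: source the layer from truncation-selected offspring
                p1_pos = rank[:donors_per_cycle]
            else:
                h = h_scores(B_pop[members], B_elite, lam)
                p1_pos = members[_rank_desc(h, ids[members])[: donors_per_cycle]]
            p1_ids = ids[p1_pos]
            p1_Z = Z[p1_pos]
            n_pre = layer_preselection[layer - 1]
            excluded = {f"layer{m}" for m in range(layer - 1)}
            eligible = ~np.isin(pop.origins.astype(str), list(excluded))
            pool_idx = rank[eligible[rank]][: min(n_pre, int(eligible.sum()))]
            preselect_used[label] = int(min(n_pre, eligible.sum()))
        for j in range(len(p1_ids)):
            pool = pool_idx[ids[pool_idx] != p1_ids[j]]
            p2 = _scoping_pick(p1_Z[j], pool, Z, ids, pvec, s_divisor)
            pvec.update(p1_Z[j])
            pvec.update(Z[p2])
            couples.append(Couple(int(p1_ids[j]), int(ids[p2]), n_offspring, label))

    return CrossPlan(
        couples,
        metadata={
            "elite_parent_ids": [int(i) for pair in pairs for i in pair],
            "layer_preselection": preselect_used,
            "layer0_pool": int(min(layer0_pool, len(pop))),
        },
    )


def _uc_matrix(
    donor_haps: np.ndarray,
    elite_haps: np.ndarray,
    u: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
    n_virtual_progeny: int,
    intensity: float,
    rho: float,
) -> np.ndarray:
    """Usefulness of every donor x elite cross via batched virtual progeny."""
    nd, ne = donor_haps.shape[0], elite_haps.shape[0]
    p1 = np.repeat(donor_haps, ne * n_virtual_progeny, axis=0)
    p2 = np.tile(np.repeat(elite_haps, n_virtual_progeny, axis=0), (nd, 1, 1))
    f1 = cross_batch(p1, p2, layout, rng)
    f3 = single_seed_descent(f1, 2, layout, rng)
    g = (f3[:, :, layout.marker_indices].sum(axis=1) - 1.0) @ u
    g = g.reshape(nd, ne, n_virtual_progeny)
    mu = g.mean(axis=2)
    sd = g.std(axis=2, ddof=1)
    return mu + intensity * rho * sd


def _greedy_assignment(U: np.ndarray) -> list[tuple[int, int]]:
    """Best-remaining-pair-first one-to-one matching (ties by row then col)."""
    U = U.copy()
    nd, ne = U.shape
    pairs = []
    used_r, used_c = set(), set()
    for _ in range(min(nd, ne)):
        best = None
        for r in range(nd):
            if r in used_r:
                continue
            for c in range(ne):
                if c in used_c:
                    continue
                if best is None or U[r, c] > best[0]:
                    best = (U[r, c], r, c)
        _, r, c = best
        used_r.add(r)
        used_c.add(c)
        pairs.append((r, c))
    return pairs


def huc_bridging_block(
    state: BreedingState,
    rng: np.random.Generator,
    n_elite_parents: int = 80,
    n_donors: int = 10,
    n_offspring: int = 20,
    intensity: float = 2.06,
    rho: float = 1.0,
    n_virtual_progeny: int = 200,
    exact_assignment: bool = False,
    relationship: str = "vanraden",
) -> CrossPlan:
    """Build the HUC-with-bridging crossing block.

    80% of the parental population forms the elite stream: the top
    ``n_elite_parents`` GEBV individuals paired by minimum relationship (40
    couples).  The bridging stream crosses the ``n_donors`` gene-bank members
    with the highest H-score one-to-one with the ``n_donors`` highest-GEBV
    elite individuals, assigning partners to maximize the summed usefulness
    criterion (greedy by default; exact rectangular assignment when
    ``exact_assignment``).
    """
    pop = state.population
    ids = pop.ids
    Z = pop.genotypes(state.layout.marker_indices)
    gebv = state.results.gebv(Z)
    freqs = (Z.mean(axis=0) + 1.0) / 2.0

    rank = _rank_desc(gebv, ids)
    elite_pos = rank[:n_elite_parents]
    pairs = elite_pair_min_relationship(
        ids[elite_pos], Z[elite_pos], gebv[elite_pos], allele_freq=freqs, method=relationship
    )
    couples = [Couple(a, b, n_offspring, "elite") for a, b in pairs]

    B_pop = _population_hebv(state, pop.haplotypes)
    B_gb = _population_hebv(state, state.gene_bank.haplotypes)
    pos_of = {int(i): int(p) for p, i in zip(elite_pos, ids[elite_pos])}
    B_elite = B_pop[elite_pos]
    h = h_scores(B_gb, B_elite, state.segmap.lam)
    donor_rows = _rank_desc(h, state.gene_bank.ids)[:n_donors]
    partner_pos = rank[:n_donors]

    U = _uc_matrix(
        state.gene_bank.haplotypes[donor_rows],
        pop.haplotypes[partner_pos],
        state.results.u,
        state.layout,
        rng,
        n_virtual_progeny,
        intensity,
        rho,
    )
    if exact_assignment:
        from scipy.optimize import linear_sum_assignment

        rr, cc = linear_sum_assignment(U, maximize=True)
        assignment = list(zip(rr.tolist(), cc.tolist()))
    else:
        assignment = _greedy_assignment(U)
    for r, c in assignment:
        couples.append(
            Couple(
                int(state.gene_bank.ids[donor_rows[r]]),
                int(ids[partner_pos[c]]),
                n_offspring,
                "bridging",
            )
        )
    return CrossPlan(
        couples,
        metadata={
            "elite_parent_ids": [int(i) for pair in pairs for i in pair],
            "uc_matrix": U.tolist(),
        },
    )


def elite_flow_counts(origins: np.ndarray) -> dict[str, int]:
    """Tally the origin tags of a newly selected elite parental set.

    Counts sum to the size of the parental set; layers absent from the input
    report zero.
    """
    origins = np.asarray(origins).astype(str)
    counts = {"elite": int(np.sum(origins == "elite"))}
    for label in LAYER_LABELS:
        counts[label] = int(np.sum(origins == label))
    other = len(origins) - sum(counts.values())
    if other:
        counts["other"] = other
    return counts
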