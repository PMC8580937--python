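"""Replicated multi-cycle simulation engine.

Orchestrates the recurrent breeding scheme: synthetic founder construction,
cycle-0 top-50 x top-50 phenotypic crossing, burn-in truncation cycles, the
strategy switch, per-cycle training-panel updates and model refits, crossing
and single-seed descent to the next 1000 F3s, and tidy per-cycle metric
capture across seeded replicates.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .genome import (
    EnvironmentModel,
    GenomeLayout,
    build_trait,
    genetic_values,
    population_metrics,
    simulate_phenotypes,
)
from .meiosis import CrossPlan, cross_batch, single_seed_descent
from .population import GeneBank, Population, build_gene_bank, generate_founders
from .prediction import RidgeBLUP, TrainingPanel, tails_update
from .selection import build_segments
from .strategies import (
    BreedingState,
    deep_scoping_block,
    elite_flow_counts,
    huc_bridging_block,
    truncation_block,
)

__all__ = [
    "SimulationConfig",
    "initialize",
    "run_cycle",
    "run_experiment",
    "run_paired_comparison",
    "summarize",
]

STRATEGIES = ("truncation", "deep_scoping", "huc_bridging")

_GENE_BANK_ID_START = 1_000_000
_OFFSPRING_ID_START = 2_000_000


@dataclass
class SimulationConfig:
    """All knobs of the simulated breeding program, with standard defaults.

    Defaults reproduce the reference study conditions: 1590 loci on 7
    chromosomes with 100 geometric-effect QTLs, founder pools of 384 and 380
    inbred lines, a 500-member gene bank, 50 couples x 20 offspring per
    cycle, plot-level heritability 0.5 with environment variance eight times
    the founder genetic variance, and 50 cycles per replicate.
    """

    # genome / trait
    n_loci: int = 1590
    n_chromosomes: int = 7
    n_qtl: int = 100
    chrom_length_cm: float = 150.0
    # founders / gene bank
    pool_sizes: tuple[int, int] = (384, 380)
    differentiation: float = 0.1
    fixed_locus_fraction: float = 0.075
    gene_bank_size: int = 500
    # phenotyping
    h2: float = 0.5
    env_scale: float = 8.0
    n_env: int = 3
    # breeding scheme
    n_founder_parents: int = 50
    n_offspring: int = 20
    ssd_generations: int = 2
    n_truncation_parents: int = 100
    # training panel
    panel_add: int = 150
    # segments / scores
    window: int = 20
    step: int = 5
    s_divisor: float = 2.0
    relationship: str = "vanraden"
    # deep scoping
    ds_elite_parents: int = 50
    ds_donors: int = 5
    ds_layers: int = 5
    ds_layer_preselection: tuple[int, ...] = (400, 300, 200, 100)
    ds_layer0_pool: int = 500
    ds_elite_set: str = "parents"
    # HUC with bridging
    huc_elite_parents: int = 80
    huc_donors: int = 10
    huc_intensity: float = 2.06
    huc_rho: float = 1.0
    n_virtual_progeny: int = 200
    huc_exact_assignment: bool = False
    # experiment
    strategy: str = "deep_scoping"
    burn_in_cycles: int = 5
    total_cycles: int = 50
    replicates: int = 100
    base_seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.total_cycles < self.burn_in_cycles:
            raise ValueError("total_cycles must be >= burn_in_cycles")
        if self.n_qtl < 1 or self.n_qtl >= self.n_loci:
            raise ValueError("need 1 <= n_qtl < n_loci")
        if len(self.ds_layer_preselection) != self.ds_layers - 1:
            raise ValueError("one pre-selection size is needed per layer after layer 0")
        if self.n_founder_parents > min(self.pool_sizes):
            raise ValueError("founder pools too small for the cycle-0 cross")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pool_sizes", "ds_layer_preselection"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["pool_sizes"] = list(d["pool_sizes"])
        d["ds_layer_preselection"] = list(d["ds_layer_preselection"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _phenotyper(state: BreedingState, rng: np.random.Generator):
    """Phenotype population members by index with the calibrated noise model."""

    def phenotype(index: np.ndarray) -> np.ndarray:
        gv = genetic_values(state.population.haplotypes[index], state.trait, state.layout)
        return simulate_phenotypes(gv, state.env, rng)

    return phenotype


def initialize(config: SimulationConfig, rng: np.random.Generator | None = None) -> BreedingState:
    """Build the cycle-0 breeding state.

    Generates founder pools, calibrates the phenotyping model on the founder
    genetic variance, phenotypes all founders, rank-pairs the top-50 of pool
    B with the top-50 of pool A by phenotype into the first 50 couples,
    advances 1000 F1s by two single-seed-descent generations to 1000 F3s,
    builds the gene bank, seeds the training panel with all founders and
    fits the prediction model.
    """
    config.validate()
    rng = np.random.default_rng(config.base_seed if rng is None else rng)
    layout = GenomeLayout.default(
        config.n_loci, config.n_chromosomes, config.n_qtl, config.chrom_length_cm, rng
    )
    trait = build_trait(config.n_qtl, rng)
    poolA, poolB = generate_founders(
        layout,
        n_per_pool=config.pool_sizes,
        differentiation=config.differentiation,
        fixed_locus_fraction=config.fixed_locus_fraction,
        rng=rng,
    )
    founders = Population.concat([poolA, poolB], provenance="founders")
    gv = genetic_values(founders.haplotypes, trait, layout)
    env = EnvironmentModel.from_founders(gv, config.h2, config.env_scale, config.n_env)
    y = simulate_phenotypes(gv, env, rng)

    na = len(poolA)
    top_a = np.argsort(-y[:na], kind="stable")[: config.n_founder_parents]
    top_b = na + np.argsort(-y[na:], kind="stable")[: config.n_founder_parents]
    # rank i of pool B crossed with rank i of pool A
    p1 = np.repeat(founders.haplotypes[top_b], config.n_offspring, axis=0)
    p2 = np.repeat(founders.haplotypes[top_a], config.n_offspring, axis=0)
    f1 = cross_batch(p1, p2, layout, rng)
    f3 = single_seed_descent(f1, config.ssd_generations, layout, rng)
    n_off = f3.shape[0]
    population = Population(
        f3,
        ids=_OFFSPRING_ID_START + np.arange(n_off),
        origins="elite",
        birth_cycles=0,
        provenance="breeding",
    )

    gene_bank = build_gene_bank(
        poolA, poolB, layout, size=config.gene_bank_size, rng=rng,
        id_start=_GENE_BANK_ID_START,
    )
    panel = TrainingPanel(
        founders.genotypes(layout.marker_indices), y, founders.ids, cycle_added=0
    )
    results = RidgeBLUP.from_panel(panel).fit()
    return BreedingState(
        layout=layout,
        trait=trait,
        env=env,
        segmap=build_segments(layout, config.window, config.step),
        population=population,
        gene_bank=gene_bank,
        panel=panel,
        results=results,
        cycle=0,
        strategy=config.strategy,
        next_id=_OFFSPRING_ID_START + n_off,
    )


def _build_plan(
    state: BreedingState, config: SimulationConfig, strategy: str, rng: np.random.Generator
) -> CrossPlan:
    if strategy == "truncation":
        Z = state.population.genotypes(state.layout.marker_indices)
        return truncation_block(
            state.results.gebv(Z),
            state.population.ids,
            rng,
            n_parents=config.n_truncation_parents,
            n_offspring=config.n_offspring,
        )
    if strategy == "deep_scoping":
        return deep_scoping_block(
            state,
            rng,
            n_elite_parents=config.ds_elite_parents,
            n_offspring=config.n_offspring,
            donors_per_cycle=config.ds_donors,
            n_layers=config.ds_layers,
            layer_preselection=config.ds_layer_preselection,
            layer0_pool=config.ds_layer0_pool,
            elite_set=config.ds_elite_set,
            relationship=config.relationship,
            s_divisor=config.s_divisor,
        )
    if strategy == "huc_bridging":
        return huc_bridging_block(
            state,
            rng,
            n_elite_parents=config.huc_elite_parents,
            n_donors=config.huc_donors,
            n_offspring=config.n_offspring,
            intensity=config.huc_intensity,
            rho=config.huc_rho,
            n_virtual_progeny=config.n_virtual_progeny,
            exact_assignment=config.huc_exact_assignment,
            relationship=config.relationship,
        )
    raise ValueError(f"unknown strategy: {strategy}")


def _materialize(
    state: BreedingState, plan: CrossPlan, config: SimulationConfig, rng: np.random.Generator
) -> Population:
    """Cross every couple and advance the offspring to F3."""
    lookup: dict[int, np.ndarray] = {}
    for pop in (state.population, state.gene_bank):
        for i, pid in enumerate(pop.ids):
            lookup[int(pid)] = pop.haplotypes[i]
    p1 = np.stack(
        [lookup[c.p1] for c in plan.couples for _ in range(c.n_offspring)]
    )
    p2 = np.stack(
        [lookup[c.p2] for c in plan.couples for _ in range(c.n_offspring)]
    )
    labels = np.array(
        [c.label for c in plan.couples for _ in range(c.n_offspring)], dtype=object
    )
    f1 = cross_batch(p1, p2, state.layout, rng)
    f3 = single_seed_descent(f1, config.ssd_generations, state.layout, rng)
    n = f3.shape[0]
    pop = Population(
        f3,
        ids=state.next_id + np.arange(n),
        origins=labels,
        birth_cycles=state.cycle + 1,
        provenance="breeding",
    )
    state.next_id += n
    return pop


def run_cycle(
    state: BreedingState,
    config: SimulationConfig,
    rng: np.random.Generator,
    strategy: str | None = None,
) -> tuple[BreedingState, dict]:
    """Advance the breeding state by one cycle and emit its metric record.

    Order of operations: tails update of the training panel (so parental
    selection uses the refreshed model), model refit, GEBV computation,
    crossing-block construction under the active strategy, elite-flow
    tally, crossing and single-seed descent to the next F3 population.
    """
    strategy = state.strategy if strategy is None else strategy
    Z = state.population.genotypes(state.layout.marker_indices)
    gebv = state.results.gebv(Z)
    tails_update(
        state.panel,
        Z,
        gebv,
        state.population.ids,
        _phenotyper(state, rng),
        cycle=state.cycle + 1,
        n_add=config.panel_add,
    )
    state.results = RidgeBLUP.from_panel(state.panel).fit()

    plan = _build_plan(state, config, strategy, rng)

    elite_ids = plan.metadata.get("elite_parent_ids", [])
    origin_of = {int(i): str(o) for i, o in zip(state.population.ids, state.population.origins)}
    flows = elite_flow_counts(
        np.array([origin_of.get(int(i), "other") for i in elite_ids], dtype=object)
    )

    new_pop = _materialize(state, plan, config, rng)
    state.population = new_pop
    state.cycle += 1
    record = {
        "cycle": state.cycle,
        "strategy": strategy,
        "sigma_u2": state.results.sigma_u2,
        "sigma_e2": state.results.sigma_e2,
        **population_metrics(new_pop.haplotypes, state.trait, state.layout),
        **{f"flow_{k}": v for k, v in flows.items()},
    }
    return state, record


def run_replicate(
    config: SimulationConfig, replicate: int, state: BreedingState | None = None
) -> tuple[BreedingState, list[dict]]:
    """One seeded replicate: burn-in truncation cycles, then the configured
    strategy until ``total_cycles``."""
    rng = np.random.default_rng((config.base_seed + replicate) % 2**31)
    if state is None:
        state = initialize(config, rng)
    records = []
    for cycle in range(config.total_cycles):
        strategy = "truncation" if cycle < config.burn_in_cycles else config.strategy
        state, rec = run_cycle(state, config, rng, strategy)
        rec["replicate"] = replicate
        records.append(rec)
    return state, records


def run_experiment(config: SimulationConfig, out_dir=None) -> pd.DataFrame:
    """Run all replicates and return (and optionally write) the tidy record
    table.  Deterministic given the base seed."""
    config.validate()
    all_records: list[dict] = []
    for r in range(config.replicates):
        _, recs = run_replicate(config, r)
        all_records.extend(recs)
    df = pd.DataFrame(all_records)
    front = ["replicate", "cycle", "strategy"]
    df = df[front + [c for c in df.columns if c not in front]]
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "cycle_records.tsv", sep="\t", index=False)
        config.to_yaml(out / "config.yaml")
    return df


def run_paired_comparison(
    config: SimulationConfig,
    strategies: tuple[str, ...] = ("truncation", "deep_scoping"),
) -> pd.DataFrame:
    """Branch each replicate's burn-in into one continuation per strategy.

    All branches of a replicate share the same founder population and
    burn-in trajectory, so end-of-run contrasts between strategies are
    paired.  Branch seeds are derived deterministically from the base seed.
    """
    config.validate()
    records: list[dict] = []
    for r in range(config.replicates):
        rng = np.random.default_rng((config.base_seed + r) % 2**31)
        state = initialize(config, rng)
        for cycle in range(config.burn_in_cycles):
            state, rec = run_cycle(state, config, rng, "truncation")
            rec.update(replicate=r, branch="burn_in")
            records.append(rec)
        for b, strat in enumerate(strategies):
            branch_state = copy.deepcopy(state)
            branch_rng = np.random.default_rng(
                (config.base_seed + 7919 * r + 104729 * (b + 1)) % 2**31
            )
            for cycle in range(config.burn_in_cycles, config.total_cycles):
                branch_state, rec = run_cycle(branch_state, config, branch_rng, strat)
                rec.update(replicate=r, branch=strat)
                records.append(rec)
    df = pd.DataFrame(records)
    front = ["replicate", "branch", "cycle", "strategy"]
    return df[front + [c for c in df.columns if c not in front]]


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle means and normal-theory 95% CIs across replicates."""
    metrics = [
        c
        for c in records.columns
        if c not in ("replicate", "cycle", "strategy", "branch")
        and pd.api.types.is_numeric_dtype(records[c])
    ]
    keys = [k for k in ("branch", "strategy", "cycle") if k in records.columns]
    g = records.groupby(keys)[metrics]
    mean = g.mean()
    half = 1.96 * g.std(ddof=1) / np.sqrt(g.count())
    out = pd.concat({"mean": mean, "ci95_half": half}, axis=1)
    out.columns = [f"{m}_{stat}" for stat, m in out.columns]
    return out.reset_index()
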