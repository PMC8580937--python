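# deepscope

A stochastic simulator of recurrent genomic-selection breeding programs,
built to study how a breeding program can **reintroduce and exploit genetic
variation** without growing its population or budget. It is aimed at
quantitative geneticists and breeding-program designers who want to compare
parental-selection strategies — plain truncation selection, a layered
pre-breeding scheme ("deep scoping") fed by a gene bank, and HUC with a
bridging population — under identical, fully reproducible conditions.

## The problem

Truncation selection on genomic estimated breeding values (GEBVs) raises the
population mean quickly but fixes QTL alleles, including unfavorable ones.
The *maximum reachable genetic value* — the best genotype still assemblable
from the alleles segregating in the population — declines irreversibly, and
the program converges to a sub-optimal plateau. A gene bank holds the lost
alleles, but its accessions have such low GEBVs that their offspring are
never selected. The simulator implements a layered solution: gene-bank
donors enter a pre-breeding stream (layer 0) and their descendants mature
through layers 1–4, each cycle crossed to progressively stronger partners,
until they compete for elite selection on equal terms.

## The model in brief

* **Trait** — L QTLs with geometric substitution effects a^k,
  a = (L−1)/(L+1); favorable homozygote +a^k, heterozygote 0. Phenotypes
  average g_i + e_j + ε_ij over 3 environments with
  σ_E² = 8 σ_g² and σ_e² scaled for plot-level h² = 0.5.
* **Prediction** — RR-BLUP, y = 1β + Zu + ε, u ~ N(0, σ_u² I); variance
  components by profile REML (spectral), GEBV ĝ = Zû; the training panel is
  refreshed each cycle by the two 75-individual GEBV tails.
* **Selection scores** — haplotype segment values H = (X ∘ 1βᵀ)M over
  20-marker windows stepped by 5; pairwise
  HEBV(i,j) = λ Σ_h max(H_{2i−1,h}, H_{2i,h}, H_{2j−1,h}, H_{2j,h}) with
  λ = step/window; H-score H(i) = max_{j∈E} HEBV(i,j); masked two-genotype
  variance S(i,j) = Σ_m var{Z_im, Z_jm} p_m; usefulness
  U = μ̂_p + i ρ σ̂_p with i = 2.06 (upper-5%-tail intensity).
* **Meiosis** — Haldane model (Poisson crossovers, no interference), two
  single-seed-descent generations from F1 to F3, 50 couples × 20 offspring
  per cycle.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Three replicates of a reduced-scale program (420 loci, 50 QTLs, 100-line
founder pools): 5 burn-in cycles of truncation selection, then the layered
pre-breeding strategy.

```python
import deepscope as ds

cfg = ds.SimulationConfig(
    n_loci=420, n_qtl=50, pool_sizes=(100, 100),
    strategy="deep_scoping", burn_in_cycles=5, total_cycles=15,
    replicates=3, base_seed=7,
)
records = ds.run_experiment(cfg)
summary = ds.summarize(records).sort_values("cycle")
print(summary[["cycle", "strategy", "top10_mean_gv_mean",
               "max_reachable_gv_mean", "polymorphic_fraction_mean"]]
      .round(3).to_string(index=False))
```

```
 cycle     strategy  top10_mean_gv_mean  max_reachable_gv_mean  polymorphic_fraction_mean
     1   truncation              10.780                 19.251                      0.893
     2   truncation              11.378                 18.210                      0.815
     3   truncation              12.257                 18.100                      0.775
     4   truncation              13.051                 17.525                      0.746
     5   truncation              13.958                 17.111                      0.698
     6 deep_scoping              14.643                 17.602                      0.783
     7 deep_scoping              14.901                 17.665                      0.810
     8 deep_scoping              15.028                 18.129                      0.827
     9 deep_scoping              15.578                 17.776                      0.833
    10 deep_scoping              15.892                 17.776                      0.792
    11 deep_scoping              16.072                 17.665                      0.811
    12 deep_scoping              16.029                 18.031                      0.794
    13 deep_scoping              16.079                 18.031                      0.818
    14 deep_scoping              16.155                 18.031                      0.806
    15 deep_scoping              16.131                 17.575                      0.790
```

Reading the numbers: during burn-in the top-10 mean genetic value climbs
while the maximum reachable value *falls* (favorable alleles are being lost)
and polymorphism erodes from 0.89 to 0.70. After the switch at cycle 5, the
gene-bank crosses push the reachable ceiling back up (17.1 → 18.1) and
polymorphism recovers to ~0.8, while the top-10 mean keeps rising — variation
is reintroduced without sacrificing short-term gain.

The same experiment from a shell:

```
deepscope simulate --config cfg.yaml --out runs/demo --replicates 3 --seed 7
deepscope summarize --in runs/demo
```

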