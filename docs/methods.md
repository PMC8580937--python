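# Methods

`deepscope` simulates a recurrent genomic-selection breeding program for an
inbreeding crop and compares parental-selection strategies that differ in how
they manage genetic variation. This note documents the model, its
assumptions, the parameters that matter, and the numerical and design
choices made where the design was genuinely open.

## The breeding scheme

Each cycle crosses 50 parental couples, 20 offspring per couple, giving 1000
F1 hybrids; two generations of single-seed descent (one selfed seed per line
per generation) produce 1000 F3 individuals, from which the next cycle's
parents are drawn. Cycle 0 phenotypes two founder pools of fully homozygous
inbred lines and rank-pairs the top-50 of each pool. All later selections
use genomic estimated breeding values (GEBVs) from an RR-BLUP model; 150
individuals per cycle are phenotyped to refresh the training panel (the
"tails" update: the 75 highest- and 75 lowest-GEBV candidates), and the 150
longest-resident panel entries are dropped so the panel size is constant.

Three strategies build the crossing block:

* **Truncation selection** — top-100 GEBV individuals, paired at random.
* **Deep scoping** — 50 elite parents (top GEBV over the whole population,
  paired by minimum genomic relationship, 25 couples → 500 elite offspring)
  plus a layered pre-breeding stream of 5 couples per layer (5 layers × 100
  offspring). Layer 0 pairs the 5 gene-bank members with the highest H-score
  against the elite parental set with S-score-maximizing partners from the
  top-500 GEBV subpopulation; layers 1–4 take the 5 highest-H-score members
  of the previous layer and pair them with S-score maximizers inside a
  shrinking GEBV pre-selection (400/300/200/100), excluding members of
  layers earlier than the source layer. The marker mask vector **p** resets
  each cycle and is updated after every committed parent, elite couples
  first, then layers 0→4.
* **HUC with bridging** — 80 elite parents (40 couples → 800 offspring) plus
  a bridging block of 10 couples pairing the 10 highest-H-score gene-bank
  donors one-to-one with the 10 highest-GEBV individuals so as to maximize
  the summed usefulness criterion U = μ̂_p + i·ρ·σ̂_p (i = 2.06, the mean of
  the upper 5% tail of a standard normal; ρ = 1).

## Trait, genome and phenotypes

The genome is a set of biallelic loci evenly spaced on 7 chromosomes
(default 1590 loci, 150 cM per chromosome). 100 loci are sampled uniformly
without replacement as QTLs; the remaining 1490 are prediction markers. The
k-th QTL has substitution effect a^k with a = (L−1)/(L+1) (L = QTL count):
favorable homozygote +a^k, unfavorable −a^k, heterozygote 0. The favorable
allele at each QTL is the '1'-coded allele with probability 0.5 (seeded,
recorded). Phenotypes average g_i + e_j + ε_ij over 3 environments, with
environment effects e_j ~ N(0, σ_E²), σ_E² = 8·σ_g²(founders), redrawn at
every phenotyping event, and plot residuals ε_ij ~ N(0, σ_e²) with σ_e²
chosen so plot-level h² = σ_g²/(σ_g²+σ_e²) = 0.5. The heritability is
defined at plot level (the reference value does not state plot vs entry-mean
level; both the level and h² itself are configurable).

Meiosis follows the Haldane model: per chromosome, crossover count ~
Poisson(map length in Morgans), crossover positions uniform, no
interference, no mutation. Map lengths are a configurable default of 150 cM
(barley-scale); they are not dataset-derived.

## Selection scores

Haplotype segments are sliding windows of 20 markers whose starts are 5
markers apart, never spanning chromosomes; a final window is anchored at the
chromosome end so every marker is covered, and chromosomes shorter than the
window form one segment. The per-haplotype segment value matrix is
H = (X ∘ 1βᵀ)M; the pairwise HEBV is λ·Σ_h max of the four haplotype entries
of the two individuals, λ = step/window = 0.25 (kept global even for a
truncated final window). With step = window, HEBV(i,i) is the OHV. The
H-score of a candidate is its maximum HEBV against the elite parental set
(the 50 committed elite parents by default; the top-500 subpopulation via
config). The S-score is Σ_m var{Z_im, Z_jm}·p_m with the two-point variance
(a−b)²/2 (the (a−b)²/4 convention is a config switch; it rescales all scores
by a constant and cannot change an argmax).

Progeny mean and SD for the usefulness criterion are estimated by simulating
200 virtual F3 progeny per candidate cross (meiosis + 2 SSD generations)
scored with the BLUP marker effects, rather than by the analytic
progeny-covariance construction — a simulation of the very process the
analytic form approximates, at far lower code complexity. Donor–elite
assignment is greedy (best remaining pair first); the exact rectangular
assignment is available behind a flag and agrees on dominant-diagonal toys.

## Prediction model

y = 1β + Zu + ε with u ~ N(0, σ_u² I_k). Variance components are estimated
by profile REML over λ = σ_u²/σ_e² using the spectral decomposition of ZZᵀ
(coarse log-grid bracket, then bounded scalar refinement; tolerance 1e-8 on
log₁₀λ), then û = σ_u² Zᵀ V⁻¹(y − 1β̂) with GLS β̂. GEBVs are Zû (fixed
mean excluded; only contrasts matter). A zero marker kernel falls back to
the mean-only model. Marker-effect uncertainty is sampled from the exact
Gaussian conditional u | y ~ N(û, (ZᵀZ/σ_e² + I/σ_u²)⁻¹) — the closed-form
counterpart of Bayesian-ridge MCMC samples, with no chain diagnostics.

All argmax selections (GEBV, H-score, S-score, pairing) break ties by
ascending individual id, making runs bit-reproducible given the base seed;
replicate r uses seed base_seed + r.

## Synthetic founders and gene bank

The founder generator emulates two related breeding panels: per locus an
ancestral '1'-allele frequency is uniform on [0.05, 0.95], except that with
probability 0.075 the locus is ancestrally fixed; pool-specific frequencies
follow a Balding–Nichols beta kernel around the ancestral value with an
F_ST-like differentiation parameter (default 0.1). The fixed-locus default
is calibrated so the combined polymorphic fraction of the default pools
(384 + 380 lines) lands at the observed 92%. Every founder is fully inbred.
The generator reproduces marginal allele-frequency structure only: it has no
linkage disequilibrium at cycle 0 (LD arises from the map and subsequent
breeding) and no pedigree structure within pools, so tests passing on it
speak to the selection machinery, not to LD-dependent prediction accuracy in
real panels.

The gene bank (500 members, static) crosses a random pool-A line with the
pool-B partner maximizing the S-score (mask all ones) and keeps the F1:
members are maximally heterozygous, carry high allelic diversity, and have
low genetic value — deliberately hard material to introduce.

## Problem sizes used in the test suite

Multi-cycle experiments in the tests run at reduced scale, chosen once as
the smallest sizes that preserve the phenomena of interest: (i) the
head-to-head deep-scoping vs truncation comparison uses 100-line founder
pools, 210 loci / 20 QTLs, 5 burn-in + 20 strategy cycles and 20 paired
replicates — a genome small enough that truncation's premature convergence
(the premise of the comparison) occurs by mid-run; (ii) the gene-bank
reintroduction and layer-flow properties use 420 loci / 50 QTLs, where
burn-in reliably fixes several unfavorable QTL alleles for layer-0 crosses
to restore. Full-scale defaults (1590 loci, 100 QTLs, 764 founders, 50
cycles, 100 replicates) are the package defaults and run unchanged, just
longer.

## Known limitations

Single additive trait; no dominance, epistasis, or genotype-by-environment
interaction beyond the additive environment effect. No crossover
interference or mutation. Founders lack realistic LD (above). The greedy
usefulness assignment is not guaranteed optimal (the exact option is).
Replicates run serially; they are embarrassingly parallel if needed.
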