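# Methods

## Model overview

`plastisim` simulates the development and evolution of a small gene
regulatory network in a single-cell organism with one quantitative trait.
Each individual carries a genome of genes of three immutable kinds:

- **regulatory genes** — code for transcription factors that regulate the
  transcription of any gene (including themselves);
- **phenotype genes** — transcription factors that additionally catalyse
  growth of the measured trait;
- **signal-binding genes** — code for a protein that forms a heterodimer
  with an externally supplied signal molecule; only the heterodimer acts as
  a transcription factor.

Each gene has a cis-regulatory region of exactly 20 binding sites and a
coding region.  A binding site carries a motif identity (one of 20), a
signed cis-regulatory weight, and an integer affinity mismatch (an implicit
amino-acid mismatch count between the site and a protein's binding domain).
The coding region carries the protein's signed inherent regulatory effect
and the single motif it recognises, plus a positive catalysis weight
(phenotype genes) or a Hill coefficient (signal-binding genes).

## Development

Development lasts a fixed T_dev = 300 min and is simulated by tau-leaping:
per time step `tau` (default 0.5 min, 600 steps), each reaction channel
fires a Poisson-distributed number of events computed from start-of-step
molecule counts, and counts are clamped at zero.  Channels: basic-TF input,
per-gene transcription, per-mRNA translation, mRNA decay, protein decay,
signal input, and signal decay.  Translation and both decay rates are fixed
for all genes, so mutation acts only through transcription.

Occupancy of a site by a protein species with abundance X is

    theta = X / (X + K0 * lambda^mismatch),

with K0 = 100 molecules and lambda = 2 per mismatch.  Each site contributes
the signed input `cis_effect * inherent_effect * theta` summed over all
matching protein species.  With A the sum of positive inputs and R the
magnitude sum of negative inputs, a gene transcribes at the
Michaelis–Menten-like rate

    r = r_max * A / (1 + A + R),

and not at all when A = 0: genes need a bound activator, so a non-evolving
**basic transcription factor** (fixed motif 0, unit activating effect,
constant input 10 molecules/min) bootstraps expression.  The concrete
A/(1+A+R) and occupancy forms are this package's choices; both are isolated
behind single functions so alternates can be swapped.

The phenotype starts at 0, never decays (irreversible plasticity), and each
step grows deterministically by `tau * k_P * sum(X_i * phenotype_effect_i)`
over phenotype genes (k_P = 0.01).  All developmental noise therefore
propagates from the stochasticity of expression and decay.

### Signals

A signal molecule is input at a rate encoding one of two cues:

- **environmental signal** — rate Pe, the current environment's optimum,
  constant within a development (open loop);
- **performance signal** — rate |Pt − Pe|, the current mismatch, recomputed
  every step (closed loop: a negative feedback during development).

The signal decays at the protein decay rate and is tracked as integer
counts through the same Poisson machinery.  Cooperative binding to a
signal-binding gene's protein follows a Hill law: the effective
availability is Se = S^n / (K^n + S^n), with n ∈ [1, 5] drawn per gene at
founding and K fixed at 2×10⁴ molecules — approximately the stationary
signal level in the low environment (Pe / protein_decay = 1000 / 0.05), so
the heterodimer operates near half-saturation there.  The heterodimer
abundance entering occupancy is Se × (signal-binding protein count), and
its regulatory identity (target motif, inherent effect) is taken from the
signal-binding gene's coding region.  Signal molecules are not consumed by
complex formation.

## Mutation

Six per-replication mutation channels: duplication (Poisson per genome,
10⁻⁸), deletion (Bernoulli per gene, 10⁻⁷), and four regulatory-effect
channels (each Bernoulli per gene, default 10⁻⁵) perturbing respectively
the inherent effect (additive Gaussian, sd 0.1), one site's affinity
mismatch (±1 step reflecting at 0 and the maximum), the coding region's
target motif (resampled uniformly over the other 19 motifs), and one site's
cis weight (additive Gaussian, sd 0.1).  The four effect rates and kernels
are package defaults, configurable.  Kinds never change; a duplicate is an
exact copy appended at the genome end with the same lineage id.  When no
event occurs the (immutable) genotype object is returned unchanged, which
makes clone-sharing in the population loop cheap and safe.

## Evolution

A haploid population of constant size N evolves with nonoverlapping
generations.  Each generation: every individual is assigned an environment
(constant low Pe = 1000; constant high Pe = 3000; or spatial heterogeneity
— an independent fair draw per individual per generation, i.e. migration
0.5), develops once, and receives Gaussian stabilizing fitness
w = exp(−ω (P − Pe)²) with ω = 5×10⁻⁵ on its realized phenotype — one
stochastic development per individual, which is exactly what makes
developmental noise costly.  Parents are drawn by fitness-proportional
multinomial sampling; each offspring genome passes through the mutation
model once.  Reproduction is clonal by default; an optional free-
recombination mode (two parents, each lineage-id group inherited from one
of them by a fair coin flip) is provided but off by default, since results
do not hinge on recombination and gene-number variation leaves crossover
ill-defined.

Founding: random genotypes (cis and inherent effects ~ N(0,1), mismatches ~
U{0..5}, phenotype effects ~ |N(1, 0.3)|, Hill n ~ U[1,5]) are rejection-
sampled until one has mean fitness in (0.15, 0.25), assayed in the low
environment under the treatment's own signal mode as the mean of
per-development fitness over `n_found` developments (default 1,000).  A
cheap 40-development pre-assay with a ±0.09-widened window filters obvious
rejects first; acceptance is decided only by the full assay.  In the
small-noise limit the window corresponds to a mean phenotype offset
|P − 1000| between ≈166.5 and ≈194.8; developmental noise widens the
admissible band slightly (Jensen gap), which is why the assay works on mean
fitness, not mean phenotype.  The accepted founder is cloned into the
population.

## Assays

- **Reaction norm**: mean final phenotype over `n_redevelop` independent
  redevelopments in each environment (full scale: 50,000), under the
  treatment's own signal mode in both environments — the signal is the only
  channel by which the environment can enter development.
- **Plasticity**: a genotype is plastic iff |mean_high − mean_low| strictly
  exceeds ΔP = 400 (20% of the optimum gap); 100/200/800 are exposed as
  alternative thresholds.
- **Developmental noise**: sample SD (n−1 denominator) of the low-
  environment redevelopments; robustness is its inverse.

The low/high batches share one seed stream per replicate (common random
numbers): means are unbiased, the variance of the plasticity contrast
shrinks, and a no-signal genotype's estimated norm is exactly flat.

Experiment summaries report, per treatment × environment cell, the fraction
of replicates plastic at the end both among all replicates and among those
whose founder was not plastic, mean ± SE noise split by plasticity, and
pairwise Welch t-tests (noise) and Fisher exact tests (plasticity counts).
Interaction regressions (OLS/ANCOVA) on the emitted tables are left to the
user.

## Scale presets and what desk-scale runs show

The full-scale configuration (`full` preset: N = 10,000, ≥100,000
generations, 200 replicates per cell, half of the heterogeneous replicates
extended to 200,000 generations, 50,000 redevelopments) is a cluster-month
workload; its per-treatment plasticity fractions are calibration targets at
that scale.  The `desk` preset is a structurally identical reduction
(N = 100, 300 generations, 2 replicates per cell, 500 redevelopments,
founder assay 200 developments) whose six mutation rates are multiplied by
100 — the factor by which N is reduced — keeping the population-wide
mutational input per generation (N·u) at its full-scale value.  At desk
scale, stabilizing selection reliably moves the founder's ≈180-unit offset
to within a few units of the optimum within 300 generations, and the
structural results (e.g. 0% plastic outcomes without a signal) are exact;
quantitative full-scale fractions are not reproduced at this scale.

## Numerical choices and limitations

- tau = 0.5 min balances leap error against cost; the suite checks that
  halving tau does not shift a birth–death stationary mean detectably.
- Poisson decay draws can exceed the current count in one leap; counts are
  clamped at zero (bias negligible at the default rates).
- Se is mathematically in [0, 1) but saturates to 1.0 in floats for
  extreme S/K; computed as 1/(1+(K/S)^n) to avoid overflow.
- Most-common-genotype ties break by first occurrence in population order.
- Canonical genotype identity is the byte-stable JSON serialization with
  sorted keys and 17-significant-digit floats; gene order is part of
  identity, though regulation itself is order-free.
- One master seed per replicate spawns independent child streams for
  founding, environment assignment, development, reproduction, and assays,
  so stages are individually reproducible.
- The model is single-celled and single-trait: no spatial or multicellular
  structure, no diploidy or linkage, no reversible phenotypes, and no
  nucleotide-level representation of binding sites.  Expression noise
  stands in for all sources of developmental instability, so conclusions
  about real multicellular systems are qualitative.
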