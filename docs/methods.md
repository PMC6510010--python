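# Methods

## Models

Three GBLUP-family models predict crossbred performance from combined
purebred (S, LR, LW) and commercial crossbred (CB) data. All share fixed
effects per population (one factor, modelled after a farm-by-sex cross,
plus one covariate), an iid common-litter effect per population, and
independent residuals per population. They differ only in the genetic
components:

* **G model** — one component over all animals with a VanRaden
  first-method relationship matrix (allele frequencies pooled across the
  entire genotyped population, scaling `F = Σ 2p_j(1−p_j)`) and a 4×4
  trait covariance over (PB_S, PB_LR, PB_LW, CB). All pairwise
  covariances are estimated by default; a flag restricts the structure
  to variances plus purebred-crossbred covariances when the cross-line
  terms are not identifiable.
* **BOA model** — three mutually independent breed-of-origin components,
  each with a *partial* relationship matrix over (purebred-b, CB)
  animals and a 2×2 covariance over (PB_b, CB). Purebred rows are
  centered with `2p_b`; a crossbred row carries only its origin-b gamete
  centered with `p_b` (alleles of other or missing origin contribute
  zero); all blocks are scaled by `F_b = Σ 2p_jb(1−p_jb)`, where `p_b`
  counts origin-b allele copies across purebreds-b and crossbreds.
  Diagonals then equal genome share in expectation: 1 for purebreds, 0.5
  for the sire line in crossbreds, 0.25 per maternal line.
* **SEL-BOA model** — breed-specific components restricted to a selected
  SNP subset plus one across-breed component on the complement. An empty
  selection degenerates exactly to the G model, the full panel to the
  BOA model; the implementation constructs literally the same component
  lists in those cases, so the equivalences are structural.

The crossbred's *purebred-performance* effect in each breed-specific
component (and the purebreds' crossbred-performance effect) is an
unobserved trait slot: it has no incidence on any record but completes
the Kronecker covariance `C ⊗ K`; its BLUP for purebred animals *is*
their GEBV for crossbred performance. In the observation-level
formulation used here these slots need no explicit representation — the
phenotypic covariance is `V = Σ_k θ_k B_k`, linear in all variance
parameters with fixed structure matrices `B_k`. The Henderson
mixed-model-equation form (with explicit zero-incidence columns) is also
provided and is verified against the V-form solutions in the tests.

Summaries follow the genome-share weighting: crossbred additive variance
`0.5σ²_S + 0.25σ²_LR + 0.25σ²_LW (+ σ²_across)`;
`h²_CB = σ²_a/(σ²_a + σ²_litter + σ²_e)`; per-component
`r_pc = cov(PB, CB)/√(σ²_PB σ²_CB)`. Estimates of `r_pc` above 1 are
fixed to 0.99 and below 0 to 0 *after* REML and *before* prediction
(the clamped covariance replaces the estimate in the BLUP step); raw
values and a clamp log are always reported.

## REML

Because `V` is linear in the parameters, average-information REML takes
a particularly clean form: score `−½(tr(PB_k) − y'PB_k Py)` and AI
matrix `½ t_k' P t_l` with `t_k = B_k Py`. Iteration starts with three
expectation-maximisation sweeps (monotone by construction; the
trait-covariance update is `C ← C + C F C / n_K` with
`F_st = y'P B_st P y − tr(P B_st)`), then switches to damped AI steps
with step-halving; any step that would lower the restricted
log-likelihood falls back to a (possibly shortened) EM step. Component
covariance matrices are bent to the nearest positive semi-definite
matrix (eigenvalue floor `1e-8` of the largest magnitude) after every
update; residual variances are floored at `1e-6` of the phenotypic
variance. Convergence: relative log-likelihood change below `tol`
(default `1e-8`) together with either a maximum relative parameter
change below `1e-6` or three consecutive sub-`tol` likelihood changes.
Starting values split the per-population phenotypic variance 45%
residual / 15% litter / 40% genetic (divided equally among the
components feeding that population), with covariances started at half
the geometric mean of the variances. The analytic score is verified
against a central-difference gradient in development; a relationship
matrix ridge of `1e-6` on the diagonal keeps `K` invertible.

At the sample sizes this package targets (hundreds of purebreds per
line), the restricted likelihood is nearly flat in the purebred additive
variance of a low-h² line, and `r_pc` — a ratio with that variance in
its denominator, constrained to the positive-definite cone — rails at
±1 in an appreciable fraction of replicates. This is a property of the
estimator, not of the implementation (field estimates on real data show
the same behaviour, e.g. values above 1 or below 0 that are then
clamped). Recovery tests therefore compare the mean estimate over seeds
against the mean realized truth within twice the empirical spread of a
single estimate.

## Breed-of-origin assignment

Phasing is taken as given: the simulator emits truth phase, external
data must arrive pre-phased. Windows tile each chromosome at nine core
lengths (25–250 SNP), each with and without a half-core offset (18
views). Every distinct purebred haplotype per window is tallied per
breed; a haplotype is assigned to a breed when ≥80% of its copies occur
in that breed. Each crossbred allele then receives one vote per
assigned window covering it; votes incompatible with the three-way
cross (non-S paternal, S maternal) are discarded; plurality decides,
ties and empty votes give missing. Quality filters — SNP with a
per-gamete assignment rate <90%, animals with <90% of the genome
assigned, SNP with an origin-specific allele seen <5 times in the
purebreds of that origin plus matching crossbred gametes — are applied
in that order, recomputing rates after each pass and repeating to a
fixpoint, which makes the whole filter idempotent.

Assignment quality depends on shared haplotype segments among purebreds,
hence on marker density per Morgan and purebred census: at the default
density (200 SNP per 1-Morgan chromosome, 300 animals per line) >95% of
alleles are assigned correctly, while halving the density collapses the
window-match rate and the 90% filters then discard most of the panel.
This mirrors the real procedure's dependence on panel density.

## SNP targeting

Purebred GEBV for crossbred performance from the BOA model are
back-solved per breed: `α̂ = F_b⁻¹ V_b' G_bb⁻¹ â` with
`V_b = M_b − 2·1p_b'`, so `V_b α̂` reconstructs `â` whenever `â` lies in
the genotype column space (more SNP than animals, or any GEBV produced
by a genomic model on that panel). LD blocks are built per breed of
origin on crossbred origin-gametes (haploid dosage, pairwise-complete
over non-missing origins): consecutive SNP join a block when r² with any
block member within a 50-SNP span exceeds 0.3 (all three knobs exposed).
Percent crossbred genetic variance per block is
`100·Var(Σ z_j α̂_j)/σ²_a · (x̄_n/n_i)` with the variance taken across
purebred-b individuals and `x̄_n` the mean block size. The denominator
`σ²_a` defaults to the REML crossbred genetic variance of breed b
(variance-table semantics); `Var(V α̂)` is available as an option and is
the appropriate choice when GEBV shrinkage at small n makes the REML
denominator so large that every block falls under the selection cap.
Selection takes blocks in descending percent (ties: larger block, then
lower coordinate) while the running per-breed total stays ≤ the 5% or
10% cap — strictly, so the cap is never exceeded; the per-breed picks
are merged and deduplicated.

## Cross-validation

Each population is split into k=4 clusters by K-means (20 seeded
restarts) on rows of the dissimilarity `d_ij = max(G) − G_ij` of its
G-matrix block (the alternative `1 − G_ij/√(G_ii G_jj)` is exposed).
Crossbred clusters are rebalanced to ≈n/4 by moving the animal with the
highest mean relationship to the smallest cluster; each crossbred
cluster is paired to one purebred cluster per breed by maximising mean
between-cluster relationship as an assignment problem, so the pairing is
a bijection. Per fold, pedigree BLUP (A-matrix by the tabular method,
pruned to ancestors of the fold) on the fold's crossbred phenotypes
yields EBV and reliabilities for the fold's purebreds; deregression
removes within-fold parent-average information on the information scale
`r²/(1−r²)` and scales the remainder by its own reliability
(`DRP = PA + (EBV − PA)/r²_own`), with weights
`w = (1−h²)/((c + (1−r²_own)/r²_own)h²)`, `c = 0.1` — a standard
deregression weighting used as a concrete stand-in for the effective
record contributions of the source procedure, and flagged as such in
outputs. Model accuracy is the w-weighted Pearson correlation between
DRP and GEBV, `SE = (1−r²)/√N`. Training fits never see validation-fold
phenotypes (crossbred or purebred).

## Simulator

The generator emulates the statistical structure the models assume:

* **Divergence.** Balding–Nichols founder frequencies: one ancestral
  frequency per locus (uniform 0.1–0.9), per-breed beta draws with drift
  `c_b` solved in closed form from the pairwise F_ST targets
  (`c_A = f_AB + f_AC − f_BC`, pairwise expectation `(c_i+c_j)/2`),
  discounted for the drift added by the pedigreed generations. The
  per-generation drift of the litter mating scheme (sires drawn per
  litter with replacement, dams without, litter size ~5) was calibrated
  once against pure-drift runs of the scheme itself — 2.18×1/(2N) —
  because closed-form per-sex effective-size formulas were ~25% off for
  this design. Defaults: F_ST 0.17 (S–LR), 0.12 (S–LW), 0.14 (LW–LR).
* **Map and meiosis.** Uniform 1 Morgan per chromosome, Poisson(1)
  crossovers, no interference; 10 chromosomes × 200 SNP by default.
  A minor-allele-frequency floor of 0.05 in at least one breed keeps
  markers informative, mirroring the count-5 filter downstream.
* **Populations.** 300 founders per line, 4 generations of litter
  mating at constant census (the final generation is phenotyped), 50 S
  sires, reciprocal F1 dams (LR×LW and LW×LR) by default, 100 F1 dams
  with ~2 litters of 5, 1,000 crossbreds. Multiple litters per F1 dam
  matter: with one litter per dam the maternal-line genetic variance is
  confounded with the common-litter effect.
* **Architecture.** 400 QTL drawn from the SNP panel; per breed, PB and
  CB allele-substitution effects are bivariate with correlation
  `qtl_effect_corr_pb_cb[b]` (defaults 0.7/0.3/1.0 for S/LR/LW), which
  therefore *is* the per-line true r_pc. A `shared_qtl_fraction` (0.3)
  of background QTL carries a crossbred effect common to all breeds
  (the purebred effect is still drawn per breed at the line's
  correlation, keeping per-line r_pc exact). A major-QTL class (20 loci
  holding 40% of the crossbred genetic variance by default) is always
  breed-specific — large-effect regions are precisely where effects
  differ by parental breed — and can be given its own PB–CB correlation
  to build regimes with concordant selected QTL over a discordant
  background.
* **Phenotypes.** `y = mean + factor level + covariate·slope + litter +
  BV + e`, with litter and residual variances scaled from the realized
  genetic variance so heritabilities (purebred 0.17/0.23/0.22, crossbred
  0.30) and the litter fraction (0.18) hold in expectation; effects are
  rescaled so the crossbred genetic variance sits at 2,300 on an
  average-daily-gain-like scale (trait mean 800).

What the simulator does **not** emulate: ancestral linkage
disequilibrium (founders are at linkage equilibrium; LD arises only
from the drift generations, so short-range LD is weaker than on a real
medium-density panel), selection during the purebred generations,
genotyping or phasing error, imputation, dominance and imprinting, and
real pig family-size or chromosome-length distributions. Passing tests
therefore validate the estimators under the models' own assumptions
plus a controlled degree of architecture misspecification — not
performance on real data, whose accuracies depend on LD structure and
data depth this desk-scale generator does not reproduce.

## Problem sizes and determinism

All randomness flows from a single integer seed through independent
spawned streams per stage (founders / cross / architecture /
phenotypes), so identical configurations reproduce bit-identical data.
Tests and the acceptance script run the estimation machinery at
deliberately moderate sizes — 300 animals for the structural
equivalence suite, the default 1,900-record study for parameter
recovery (10 seeds), and a compressed 250-SNP / 1,050-animal design for
the cross-validated model comparison (10 seeds) — chosen so each suite
completes in minutes while keeping the contrasts of interest
identifiable.

## Known limitations

* Dense linear algebra throughout: O(N³) per REML iteration with N the
  number of records; comfortable to a few thousand records, not a
  routine-evaluation engine.
* The deregression weighting is a documented approximation of the
  cited effective-record-contribution algebra.
* Boundary railing of `r_pc` at desk-scale data sizes (see above);
  interpret single-replicate correlations with their SEs.
* The LD-block constructor is a simple greedy rule standing in for the
  companion study's procedure; its three knobs are recorded in outputs.
* Breed labels are fixed to a three-way terminal cross (one sire line,
  two maternal lines); generalising the composition mask is future
  work.
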