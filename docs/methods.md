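# Methods

This note documents the models implemented in `ldtrees`, the meaning and
defaults of every tunable parameter, what the synthetic-data generator
does and does not emulate, the numerical choices, and known limitations.

## 1. Split criterion and information measures

All tree growth uses the class-entropy information gain of a binary
case/control composition:

    discriminatingScore(cut, D) = H(D) − w_ℓ·H(D_ℓ) − w_r·H(D_r),

where `H` is the entropy of the case/control proportions, `D_ℓ`/`D_r`
the observations on either side of the cut and `w` their relative
sizes. Entropies and mutual informations are reported in **bits**
(base-2 logs); normalized quantities (NMI = MI / max(H(X), H(Y))) are
base-invariant, so the FLTM behaves identically under any base. An
empty child contributes zero; tiny negative float residue is clamped
to 0.

Contingency machinery for QC and the baseline: Cochran–Armitage trend
test with dosage scores (0, 1, 2), no continuity correction, p from a
1-df χ²; 2-df Pearson genotypic χ² with empty genotype columns dropped
(df collapse); exact two-sided Hardy–Weinberg test by full enumeration
of heterozygote counts conditional on allele counts, summing the
probabilities of configurations no more probable than the observed one.

## 2. T-Trees and the hybrid forest

A forest of `T` meta-trees is grown on bootstrap copies (same size,
with replacement) of the individuals. At a meta-node with observations
`D`:

* `min(K, #clusters)` clusters are drawn without replacement from the
  cluster map;
* per candidate, one Extra-tree is grown on `D` restricted to the
  cluster's SNPs: at each of its nodes the candidate variables (`k` =
  the whole cluster by default) each receive one threshold drawn
  uniformly in the (min, max) of their values at the node, and the best
  draw by discriminating score wins (ties → first drawn);
* each observation is assigned the case probability of the Extra-tree
  leaf it reaches — the meta-variable ν; its domain is the set of
  distinct leaf labels reached;
* the optimal meta-cutpoint is the ν-domain value (excluding the
  maximum; ties → smallest θ) maximising the discriminating score of
  the partition ν ≤ θ vs ν > θ;
* the candidate cluster with the best meta-cutpoint score wins; a best
  score of zero (or no candidate with ≥ 2 distinct ν values) makes the
  node a meta-leaf labeled with its case fraction, as does `|D| < S_n`
  or an exhausted `S_t` budget.

With the contiguous-block map this is T-Trees; with the FLTM layer-1
map it is the hybrid method. The forest code is identical — only the
map changes — which is what makes the two directly comparable.

**Importance.** `raw(v) = Σ (|D_e| / |D_bootstrap|) · gain(e)` over
every split node `e` on SNP `v` inside the *winning* Extra-tree of
every meta-node of every meta-tree; losing candidates are discarded
with their trees. Normalization by the total (default) or the maximum
is available. Prediction routes an individual through each meta-tree
(embedded tree → ν → compare θ) and averages the meta-leaf labels.

**Parameters** (reference full-scale values): `T = 1000` meta-trees;
`S_n = 2000` observations (meta-leaf threshold — set to half the 4,000
reference subjects, so meta-trees are intentionally shallow and the
ensemble relies on aggregation); `S_t = ∞` meta-node budget; `K = 1000`
candidate clusters per meta-node; `s_n = 1`, `s_t = 5` (embedded-tree
leaf threshold and split-node budget — embedded trees are weak
learners); `k` = cluster size; `B = 20` SNPs per contiguous block.
`ForestParams.desk(n)` scales this to desk problems: `T = 50`,
`K = 100`, and `S_n = n/2`, keeping the reference `S_n`/sample ratio.
Budgets (`s_t`, `S_t`) count *split* nodes and are consumed in
depth-first creation order, left child first.

**Determinism.** Every random draw flows from one master seed through
counter-based streams keyed by (seed, tree) for bootstraps and (seed,
tree, meta-node index) for node-level draws, so results are bit-
identical across repeated runs and across `n_jobs` settings;
parallelism is over meta-trees only.

**Missing genotypes** are mode-imputed per SNP once before forest
learning (QC bounds missingness, so the impact is small); the FLTM EM
instead marginalizes missing values exactly.

## 3. The FLTM latent-tree LD model

Learning iterates over "active variables" (initially the SNPs):

1. build the dissimilarity graph: edge (i, j) iff same chromosome and
   |pos_i − pos_j| ≤ δ (inclusive), weight 1 − NMI; constant variables
   are isolated;
2. DBSCAN on that graph: core point = ≥ `N_min` neighbours at distance
   ≤ R; clusters = connected components of core points; border points
   attach to their smallest-index core neighbour's cluster; noise →
   singletons, so the result is always a partition;
3. per cluster of size ≥ 2: latent cardinality
   `max(2, round(min(α + β·n_c, card_max)))` with α = 0.2, β = 2,
   card_max = 10 (the literal affine heuristic; it caps at 10 for
   clusters of ≥ 5 SNPs); a latent class model is fitted by EM (best of
   `nb_em_restarts = 10` seeded restarts, tolerance 1e-4 on the
   log-likelihood, ≤ 200 iterations); the latent column is imputed by
   sampling each individual's posterior P(L | children); the latent is
   **validated** iff the mean over children of NMI(L, child) ≥ τ = 0.3
   (inclusive);
4. validated latents replace their children (position = mean child
   position); invalid latents leave their children active; a cluster
   whose exact child set already failed validation is not refitted.

The loop stops when an iteration validates nothing or one variable
remains. Latent counts are bounded by 3n by construction. Only the
**layer-1** cluster map (child sets of first-iteration validated
latents, uncovered SNPs as singletons) feeds the hybrid forest; deeper
layers are retained for inspection.

**Selecting R.** One FLTM is learned per radius in the grid and the
model maximising the *LD coverage* criterion is kept (ties → smallest
R): the size-weighted validation score summed over layer-1 latents,
divided by the SNP count — i.e. the mean over SNPs of the NMI their
latent achieves, counting singletons as 0. Normalizing within validated
clusters only would favour arbitrarily small, tight clusters and make
the selection monotone in R; dividing by n balances cluster quality
against the fraction of the panel actually modeled. The reference grid
is 0.05–0.90 step 0.05; the desk experiments use {0.3, 0.5, 0.7}
(step 0.2): on NMI dissimilarities, which concentrate near 1 for
unlinked pairs, radii ≳ 0.8 chain entire δ-windows into genome-scale
clusters whose degenerate LCMs fail τ-validation anyway, at roughly
25× the cost.

**EM details.** Random Dirichlet(1) initialization of the prior and
CPTs per restart (restart r seeded seed + r); E-step in log space over
the *unique* child-value patterns (weighted by multiplicity — on
LD-structured data this collapses hundreds of individuals onto few
patterns); missing child values are skipped in the E-step and excluded
from their CPT's M-step counts; probabilities are floored at 1e-300
inside logs only, so the update is the exact EM and the likelihood is
non-decreasing to float precision.

## 4. Quality control and the single-SNP baseline

Two presets: `simulated` removes SNPs with MAF < 0.05 or exact HWE
p < 0.001; `wtccc` removes SNPs with missingness > 5%, missingness > 1%
together with MAF < 5%, or exact HWE / trend / genotypic-test p below
5.7e-7 (consortium-style rules; the association rules are never applied
to simulated data). Removal reasons are recorded per SNP; the filter is
idempotent. The baseline scan tests each SNP's 2×3 table over
non-missing calls — the 2-df genotypic test by default (the generic
contingency-table choice; the trend test is selectable and the choice
is recorded in the run config) — and ranks by ascending p, ties broken
by dataset order so top-k lists are reproducible. Monomorphic SNPs get
p = 1.

## 5. The synthetic-data generator

Real GWAS panels (access-controlled) are replaced by a haplotype-block
generator that preserves the one property every method here exploits:
**limited local haplotype diversity**. The panel is partitioned into
blocks of 5–20 SNPs; each block carries 8 distinct haplotypes with
Dirichlet(1) frequencies; a gamete picks one haplotype index per block
along a Markov chain (the index is redrawn with probability
`recomb_between_blocks = 0.5` per block boundary, giving strong
within-block LD and decaying cross-block LD); an individual is the sum
of two independent gametes, so single-SNP genotypes are
Hardy–Weinberg. Positions are 1 kb apart on one chromosome.

**Disease model.** Per causal SNP, genotype relative risks follow the
genetic model — additive (γ, 2γ−1), dominant (γ, γ), recessive (1, γ)
— and penetrances solve f0 = K / (p₀ + γ₁p₁ + γ₂p₂) under HWE
frequencies of the risk (minor) allele, K = prevalence = 0.01. Multiple
causal SNPs (10 per replicate, spread over distinct blocks, population
MAF inside the configured interval) combine **multiplicatively on the
relative-risk scale**, with the baseline solved so the population
prevalence is exactly K in expectation: this log-additive multi-locus
model preserves each SNP's *marginal* GRR at the configured value,
which is the convention of resampling-based GWAS simulators.
Independent-attack combination (1 − Π(1 − f_i)) was tried first and
rejected: with 10 causal SNPs it dilutes every marginal GRR to ~1.3,
silently changing the study condition. Joint risks of extreme
multi-locus genotypes (probability ~1e-10) are clipped at 1. Disease
status is assigned by Bernoulli draws and individuals are
rejection-sampled until exactly the configured case and control counts
are reached; causal SNPs remain in the analysed panel.

**What the generator does not emulate:** recombination-map realism,
allele-frequency spectra from real populations, population structure
and relatedness, genotyping-platform error patterns, long-range LD.
Passing tests therefore demonstrate the machinery's correctness and
the methods' relative behaviour under controlled LD, not performance
on real cohorts.

## 6. Evaluation harness

* **Top-k recovery**: 100 · Σ_r |causal_r ∩ top-k_r| / Σ_r |causal_r|
  over replicates, for k ∈ {25, 50, 100, 200, 1000}; monotone in k.
* **AUC**: Mann–Whitney formulation with ties credited ½.
* **Cross-validation**: 10 stratified folds (stratification prevents
  single-class test folds at desk sizes); the LD map is built once on
  the full dataset and shared across folds; the forest is refitted per
  fold with seed + fold.
* **Importance comparison**: two-sided Wilcoxon rank-sum (exact when
  the combined tie-free sample is < 50, tie-corrected normal
  approximation otherwise), Pearson correlation, and a quantile table
  at 25/50/75% plus the positions of the top-300/200/100/50/20/10
  scores, computed as (1 − n_top/n) quantiles of the data's own n.
* **Intersections**: pairwise and full top-100 set intersections; a
  SNP's max-rank across methods defines top\*m membership (jointly in
  every method's top m).

## 7. Desk-scale experiment sizes

The reference full-scale protocol (20,000 SNPs × 4,000 individuals,
30 replicates × 27 conditions, T = 1000) is a cluster-scale
computation. The packaged experiments (`ldtrees.experiments`,
`scripts/acceptance.py`) run one condition — additive, GRR 1.8, causal
MAF 0.25–0.35, the clearest-signal cell of the condition grid — at
2,000 SNPs, 500 + 500 individuals, 10 causal SNPs, 5 replicates,
T = 50, K = 100, S_n = 500, R grid {0.3, 0.5, 0.7}; the null control
reruns the identical pipeline with GRR = 1. These sizes are the
package's chosen desk conditions; every full-scale value remains the
library default so the reference setting is one parameter object away.

## 8. Known limitations

* Genotype-threshold Extra-trees see dosages as ordered (0 ≤ 1 ≤ 2);
  purely heterotic (0/2 vs 1) single-SNP effects need two splits.
* The FLTM cardinality heuristic caps at 10 very quickly (any cluster
  of ≥ 5 SNPs); large clusters are summarized coarsely.
* DBSCAN border-point assignment (smallest-index core neighbour) and
  p-value tie-breaking (dataset order) are deterministic conventions,
  not optimality claims.
* The Wilcoxon/Pearson comparison treats importance scores as i.i.d.
  samples; spatial correlation along the genome is ignored, as in the
  peer-analysis protocol it mirrors.
* `select_R` learns one full FLTM per grid point; its cost is linear
  in the grid size and dominated by the largest radius.
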