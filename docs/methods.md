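# Methods

`matryoshka` delimits nested genetic lineages from diploid multilocus
microsatellite genotypes. This note documents the models, the decision
rules, the synthetic data the test suite runs on, and the numerical and
design choices a user should know about.

## Data model

The universal input is an N × L table of diploid genotypes: two positive
integer allele codes per individual per locus, with a missing mask (a
locus is typed or not — half-calls in input files are promoted to fully
missing with a warning, since every estimator below treats loci as
typed-or-not). Samples carry a four-level geographic hierarchy
(site < island < ecoregion < province). Supported dialects: GenePop 4.x
(missing `000`), STRUCTURE two-row (missing `0`), long CSV (missing =
empty cells). Allele codes are carried verbatim; fragment-size binning is
upstream of this package.

## Clone screening

Repeated multilocus genotypes (MLGs) signal clonemates. Two policies:
*strict* (default) — two individuals match iff neither has missing data
and all allele pairs agree as unordered multisets; *tolerant* — match on
all loci typed in both, with ≥ 1 shared typed locus, grouped by transitive
closure. The closure can chain individuals never directly compared; a
warning reports pairs merged with no shared typed locus. One
representative per MLG (first by input order) proceeds to analysis.

## Bayesian admixture model

Each individual i carries admixture proportions `q_i` over K clusters
(symmetric Dirichlet(α) prior, α ~ Uniform(0, α_max), α_max = 10 by
default). Each allele copy picks an origin cluster from `q_i`, then an
allele from that cluster's frequencies `P_kl`. Under the default
*correlated* frequency prior, cluster frequencies drift from shared
ancestral frequencies `π_l` with cluster-specific intensity `F_k`:

    P_kl ~ Dirichlet( π_l · (1 − F_k) / F_k )

(the multiallelic Balding–Nichols model). The *independent* alternative
uses a flat Dirichlet(1). Missing allele copies contribute nothing to
the likelihood; no imputation is performed.

Inference is by Gibbs sampling: allele-copy origins, then `q_i`, then
`P_kl`; `F_k` by random-walk Metropolis on the logit scale (step 0.3,
Uniform(0,1) prior), `π_l` by a Dirichlet-proposal Metropolis
(concentration 200), α by a Gaussian random walk (step 0.05). Posterior
means are accumulated after burn-in. Desk-scale defaults are 5,000
burn-in and 20,000 retained sweeps; the delimitation engine and the
acceptance script use 1,000 / 4,000 with 5 replicate chains per K — for
13 highly polymorphic loci and the effect sizes simulated below, chains
reach the dominant mode within a few hundred sweeps and the threshold
rule consumes only the posterior means, so longer runs change no
decision. Replicate chains are reconciled by Hungarian assignment on the
Q-overlap matrix — exact for averaging a handful of runs, replacing
heuristic label-matching searches. Hard labels break ties toward the
lowest cluster index.

## DAPC

The assumption-free counterpart: genotypes become allele-count rows
(0/1/2 per allele column; a missing locus contributes twice the overall
allele frequencies, so each locus block still sums to 2), columns are
centered, PCA compresses, k-means (k-means++, 10 restarts) discovers
groups on the scores, and linear discriminant analysis assigns posterior
memberships from Gaussian class-conditionals with pooled covariance.

Two retention rules, on purpose: group discovery keeps (nearly) all PCs;
the discriminant step keeps the smallest count explaining ≥ 90% of
variance, capped at N/3 (an overfitting guard). The group-count score is
fixed as BIC(K) = n·ln(WSS_K/n) + K·ln(n) so results are reproducible
bit-for-bit. Note its behaviour honestly: on data with real clusters it
has a pronounced minimum at the true K (simulations below recover K = 3
with ARI 1.0), but on unstructured data the curve is nearly flat and a
trivial K = 2 can win by less than one penalty unit — the curve alone is
not a K-selector, which is exactly why the delimitation engine never uses
its argmin and instead evaluates every candidate K by cross-method
congruence.

## Threshold assignment and the congruence rule for K

An individual is **pure** in cluster k iff its assignment probability
exceeds τ_pure = 0.75 in *every* replicate run (strict inequality);
otherwise it is **admixed** over the clusters whose mean probability
exceeds τ_comp = 0.1 (below 0.1 is noise), and **unassignable** if none
does. Raising τ_pure can only shrink the pure set.

**Method discordance** between two labelings is the mismatch fraction
after Hungarian matching of their confusion matrix, computed over
individuals confidently assigned by both methods.

**Congruent K.** For each candidate K from 2 to k_max (default 4):

1. *Coherence gate*: the replicate admixture chains must agree — the
   largest pairwise mean |ΔQ| after alignment must not exceed
   τ_rep = 0.05. Chains stuck in different modes (the signature of a K
   the data cannot support) fail this gate, mirroring the requirement
   that colonies be assigned identically across runs.
2. *Full-sample check*: every cluster must hold at least `min_node` (10)
   pure members under both methods, and admixture-vs-DAPC discordance
   must stay within τ_disc = 0.05 (a default justified by the 1.9–4.7%
   discordances such data produce; configurable).
3. *Subset check*: within every child of the previously accepted
   partition that the candidate K subdivides, both methods are rerun at
   the child's cluster count; the reruns must be coherent and map
   one-to-one onto the full-sample clusters within τ_disc (all method ×
   scope combinations). A child the candidate keeps whole imposes no
   constraint here — deeper structure inside it belongs to the recursion,
   not to this K.

The accepted K is the highest congruent candidate (1 if none). In the
simulated nested design this behaves as intended: at the top level the
true lineage count passes all gates, while one-too-few and one-too-many
K fail the coherence gate because replicate chains disagree about which
groups to merge or split.

**Recursive splitting** applies the rule at the root, records and
excludes each node's admixed individuals, and recurses into every child
until K = 1 or fewer than 2·min_node members remain. Leaves plus
exclusion lists exactly partition the input.

## Differentiation statistics

* **Weir–Cockerham F_ST (θ)** from per-locus, per-allele components a, b,
  c with the standard unequal-sample-size machinery (n̄, n_c, weighted p̄,
  s², h̄). Multilocus θ is the ratio of summed components; per-locus
  global θ_l comes with mean ± SE over loci. Negative estimates are
  reported, not truncated. Monomorphic loci are excluded from ratios;
  a locus enters a comparison only with ≥ 2 typed individuals per group
  (pairwise deletion). p-values by permutation of individuals between
  groups (999 by default).
* **Jost's D_est** with Nei–Chesser corrections: harmonic-mean sample
  size Ñ, H_S = (2Ñ/(2Ñ−1))(1 − mean Σp²), H_T = 1 − Σp̄² + H_S/(2Ñn),
  D_l = [(H_T−H_S)/(1−H_S)]·n/(n−1), arithmetic mean over polymorphic
  loci.
* **Na / Np**: observed and private allele counts per group with
  mean ± SE over loci and the full frequency spectra.
* **Genotypic LD**: G-tests on single-locus genotype contingency tables
  per locus pair, null by permuting one locus among individuals within
  groups (margins are permutation-invariant, so Σ O·ln O is used as the
  sufficient statistic), Bonferroni threshold α/(L(L−1)/2). The default
  10,000 permutations resolve p below the Bonferroni level for 78 pairs.
* **AMOVA** (group > population > individual) on the allele-identity
  squared distance δ²(i,j) = Σ_l (2 − shared alleles), rescaled by L/L′
  over co-typed loci; variance components via the standard
  unequal-size coefficients; Φ_CT, Φ_SC, Φ_ST with the three canonical
  permutation schemes.

## Hybrid classification

Six genealogical categories (P1, P2, F1, F2, BC1, BC2) are defined by
their expected per-locus gene-origin-pair proportions — (1,0,0), (0,0,1),
(0,1,0), (¼,½,¼), (½,½,0), (0,½,½). A Gibbs sampler alternates category
assignments, per-locus origin pairs, parental allele frequencies
(Dirichlet(1) prior) and category mixing proportions (Dirichlet(1));
loci are treated as independent. The two putative parental pools anchor
the gene pools through the chain initialisation only — every individual's
category remains free. An individual is called a hybrid when its summed
posterior over the four non-parental categories exceeds 0.5
(configurable). Known limitation: with *undifferentiated* parental pools
the likelihood is flat and the exact posterior equals the prior, but a
finite chain collapses onto a single category through mixing-proportion
reinforcement — the verdicts then carry no discrimination between pools
and must not be interpreted. Desk-scale defaults 5,000 / 50,000 sweeps.

## Distance network

The shared-allele distance D_AS is 1 minus the shared-allele proportion
over co-typed loci, with multiset sharing (A/A vs A/B shares 1). The
minimum spanning tree uses Kruskal's algorithm with deterministic
(distance, i, j) tie-breaking; missing-data blocks yield a spanning
forest. The triangle inequality is *not* asserted for D_AS with missing
data.

## Synthetic data generator

The generator is first-class, tested code and defines the conditions the
suite certifies. Ancestral frequencies π_l ~ Dirichlet(1) over 14
alleles at 13 loci drift into 3 lineages (Balding–Nichols with
F_level1 = 0.20), which drift into {3, 2, 3} nested clusters
(F_level2 = 0.12) — the same Dirichlet drift that is the clustering
model's prior, so parameter recovery compares like with like. Eight
sites each draw 150 individuals from a uniform mixture of all eight
clusters (sympatry everywhere; sites add no drift of their own), giving
~150 per cluster. Genotypes are Hardy–Weinberg draws from cluster
frequencies. Then 6% of individuals are overwritten as gene-by-gene
admixtures of two sibling clusters (weights Dirichlet(1,1)), 0.7% as F2
hybrids (per-locus origin pairs from the (¼,½,¼) law), and 5% of cells
are masked missing completely at random (the studies this emulates give
no overall rate; 5% is a realistic microsatellite dropout level, while
the admixture/hybrid rates are the reported ones). Everything is
deterministic under the config seed, and a full truth record (labels,
admixture weights, hybrid parents, all frequency tensors) is returned.

What the generator does *not* emulate: mutation processes (SMM/IAM),
site-level drift or isolation by distance, genotyping error beyond MCAR
dropout, inbreeding within clusters (HWE is assumed), and any association
between missingness and admixture — so passing tests certify the
machinery under the stated model, not robustness to those features of
real data. Realized drift varies across a 13-locus draw (the multilocus
F_ST of one dataset scatters around the design F with SD ≈ 0.02–0.05),
which is why estimator-bias checks compare against the estimator's
infinite-sample limit on the realized frequencies, or average over
replicate datasets.

A note on truth labels for spiked individuals: admixed and F2 spikes have
*mixture* ancestry, not a cluster label, so recovery scores (ARI) are
computed over individuals whose ground truth is a single cluster.

## Problem sizes and determinism

The test suite and the acceptance script run the full nested design
(1,200 individuals, 13 loci) with 5 replicate chains of 1,000 + 4,000
sweeps per candidate K, 199 permutations for F_ST/D_est/AMOVA p-values
and 5,000 for LD — sizes chosen so the whole analysis reproduces the
qualitative and quantitative structure of the design in minutes on one
core. All samplers are deterministic under their seeds (the numba global
RNG is seeded per chain); reruns with the same configuration are
byte-identical.

## Known limitations

* The congruence rule's wrong-K rejection relies on replicate chains
  falling into different modes; with very few chains (< 3) a spurious K
  can slip through. Five replicates are the default in the acceptance
  configuration.
* The Gibbs sampler has no tempering or split-merge moves; for K far
  above the number of real groups it simply fails the coherence gate
  rather than sampling the full multimodal posterior.
* D_AS with heavy missing data is not metric; the MST is a visual
  diagnostic, not an inference.
* The hybrid classifier assumes exactly two parental pools and the six
  canonical categories; later-generation backcrosses are absorbed into
  the nearest category.
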