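# Methods

## Problem setting

`l1l2pheno` predicts a real-valued trait from genome-wide SNP genotypes and
simultaneously selects the markers that carry the signal.  The data are a
samples × SNPs dosage matrix X (additive {0, 1, 2} coding: copies of the
minor allele), a trait vector y, and a family label per sample.  Cohorts of
related individuals — sibling groups, stock crosses — make family structure
the dominant confounder: relatives share long genotype stretches, so any
split that separates relatives into train and test leaks information.

## The estimator

The selection step solves the naive elastic net

    min_w  (1/n) ||y − X w||²  +  μ ||w||²  +  τ ||w||₁

by proximal gradient descent (ISTA; Nesterov acceleration on by default).
The ℓ1 term produces exact zeros, the ℓ2 term spreads weight over groups of
correlated SNPs instead of picking one arbitrarily.  The normalization of
the residual term by 1/n is a package convention, chosen so that (μ, τ)
grids transfer across sample sizes; grids should be built in log space
relative to `tau_max`, the smallest τ with an all-zero solution.

Because every ℓ1 minimizer is shrunken, selection is followed by a ridge
refit restricted to the selected support S:

    w̃ = (X_Sᵀ X_S + λ n I)⁻¹ X_Sᵀ y

λ controls the bias of the reported weights; λn matches the 1/n loss
convention.  Predictions use the refit weights plus an intercept.

Numerical choices:

- Columns are standardized to zero mean / unit variance and y centered
  before solving; weights are reported on the standardized scale (so
  magnitudes are comparable across SNPs) and the intercept restores the
  trait scale at prediction time.
- Step size 1/L, with L = largest eigenvalue of (2/n)XᵀX + 2μI found by
  power iteration.  Convergence: relative ℓ2 change of w below `tolerance`
  (default 1e-6; the protocol driver uses 1e-5) or `max_iterations`
  (default 10,000) — hitting the cap sets a flag instead of raising, since
  a coarse grid point must not abort a cross-validation sweep.
- Warm starts along a descending τ path are used inside cross-validation;
  the fixed point is unique for μ > 0 so warm starting changes cost, not
  answers.
- An empty support (large τ) yields a degenerate model that predicts the
  training mean and scores a squared correlation of 0.
- Feature ranking orders the support by decreasing |refit weight|, ties
  broken lexicographically by SNP name so rankings are deterministic.

## Stability of ranked lists

Repeated fits yield partial ranked marker lists over the p SNPs.  A list of
length k is completed to a full rank vector by assigning every unlisted SNP
the mean unoccupied rank (k + 1 + p)/2 — the per-element expectation over
uniform extensions of the list to a permutation.  Two completed vectors are
compared with the Canberra distance Σ|aᵢ − bᵢ|/(aᵢ + bᵢ), which penalizes
disagreements near the top of a list more than equal-sized disagreements
near the bottom.  The stability indicator of a set of lists is the mean
over all pairwise distances; lower means more reproducible selection.  An
optional normalization divides by the Monte-Carlo expected distance between
two random full permutations (fixed internal seed), giving a scale-free
score for plots; model selection uses the raw value.  A completion-based
distance is one of several possible partial-list extensions; absolute
values are comparable only within a fixed universe size and completion
rule.

## The data analysis protocols

**Nested accuracy–stability protocol** (the default): the cohort is split
`n_resamplings` times (default 15) into development/validation at the
family level — families are shuffled and assigned to development until it
holds `dev_fraction` (default 0.7) of samples.  On each development set,
every grid triple (μ, τ, λ) is scored by family-respecting k-fold CV
(default k = 10): mean held-out squared error, plus the Canberra stability
of the k fold-wise ranked lists.  Selection takes, among grid points within
`mse_tolerance_fraction` (default 5%) of the best CV error, the one with
the lowest stability indicator; ties prefer sparser models (larger τ), then
lexicographic (μ, τ, λ), making the rule a total order and hence invariant
to grid enumeration order.  The winning triple is refit on the full
development set and scored once on the untouched validation families as the
squared Pearson correlation between prediction and truth.  The protocol
asserts on every run that no sample appears on both sides of a split.

**Bootstrap baseline protocol**: grid search over a plugin regressor
(Gaussian-kernel SVR via scikit-learn; linear-kernel weights for ranking)
on interfamily half-splits, maximizing mean squared correlation, followed
by evaluation on fresh interfamily resamplings.  Because selection and
evaluation resample the same cohort, results carry a
`selection_bias_prone` flag.

**Permutation control**: the whole nested protocol re-run on phenotypes
shuffled uniformly at random.  Any mean validation r² meaningfully above
zero indicates leakage in the protocol rather than signal in the data.

## Saturation

Sparse selection keeps roughly one SNP per correlated group.  To recover
the discarded group members: a SNP is *top-ranked* if its |weight| reaches
the top `percentile` (default 10) of the nonzero weights in at least
`min_runs` of the resamplings (default 14 of 15).  Taking the percentile
over nonzero weights only is deliberate — over all p weights of a sparse
model the cut would be 0.  For dense baseline weights (linear SVR) the
percentile is over all weights (`dense=True`).  Every SNP whose genotype
column correlates with a top-ranked SNP at |r| ≥ threshold is reported with
its correlation, same-chromosome base-pair distance (cross-chromosome pairs
are kept but excluded from distance statistics), and model weight (0 when
eliminated).  The threshold sweep (default {0.6, 0.7, 0.8, 0.9}) pools
distances per threshold; under decaying LD the pooled median shrinks as the
threshold rises.

## Synthetic cohorts

The generator emulates the statistical structure of a heterogeneous-stock
mapping population at desk scale.  Per family, two founders; each founder
haplotype is built block-wise: the block's first SNP carries a
Bernoulli(maf) seed allele (maf drawn per block from `maf_range`), the
remaining SNPs are noisy copies.  Two LD shapes:

- `ld_mode="seed"` (default): each copy flips independently from the seed
  with `within_block_flip_prob` f, giving near-constant within-block
  correlation ≈ (1 − 2f) (measured ≈ 0.87 at f = 0.05).
- `ld_mode="chain"`: each SNP flips from its left neighbour, giving
  geometric decay ≈ (1 − 2f)^k with within-block offset k — the shape that
  makes distance-vs-threshold behaviour visible.

Offspring receive one haplotype per parent per chromosome (no
within-chromosome recombination; a one-generation nuclear family rather
than a multi-generation pedigree — sufficient for interfamily splitting and
leakage tests to be meaningful).  Causal SNPs sit one per chosen block, at
the block seed, with effects ± Uniform(`effect_size_range`).  Noise
variance is set so Var(Xβ)/Var(y) equals the requested h²; the realized
value is recorded.  Calls are masked uniformly at `missing_rate` (default
0.0014, i.e. 0.14%).

Defaults are 120 families × 5 sibs, 2000 SNPs in 10-SNP blocks over 5
chromosomes, 20 causal SNPs, h² = 0.3: a trait architecture on which
prediction is genuinely hard (expected protocol r² roughly 0.1–0.25, well
below h², because 20 small effects must be estimated from ~100 effective
independent genotypes per causal SNP).  The protocol-level verification
runs instead use a concentrated architecture — 300 two-sib families, 5
causal loci, effects ±Uniform(0.5, 2), MAF 0.2–0.5, same n = 600,
p = 2000, h² = 0.3 — under which a correct implementation attains mean
validation r² above 0.2 while the permutation control stays below 0.02.
Problem sizes throughout (5 resamplings, 5-fold internal CV, 12-point
grids) are chosen so a full verification pass completes on a single CPU
workstation.

What the generator does not model: recombination within chromosomes,
multi-generation pedigrees, population stratification beyond family
blocks, genotyping error other than uniformly missing calls, dominance or
epistasis.  Passing tests therefore demonstrate correctness of the
machinery and its behaviour under the stated genetic architecture, not
performance on any real cohort.

## Imputation

Missing calls are filled by draws from the per-locus genotype-class
frequencies among called samples — class frequencies rather than
HWE-implied allele draws, which preserves each locus's marginal genotype
distribution exactly.  One seeded stream is consumed in SNP order so
adding samples does not reshuffle draws at unrelated loci.  This is
deliberately naive (it can create Mendelian inconsistencies within
families and ignores LD); it is adequate when missingness is rare, and the
missingness report exists to verify that premise.

## Known limitations

- The accuracy–stability selection rule is one reasonable determinization
  of "maximal accuracy and stability"; other trade-off rules (e.g. Pareto
  scalarization) would select differently on flat error surfaces.
- Stability values depend on the list-completion convention and universe
  size; compare them only within a run.
- The bootstrap baseline's r² is optimistic by construction; it is kept as
  a comparator, not a recommendation.
- ped/map support covers the whitespace text dialect only (no binary
  variants); two-allele loci only.
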