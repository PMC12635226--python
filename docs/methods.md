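# Methods

## The crosstalk model

The pipeline quantifies intercellular signaling between annotated cell
subsets (e.g. MSC, adipocyte 1, adipocyte 2) sampled under two conditions,
an age group label `young` or `old` per cell.  For a ligand-receptor gene
pair (l, r), a sender subset i, a receiver subset j and one age group, the
interaction score is the product of group means

    S = e̅_{i,l} × e̅_{j,r}

where e̅_{i,l} is the arithmetic mean expression of the ligand gene over
the cells of subset i in that age group, and e̅_{j,r} the mean of the
receptor gene over subset j in the same age group.  The score is a proxy,
not a mechanistic model: it is large when both partners are abundantly
expressed in the right populations, and it is exactly zero whenever either
group mean is zero.

Significance is assessed by a label-permutation null.  The age-group label
is randomly shuffled *within each cell subset* (subset membership is never
altered, so per-subset young/old counts are preserved exactly), the score
is recomputed as S_p, and this is repeated N times (default N = 1000).
The p-value is

    p = n / N

where n counts permuted scores at least as large as the observed score —
ties count, so the test is one-sided for up-regulation in the scored age
group, and p = 0 is attainable.  An interaction is flagged significant
when p ≤ 0.01.  Down-regulation during aging is obtained symmetrically by
reading the young-group records.  A bias-corrected alternative
(n+1)/(N+1) can be reported alongside (`--pseudo`), but the headline value
is the plain ratio.

Permutations are shared: one within-subset shuffle per iteration is
applied to every subset simultaneously and reused across all pairs and all
(sender, receiver) combinations.  This gives a coherent joint null, O(N)
shuffles instead of O(N·pairs), and lets the engine compute all group
means per iteration as a single matrix product.  Sampling is uniform over
within-subset label arrangements, with replacement; the identity
arrangement may be drawn.  When sender and receiver are the same subset, a
single shuffle serves both roles.

Receptors are treated as single genes; multi-subunit receptor complexes
are out of scope.  No multiple-testing correction is applied to the
crosstalk p-values by default (the raw 0.01 rule); Benjamini-Hochberg
values can be added downstream from the emitted table.

### Expression scale

Group means are computed on whatever layer is passed in; the pipeline
default is cp10k (counts scaled per cell to a total of 10,000), linear
scale.  Means of log-transformed values would distort the product score
(the mean of logs is not the log of the mean), so log1p_cp10k is available
but not the default.  The chosen layer is recorded in the output header.
Multiplying the whole layer by a constant c multiplies every S by c² and
leaves every p unchanged.

### Numerical choices

* **Tie tolerance.**  Permuted group means are sums of the same values in
  a different order, which can differ from the observed means in the last
  float bit.  S_p ≥ S is therefore evaluated with a relative tolerance of
  1e-9, so true ties always count as "as or higher" (this is what makes
  the degenerate constant-expression case return p = 1 exactly).
* **Exact p arithmetic.**  p is stored as the exact float quotient n/N;
  no pseudocount, continuity or tail correction is applied.
* **Calibration runs use N = 999.**  On the discrete support {0, 1/N, …,
  1}, the probability that p ≤ 0.01 under exchangeability is
  (⌊0.01·N⌋+1)/(N+1); with N = 1000 that is 11/1001 ≈ 0.011, slightly
  above nominal.  N = 999 gives exactly 10/1000 = 0.01, so type-I
  calibration checks run at N = 999.  The analysis default stays at
  N = 1000.
* **Subsets lacking one age group** cannot contribute to the null and are
  excluded from scoring with a warning; pairs with a gene absent from the
  matrix are diverted to a skipped-pairs table rather than scored.

## Quality control

Cells are removed when they have fewer than 200 detected genes (nonzero
counts) *or* more than 10% of their counts on mitochondrial genes
(name prefix `MT-` by default).  The inequalities are strict: a cell with
exactly 200 detected genes or exactly 10% mitochondrial counts is kept.
The union rule is the default because it is standard practice; the
literal conjunctive reading is available as `qc_rule: intersection`.
After cell filtering, genes expressed in fewer than 3 of the *surviving*
cells are removed (strict again: a gene in exactly 3 cells stays).  The
filter runs in one pass — cell rules first, then the gene rule — and is
idempotent.  The mitochondrial share is computed from counts (UMIs), the
usual proxy for reads at this stage.

## Differential expression

Both flagging rules use the two-sided Wilcoxon rank-sum (Mann-Whitney)
test with midrank tie handling: exact enumeration when both groups have at
most 8 observations and no ties, the normal approximation with tie
correction otherwise.

* **Cluster markers** (group vs rest): a gene is flagged when the
  Bonferroni-corrected p is below 0.01 *and* the fold change exceeds 1.5.
  Fold change is the ratio of linear-scale means (log layers are de-logged
  first) with a pseudocount of 1e-9; a log2-difference mode is available
  and flags identically.
* **Aging-associated genes** (old vs young within one subset):
  Benjamini-Hochberg adjusted p-values are always reported, but the flag
  uses the raw p against 0.05 by default, with a switch
  (`aging_use_bh`) to flag on the adjusted value.  The direction field
  records whether the gene is higher in the old or the young cells.

## Synthetic data generator

The generator emulates the statistical structure the crosstalk test
assumes, so every downstream stage can be validated against a known
truth:

* counts are negative binomial (gamma-Poisson), mean
  `baseline_mean × gene_factor × lib_factor` with size parameter
  `dispersion` (default mean 2.0, size 5.0 — overdispersion typical of
  droplet scRNA-seq);
* per-gene factors are log-normal with unit mean (sigma 0.5), giving a
  right-skewed mean distribution;
* per-cell library-size factors are log-normal with unit mean (sigma
  0.3), which is what makes normalization choices testable;
* a planted effect multiplies the ligand gene's mean in the (sender
  subset, age group) cells and the receptor gene's mean in the (receiver
  subset, age group) cells by `fold`, and is returned verbatim in a truth
  table;
* decoy ligand-receptor pairs are drawn from untouched, non-mitochondrial
  genes, so they carry no age signal by construction;
* planted low-quality cells either keep a small random fraction of genes
  (capped below the 200-gene convention) or have their mitochondrial
  means inflated to roughly a 40% share, or both, so QC outcomes are
  forced by construction;
* with no planted effects the young and old cells of every subset are
  drawn from the identical distribution, making age labels exchangeable —
  the basis of all null-calibration tests.  Low-quality cells get their
  age label at random for the same reason.

A fixed seed makes the output byte-identical across processes.

What the generator does **not** emulate: real cluster structure and
marker programs, batch effects, doublets, zero-inflation beyond the NB,
gene-gene correlation, or the deep imbalance of real subset sizes.
Passing tests therefore demonstrate that the statistical machinery is
correct under its own assumptions, not that those assumptions hold in any
particular tissue.

One caveat worth knowing: per-cell library factors are shared by all
genes of a cell, so on *raw* counts the young/old mean differences of
different genes are correlated through them.  Null-uniformity checks are
run on normalized values, where this common factor cancels.

## Problem sizes used in the checks

The shipped tests and the acceptance script use deliberately small
instances: exhaustive-enumeration comparisons run on 2 subsets with 2
young + 2 old cells each (36 arrangements, Monte-Carlo N = 10,000);
type-I calibration on 2 × 1,000 null interactions (500 decoy pairs, 50
cells per age, N = 999); power on 20 replicate datasets with a 4-fold
planted effect, 200 cells per (subset, age) and N = 1000; the null
aging-gene rate on 2,000 genes with 100 cells per age.  These sizes give
the binomial intervals quoted in the tests while keeping a full run in
the order of seconds.

## Known limitations

* The score uses group means only; it ignores expression variance and
  the fraction of expressing cells, and a few strongly expressing cells
  can dominate a mean.
* p = 0 records mean "never reached in N permutations", not impossibility;
  resolution is 1/N.
* Shared permutations correlate the p-values of different records within a
  run (deliberately, for a coherent joint null); treat per-run false
  positive counts, not individual borderline records, as the calibrated
  quantity.
* The trajectory-conditional variant of the analysis is covered only in
  the sense that any user-supplied grouping labels (e.g. pseudotime bins)
  can stand in for cell subsets; the package does not learn trajectories.
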