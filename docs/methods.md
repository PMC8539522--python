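# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Rarefaction

Unequal sequencing effort is normalised by subsampling every sample's
reads *without replacement* to a common depth (default 2000 reads/sample),
i.e. one multivariate-hypergeometric draw per sample
(`numpy.random.Generator.multivariate_hypergeometric`). Consequences: each
rarefied cell is bounded by the original count, retained columns sum
exactly to the depth, and the expected rarefied count is
`depth × countᵢⱼ/totalⱼ`. Samples below the depth are dropped with a
warning rather than scaled, since scaling would break the count semantics
downstream (integer reads per function). A single draw is taken per run;
the seed is an explicit argument, and averaging over draws is available by
rerunning with different seeds.

## Rule-based function annotation

The rule database is flat text: group headers at column 0, indented member
lines that are either taxon patterns or `add_group:<name>` directives.
Pattern semantics are deliberately simple and case-sensitive: `*` matches
any substring greedily and a starred pattern must cover the whole taxonomy
string, while a literal (star-free) pattern matches as a substring of a
single rank segment. The `add_group` closure is resolved transitively over
the inclusion DAG (cycles and dangling references are parse errors), so a
group's effective pattern set includes those of every group it contains.
Annotation is monotone by construction: adding a rule can only add
assignments. A ZOTU may match one group, several, or none; unmatched ZOTUs
contribute to no function, and a ZOTU's reads count fully toward every
category it belongs to (no fractional splitting — multi-cycle metabolisms
are biologically legitimate).

### De-nesting (regrouping)

Because of `add_group` nesting, raw output double-counts reads across
overlapping categories. The regroup specification (an editable YAML file)
fixes this in two steps: `merge_map` renames/merges raw groups into
canonical categories (unioning their ZOTU sets), then `subtract_map`
removes from each canonical category the ZOTUs of the listed categories.
The bundled specification defines Chemo-1 (aerobic chemoheterotrophy minus
biopolymer, one-carbon and aromatic-hydrocarbon degraders), Chemo-2
(aromatic hydrocarbon degradation), Chemo-3 (residual chemoheterotrophy
after removing Chemo-1, Chemo-2 and the same specialist families), a
merged "dissimilatory nitrate reduction" for the three nitrate-respiring
raw groups, and a subtraction of the one-carbon specialists from the
umbrella methylotrophy. The subtract list for Chemo-1/Chemo-3 covers the
biopolymer, one-carbon and aromatic families and is configurable — the
exact residual membership is a data decision, not code. Umbrella groups
fully covered by their members (e.g. respiration of sulfur compounds) are
dropped rather than kept as duplicates. Reads are recomputed from the
final ZOTU sets, so the output is internally consistent by construction.

### Element accounting

Each canonical category maps to a biogeochemical cycle (C, N, S, Fe, H or
other). The bundled `element_map_synthetic90.tsv` is a synthetic stand-in
catalog for the full 90-category database (which is not redistributed
here): its names are representative and its element distribution matches
the full database's summary (49 C, 16 N, 11 S). The miniature rule set
ships with its own canonical-category element map. The C:N:S metabolic
ratio divides summed C- and N-cycle read assignments by the S-cycle sum
(sulfur = 1). When a sample has no sulfur-cycle reads the ratio is
undefined; the raw sums are reported with a flag instead of dividing.
Category *counts* per element are returned alongside, since either reads
or counts can be of interest; the reads-based ratio is the default because
count-based ratios cannot exceed the catalog's category totals and are too
coarse for per-sample comparison.

## Diversity indices

All indices operate on the per-category assigned-read vector of the
de-nested table. Shannon H uses natural logarithms (the evenness relation
J = H/ln S then holds exactly, which is also how the published index
panels are internally consistent). Chao1 is the bias-corrected form
`S + F₁(F₁−1)/(2(F₂+1))`, defined also when no doubletons occur. For
Menhinick's index `S/√N`, `N` defaults to the total assigned reads in the
sample; the rarefaction depth is an equally defensible definition and can
be passed explicitly — the two differ because not every read is assigned
to a function.

## CLPP plate scoring

Plates hold 31 substrates in triplicate plus 3 water controls
(8 × 12 grid, the standard catalog bundled as YAML: 10 carbohydrates, 9
carboxylic acids, 6 amino acids, 4 polymers, 2 amines). A well's 0–3 rank
is the number of strictly ascending intensity cutoffs its
*control-subtracted* intensity exceeds, which makes scoring invariant to
global intensity shifts. The primary contract takes absolute cutoffs; a
helper derives default cutoffs at 15/40/70% of the maximum
control-subtracted intensity on the plate for uncalibrated data. These two
are kept separate deliberately: percent-of-max cutoffs adapt to the
plate's dynamic range, while rank-aligned absolute cutoffs (e.g. at the
midpoints between rank signals) are what make planted profiles exactly
recoverable — the recovery guarantee holds when the noise standard
deviation is below half the smallest cutoff gap, with a safety margin for
the noisy control mean. Substrates with exactly one positive replicate are
false positives: their score is forced to 0 and they are excluded from
`S`. AWCD sums the control-subtracted substrate means floored at 0 over
all 31 substrates; H and J use the mean ranks of used substrates (ranks,
not raw intensities — the qualitative scale is the unit of observation
here). Plate photographs are read by averaging a centred disc per grid
position; the intensity-table entry point is primary and the image path
is a convenience.

## Clustering and db-RDA

Sample clustering uses Bray–Curtis dissimilarity (`Σ|x−y| / Σ(x+y)`; a
comparison of two all-zero profiles is defined as 1) with complete linkage
by default. Agglomeration is implemented natively (naive O(n³), fine at
heatmap scale) so that ties break deterministically on the
lexicographically smallest label pair — the merge sequence and leaf order
are then reproducible regardless of input order, which an off-the-shelf
linkage does not guarantee; on matrices with distinct entries it agrees
with scipy's linkage exactly (verified in tests).

db-RDA Gower-centres the squared sample distance matrix, extracts
principal coordinates (eigenvalues below a relative tolerance are
discarded; negative eigenvalues from non-Euclidean distances are
discarded with a warning), regresses the coordinates on the centred
constraints (collinear columns dropped by rank-revealing QR with a
warning) and eigen-decomposes the fitted values. Axis variances are
fractions of total inertia, so constrained plus unconstrained fractions
sum to 1 and the Euclidean case reduces exactly to classical RDA on the
centred response — a property the tests verify to 1e−8. Either direction
(utilisation profiles as response and function categories as constraints,
or the reverse) is a caller decision; the function is symmetric in its
interface.

## Co-occurrence network

**Metrics.** Pearson and Spearman correlation, mutual information,
Bray–Curtis dissimilarity and symmetrised Kullback–Leibler divergence are
computed between ZOTU profiles on the per-sample relative-abundance
matrix. KL uses a pseudocount of half the smallest nonzero relative
abundance and renormalises each profile to a distribution over samples,
making it scale-invariant. MI discretises each profile into
`b = max(2, ⌊√n_samples⌋)` equal-frequency bins (ordinal ranks, ties
broken by position). Constant profiles yield undefined correlations; the
score is recorded as missing for that metric rather than imputed.

**Candidates.** Per metric, the k most co-occurring and k most mutually
exclusive pairs are kept (dissimilarities invert the direction: small =
co-occurrence). MI contributes co-occurrence candidates only by default,
since low MI means absence of association rather than exclusion
(configurable). Ties break on the lexicographic pair id. Note that k at or
above the pair count makes every metric support both directions of every
pair — a degenerate setting; k should be small relative to the number of
pairs.

**Significance (ReBoot).** The null distribution permutes each ZOTU's
values independently across samples and then renormalises every sample to
unit sum, which destroys association while preserving the compositional
closure that induces spurious correlation. The stability distribution
bootstraps samples with replacement. The p-value is the two-sided Gaussian
tail of the bootstrap-mean score under a normal fit (mean, sd) to the
permutation null; a degenerate null (sd = 0) gives p = 1, and all
p-values are clamped below at 1/(n_iter+1), never 0. 100 iterations is
the default; fewer than 10 is rejected as unstable. The exact
permutation-to-p contract is isolated in one function so alternative
schemes can be swapped.

**Merging (Brown's method).** ψ = −2Σ ln pᵢ is referred to a scaled
chi-square c·χ²(f) with c = Var(ψ)/(2E[ψ]), f = 2E[ψ]²/Var(ψ) and
E[ψ] = 2k. Under the null each −2 ln pᵢ is χ²(2) with known variance 4,
so only the between-metric dependence needs estimating: per-metric pseudo
p-values are recomputed on the *shared* permutation replicates (rank-based,
two-sided), and their empirical correlation matrix is combined with the
known marginal variance, `Var(ψ) = 4·Σᵢⱼ ρᵢⱼ`. This keeps both limits
exact despite the discreteness of rank pseudo p-values: zero correlation
reduces to Fisher's method (c = 1, f = 2k) and perfectly duplicated
metrics collapse to the single-metric p (f = 2). Empirical covariance was
preferred over the classical polynomial approximation because the five
metrics here are far from jointly Gaussian.

**FDR and summary.** Merged p-values are corrected by Benjamini–Hochberg
(statsmodels) and edges kept at q ≤ 0.05. An edge's sign must be unanimous
across its supporting metrics (correlation sign; dissimilarity top =
positive, bottom = negative); conflicting edges are dropped and counted.
Nodes are attributed to the lake holding >90% of their reads. The
published attribution rule leaves shares in (70%, 90%] formally unstated;
they fall to N.A. here because assignment requires the strict >90% rule.
Per-lake positive/negative degrees count edge endpoints by sign; the
totals always equal twice the accepted edge count.

## Synthetic data

The community generator draws per-ZOTU base abundances log-normally
(σ default 1.0, the standard rank-abundance shape for microbial
communities), concentrates a target fraction (default 0.95) of each
lake-specific ZOTU's expected mass in its home lake, spreads shared ZOTUs
evenly, adds planted associations through a shared standard-normal latent
factor on the log scale (loading = strength; negative pairs load with
opposite sign), and draws counts multinomially at a fixed depth per
sample (2000 by default, matching the rarefaction depth, so generated
tables are already depth-uniform). Taxonomy strings are assembled from
one designated, mutually non-substring taxon fragment per rule group, so
the planted function memberships — including `add_group` closure — are
recovered exactly by annotation. The plate generator maps planted 0–3
ranks linearly to intensity (50 units/rank by default over a control
baseline of 20) with Gaussian noise, and can force a single replicate
positive to exercise the false-positive rule.

What the generators do **not** emulate: sequencing error and chimeras,
taxonomy misassignment, overdispersion beyond multinomial noise,
phylogenetic correlation between ZOTUs, partial pattern matches against
realistic taxonomies, time-resolved colour development on plates, and
uneven library sizes (depth is fixed per sample). Passing tests therefore
demonstrate correctness of the pipeline's accounting and statistics under
its stated model, not robustness to upstream artefacts of real surveys.

## Validation problem sizes

The self-validation harness (`polarfunc.validation`) uses 200 null
replicates of 15 ZOTUs × 10 samples for the false-edge rate (acceptance
bound: one-sided binomial 95% band around the nominal 5% per-edge rate)
and 30 replicates × 3 planted pairs over 16 samples for sensitivity
(denominator restricted to pairs whose realised abundance correlation is
at least 0.9; latent strength 3.0 realises r ≈ 0.95–0.999), both at 100
permutation/bootstrap iterations — sizes chosen so the whole panel runs
in about a minute on one CPU while leaving the binomial bounds meaningful.
With few samples the per-metric permutation null is coarse; the Gaussian
fit to the null smooths this, and the p-value floor keeps merged p-values
honest.

## Known limitations

* Wildcard matching is substring-based; it does not implement rank-aware
  semantics (e.g. a genus pattern also matches an identically named
  family segment).
* The ReBoot p-value contract (Gaussian null, bootstrap-mean statistic)
  is one reasonable choice among several; it is isolated behind a single
  function for that reason.
* db-RDA reports no axis significance tests (none are computed anywhere
  in the pipeline).
* With one sample per lake, network metrics operate across lakes only;
  within-lake replication is required for within-lake association claims.
* Chao1 on function categories estimates category richness under the
  same abundance-sampling assumptions as for species; categories are not
  exchangeable species, so it is a comparative index here, not a census
  estimate.
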