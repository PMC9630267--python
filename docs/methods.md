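# Methods

`xprio` implements a disease-gene prioritization pipeline of the kind used
to nominate candidate disorder genes on the human X chromosome: genes with
known monogenic-disorder associations are contrasted with genes never
associated with disease, first through univariate decile-enrichment
thresholds on constraint and conservation metrics, then through a
supervised classifier ensemble over a wide per-gene feature table.  All
stages run end-to-end on a synthetic gene universe with planted class
structure, so every quantitative behaviour of the pipeline is testable
without access to the licensed or versioned resources (OMIM, gnomAD, GTEx,
BrainSpan, HGMD, DECIPHER) that a real analysis would consume.

## Gene universe and pre-classification

Genes carry a disorder class — `confirmed` (established monogenic
disorder), `PMT` (provisional / susceptibility / trait associations) or
`no_disorder` — plus a brain-disorder flag (not applicable to no-disorder
genes) and a flag for tolerance to homozygous loss-of-function (LoF)
variants, which is an *input* (in real data it comes from population
sequencing, e.g. the list of genes with at least one homozygous LoF
carrier), never recomputed here.  Crossing the three axes yields ten
subgroups; two of them form the supervised training classes:

* **Cbi** — confirmed brain-disorder genes intolerant of homozygous LoF
  (positives, value 1.0);
* **NDt** — no-disorder genes tolerant of homozygous LoF, "dispensable"
  genes (negatives, value 0.0).

Phenotype flags (intellectual disability, seizures, language, motor,
spasticity, ataxia) are derived from free-text clinical-synopsis sections
by case-insensitive substring matching against editable phrase lists
(`xprio/data/phenotype_terms.yaml`).  There is no negation parsing — "no
seizures reported" sets the seizures flag — a deliberate mirror of
free-text database searches, documented as a limitation.

Canonical transcripts follow the standard priority: MANE Select first,
else the longest APPRIS-annotated transcript (length ties broken
lexicographically on transcript id), else the only transcript; anything
else is an error rather than a silent guess.  Close paralogues are genes
with at least one paralogue hit whose target-identity and query-identity
percentages both exceed the 95th percentile of the respective
distributions over all hits (percentiles use linear interpolation between
order statistics, so thresholds are exactly reproducible).

X-inactivation consensus takes per-study calls (escape / non-escape /
variable) and assigns one of seven categories.  The source literature
describes the categories qualitatively; the exact vote margins are this
package's choices: fewer than 2 studies → `not_available`; "variable"
strictly modal → `variable`; equal escape and non-escape counts →
`discordant`; a winner supported by all or all-but-one studies →
high-confidence, by a strict plurality → low-confidence.

## The 83-column feature table

Features come in six groups with fixed sizes — constraint (35),
conservation (2), adult expression (19), developmental brain expression
(16), gene structure (4), chromosomal position (2), paralogy (5) — and the
concrete column names ship as an editable YAML schema
(`xprio/data/feature_schema.yaml`).  Constraint metrics are taken per gene
from the transcript with the lowest LOEUF.  Notable definitions:

* **tau** (tissue specificity): after collapsing brain regions into a
  cerebellar and an other-brain metavalue (medians), per-tissue values are
  transformed to log2(TPM+1), normalized by the maximum, and
  τ = Σ(1−x_i)/(N−1).  τ=0 means uniform expression, τ=1 single-tissue;
  τ<0.6 is conventionally "broadly expressed".  τ is undefined (masked)
  for unexpressed genes.  `tau_1`/`tau_2` are the female/male versions.
* **Promoter CpG density**: observed/expected ratio
  #CpG / (#C · #G) · N over the ±2 kb window around the TSS, with CpG
  counted by a sliding one-base scan; undefined when C or G is absent.
* **Conservation scores**: unweighted mean of per-base phastCons-style
  scores over the coding sequence (exon score) or the 4 kb promoter
  window.  Bases missing from the track are excluded from both numerator
  and denominator — missing track data is not evidence of
  non-conservation.
* **Positional features**: distances from the TSS to the nearest
  centromere boundary and to the telomere of the TSS's arm.
* Developmental expression uses three age groups (prenatal; postnatal up
  to and including 4 years; older than 4 years) plus the pooled postnatal
  group, each stratified by sex; RPKM inputs are converted to TPM
  (TPM_g = RPKM_g/ΣRPKM · 10⁶) before aggregation.  Mean/variance
  features are computed on raw TPM; the log2 transform is used only
  inside tau.

Coordinates are 0-based half-open throughout.  Missing values are recorded
in an explicit mask and never imputed during assembly; imputation happens
only inside the ML preprocessing, where it can be fit on training genes
alone.

## Statistics

* Fisher tests are two-sided exact (sum of fixed-margin table
  probabilities no larger than the observed table's).  The reported odds
  ratio is the unconditional sample OR (a·d)/(b·c); when any cell is zero,
  10⁻⁴ is added to every cell before forming the OR that enters the log2
  transform, keeping it finite.  The conditional MLE is also exposed.
* Multiple testing is Bonferroni with an explicit `n_tests` argument; the
  caller owns the family definition (the pipeline default for decile
  enrichment is 30 = 10 deciles × 3 metrics).
* Decile boundaries are the 10%–90% quantiles (linear interpolation);
  genes bin into right-closed intervals, so a value equal to a boundary
  falls in the lower decile.  Decile enrichment is therefore invariant
  under strictly monotone transforms of the metric.
* Mann-Whitney U burden tests are two-sided; exact for tie-free samples of
  at most 50 per group, otherwise the normal approximation with tie
  correction.
* The domain test is the upper-tail exact binomial P(X ≥ k) with success
  probability = pooled domain length / pooled protein length.

## LME thresholds

For each of LOEUF (low extreme), missense-Z and exon conservation (high
extremes), the threshold is the outer boundary of the maximal *contiguous*
run of enriched deciles starting at the metric's informative extreme, so
every threshold equals a pooled decile boundary by construction.
Whether the source procedure required contiguity is not stated;
contiguity-from-the-extreme is this package's rule.  If no extreme decile
is enriched the criterion is disabled (with a warning when enrichment
exists elsewhere).  Comparisons at the threshold are inclusive (≤ for
LOEUF, ≥ for the others).  A gene's LME status counts satisfied criteria;
the "at least `min_criteria`" cut defaults to 1.  Euler-style subset
counts are emitted per disorder class.

## Classifier tournament, calibration, FDR threshold

Features are min-max normalized to [0,1] with statistics from the training
genes only; values outside the training range clip, constant features map
to 0.5 (warned), and missing cells are imputed with the training median.

Nested cross-validation uses stratified outer 10-fold / inner 5-fold
splits (stratification is this package's choice, protecting the minority
class) with hyperparameters selected by mean inner MCC; the search is a
grid when the finite grid has ≤ 100 combinations and random with 100
draws otherwise.  MCC is the tournament score because its chance level is
0 regardless of class imbalance.  The default registry holds the five
tournament-winning families — adaptive boosting, bootstrap-aggregated
trees, linear max-margin, multilayer perceptron, random forest — plus a
constant-baseline control; the tournament structure, not a specific list
of families, is the method, and the registry is configurable.

The top five families by mean outer MCC (ties: lower MCC standard
deviation, then name) are refit on all training data.  Families that emit
decision scores rather than probabilities (the linear max-margin model)
are wrapped in 5-fold cross-validated sigmoid calibration; a family that
can emit neither is excluded with a warning and the next-ranked family
promoted.  Per-gene probabilities for training genes come from this
refit-on-all model (not from held-out folds) — flagged here because the
alternative (fold-wise out-of-sample probabilities) is defensible too.

The FDR threshold t for a target rate d scans the distinct training
scores of the positive class B in decreasing order, with positives
defined as score ≥ t, and returns the smallest candidate for which the
running fraction of known-negative genes D among positives stays below d
at it and at every larger candidate.  Candidates are restricted to B
scores because a threshold strictly between two B scores admits only
extra negatives without gaining sensitivity.  If even the single top
score violates the bound, the scan returns an explicit failure result and
no gene can satisfy the mean-probability condition.  The default
prediction rule is the conjunction: all five per-classifier probabilities
> 0.5 *and* mean probability > t; the disjunction of the two conditions
is available as a config switch.

Feature importance is the mean MCC drop over random permutations of each
feature column, scored through the ensemble's mean probability at the 0.5
cut; reproducible from its seed.

## Synthetic data: what it emulates and what it does not

The generator plants per-class distributions for all 83 features
(normal for Z-scores, beta for bounded scores, log-normal for
expression-like and length-like quantities, Poisson for counts) and
realizes raw data consistent with them: promoter sequences from a
first-order Markov chain whose C→G transition is scaled to the requested
CpG observed/expected ratio (with the G marginal compensated so GC
content stays on target); a piecewise-constant conservation track whose
run means follow the planted exon/promoter conservation; expression
samples across 18 adult tissues × 2 sexes plus 3 developmental age
groups, with breadth driven by the planted tau target; per-transcript
constraint tables where the canonical transcript carries the gene-level
values and secondary transcripts get higher LOEUF; paralogue hits,
variant tables, protein-domain and database-membership tables with
class-dependent rates.  Defaults encode the study conditions: class
proportions ≈ 0.25 / 0.03 / 0.72 (confirmed / PMT / no-disorder, the
chromosome-X census), disorder genes with lower LOEUF, higher misZ,
higher conservation, broader and brain-shifted expression, denser CpG
promoters, fewer close paralogues and higher curated-variant rates, with
PMT intermediate throughout.

A fast direct-draw path (`generate_feature_table`) samples the 83 columns
straight from the planted distributions for studies of the enrichment and
ML stages.  Truth labels are written separately (`truth.json`) so stages
can run blind.

Deliberately *not* emulated: realistic human sequence composition,
linkage or correlation structure between genes (features are drawn
independently given the class, so real-data collinearity among constraint
metrics is absent), raw reads or genotypes, and real chromosome
geometry (scaled-down constant chromosome lengths, default 2 Mb with a
200 kb centromere).  Passing tests therefore demonstrate that the
*procedures* are correct and well calibrated under known ground truth —
not that any particular real gene list would be reproduced.

## Numerical choices and degenerate inputs

* Quantiles and percentiles: linear interpolation between order
  statistics, everywhere.
* Ties at decile boundaries go to the lower decile (right-closed bins).
* log2-OR pseudo-count: 10⁻⁴ added to every cell only when some cell is
  zero.
* Empty universe (`n_genes=0`) yields empty tables without error;
  all-zero expression samples, single-transcript genes without
  annotations, empty paralogue tables and empty database maps all have
  defined behaviour (error, pass-through, or skip-with-notice as
  documented per function).
* Determinism: one `numpy` Generator per run seeds everything, including
  fold assignment, model seeds and calibration splits; identical
  configurations reproduce byte-identical written outputs.

## Problem sizes used by the test suite

The suite exercises the pipeline at sizes chosen to make the statistical
contracts sharp while staying desk-scale: 2,000-gene balanced tables
(baseline MCC), 5,000 genes × 100 simulations (threshold recovery),
5,000 genes × 20 seeds with a 50/50 train/holdout split of the known
classes (FDR and sensitivity contracts — the threshold is estimated on
the training half and evaluated on the held-out half, since evaluating on
the estimation set would make the bound true by construction), 10,000
genes × 100 simulations (decile-enrichment null), and five label
permutations of a 600-gene table (chance-level MCC for every family).
The end-to-end determinism check runs the full pipeline twice at 250
genes with the light registry.

## Known limitations

* Phenotype flagging has no negation or section parsing.
* The feature schema's exact column composition beyond the named metrics
  is a design choice aligned to the stated group sizes, shipped as config.
* The registry's hyperparameter grids are small by design; the tournament
  is structural, not an exhaustive reproduction of any particular 25-model
  sweep.
* PAR genes are retained in all computations and flagged, rather than
  excluded.
* Real-data headline numbers (gene counts, exact thresholds such as
  LOEUF ≤ 0.326) depend on resource snapshots and are out of scope; the
  package reproduces the procedures and their statistical behaviour.
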