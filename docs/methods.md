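# Methods

## Differential effects

Each case-control comparison arrives as a genes × samples matrix already
on the log2 scale (microarray intensities, RNA-seq expression estimates,
or SWATH-MS abundances are treated identically downstream). The effect of
record is the log2 fold change `lfc = mean(case) − mean(control)` with a
two-sided Welch unequal-variance t-test p-value. Welch was chosen because
the pooled cohorts mix platforms and have strongly unequal arm sizes (3 v 3
up to 110 v 31), and it needs no equal-variance assumption; the test
function is a plain `case, control → p` callable, so moderated or
rank-based alternatives can be slotted in. Genes with zero variance in
both arms get `p = 1` and the lfc as computed: with no spread there is no
evidence either way, and NaNs would poison downstream sign counting. No
multiple-testing correction is applied at this stage — consumers
(consistency percentages, candidate tables) are defined on raw
per-comparison p-values.

## Grouping, consistency and candidate selection

Comparisons partition into six meta-analysis groups by subtype, tissue
class and modality: CNS-fALS (5 comparisons), CNS-sALS (7), and the four
diMN groups (one comparison each). Directional consistency of a gene in a
group is `100 × #{lfc > 0} / n` (strict inequality; `lfc = 0` counts
toward neither direction), rounded **half-up** to a whole percent — the
half-up rule is what maps 6/7 to 86 rather than 85.

The metascore aggregates heterogeneous score families (omics, text,
finance, key-opinion-leader) as a nonnegative-weighted mean of per-family
rank-normalized scores (average ranks for ties, scaled to (0, 1]).
Rank-normalization makes families on arbitrary scales commensurable; the
aggregation sits behind one function so a different scheme is a one-line
swap. Ranking ties break lexicographically by gene id for determinism.
The omics family score of a gene in a group is the mean over the group's
comparisons of `sign(lfc) · (−log10 p)` — a signed evidence measure that
rewards consistent, well-supported shifts; p-values are floored at 1e-300
before the log.

The filter cascade is order-preserving: optional requirements for a
druggable class and an existing small-molecule association, exclusion of
essential genes, and (in novel mode) a minimum novelty level, followed by
a top-k cut (default 50). Novel mode restricts the enabled score families
to omics alone, mirroring a no-prior-knowledge setting. A candidate must
appear in at least one group's filtered top list; CNS candidates must
additionally reach ≥ 80% consistency (after rounding) in one direction
for fALS, sALS or both, while diMN candidates carry their group's lfc and
p-value directly.

## Time-machine validation

A chronology of (gene, first clinical-trial year) is split at a cutoff
year; the year equal to the cutoff counts as training-side ("after the
given year" is read strictly). For a ranking of N genes containing
`targets_N` evaluated targets, of which `targets_k` land in the top-k:

- `ELFC = log2((targets_k / k) · (N / targets_N))`, with 0.1 substituted
  when `targets_k = 0` so the logarithm stays finite. The substitution
  applies to ELFC only.
- `HGPV = −log10 P(X > targets_k)`, X ~ Hypergeometric(N, targets_N, k),
  i.e. one minus the CDF at the observed count. A tail of exactly zero
  (the count sits at the top of its support) is clamped to 300 by default
  rather than reported as infinity.

The strict tail excludes the observed count and is therefore not a
calibrated p-value: whenever the discrete survival-function jump straddles
a level α, the exceedance rate under random rankings overshoots α by
construction. The inclusive variant `P(X ≥ targets_k)` is available via
`hgpv(..., inclusive=True)` and carries the usual `P(p ≤ α) ≤ α`
guarantee; the calibration test in the suite exercises it. Both metric
functions are label-agnostic — the caller decides which target set
(post-cutoff entrants or anything else) is evaluated.

## Pathway dysregulation

The activation scorer is a deliberately simple, documented stand-in for
topology-aware pathway activation scoring: a weighted mean of member-gene
lfc values, with optional per-gene topology weights (uniform by default)
and a soft significance gate — genes with `p ≥ 0.05` keep half their
weight rather than being dropped, which keeps small pathways stable. The
scorer is pluggable: the calling stage consumes any
(pathway × comparison) table of signed scores.

A pathway is called dysregulated in a group when (1) its score sign
agrees in ≥ 80% of the group's comparisons — fractions compared exactly,
so 7 comparisons need 6; zero scores count toward neither direction — and
(2) its absolute score reaches 0.01 in at least one comparison of the
group (the magnitude clause is read as a max over comparisons, which also
covers mixed-sign corner cases).

Process-level enrichment uses the hypergeometric formula in its printed
index convention: `p = 1 − Σ_{i=0}^{r−1} C(K, i) C(N−K, n−i) / C(N, n)`
with N total pathways, K dysregulated pathways in the process, n total
dysregulated pathways and r pathways in the process. Note the roles of K
and r are swapped relative to the conventional orientation (population
successes r, observed overlap K); the conventional tail `P(X ≥ K)` for
X ~ HG(N, r, n) is available behind `orientation="conventional"`.
Impossible binomial terms contribute zero, and raw p-values are Bonferroni
multiplied by the number of processes tested (27 in the bundled
Reactome-style hierarchy), capped at 1.

The similarity network connects called pathways whose gene-content
similarity strictly exceeds 0.35. The default coefficient is Jaccard; the
EnrichmentMap-style combined coefficient ½(Jaccard + overlap) is a config
option, since published network figures built with that tool family can
use either. Reported clusters are connected components with more than
three pathways.

## Modifier-screen scoring

Eye-degeneration modification under RNAi is graded on integers −4 … 2
(negative = rescue, positive = enhancement). An ortholog's score is the
arithmetic mean over scored offspring — half-scores such as −3.5 encode an
offspring split between −4 and −3; lethal crosses yield no score and are
never imputed. Classification boundaries are inclusive: ≤ −3 strong
rescue, ≤ −2 moderate, ≤ −1 mild, (−1, 1) no effect, ≥ 1 mild
enhancement, ≥ 2 moderate enhancement — the inclusive reading is the only
one consistent with every interpretation cell in the bundled screen
table (e.g. −2.5 is moderate). A gene with several orthologs is
represented by the score of maximal absolute value, with ties broken
toward rescue; that convention is flagged in the aggregation code because
mixed-sign ties do not occur in the bundled table.

## Synthetic studies

The generator reproduces the shape of the study design: 12 CNS
comparisons (5 fALS, 7 sALS) and 4 diMN comparisons with the published
per-comparison arm sizes, group labels, and modalities. Expression is
additive on the log2 scale: a per-gene baseline N(8, 1.5²) shared across
comparisons, plus Gaussian noise with modality-specific defaults (0.5 for
microarray/RNA-seq, 0.6 for SWATH-MS — proteomic abundances are treated
identically downstream, just noisier), plus planted signal. A planted
target shifts its case arm by ±effect in each comparison independently
with probability `penetrance`; a planted pathway shifts all its member
genes coherently by ±magnitude in every comparison. External score
families (text/finance/KOL) are unit-normal with a +2 boost for planted
targets, and planted targets are guaranteed druggable, small-molecule
associated, non-essential and maximally novel, so recovery tests measure
the statistics rather than annotation luck. Generation is a pure function
of the config (one seeded generator consumed in fixed order), giving
byte-identical bundles per seed.

What the generator does **not** emulate: batch and platform effects,
gene-gene correlation outside planted pathways, count-level noise
(everything is already normalized log2), missing values, and shared
controls between comparisons. Passing recovery tests therefore show the
pipeline recovers planted structure under its own model assumptions, not
that it is robust to real-data artifacts.

Recovery checks use deliberately chosen, fixed conditions: the
planted-target check runs on a CNS-like group of five 10 v 10 comparisons
with effect 1.5 log2 units at full penetrance among 2000 genes; the
planted-pathway check runs on the design's best-powered arm (the diMN
sALS comparison, 110 v 31) with five 50-gene pathways at magnitude 0.05 —
on a 3 v 3 arm a 0.05 shift is below any scorer's noise floor, so the
group with real power carries the check. Problem sizes in the test suite
(hundreds to a few thousand genes, tens of permutation replicates) are
chosen to exercise every code path at desk scale.

## Numerical choices and limitations

- Consistency rounds half-up via `floor(x + 0.5)`; Python's banker's
  rounding would break the 6/7 → 86 contract.
- Hypergeometric tails come from `scipy.stats.hypergeom`; the
  process-enrichment formula is evaluated with exact integer binomials
  (`math.comb`) so small-count results are exact. Both are cross-checked
  against exhaustive subset enumeration for all population sizes ≤ 12.
- The pipeline seed fans out to per-stage seeds by SHA-256 hashing, so
  stages are decoupled and all derived seeds stay below 2³¹.
- The published enrichment p-values for real cohort data depend on the
  proprietary pathway scorer and the full pathway database and are not
  recomputable here; the bundled hierarchy is a 27-process Reactome-style
  stand-in, and the activation scorer is a stand-in by design.
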