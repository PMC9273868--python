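# targetscout

Tooling for multi-cohort therapeutic-target prioritization in amyotrophic
lateral sclerosis (ALS), aimed at computational biologists who want the
analysis layer of an AI-assisted target-discovery workflow as an open,
testable library rather than a platform black box.

ALS case-control expression cohorts are heterogeneous: post-mortem CNS
tissue (microarray and RNA-seq) and patient-derived motor-neuron (diMN)
cultures profiled transcriptomically and proteomically, split into familial
(fALS) and sporadic (sALS) subtypes. targetscout implements the statistics
that turn those cohorts into ranked, filtered target lists, and the
validation machinery around them:

- **Differential effects** — per comparison, each gene gets a log2 fold
  change (LFC, case − control) and a Welch two-sample p-value.
- **Meta-analysis grouping and directional consistency** — comparisons pool
  into six groups (CNS fALS/sALS; diMN transcriptomic/proteomic ×
  fALS/sALS). A gene's consistency is the percentage of a group's
  comparisons with LFC > 0 (or < 0), rounded half-up: 6 of 7 → 86%.
  CNS candidates must reach ≥ 80% in one direction and sit in a group's
  top-50 metascore list after a druggability/novelty filter cascade.
- **Time-machine validation** — split a target chronology at a cutoff year
  and score any ranking's top-*k* enrichment for post-cutoff trial entrants:
  `ELFC = log2((targets_k / k) · (N / targets_N))` (0.1 substituted for a
  zero count) and `HGPV = −log10 P(X > targets_k)` for
  X ~ Hypergeometric(N, targets_N, k).
- **Pathway dysregulation** — signed pathway activation scores (a
  documented weighted-mean stand-in behind a pluggable interface), the
  80%-unidirectional / 0.01-magnitude calling rule, process-level
  hypergeometric enrichment with Bonferroni correction over 27 top-level
  processes, and a gene-set similarity network (coefficient > 0.35) whose
  connected components of more than three pathways are reported.
- **Modifier-screen scoring** — the Drosophila eye-degeneration scale
  (−4 strongest rescue … 2 strongest enhancement), offspring-mean ortholog
  scores, best-ortholog gene representation and category bookkeeping.
- **Synthetic studies** — a seeded generator that reproduces the study
  design's shape (12 CNS + 4 diMN comparisons with the published arm
  sizes) with planted targets and pathways, so every stage is testable
  without access to any cohort data. Transcriptions of the published
  design, candidate and screen tables ship as plain-TSV fixtures.

## Worked example

```python
from targetscout import fly_screen as fs, target_prioritization as tp
from targetscout import time_machine as tm

# Directional consistency, as reported in candidate tables
tp.consistency([0.4, 1.2, 0.1, 0.8, -0.2], "up")         # -> 80
tp.consistency([0.4, 1.2, 0.1, 0.8, 0.3, 0.9, -0.2], "up")  # -> 86

# Time-machine metrics for a ranking with 5 of 50 targets in its top 10
c = tm.EnrichmentCounts(targets_k=5, k=10, targets_N=50, N=1000)
tm.elfc(c)   # -> 3.3219...  (10-fold enrichment over background)
tm.hgpv(c)   # -> 5.6800...  (tail probability ~2e-6)

# Screen summary over the bundled modifier-screen table
fs.summarize(fs.load_screen_table())["n_strong_or_moderate_rescue"]  # -> 18
```

A full synthetic run (generate → effects → prioritize → validate →
pathways → screen) is one command; the manifest records checksums so the
same seed reproduces identical bytes:

```
targetscout run-all --seed 1 --out scratch/demo
targetscout report --manifest scratch/demo/run_manifest.json --out scratch/demo/report
```

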