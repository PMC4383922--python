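# Methods

## Overview

`mirfunc` implements two file-based procedures for microRNA annotation:

1. **Functional-miRNA classification** (`mirfunc.funcmir`): every precursor
   miRNA is scored on four independent evidence criteria; the criterion
   scores sum to a composite, and a composite of 3 or higher classifies the
   precursor as functional. For each precursor the dominantly expressed
   mature arm is selected, optionally with a secondary arm.
2. **Seed-complementarity target scanning** (`mirfunc.seedscan`): user
   miRNA or target sequences are screened for perfect 7-mer seed matches,
   and matching pairs are ranked on a 50–100 presentation scale.

Both operate entirely offline on miRBase-style FASTA, tab-delimited tables
and plain-text lists (`mirfunc.mirbase_io`).

## Scoring model

| criterion     | raw input                                   | brackets → score                |
|---------------|---------------------------------------------|---------------------------------|
| PubMed        | # distinct PubMed records for the precursor | 2→1, 3→2, ≥4→3                  |
| conservation  | # other species with a 5′-prefix ortholog   | 1→1, ≥2→2                       |
| expression    | pooled abundance, reads per million (RPM)   | 1–10 (inclusive)→1, >10→2       |
| miRBase       | High Confidence flag                        | flagged→1                       |

composite = sum of the four (0–8); functional ⇔ composite ≥ 3.

Interpretive choices where the published rules leave room:

* **Sub-bracket inputs score 0** (one PubMed record, no orthologs,
  RPM < 1): only positive brackets are defined, so 0 is the complement.
* **The 1–10 RPM bracket is inclusive on both ends** and the upper bracket
  strict (>10); a literal reading of "1–10 … over 10".
* **Orthology** of two matures requires an identical 5′ prefix of
  `min(19, len_a, len_b)` nt. The 19-nt rule reflects post-transcriptional
  3′-end variability; for matures shorter than 19 nt the comparison degrades
  gracefully and stays symmetric. A mature's own species never counts.
* **RPM aggregation across experiments is pooled**:
  `1e6 · Σ_j counts_j / Σ_j library_size_j`. Pooling is robust to shallow
  libraries; a mean-of-per-experiment-RPM alternative is selectable via
  `ScoringParams(rpm_aggregation="mean")`.
* **Granularity**: PubMed counts and the High Confidence flag attach to the
  precursor (gene-level, matching the NCBI Gene→PubMed mapping);
  conservation and expression are the maximum over the precursor's mature
  arms. "Independent studies" is operationalized as distinct PubMed IDs —
  the association files carry no study-independence metadata.

### Mature-arm selection

The dominant arm is the one with the highest pooled RPM; ties prefer the 5p
arm, then the lexicographically smaller identifier (the published procedure
is silent on ties; a deterministic rule is required for reproducible
output). A secondary arm is reported — only for functional precursors — iff
its RPM is no less than 10% of the dominant arm's AND no less than 5 RPM;
both bounds inclusive ("no less than").

### Criterion-contribution analysis

A criterion is *required* for a functional call iff removing its score drops
the composite below the threshold. Non-functional precursors have no
required criteria. `n_supporting_criteria` counts criteria with a strictly
positive score.

## Target scanning

* **Input bounds**: miRNA submissions 17–30 nt, target submissions
  100–30 000 nt, both inclusive. Sequences are whitespace-stripped,
  case-folded and T→U transcribed before validation; anything outside
  {A,C,G,U,T} is rejected with its position.
* **Seed**: miRNA positions 2–8 (1-based; the standard 7-mer convention —
  configurable via `ScanParams`). The target sense strand is searched for
  perfect Watson–Crick complements of the seed; no wobble pairs, overlaps
  allowed, coordinates 0-based half-open internally and 1-based inclusive in
  reports.
* **Surrogate score**: targets/miRNAs with ≥1 site get

  `score = min(100, 50 + round(30·(1 − 2^−(n−1)) + 20·min(1, 7n/L)))`

  with `n` the site count and `L` the target length — a saturating
  count term plus a small coverage-density term, clamped to the conventional
  50–100 presentation range. It is monotone in site count at fixed length
  and in density; one site on a long target sits at the floor (50). This is
  an explicit presentation-scale surrogate for counting seed evidence; it is
  **not** a trained target-prediction model, carries no free-energy,
  conservation or context features, and result tables label it
  `surrogate_score`.
* **Ranking**: rows sort by descending score; ties break by ascending
  target ID (miRNA mode) or miRNA name (target mode), making output
  invariant to input file order.

## Synthetic fixtures

`mirfunc.synthetic_fixtures.generate` writes every input dialect the
pipeline reads, from a single RNG seed (byte-identical re-runs). Default
conditions, chosen once to emulate a realistic five-species miRNome:

* 40 miRNA families over hsa/mmu/rno/cfa/gga; 20% of families are shared
  across ≥2 species with identical 5′ 19-mers and divergent 3′ tails
  (real miRNomes have a conserved minority); 75% of precursors express both
  arms.
* 81 expression experiments (the size of the public small-RNA-seq compendium
  the expression criterion draws on), library sizes 0.5–2 million reads,
  counts negative-binomial with dispersion 5 around per-arm mean abundances
  drawn log-uniformly from 0.01–60 RPM — overdispersed, mostly-low
  abundances spanning all three expression brackets.
* Zero-inflated literature evidence (55% of precursors unreferenced,
  positives 1 + Poisson(1.5)) and a 15% high-confidence fraction,
  approximating the published evidence-tier proportions in which roughly
  one-third of entries end up functional.
* 25 UTRs of 300–3000 nt with 2 planted seed-complementary sites each, at
  recorded coordinates. Incidental (unplanted) seed matches are allowed and
  reconciled against a naive all-window oracle rather than suppressed —
  suppression would bias sequence composition.

What the generator does **not** emulate: real miRBase sequence content and
naming history, hairpin secondary structure, correlated expression across
tissues, citation-count heavy tails, and UTR compositional bias (GC content,
repeats). Passing the recovery tests therefore demonstrates that the
pipeline applies the scoring and scanning rules exactly as specified on
inputs with the stated statistical shape — not that the rules themselves
generalize to any particular real miRNome snapshot.

### Ground-truth oracle

Ground truth is computed by `oracle_scores`, a deliberately independent
straight-line re-implementation: it re-parses the written files with plain
string code and applies the bracket rules as literal `if/elif` chains,
sharing no code with the pipeline. Pipeline-vs-oracle agreement is asserted
to be exact (the procedure is deterministic, so recovery is 100% or a bug).
Planted-site coordinates are generation knowledge and are recorded at
planting time.

## Numerical and degenerate-input choices

* All counts are integers; RPM values are IEEE doubles computed as
  `1e6·total/total_library` in both pipeline and oracle, so equality
  comparisons at bracket boundaries are exact.
* Missing library sizes default to per-experiment column sums (logged
  warning); an all-zero toy column gets size 1 so RPM stays defined.
* A mature absent from the count table has 0 RPM; an empty high-confidence
  list or PubMed map simply scores 0 on those criteria.
* A precursor with no linked mature arms is a validation error, as is a
  hairpin shorter than a mature it hosts, a duplicate precursor name or
  transcript ID, a negative/fractional count (reported with cell
  coordinates), and a non-positive PubMed ID.
* Test-suite problem sizes: property sweeps use compact fixture specs
  (8 families, 10 experiments, 4 UTRs) across 20 varied parameterizations,
  plus the full default conditions for the end-to-end recovery gate; the
  seed-scan oracle sweep covers 1000 random miRNA/target pairs including
  low-entropy alphabets that provoke overlapping matches.

## Known limitations

* The surrogate score ranks by seed-match evidence only; it must not be
  read as a probability of repression or compared across scanners.
* Orthology by exact 5′-prefix identity finds only very close orthologs; a
  single 5′ SNV breaks it (by design — it mirrors the published rule).
* The precursor↔mature join uses name stems; pathological naming (matures
  whose stem matches several unrelated precursors) would attach them to all,
  as real multi-locus families do.
* No attempt is made to reproduce snapshot-dependent genome-wide counts;
  those depend on specific miRBase/PubMed/RNA-seq releases.
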