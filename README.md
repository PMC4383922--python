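# mirfunc

Offline toolkit for two recurring microRNA-annotation tasks:

* **Which miRBase entries are real, functional miRNAs?** Many deposited
  miRNAs are unlikely to play regulatory roles or are false discoveries from
  high-throughput studies. `mirfunc` scores every precursor miRNA on four
  independent evidence criteria — literature support, cross-species
  conservation, expression level and miRBase High Confidence status — and
  classifies it by the composite score.
* **Where could a miRNA bind?** A seed-match scanner screens user miRNA or
  target sequences for perfect 7-mer seed complementarity and returns ranked
  site tables.

It is written for computational biologists who need these procedures
reproducible and scriptable: plain FASTA/TSV in, TSV out, deterministic
everywhere, no network access.

## The scoring model

For each precursor miRNA with associated evidence:

* **PubMed score** — distinct associated PubMed records *n*:
  score 1 for *n* = 2, 2 for *n* = 3, 3 for *n* ≥ 4.
* **Conservation score** — number of other species carrying an ortholog
  (identical 5′-end 19 nt of a mature arm; 3′ ends are ignored as
  post-transcriptionally variable): 1 for one species, 2 for two or more.
* **Expression score** — pooled abundance across RNA-seq experiments,
  RPM = 10⁶·Σcounts/Σlibrary sizes: 1 for 1–10 RPM, 2 for >10 RPM.
* **miRBase score** — 1 if flagged High Confidence.

The composite is the sum (0–8); **composite ≥ 3 ⇒ functional**. For each
precursor the dominantly expressed mature arm is selected, plus a secondary
arm if its expression is ≥10% of the dominant arm's and ≥5 RPM. A removal
analysis reports which criteria each functional call *requires*.

The scanner extracts the miRNA seed (positions 2–8), reverse-complements it
and reports every perfect match on the target sense strand; pairs with ≥1
site get an explicit surrogate score on the conventional 50–100 scale
(monotone in site count and density — see `docs/methods.md`; it is not a
trained target-prediction model).

## Worked example

```sh
$ mirfunc fixtures --outdir demo --seed 21          # synthetic inputs + truth
$ mirfunc annotate --matures demo/mature.fa --hairpins demo/hairpin.fa \
    --counts demo/counts.tsv --pubmed demo/mirna2pubmed.tsv \
    --highconf demo/high_confidence.txt --out demo/annotation.tsv
```

or from Python (`examples/annotate_functional_mirnas.py`):

```text
57 precursors scored; 24 classified functional
name                 scores(P,C,E,M)  composite  functional  dominant arm
cfa-mir-s001         (3,0,0,0)            3        True       MIMAT0000001
mmu-mir-s003         (0,2,2,0)            4        True       MIMAT0000003
cfa-mir-s003         (0,2,0,0)            2        False      MIMAT0000004
```

`cfa-mir-s001` is called functional purely on literature evidence (≥4
PubMed records, score 3 = threshold); `cfa-mir-s003` is conserved in two
or more species (score 2) but nothing else, so its composite of 2 falls
short. Scanning (`examples/scan_custom_mirna.py`):

```text
query hsa-miR-s030-3p, seed (positions 2-8): UCGGCGG
9 of 25 UTRs carry at least one seed site
rank  score  target     gene     sites (1-based)
   1     65  NM_900014  GENE15   975-981;1106-1112
   4     50  NM_900000  GENE1    879-885
```

Two seed-complementary sites rank NM_900014 (score 65) above single-site
UTRs at the 50 floor; positions are 1-based inclusive coordinates of the
seed's reverse complement.

The `examples/` directory holds one short narrative script per capability:
annotation, both scan modes, and fixture generation.

## Layout

```
src/mirfunc/
  mirbase_io.py          readers/writers: FASTA, count tables, PubMed maps,
                         ID lists, result TSVs
  funcmir.py             criterion scores, composite classification,
                         arm selection, contribution analysis
  seedscan.py            validation, seed extraction, site finding, ranking
  synthetic_fixtures.py  seeded fixture generator + independent scoring oracle
  cli.py                 `mirfunc annotate | scan | fixtures`
docs/methods.md          model details, parameter defaults, design choices
examples/                narrative scripts, one per capability
```
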