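# savmir

A small-RNA profiling toolkit for two-condition (winged vs wingless morph)
miRNA studies. It implements the full analysis chain as reusable, tested
modules:

| module | what it does |
|---|---|
| `savmir.synthio` | ground-truthed synthetic references (genome, hairpin precursors, matures, ncRNA/repeat decoys) and two-condition FASTQ libraries with known per-miRNA fold changes |
| `savmir.readproc` | 3' adapter trimming, length / mean-quality / composition filters with an exact removal ledger, tag collapsing, library summaries |
| `savmir.annot` | ≤1-mismatch ungapped mapping, decoy subtraction, conserved / semi-conserved / novel classification, seed families, single-hairpin MFE folding and precursor validation |
| `savmir.diffexp` | library-size normalization, magnitude fold change + signed log2FC, per-miRNA 2×2 Pearson chi-squared on raw counts, Bonferroni correction, DE calling at FC ≥ 1.5 and p ≤ 0.05 |
| `savmir.qpcr` | 2^-ddCt relative quantification against a reference assay (default U6) with technical-then-biological averaging and a two-sample t-test |
| `savmir.targetseed` | canonical 8mer / 7mer-m8 / 7mer-A1 seed-site scanning of UTRs and hypergeometric term over-representation |
| `savmir.pipeline` | single-config orchestration with a hashed, deterministic run manifest |

`savmir.datasets.winged_wingless_table()` bundles the published 32-row
WL-vs-W normalized-count table used to validate the fold-change arithmetic
and significance calling.

## CLI

```bash
savmir simulate --seed 1 --n-mirnas 50 --depth 100000 --out sim/
savmir clean sim/cond1.fastq cleaned/ --adapter3 TGGAATTCTCGGGTGCCAAGG
savmir annotate cleaned/tags.fa out/ --mature sim/ref/matures.fa \
    --genome sim/ref/genome.fa --ncrna sim/ref/ncrna.fa --repeats sim/ref/repeats.fa
savmir diffexp counts.tsv de.tsv --totals 887980,1033351
savmir qpcr ct.tsv qout/ --reference U6 --calibrator wingless
savmir targets mirnas.fa utrs.fa tout/ --terms go.tsv --alpha 0.001
savmir run config.yml          # full pipeline from a YAML config
```

A pipeline config accepts any `RunConfig` field (see
`savmir/pipeline.py`); with no input FASTQs it simulates libraries first
and records everything in `manifest.json`.

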