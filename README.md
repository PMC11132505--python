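# lcdscope

Proteome-wide detection, classification and statistical analysis of
**low-complexity domains (LCDs)** — protein regions dominated by one or two
amino acids, such as polyQ tracts, H/Q-rich stretches or S/G-rich linkers.
`lcdscope` is aimed at researchers surveying LCD content across organisms:
it scans protein FASTA files, classifies every domain it finds into one of
400 composition classes, and provides the statistics needed to compare LCD
repertoires within and between proteomes.

## The method

A protein is scanned with a sliding window of width *W* = 20 residues (unit
stride). A window belongs to an LCD class when

- the windowed composition of the class's **primary** amino acid is
  ≥ *c*₁ = 40%,
- for the 380 two-letter (**secondary**) classes, the composition of a
  distinct secondary amino acid is additionally ≥ *c*₂ = 20%, and
- the **linear dispersion** of each searched amino acid — a [0, 1] statistic
  that is 1 for perfectly even spacing and decreases as occurrences
  cluster — is ≥ δ = 0.5.

All overlapping passing windows are merged into contiguous domains. Class
labels are positional: `HQ` is the search with the 40% threshold on H and
the 20% threshold on Q; `QH` is a distinct class. With 20 primary and
20 × 19 secondary classes, the full search space is 400 classes.

On top of the scanner, `lcdscope` computes:

- **Descriptive statistics** — per-organism class counts, organism-level
  class frequencies with rarity bins, per-residue occupancy, secondary-class
  shares, domain-of-life-specific classes, co-occurrence combinations and
  Pfam-clan concentration.
- **Scrambled-proteome enrichment** — each proteome is scrambled once by a
  seeded Fisher–Yates shuffle that preserves protein count, every protein
  length and every initiator residue; per class, the number of
  LCD-containing proteins in the original vs scrambled proteome is tested
  with a two-sided Fisher's exact test, Holm–Šidák corrected within the
  organism, and summarized as ln odds ratios with Woolf 95% CIs (a +1
  pseudocount, flagged as biased, handles zero cells).
- **GO-term enrichment** — per LCD class, the LCD-containing protein set is
  tested against the proteome background (one-sided Fisher, single-step
  Šidák), reported for terms of ontology depth ≥ 4, and aggregated across
  organisms as the percentage sharing each (class, term) pair.
- **Occupancy signatures** — each proteome is a 400-component vector of
  per-residue occupancy percentages, compared by percentile rank, raw
  difference and Manhattan distance (over the 380 secondary classes by
  default), with complete-linkage clustering and Newick export.
- **Synthetic data** — a generator for proteomes with configurable
  background amino-acid frequencies, planted LCDs of any class, and toy
  GO/annotation/clan bundles, so the whole pipeline is testable without
  downloads.

## Worked example

Generate a small synthetic survey and scan one organism:

```
$ lcdscope simulate --seed 42 --out-dir demo
bundle with 20 organisms written under demo
$ lcdscope scan --fasta demo/SYNEUK001.fasta --classes all --out demo/SYNEUK001.lcds.tsv
14 LCDs written to demo/SYNEUK001.lcds.tsv
$ lcdscope stats --fasta demo/SYNEUK001.fasta --lcds demo/SYNEUK001.lcds.tsv --out-dir demo/stats
counts and signature written under demo/stats
$ cat demo/stats/SYNEUK001.counts.tsv
class_label     n_proteins_with_lcd     n_lcds  n_lcd_residues
H       3       3       156
HQ      3       3       156
Q       6       6       320
QG      1       1       22
QH      1       1       20
```

This organism carries six proteins with Q-rich LCDs (320 residues inside
the class-Q domain union) and three proteins whose H-rich regions also
qualify as the secondary class `HQ` (≥40% H plus ≥20% Q). The nonzero
components of its occupancy signature:

```
    occupancy_pct
H        3.534209
Q        7.249660
HQ       3.534209
QG       0.498414
QH       0.453104
```

i.e. 7.25% of all residues in this proteome lie inside Q-class LCDs. The
`enrich`, `go`, `cluster` and `run` subcommands (and the equivalent library
functions in `lcdscope.enrichment`, `lcdscope.ontology`,
`lcdscope.signatures`, `lcdscope.pipeline`) build the comparative layers on
top; see `docs/methods.md` for the models and conventions.

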