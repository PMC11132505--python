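# Methods

## LCD model and scanner

A low-complexity domain (LCD) is operationalized compositionally: a maximal
run of overlapping sliding windows (width *W*, stride 1) in which one amino
acid (primary classes) or an ordered pair of amino acids (secondary
classes) exceeds minimum windowed composition thresholds, with the target
residues spread across the window rather than collapsed into one clump.
Merged domains are reported with 1-based inclusive coordinates and the
composition of the merged span; the merged span itself is not re-validated
or trimmed — every constituent window passed, and the merged composition
may legitimately fall below the window threshold.

Tunable parameters (all exposed on `ClassSpec` and every CLI command):

| parameter | default | units | role |
|---|---|---|---|
| `window_size` (*W*) | 20 | residues | sliding-window width; also the minimum LCD length |
| `primary_threshold` (*c*₁) | 0.40 | fraction | minimum windowed composition of the primary amino acid |
| `secondary_threshold` (*c*₂) | 0.20 | fraction | minimum composition of the secondary amino acid (two-letter classes only) |
| `dispersion_threshold` (δ) | 0.5 | dimensionless | minimum linear dispersion, applied separately to each searched amino acid |

Combinations with *c*₁ + *c*₂ > 1 are rejected at configuration time as
invalid thresholds. Class labels are positional (`HQ` ≠ `QH`): the realized
composition of the secondary amino acid may exceed that of the primary.
Non-canonical letters (X, U, O, B, Z, J) count toward window length but
toward no composition, so they can only dilute, never create, a class.

### Linear dispersion

For *k* occurrences of the target amino acid at positions
p₁ < … < p_k inside a window of width *W*, take the *k* + 1
boundary-inclusive gaps (p₁, p₂ − p₁, …, *W* + 1 − p_k), whose population
standard deviation σ is min–max normalized against the most even and most
clustered placements of *k* residues in the window:

    dispersion = 1 − (σ − σ_min) / (σ_max − σ_min)

with dispersion ≡ 1 when *k* < 2 or when σ_max = σ_min (homopolymeric
windows). Both extremes have closed forms — most even: gaps as equal as
possible; most clustered: a contiguous run at one end, i.e. one gap of
*W* − *k* + 1 and *k* gaps of 1 — and the test suite verifies them against
exhaustive enumeration of all placements for *W* ≤ 12 and the classic
5-in-20 case. This formulation was chosen because it satisfies all the
properties the pass criterion needs (exactly 1 at even spacing, 0 at full
clustering, strictly decreasing as occurrences cluster, bounded in [0, 1]);
a gap vector without the window boundaries degenerates (a fully clustered
run has all internal gaps equal, hence zero standard deviation) and cannot
be normalized this way. The statistic lives behind the single function
`linear_dispersion`, so an alternative convention can be swapped in without
touching the scanner; results from tools using a different dispersion
formula are expected to agree qualitatively, not residue-for-residue.

### Numerical conventions

Threshold comparisons use `value ≥ threshold − 1e−9` so that exact
fractions (e.g. 8/20 against 0.40) are never lost to floating-point
representation. Windows merge only when they share at least one residue;
abutting windows remain separate domains. The batched proteome scanner
computes per-window residue counts once per protein and window size and
shares them across all 400 class predicates; its output is identical (not
just equivalent) to independent per-class scans, which the tests assert.

## Scrambled-proteome null and enrichment test

The null model asks: given this proteome's exact residue pool, protein
count, protein lengths and initiator residues, how many proteins would
contain an LCD of each class by chance? Each proteome is scrambled once:
initiator residues are set aside, the remaining residues pooled and
shuffled by an in-place Fisher–Yates shuffle (numpy PCG64 generator; the
generator family and seed are recorded in run manifests because scrambled
outputs are generator-dependent), then re-segmented into the original
lengths with initiators restored. Conservation of protein count, lengths,
initiators and the residue multiset is asserted on every run.

Per class, the 2×2 table (proteins with/without an LCD, original vs
scrambled) is tested with a **two-sided** Fisher's exact test — two-sided
because both enrichment and depletion are reported — computed with exact
integer arithmetic over the hypergeometric support (ties between table
probabilities are decided exactly, not by a floating-point tolerance).
Within an organism, p-values are **Holm–Šidák** adjusted across the classes
with at least one LCD-containing protein in either proteome; classes absent
from both are carried through unadjusted, flagged unrepresented, and count
as not significant in cross-organism summaries. Effect size is the natural
log odds ratio with a Woolf 95% CI (z = 1.96); when either with-LCD cell is
zero a +1 pseudocount is added to all four cells and the estimate flagged
biased — conservative in the typical case where the zero sits in the
scrambled proteome. Domain-of-life summaries report the percentage of
organisms significantly enriched/depleted per class (denominator: all
organisms in the group) and the median lnOR with biased estimates included.

A single scramble per organism follows the survey design; calibration is
established separately: testing one scramble against an independent
re-scramble of the same proteome yields post-correction significance at a
rate at or below α (checked over 50 seed pairs in the tests, 25 in the
acceptance script).

## GO enrichment

The ontology is read from OBO (is_a edges only; obsolete terms skipped;
dangling edges dropped with a warning; cycles are a hard error). Term
*depth* is the longest is_a path from the namespace root — the stricter of
the two common conventions; the shortest-path "level" is deliberately not
used. Annotations come from GAF 2.x, restricted to the proteome, with
NOT-qualified rows skipped and no ancestor propagation by default
(propagation is available behind a flag). For each LCD class the study set
is the proteins with ≥1 LCD of that class and the background is the whole
proteome. Each term annotating ≥1 background protein is tested one-sided
for enrichment (hypergeometric upper tail); single-step Šidák correction
uses the number of terms tested, and the depth ≥ 4 reporting filter is
applied after correction, so it never changes a p-value. Cross-organism
sharing reports, for every (class, term) pair significant in at least one
organism, the percentage of the group's organisms in which it is
significant.

GOATOOLS-style enrichment is reimplemented here directly (obonet + scipy)
rather than wrapped; conventions above (sidedness, propagation, correction
scope, depth definition) are pinned by tests.

## Occupancy signatures and clustering

A proteome's LCD content is the 400-vector of per-residue occupancy
percentages (class LCD residue-union ÷ total residues × 100), keys fixed as
20 primary then 380 secondary classes. Comparisons:

- **Percentile rank** within a cohort uses the midrank convention with
  self-inclusion — symmetric under ties, and cohort ranks average to
  exactly 50 per class.
- **Manhattan distance** defaults to the 380 secondary classes (the
  primary classes are near-universal and would dominate otherwise); the
  full 400-key variant is a parameter.
- **Complete-linkage clustering** is a native agglomerative implementation
  (cluster distance = maximum over cross pairs, ties broken by the smallest
  index pair) returning a merge list plus Newick export; heights are
  provably non-decreasing. The tests verify it against an independent
  hierarchical-clustering reference via cophenetic distances.
- Viruses are excluded from clustering by default (their proteomes are too
  small for stable occupancy vectors); overridable.
- Group-level distance matrices average organism-pair distances (not
  distances between group-mean signatures); within-group means exclude
  self-pairs and are undefined for singleton groups.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the analysis assumes:
i.i.d. background residues at configurable frequencies (presets: `uniform`;
`swissprot`, database-average frequencies; `falciparum-like`, strongly
N/K-enriched to mimic compositionally skewed proteomes), uniform protein
lengths, an initiator M per protein, planted LCDs with evenly interleaved
target residues (so composition and dispersion criteria are met by
construction, independent of the dispersion formula's fine detail), and a
toy GO bundle whose planted term sits at depth 4 with decoy siblings.
It does **not** emulate paralog families, repeat-expansion evolution,
correlated residue order, isoform redundancy, or realistic length and
annotation distributions — so passing tests demonstrate correctness of the
pipeline's logic and calibration of its statistics under the stated model,
not performance on the idiosyncrasies of real proteomes.

Study-bundle defaults (4 domains × 5 organisms, 30 proteins of 80–200
residues each; Q planted in 100% of eukaryotes, 60% of bacteria, 40% of
archaea, no viruses; HQ plus an HQ↔GO-term association in eukaryotes) are
sized so that every planted contrast — frequency ordering across domains, a
eukaryote-specific class, an enriched class, a shared functional
association — is recoverable by the corresponding pipeline stage.

## Problem sizes

The validation suite uses: 1,000 random sequences (20–500 residues, three
background presets, 40 sampled classes) for scanner/brute-force
equivalence; 100 planted-LCD fixtures for recall; 50 seeds for scramble
conservation and for null–null calibration (200-protein proteomes, all 400
classes); a 1,000-protein fixture with 5% planted HQ proteins against 20
scramble seeds for enrichment recovery; 5-organism bundles for GO
recovery; 200 random matrices (n ≤ 12) for clustering agreement; and
window {20–60} × composition {30–60, 20–60} grids on a 20-protein planted
fixture for monotonicity. The acceptance script uses the same designs at
300 sequences / 25 calibration seeds / 100 matrices.

On the window-size grid, monotonicity is asserted on per-class counts of
LCD-containing proteins: residue occupancy is structurally non-monotone in
window size, because a wider passing window spans more residues and merged
domains therefore extend further beyond a planted region even as the
number of passing windows falls. On composition grids both protein and
residue counts are asserted, where monotonicity is a theorem.

## Known limitations

- The linear-dispersion normalization is this package's own pinned
  convention; exact residue-level agreement with other LCD scanners is not
  claimed.
- One scramble replicate per organism estimates the null by design;
  distributional uncertainty of the scrambled count itself is not modeled.
- Every FASTA record is treated as one protein; isoform collapsing is the
  caller's responsibility.
- GO analysis consumes is_a edges only; part_of/regulates relationships and
  evidence-code filtering are out of scope.
- Fisher's exact test falls back silently to large-sample behavior nowhere:
  tables are always computed exactly, which for extremely large balanced
  margins costs big-integer arithmetic time (irrelevant at proteome-survey
  scales, where the with-LCD margin is small).
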