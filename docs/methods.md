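# Methods

## Model and pipeline

`compspec` treats a genome as a mosaic of fixed-length segments and
characterizes each segment by a *compositional spectrum*: the frequency
vector of mismatch-tolerant occurrences of a fixed probe-word set.  The
working hypothesis behind the pipeline is that segments of similar GC can
still differ systematically in word usage ("organizational patterns",
OPs), and that this organizational signal correlates with the functional
identity of resident genes.  The pipeline therefore separates the two
axes explicitly: GC binning first, spectrum clustering strictly within a
GC bin afterwards, and enrichment always against the same-bin background,
so that any detected association is organizational rather than
compositional.

Stages: (1) tile each sequence with non-overlapping windows; (2) compute
spectra; (3) per GC class, build the 1 − Spearman distance matrix and a
neighbor-joining tree, and cut it into OP groups; (4) pool the genes of
each group and test every functional term against the class background;
(5) rebuild size-matched random groups, re-run the identical enrichment,
and compare real vs random.

## Parameters

| parameter | default | notes |
|---|---|---|
| `window_len` | 100 000 bp | segment size; trailing partial windows are discarded so that all spectra are computed on equal-length sequences |
| GC bin edges | 0.37, 0.42, 0.47, 0.52 | half-open `[lo, hi)` bins labelled L1, L2, H1, H2, H3; a boundary value goes to the upper bin |
| `max_ambiguous_frac` | 0.5 | windows with more N than this are dropped; GC uses unambiguous bases only |
| `n_words` | 100 | probe words drawn uniformly without replacement, seed recorded |
| `L` (word length) | 10 (ACGT), 20 (RY) | the two-letter purine/pyrimidine alphabet uses doubled length to keep word specificity comparable |
| `r` (Hamming tolerance) | 2 (ACGT), 4 (RY) | RY default scales r with L so the per-letter tolerance (r/L = 0.2) is preserved |
| `use_complementary` | true | reverse-complement probes counted and merged per word; makes spectra strand-symmetric, so counting one genomic strand suffices |
| `n_groups` / `cut_threshold` | 3 / – | tree-cutting control: remove the longest internal edges until `n_groups` components exist, or every internal edge ≥ threshold |
| `min_group_size` | 20 | smaller components are pooled as unassigned |
| `alpha` | 0.05 | a group counts as enriched when ≥ 1 term reaches BH-adjusted p ≤ alpha |
| `min_term_genes` | 3 | terms with fewer background genes are not tested (tiny terms are unstable) |
| `background` | `gc_class` | enrichment background: genes of the same GC class (a `global` option exists) |
| `n_replicates` | 10 | random-group redistributions; 10 replicates of G real groups give 10·G random groups |

Word choice is part of the method configuration, not of the data: the
probe set is generated once from `(n, L, alphabet, seed)` and reused for
every segment, and the manifest records the seed.

## Statistical components

* **Spectrum distance.** d = 1 − r_s with average ranks for ties
  (rank-Pearson).  Affine rescalings of d (e.g. (1 − r_s)/2) change
  neither the rank structure nor the neighbor-joining topology, so only
  the plain form is exposed.
* **Neighbor joining.** Saitou–Nei agglomeration (via scikit-bio) on ids
  sorted lexicographically, which fixes tie-breaking; negative branch
  lengths are clamped to zero and the clamped total is logged.  Additive
  matrices are recovered exactly (verified against a path-length oracle
  in the tests).
* **Enrichment.** One-tailed hypergeometric tail P(X ≥ k) for each term;
  Benjamini–Hochberg step-up across the terms of one group (mirroring
  per-gene-list practice; a global option would be a one-line change but
  alters the meaning of the per-group characteristic counts).  An EASE
  -style variant (discount one supporting gene) is available and off by
  default.  Genes are assigned to the segment containing their start
  coordinate, so a boundary-spanning gene is counted exactly once.
* **Fisher 2×2.** Two-tailed by the minimum-likelihood rule: sum all
  same-margin tables whose probability does not exceed the observed
  table's (relative tolerance 1e-7), cross-checked in the tests by
  exhaustive enumeration of every table of total size ≤ 30.  Two-tailed
  conventions differ between software packages — some legacy programs
  truncate the opposite tail — so the reproduction script reports the
  one-tailed value alongside the two-tailed one for the reference
  group-count table.
* **Mann–Whitney U.** U = min(U_x, U_y) from average ranks; Z from the
  tie-corrected normal approximation, without continuity correction
  (a continuity flag exists); p two-tailed.  Characteristic values from
  all random replicates are pooled into one random-side distribution, and
  only "non-empty" (enriched) groups enter the characteristic
  distributions.

## The synthetic generator

The generator emulates the structure the pipeline is designed to detect:

* **Segments with latent OP classes.**  Each class is a set of 8
  signature elements of 60 bp, disjoint between classes, planted at
  5 placements/kb (uniform over all non-overlapping arrangements) into
  i.i.d. background.  Signature elements are drawn with their G+C count
  matching the background target, and residual GC drift after planting is
  compensated by transition flips (A↔G, T↔C) at background positions, so
  every emitted segment stays inside its intended GC bin: classes differ
  organizationally, not compositionally.
* **Why 60 bp elements.**  A planted literal is visible to the spectrum
  only if some probe word lies within Hamming r of some window of planted
  material.  A random 10-mer probe is within r = 2 of a given 10-mer with
  probability 436/4¹⁰ ≈ 4.2 × 10⁻⁴, so 10-bp signatures would almost
  never intersect a 100-word probe set.  Eight 60-bp elements expose
  8 × 51 = 408 distinct 10-mer windows per class; with 100 probes plus
  their complements the expected number of probes in reach is ≈ 34 per
  class, so every class is reliably sampled by any probe seed while the
  signal still passes through the generic fuzzy-counting channel.
* **Genes and terms.**  Gene counts are Poisson per segment
  (default mean 0.39, a moderate-GC genome-scale density; length 1 kb);
  each gene's term is the class-linked term with probability β
  (`coupling_beta`, default 0.8) and uniform otherwise.  β = 0 is the
  exact null of the randomization test; β = 1 makes terms deterministic.

What the generator does **not** emulate: repetitive elements and
masked-repeat mosaics, isochore-scale GC gradients, a real ontology (terms
are flat, disjoint labels; one term per gene), gene structure and
transcription, and chromosome-scale long-range correlations.  Passing the
recovery tests therefore shows that the pipeline detects organizational
word-usage signal coupled to gene labels under controlled conditions — it
does not certify performance on real genomes, where the OP signal is
weaker, confounded with repeats, and terms overlap heavily.

## Experiments and problem sizes

* **Planted-structure recovery** (tests: 5 seeds; script: 3 seeds):
  3 classes × 40 segments × 20 kb in one GC bin, planting 5/kb, β = 0.8.
  Scored by adjusted Rand index of the recovered partition (unassigned
  segments count as their own label) and by detection of all linked terms
  at adjusted p ≤ 0.05.
* **Null calibration** (tests: 100 replicates; script: 50): reduced
  replicates of 2 classes × 20 segments × 5 kb with β = 0 and gene
  density raised to 2/segment so the enrichment machinery actually runs
  under the null; the real-vs-random Fisher p should fall below 0.05 in
  at most a nominal fraction of replicates.

These sizes are desk-scale study conditions chosen so the organizational
signal is strong and the statistics well-exercised; they are fixed in the
code, not tuned per run.

## Numerical and degenerate-input choices

* IUPAC ambiguity codes collapse to N on input; an N mismatches every
  probe letter, so masked runs deflate counts rather than inflating them.
* A window with no unambiguous base has undefined GC and is dropped; a
  segment with M = 0 (no probe matches anywhere) has an undefined
  spectrum, is flagged, and is excluded from distance computations.
* The distance matrix is symmetrized against floating-point noise and
  clipped at 0; Spearman on a constant spectrum is refused rather than
  returning NaN.
* −log₁₀ p is capped at 300 digits (p floored at 1e-300).
* All tie-breaks (NJ joins, edge cuts, group labelling) resolve by
  lexicographic segment id; every random draw flows from a named seed, so
  reruns with one configuration are byte-identical.

## Known limitations

* Neighbor joining is O(k³) in the number of segments per GC class;
  desk-scale bins (≲ a few thousand segments) are fine, whole-genome
  bins would need sketching or a different clusterer.
* The tree-cutting rule (longest internal edges, minimum size) is one of
  several defensible choices; group counts are user parameters, not
  estimated from the data.
* The enrichment treats terms as opaque and independent; with a real GO
  annotation the per-group BH correction is approximate because terms
  overlap.
* Only over-representation is tested, matching the question asked of the
  data; depletion would need the other tail.
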