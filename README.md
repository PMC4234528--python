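# compspec

Compositional spectrum analysis (CSA) of genome organization: an
alignment-free pipeline that asks whether genomic segments with a similar
*organizational pattern* (OP) — similar usage of oligonucleotide "words",
beyond plain GC content — tend to harbor functionally related genes.

The pipeline is aimed at genome analysts studying large-scale sequence
heterogeneity: it partitions chromosome-scale sequences into fixed-length
segments (100 kb by default), bins segments into five GC classes named
after the isochore families (L1 <37%, L2 37–42%, H1 42–47%, H2 47–52%,
H3 >52%), clusters the segments of each class by spectrum similarity into
OP groups, tests each OP group for enrichment in functional gene
categories, and quantifies how non-random that enrichment is against
size-matched random groups.

## The method

**Compositional spectrum.** Fix a probe set *W* of *n* words
*w₁ … wₙ* of length *L* (default: *n* = 100 random 10-mers over
{A,C,G,T}; alternatively 20-mers over the purine/pyrimidine alphabet
R/Y).  For a segment *S*, the count *mᵢ* is the number of sliding windows
of *S* within Hamming distance *r* of *wᵢ* (default *r* = 2; an N never
matches; by default the reverse-complement set *W′* is counted and merged
per word, making spectra strand-symmetric).  With *M* = Σᵢ *mᵢ*, the
spectrum is the frequency vector *F*(*W*, *S*) with *fᵢ* = *mᵢ*/*M*.

**Distance and clustering.** The distance between two segments is
*d* = 1 − *r*ₛ, where *r*ₛ is the Spearman rank correlation of their
spectra.  Within each GC class, the pairwise distance matrix is clustered
with neighbor joining; OP groups are read off the tree by cutting the
longest internal edges (group count or edge-length threshold, with a
minimum group size).

**Enrichment and the randomization test.** Genes are assigned to segments
by start coordinate; each OP group's pooled gene list is tested for
over-representation of every functional term against all genes of the
same GC class (one-tailed hypergeometric test, Benjamini–Hochberg
correction per group).  To show the enrichment is a property of the OPs
and not of group sizes, segments are redistributed into size-matched
random groups (10 replicates by default) that run through the identical
enrichment; real and random groups are compared by a two-tailed Fisher
exact test on enriched-group counts and by tie-corrected Mann–Whitney U
tests on per-group characteristics (−log₁₀ adjusted p of enriched terms,
number of enriched terms, number and fraction of "involved" segments).

A fully synthetic data generator plants OP classes as literal signature
elements at matched GC and couples gene labels to classes with tunable
strength, so the whole pipeline is testable without any downloads.

## Worked example

Generate a synthetic genome with three planted OP classes inside one GC
bin (the default: 3 classes × 40 segments × 20 kb at GC 0.45, signature
planting 5/kb, gene–term coupling β = 0.8) and run the full pipeline:

```python
from compspec import RunConfig, SyntheticSpec, generate_synthetic_dataset, run_pipeline

spec = SyntheticSpec(seed=5)
fasta, bed, terms, truth = generate_synthetic_dataset(spec, "demo/data")

cfg = RunConfig(fasta=str(fasta), annotation=str(bed), term_map=str(terms),
                outdir="demo/run", window_len=spec.segment_len,
                n_groups=3, min_group_size=10)
manifest = run_pipeline(cfg)
print("segments:", manifest["counts"]["segments_per_class"])
print("OP groups:", manifest["counts"]["op_groups"],
      "| enriched:", manifest["counts"]["real_groups_enriched"], "of 3 real vs",
      manifest["counts"]["random_groups_enriched"], "of 30 random")
print("real-vs-random Fisher p:", round(manifest["summary"]["fisher_p_two_tailed"], 5))
```

prints

```
segments: {'H1': 120}
OP groups: 3 | enriched: 3 of 3 real vs 0 of 30 random
real-vs-random Fisher p: 0.00018
```

All 120 segments fall into the H1 GC bin (the classes differ only
organizationally), neighbor joining splits them into three OP groups of
40, and each group is enriched in exactly the functional term coupled to
its planted class (`demo/run/enrichment.tsv`):

```
group_id  term_id  k  n        p_adj
    H1-a term_op3 10 12 7.979827e-08
    H1-b term_op1 11 15 5.339443e-07
    H1-c term_op2 17 17 7.867662e-11
```

Here *k* of the group's *n* genes carry the term; none of the 30
size-matched random groups is enriched in anything, and the Fisher
comparison (3/3 vs 0/30) gives p ≈ 1.8 × 10⁻⁴ — the planted association
between organization and function is detected as strongly non-random.

The same run is available from the shell:

```sh
compspec simulate --seed 5 --outdir demo/data
compspec run-all --config demo/config.yaml     # or stage by stage:
compspec segment --config demo/config.yaml
compspec spectra --config demo/config.yaml
compspec cluster --config demo/config.yaml
compspec enrich --config demo/config.yaml
compspec randomize --config demo/config.yaml
```

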