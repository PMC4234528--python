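"""End-to-end orchestration: segment -> spectra -> cluster -> enrich -> randomize.

Every stage reads its inputs from, and writes its outputs to, plain-text
files under the run's output directory, so subcommand-by-subcommand
execution and ``run_pipeline`` produce identical results.  All randomness
flows from seeds recorded in the configuration; reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from compspec import clustering, enrichment, randomization, segmentation, spectra

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.  Paths are resolved as given."""

    fasta: str
    annotation: str
    term_map: str
    outdir: str
    annotation_format: str = "bed"  # "bed" | "gff3"
    feature_type: str = "gene"  # GFF3 only
    # segmentation
    window_len: int = segmentation.DEFAULT_WINDOW_LEN
    max_ambiguous_frac: float = segmentation.DEFAULT_MAX_AMBIGUOUS
    gc_bin_edges: tuple[float, ...] = segmentation.DEFAULT_GC_EDGES
    # spectra
    n_words: int = spectra.DEFAULT_N_WORDS
    word_len: int | None = None  # alphabet default when None
    r: int | None = None  # alphabet default when None
    alphabet: str = "ACGT"
    use_complementary: bool = True
    word_seed: int = 17
    # clustering
    n_groups: int | None = 3  # per GC class; exclusive with cut_threshold
    cut_threshold: float | None = None
    min_group_size: int = clustering.DEFAULT_MIN_GROUP_SIZE
    # enrichment
    alpha: float = randomization.DEFAULT_ALPHA
    min_term_genes: int = enrichment.DEFAULT_MIN_TERM_GENES
    ease_penalty: bool = False
    background: str = "gc_class"  # "gc_class" | "global"
    # randomization
    n_replicates: int = randomization.DEFAULT_N_REPLICATES
    random_seed: int = 99

    def __post_init__(self) -> None:
        if self.background not in ("gc_class", "global"):
            raise ValueError("background must be 'gc_class' or 'global'")
        if (self.n_groups is None) == (self.cut_threshold is None):
            raise ValueError("set exactly one of n_groups / cut_threshold")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "gc_bin_edges" in data:
            data["gc_bin_edges"] = tuple(data["gc_bin_edges"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gc_bin_edges"] = list(d["gc_bin_edges"])
        return d

    def validate_paths(self) -> None:
        for name in ("fasta", "annotation", "term_map"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    def spectrum_params(self) -> spectra.SpectrumParams:
        r = self.r if self.r is not None else spectra.DEFAULT_R[self.alphabet]
        return spectra.SpectrumParams(r=r, use_complementary=self.use_complementary)


# ---------------------------------------------------------------------------
# stages


def stage_segment(cfg: RunConfig) -> Path:
    """Cut the genome into windows and write ``segments.tsv``."""
    cfg.out.mkdir(parents=True, exist_ok=True)
    sequences = segmentation.read_fasta(cfg.fasta)
    segments = segmentation.segment_genome(
        sequences, cfg.window_len, cfg.max_ambiguous_frac, cfg.gc_bin_edges
    )
    path = cfg.out / "segments.tsv"
    segmentation.segments_to_frame(segments).to_csv(path, sep="\t", index=False)
    logger.info("stage segment: %d segments retained -> %s", len(segments), path)
    return path


def _load_segments(cfg: RunConfig) -> pd.DataFrame:
    path = cfg.out / "segments.tsv"
    if not path.exists():
        raise FileNotFoundError(f"run the segment stage first: missing {path}")
    return pd.read_csv(path, sep="\t")


def stage_spectra(cfg: RunConfig) -> Path:
    """Compute every retained segment's spectrum; write ``spectra.tsv``
    (frequency matrix) and ``wordset.tsv`` (probe-word manifest)."""
    seg_table = _load_segments(cfg)
    sequences = {s.seq_id: s for s in segmentation.read_fasta(cfg.fasta)}
    ws = spectra.generate_word_set(cfg.n_words, cfg.word_len, cfg.alphabet, cfg.word_seed)
    params = cfg.spectrum_params()

    pairs = [
        (row.segment_id, sequences[row.seq_id].residues[row.start : row.end])
        for row in seg_table.itertuples()
    ]
    specs = spectra.compute_spectra(pairs, ws, params)
    n_undefined = sum(not s.defined for s in specs)
    if n_undefined:
        logger.warning("stage spectra: %d segments with undefined spectra excluded",
                       n_undefined)
    spec_path = cfg.out / "spectra.tsv"
    spectra.spectra_to_frame(specs, ws).to_csv(spec_path, sep="\t")
    spectra.word_set_manifest(ws, params).to_csv(
        cfg.out / "wordset.tsv", sep="\t", index=False
    )
    return spec_path


@dataclass(frozen=True)
class _RowSpectrum:
    segment_id: str
    frequencies: np.ndarray


def _load_spectra_by_class(cfg: RunConfig) -> dict[str, list[_RowSpectrum]]:
    spec_path = cfg.out / "spectra.tsv"
    if not spec_path.exists():
        raise FileNotFoundError(f"run the spectra stage first: missing {spec_path}")
    mat = pd.read_csv(spec_path, sep="\t", index_col="segment_id")
    seg_table = _load_segments(cfg)
    gc_of = dict(zip(seg_table.segment_id, seg_table.gc_class))
    by_class: dict[str, list[_RowSpectrum]] = {}
    for seg_id, row in mat.iterrows():
        by_class.setdefault(gc_of[seg_id], []).append(
            _RowSpectrum(seg_id, row.to_numpy(dtype=float))
        )
    return by_class


def stage_cluster(cfg: RunConfig) -> Path:
    """Per GC class: distance matrix, NJ tree (``trees/<class>.nwk``) and
    OP groups; write ``groups.tsv``."""
    by_class = _load_spectra_by_class(cfg)
    tree_dir = cfg.out / "trees"
    tree_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gc_class in sorted(by_class):
        members = by_class[gc_class]
        if len(members) < 3:
            logger.warning("stage cluster: class %s has %d (<3) segments, skipped",
                           gc_class, len(members))
            for m in members:
                rows.append((m.segment_id, gc_class, clustering.UNASSIGNED))
            continue
        dm = clustering.distance_matrix(members)
        tree = clustering.neighbor_joining(dm)
        (tree_dir / f"{gc_class}.nwk").write_text(clustering.tree_to_newick(tree))
        n_groups = min(cfg.n_groups, len(members)) if cfg.n_groups is not None else None
        groups, unassigned = clustering.extract_op_groups(
            tree, gc_class, cfg.min_group_size, n_groups, cfg.cut_threshold
        )
        for g in groups:
            rows.extend((sid, gc_class, g.group_id) for sid in sorted(g.segment_ids))
        rows.extend((sid, gc_class, clustering.UNASSIGNED) for sid in sorted(unassigned))
    path = cfg.out / "groups.tsv"
    pd.DataFrame(rows, columns=["segment_id", "gc_class", "group_id"]).sort_values(
        ["gc_class", "group_id", "segment_id"]
    ).to_csv(path, sep="\t", index=False)
    return path


def _load_groups(cfg: RunConfig) -> list[clustering.OPGroup]:
    path = cfg.out / "groups.tsv"
    if not path.exists():
        raise FileNotFoundError(f"run the cluster stage first: missing {path}")
    table = pd.read_csv(path, sep="\t")
    groups = []
    for (gc_class, group_id), sub in table.groupby(["gc_class", "group_id"]):
        if group_id == clustering.UNASSIGNED:
            continue
        groups.append(
            clustering.OPGroup(group_id, gc_class, frozenset(sub.segment_id))
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def _enrichment_inputs(cfg: RunConfig):
    """Shared plumbing for the enrichment and randomization stages."""
    seg_table = _load_segments(cfg)
    segments = [
        segmentation.Segment(
            row.segment_id, row.seq_id, row.start, row.end,
            row.gc_fraction, row.gc_class, row.ambiguous_fraction,
        )
        for row in seg_table.itertuples()
    ]
    genes = segmentation.read_gene_annotation(
        cfg.annotation, cfg.annotation_format, cfg.feature_type
    )
    mapping = enrichment.assign_genes_to_segments(genes, segments)
    tm_path = Path(cfg.term_map)
    terms = (
        enrichment.TermMap.from_gmt(tm_path)
        if tm_path.suffix == ".gmt"
        else enrichment.TermMap.from_tsv(tm_path)
    )
    gc_of = dict(zip(seg_table.segment_id, seg_table.gc_class))
    background_by_class: dict[str, list[str]] = {}
    for gene, seg in mapping.items():
        background_by_class.setdefault(gc_of[seg], []).append(gene)
    if cfg.background == "global":
        everything = sorted(mapping)
        background_by_class = {cls: everything for cls in background_by_class}
    return mapping, terms, background_by_class, gc_of


def _enrich_groups(
    groups: Sequence[clustering.OPGroup],
    mapping: Mapping[str, str],
    terms: enrichment.TermMap,
    background_by_class: Mapping[str, Sequence[str]],
    cfg: RunConfig,
) -> list[enrichment.EnrichmentResult]:
    results = []
    for group in groups:
        group_genes = enrichment.collect_group_genes(group, mapping)
        results.extend(
            enrichment.fisher_enrichment(
                group_genes,
                background_by_class.get(group.gc_class, []),
                terms,
                cfg.min_term_genes,
                group_id=group.group_id,
                gene_to_segment=mapping,
                ease_penalty=cfg.ease_penalty,
            )
        )
    return results


def stage_enrich(cfg: RunConfig) -> Path:
    """Test every OP group against its GC-class background; write
    ``enrichment.tsv``."""
    groups = _load_groups(cfg)
    mapping, terms, background_by_class, _ = _enrichment_inputs(cfg)
    results = _enrich_groups(groups, mapping, terms, background_by_class, cfg)
    path = cfg.out / "enrichment.tsv"
    enrichment.enrichment_to_frame(results).to_csv(path, sep="\t", index=False)
    return path


def stage_randomize(cfg: RunConfig) -> Path:
    """Build size-matched random groups, rerun the enrichment on them and
    write the real-vs-random ``comparison.json`` plus per-group
    ``characteristics.tsv``."""
    groups = _load_groups(cfg)
    if not groups:
        raise ValueError("no OP groups to compare; check clustering parameters")
    mapping, terms, background_by_class, gc_of = _enrichment_inputs(cfg)

    # the random pool is exactly the clustered segments of each class
    table = pd.read_csv(cfg.out / "groups.tsv", sep="\t")
    segments_by_gc = {
        gc_class: sorted(sub.segment_id) for gc_class, sub in table.groupby("gc_class")
    }
    group_sizes = {}
    for g in sorted(groups, key=lambda g: g.group_id):
        group_sizes.setdefault(g.gc_class, []).append(g.size)

    real_results = _enrich_groups(groups, mapping, terms, background_by_class, cfg)
    real_chars = randomization.summarize_group_characteristics(
        groups, real_results, cfg.alpha
    )

    replicates = randomization.make_random_groups(
        segments_by_gc, group_sizes, cfg.n_replicates, cfg.random_seed
    )
    random_groups = [g for rep in replicates for g in rep]
    random_results = _enrich_groups(
        random_groups, mapping, terms, background_by_class, cfg
    )
    random_chars = randomization.summarize_group_characteristics(
        random_groups, random_results, cfg.alpha
    )

    report = randomization.compare_real_vs_random(real_chars, random_chars)
    path = cfg.out / "comparison.json"
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))

    char_rows = [
        {"side": side, **dataclasses.asdict(c)}
        for side, chars in (("real", real_chars), ("random", random_chars))
        for c in chars
    ]
    char_frame = pd.DataFrame(char_rows)
    char_frame["neglog10_p"] = char_frame["neglog10_p"].map(
        lambda v: ",".join(f"{x:.6g}" for x in v)
    )
    char_frame.to_csv(cfg.out / "characteristics.tsv", sep="\t", index=False)
    return path


STAGES = ("segment", "spectra", "cluster", "enrich", "randomize")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order and write ``manifest.json``.

    The manifest records the configuration (seeds included), the output
    paths of every stage and audit counts.  Reruns with an identical
    configuration are byte-identical.
    """
    config.validate_paths()
    config.out.mkdir(parents=True, exist_ok=True)
    outputs = {}
    outputs["segments"] = str(stage_segment(config))
    outputs["spectra"] = str(stage_spectra(config))
    outputs["wordset"] = str(config.out / "wordset.tsv")
    outputs["groups"] = str(stage_cluster(config))
    outputs["trees"] = str(config.out / "trees")
    outputs["enrichment"] = str(stage_enrich(config))
    outputs["comparison"] = str(stage_randomize(config))
    outputs["characteristics"] = str(config.out / "characteristics.tsv")

    seg_table = pd.read_csv(outputs["segments"], sep="\t")
    groups_table = pd.read_csv(outputs["groups"], sep="\t")
    comparison = json.loads(Path(outputs["comparison"]).read_text())
    manifest = {
        "config": config.to_dict(),
        "outputs": outputs,
        "counts": {
            "segments_retained": int(len(seg_table)),
            "segments_per_class": {
                str(k): int(v)
                for k, v in seg_table.gc_class.value_counts().sort_index().items()
            },
            "op_groups": int(
                groups_table.group_id.nunique()
                - (clustering.UNASSIGNED in set(groups_table.group_id))
            ),
            "unassigned_segments": int(
                (groups_table.group_id == clustering.UNASSIGNED).sum()
            ),
            "real_groups_enriched": comparison["n_real_enriched"],
            "random_groups_enriched": comparison["n_random_enriched"],
        },
        "summary": {"fisher_p_two_tailed": comparison["fisher_p_two_tailed"]},
    }
    (config.out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


# ---------------------------------------------------------------------------
# bookkeeping


def genes_per_segment(n_genes: int, n_segments: int) -> float:
    """Genes-per-segment ratio, rounded to the 2 decimals used in reports."""
    if n_segments <= 0:
        raise ValueError("n_segments must be positive")
    return round(n_genes / n_segments, 2)


def gc_class_summary(
    segments: Sequence[segmentation.Segment],
    gene_mapping: Mapping[str, str],
    groups: Sequence[clustering.OPGroup] = (),
) -> pd.DataFrame:
    """Per-GC-class bookkeeping: segment, gene and OP-group counts with
    the genes-per-segment ratio, plus a Total row."""
    seg_class = {s.segment_id: s.gc_class for s in segments}
    rows = []
    group_count: dict[str, int] = {}
    for g in groups:
        group_count[g.gc_class] = group_count.get(g.gc_class, 0) + 1
    gene_class_counts: dict[str, int] = {}
    for gene, seg in gene_mapping.items():
        cls = seg_class.get(seg)
        if cls is not None:
            gene_class_counts[cls] = gene_class_counts.get(cls, 0) + 1
    for cls in segmentation.GC_CLASSES:
        n_seg = sum(1 for c in seg_class.values() if c == cls)
        if n_seg == 0:
            continue
        n_genes = gene_class_counts.get(cls, 0)
        rows.append(
            {
                "gc_class": cls,
                "op_groups": group_count.get(cls, 0),
                "segments": n_seg,
                "genes": n_genes,
                "genes_per_segment": genes_per_segment(n_genes, n_seg),
            }
        )
    total_seg = sum(r["segments"] for r in rows)
    total_genes = sum(r["genes"] for r in rows)
    rows.append(
        {
            "gc_class": "Total",
            "op_groups": sum(r["op_groups"] for r in rows),
            "segments": total_seg,
            "genes": total_genes,
            "genes_per_segment": genes_per_segment(total_genes, total_seg),
        }
    )
    return pd.DataFrame(rows)
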