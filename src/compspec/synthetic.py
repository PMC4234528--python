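"""Synthetic genomes with planted organizational-pattern (OP) classes.

The generator emits everything the pipeline consumes — FASTA, BED gene
annotation, gene->term map — together with the ground truth, so that
segment clustering and term enrichment can be validated end to end.

Each OP class is realized as a set of "signature" sequence elements:
literal words, disjoint between classes, planted at a fixed per-kb rate
into i.i.d. background of the class's target GC.  Signature words are
drawn with their GC count matching the background target and residual GC
drift is compensated after planting, so all classes can sit inside one GC
bin: the classes differ organizationally (word usage), not
compositionally.  Signature elements default to 60 bp — long enough that
a random 10-mer probe set reliably samples their internal windows — and
eight per class.

Gene functional labels couple to the segment's OP class with tunable
strength ``coupling_beta``: with probability beta a gene receives the
term linked to its class, otherwise a uniformly random term.  beta = 0 is
the null (labels independent of organization); beta = 1 is deterministic
coupling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_CLASSES = ("op1", "op2", "op3")
DEFAULT_SEGMENTS_PER_CLASS = 40
DEFAULT_SEGMENT_LEN = 20_000
DEFAULT_GC_TARGET = 0.45
DEFAULT_PLANTING_RATE = 5.0  # placements per kb
DEFAULT_GENE_DENSITY = 0.39  # mean genes per segment (moderate-GC genome scale)
DEFAULT_GENE_LEN = 1_000
DEFAULT_N_TERMS = 9
DEFAULT_COUPLING_BETA = 0.8
DEFAULT_N_SIGNATURE_WORDS = 8
DEFAULT_SIGNATURE_WORD_LEN = 60


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``gc_target`` applies to every class by default, which keeps all
    segments in one GC bin and isolates the organizational signal; pass
    ``gc_target_per_class`` to spread classes over bins instead.
    """

    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_segments_per_class: int = DEFAULT_SEGMENTS_PER_CLASS
    segment_len: int = DEFAULT_SEGMENT_LEN
    n_chromosomes: int = 3
    gc_target: float = DEFAULT_GC_TARGET
    gc_target_per_class: Mapping[str, float] | None = None
    planting_rate: float = DEFAULT_PLANTING_RATE
    n_signature_words: int = DEFAULT_N_SIGNATURE_WORDS
    signature_word_len: int = DEFAULT_SIGNATURE_WORD_LEN
    gene_density: float = DEFAULT_GENE_DENSITY
    gene_len: int = DEFAULT_GENE_LEN
    n_terms: int = DEFAULT_N_TERMS
    coupling_beta: float = DEFAULT_COUPLING_BETA
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("need at least one OP class")
        if self.planting_rate < 0:
            raise ValueError("planting_rate must be >= 0")
        if not 0.0 <= self.coupling_beta <= 1.0:
            raise ValueError("coupling_beta must lie in [0, 1]")
        if self.n_terms < len(self.classes):
            raise ValueError("need at least one term per class")
        if self.gene_len > self.segment_len:
            raise ValueError("gene longer than segment")
        for gc in self.class_gc_targets().values():
            if not 0.0 < gc < 1.0:
                raise ValueError(f"gc_target {gc} must lie strictly inside (0, 1)")

    def class_gc_targets(self) -> dict[str, float]:
        if self.gc_target_per_class is not None:
            return dict(self.gc_target_per_class)
        return {c: self.gc_target for c in self.classes}


@dataclass(frozen=True)
class GroundTruth:
    """The latent structure behind one emitted dataset."""

    segment_to_class: dict[str, str]
    gene_to_segment: dict[str, str]
    gene_to_term: dict[str, str]
    class_to_term: dict[str, str]
    signature_words: dict[str, tuple[str, ...]]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["signature_words"] = {
            c: list(ws) for c, ws in self.signature_words.items()
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["signature_words"] = {
            c: tuple(ws) for c, ws in data["signature_words"].items()
        }
        return cls(**data)


def emit_background(length: int, gc_target: float, seed: int) -> str:
    """I.i.d. background with P(G) = P(C) = gc_target/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_target) / 2.0, gc_target / 2.0
    draw = rng.choice(4, size=length, p=[at, gc, gc, at])  # A C G T
    return _BASES[draw].tobytes().decode("ascii")


def _gc_count(arr: np.ndarray) -> int:
    return int(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))))


def plant_words(background: str, words: Sequence[str], rate: float, seed: int) -> str:
    """Overwrite ceil(rate * len/1000) non-overlapping positions with
    uniformly chosen signature words.

    Placements are uniform over all non-overlapping arrangements.  GC
    drift caused by planting is compensated by transition flips
    (A<->G, T<->C) at random background positions outside the planted
    blocks, restoring the pre-planting GC count exactly when enough
    background remains (best effort otherwise, logged).
    """
    if rate == 0 or not words:
        return background
    lengths = {len(w) for w in words}
    if len(lengths) != 1:
        raise ValueError("signature words must share one length")
    word_len = lengths.pop()
    n = len(background)
    if word_len >= n:
        raise ValueError("signature words must be shorter than the background")
    k = math.ceil(rate * n / 1000.0)
    free = n - k * word_len
    if free < 0:
        raise ValueError(
            f"planting rate {rate}/kb cannot place {k} non-overlapping "
            f"{word_len}-mers in {n} bp"
        )
    rng = np.random.default_rng(seed)
    # Uniform non-overlapping placement: choose k block slots among the
    # k + free token positions, then expand blocks to their full length.
    tokens = np.sort(rng.choice(free + k, size=k, replace=False))
    starts = tokens + np.arange(k) * (word_len - 1)

    arr = np.frombuffer(background.encode("ascii"), dtype=np.uint8).copy()
    gc_before = _gc_count(arr)
    planted_mask = np.zeros(n, dtype=bool)
    word_arrs = [np.frombuffer(w.encode("ascii"), dtype=np.uint8) for w in words]
    choices = rng.integers(0, len(words), size=k)
    for start, wi in zip(starts, choices):
        arr[start : start + word_len] = word_arrs[wi]
        planted_mask[start : start + word_len] = True

    deficit = gc_before - _gc_count(arr)  # >0: planting removed GC
    if deficit != 0:
        if deficit > 0:
            candidates = np.flatnonzero(
                ~planted_mask & ((arr == ord("A")) | (arr == ord("T")))
            )
            swap = {ord("A"): ord("G"), ord("T"): ord("C")}
        else:
            candidates = np.flatnonzero(
                ~planted_mask & ((arr == ord("G")) | (arr == ord("C")))
            )
            swap = {ord("G"): ord("A"), ord("C"): ord("T")}
        n_flip = min(abs(deficit), candidates.size)
        if n_flip < abs(deficit):
            logger.warning(
                "plant_words: GC compensation short by %d bases", abs(deficit) - n_flip
            )
        flip = rng.choice(candidates, size=n_flip, replace=False)
        for pos in flip:
            arr[pos] = swap[int(arr[pos])]
    return arr.tobytes().decode("ascii")


def _signature_word(rng: np.random.Generator, length: int, gc_count: int) -> str:
    """A random word with exactly ``gc_count`` G/C bases."""
    is_gc = np.zeros(length, dtype=bool)
    is_gc[rng.choice(length, size=gc_count, replace=False)] = True
    gc_draw = rng.integers(0, 2, size=length)  # 0: C/ A, 1: G/ T
    out = np.where(is_gc, np.where(gc_draw == 1, ord("G"), ord("C")),
                   np.where(gc_draw == 1, ord("T"), ord("A")))
    return out.astype(np.uint8).tobytes().decode("ascii")


def make_signature_words(spec: SyntheticSpec, seed: int) -> dict[str, tuple[str, ...]]:
    """Disjoint per-class signature word sets at the class GC target."""
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    out: dict[str, tuple[str, ...]] = {}
    for cls, gc in spec.class_gc_targets().items():
        gc_count = round(spec.signature_word_len * gc)
        words = []
        while len(words) < spec.n_signature_words:
            w = _signature_word(rng, spec.signature_word_len, gc_count)
            if w not in used:
                used.add(w)
                words.append(w)
        out[cls] = tuple(words)
    return out


def generate_synthetic_dataset(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[Path, Path, Path, GroundTruth]:
    """Emit FASTA, BED and term-map files plus the ground truth.

    Segments of all classes are generated, shuffled, and concatenated into
    chromosomes; genes are placed Poisson(gene_density) per segment with
    their term drawn by the coupling rule.  Returns
    ``(fasta_path, bed_path, termmap_path, ground_truth)``; the ground
    truth is also written as ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    signatures = make_signature_words(spec, sub_seed())
    gc_targets = spec.class_gc_targets()

    labelled: list[tuple[str, str]] = []  # (class, residues)
    for cls in spec.classes:
        for _ in range(spec.n_segments_per_class):
            bg = emit_background(spec.segment_len, gc_targets[cls], sub_seed())
            labelled.append(
                (cls, plant_words(bg, signatures[cls], spec.planting_rate, sub_seed()))
            )
    order = rng.permutation(len(labelled))
    labelled = [labelled[i] for i in order]

    chrom_chunks = np.array_split(np.arange(len(labelled)), spec.n_chromosomes)
    segment_to_class: dict[str, str] = {}
    segment_bounds: list[tuple[str, str, int]] = []  # (segment_id, chrom, start)
    fasta_path = outdir / "genome.fasta"
    with open(fasta_path, "w") as fh:
        for ci, chunk in enumerate(chrom_chunks):
            chrom = f"chr{ci + 1}"
            fh.write(f">{chrom}\n")
            pos = 0
            for idx in chunk:
                cls, residues = labelled[idx]
                seg_id = f"{chrom}:{pos}-{pos + spec.segment_len}"
                segment_to_class[seg_id] = cls
                segment_bounds.append((seg_id, chrom, pos))
                fh.write(residues + "\n")
                pos += spec.segment_len

    # Genes and their terms.
    linked = {cls: f"term_{cls}" for cls in spec.classes}
    decoys = [f"term_bg{i + 1}" for i in range(spec.n_terms - len(spec.classes))]
    all_terms = sorted(set(linked.values()) | set(decoys))
    gene_to_segment: dict[str, str] = {}
    gene_to_term: dict[str, str] = {}
    bed_path = outdir / "genes.bed"
    termmap_path = outdir / "terms.tsv"
    gene_counter = 0
    with open(bed_path, "w") as bed, open(termmap_path, "w") as tmap:
        for seg_id, chrom, seg_start in segment_bounds:
            cls = segment_to_class[seg_id]
            for _ in range(int(rng.poisson(spec.gene_density))):
                gene_counter += 1
                gene_id = f"g{gene_counter:05d}"
                start = seg_start + int(
                    rng.integers(0, spec.segment_len - spec.gene_len + 1)
                )
                bed.write(f"{chrom}\t{start}\t{start + spec.gene_len}\t{gene_id}\n")
                if rng.random() < spec.coupling_beta:
                    term = linked[cls]
                else:
                    term = all_terms[int(rng.integers(0, len(all_terms)))]
                tmap.write(f"{gene_id}\t{term}\n")
                gene_to_segment[gene_id] = seg_id
                gene_to_term[gene_id] = term

    truth = GroundTruth(
        segment_to_class=segment_to_class,
        gene_to_segment=gene_to_segment,
        gene_to_term=gene_to_term,
        class_to_term=linked,
        signature_words=signatures,
    )
    truth.to_json(outdir / "ground_truth.json")
    logger.info(
        "synthetic dataset: %d segments, %d genes, %d terms -> %s",
        len(segment_to_class), gene_counter, len(all_terms), outdir,
    )
    return fasta_path, bed_path, termmap_path, truth


def evaluate_recovery(
    predicted: Mapping[str, str], truth: Mapping[str, str]
) -> dict:
    """Adjusted Rand index and per-class precision/recall of a predicted
    segment partition against the planted classes.

    Each truth class is matched to the predicted group with the largest
    overlap; precision and recall refer to that match.
    """
    shared = sorted(set(predicted) & set(truth))
    if not shared:
        raise ValueError("predicted and truth share no segment ids")
    pred_labels = [predicted[s] for s in shared]
    true_labels = [truth[s] for s in shared]
    ari = float(adjusted_rand_score(true_labels, pred_labels))

    per_class = {}
    for cls in sorted(set(true_labels)):
        cls_ids = {s for s in shared if truth[s] == cls}
        overlap_by_group: dict[str, int] = {}
        for s in cls_ids:
            overlap_by_group[predicted[s]] = overlap_by_group.get(predicted[s], 0) + 1
        best_group, best_overlap = max(
            overlap_by_group.items(), key=lambda kv: (kv[1], kv[0])
        )
        group_size = sum(1 for s in shared if predicted[s] == best_group)
        per_class[cls] = {
            "matched_group": best_group,
            "precision": best_overlap / group_size,
            "recall": best_overlap / len(cls_ids),
        }
    return {"ari": ari, "n_segments": len(shared), "per_class": per_class}
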