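"""Genome segmentation, GC classification and annotation input.

Chromosome-scale sequences are cut into non-overlapping fixed-length
windows (100 kb by default) and each window is assigned to one of five GC
classes.  The class names (L1, L2, H1, H2, H3) follow the isochore-family
nomenclature, but the binning is a plain partition of the GC axis — no
isochore segmentation algorithm is involved.

Coordinates are 0-based half-open throughout.  BED input is taken as-is;
GFF3 is converted from its 1-based inclusive convention on input.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GC_CLASSES = ("L1", "L2", "H1", "H2", "H3")
#: Half-open bin edges on the GC fraction: L1 < 0.37 <= L2 < 0.42 <= H1 < 0.47 <= H2 < 0.52 <= H3
DEFAULT_GC_EDGES = (0.37, 0.42, 0.47, 0.52)
DEFAULT_WINDOW_LEN = 100_000
DEFAULT_MAX_AMBIGUOUS = 0.5

# Uppercase A/C/G/T survive; case is folded; every other symbol (IUPAC
# ambiguity codes included) becomes N.
_NORMALIZE_TABLE = str.maketrans(
    {i: "N" for i in range(256)}
    | {ord(c): c for c in "ACGTN"}
    | {ord(c): c.upper() for c in "acgtn"}
)


def normalize_residues(residues: str) -> str:
    """Fold case and collapse every non-ACGT symbol to N."""
    return residues.translate(_NORMALIZE_TABLE)


@dataclass(frozen=True)
class GenomeSequence:
    """One input sequence with residues normalized to the {A,C,G,T,N} alphabet."""

    seq_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Segment:
    """A fixed-length genomic window with its GC classification.

    ``gc_fraction`` is computed over unambiguous bases only and is ``None``
    when the window contains no unambiguous base at all (in which case the
    segment is never retained by :func:`segment_genome`).
    """

    segment_id: str
    seq_id: str
    start: int
    end: int
    gc_fraction: float | None
    gc_class: str | None
    ambiguous_fraction: float


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval in 0-based half-open coordinates."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if not self.seq_id:
            raise ValueError(f"gene {self.gene_id}: empty seq_id")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA file, normalizing residues.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    file with no FASTA records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        GenomeSequence(rec.id, normalize_residues(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def gc_content(residues: str) -> float:
    """GC fraction over unambiguous bases; raises on an all-N input."""
    g = residues.count("G")
    c = residues.count("C")
    unambiguous = len(residues) - residues.count("N")
    if unambiguous == 0:
        raise ValueError("undefined GC: no unambiguous bases")
    return (g + c) / unambiguous


def classify_gc(
    gc_fraction: float, bin_edges: Sequence[float] = DEFAULT_GC_EDGES
) -> str:
    """Assign a GC fraction to a class under half-open [lo, hi) binning.

    A value equal to an edge goes to the upper bin, so 0.42 is H1, not L2.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction {gc_fraction} outside [0, 1]")
    edges = tuple(bin_edges)
    if len(edges) != len(GC_CLASSES) - 1 or list(edges) != sorted(edges):
        raise ValueError(f"need {len(GC_CLASSES) - 1} sorted bin edges, got {edges}")
    return GC_CLASSES[bisect_right(edges, gc_fraction)]


def segment_genome(
    sequences: Sequence[GenomeSequence],
    window_len: int = DEFAULT_WINDOW_LEN,
    max_ambiguous_frac: float = DEFAULT_MAX_AMBIGUOUS,
    bin_edges: Sequence[float] = DEFAULT_GC_EDGES,
) -> list[Segment]:
    """Tile each sequence with non-overlapping fixed-length windows.

    Windows start at coordinate 0; the trailing partial window is
    discarded.  Windows whose ambiguous (N) fraction exceeds
    ``max_ambiguous_frac``, or that contain no unambiguous base, are
    dropped.  GC is computed over unambiguous bases only.
    """
    if window_len <= 0:
        raise ValueError(f"window_len must be positive, got {window_len}")
    if not 0.0 <= max_ambiguous_frac <= 1.0:
        raise ValueError("max_ambiguous_frac must lie in [0, 1]")

    segments: list[Segment] = []
    n_dropped = 0
    for seq in sequences:
        for start in range(0, seq.length - window_len + 1, window_len):
            end = start + window_len
            window = seq.residues[start:end]
            n_ambiguous = window.count("N")
            amb_frac = n_ambiguous / window_len
            if amb_frac > max_ambiguous_frac or n_ambiguous == window_len:
                n_dropped += 1
                continue
            gc = gc_content(window)
            segments.append(
                Segment(
                    segment_id=f"{seq.seq_id}:{start}-{end}",
                    seq_id=seq.seq_id,
                    start=start,
                    end=end,
                    gc_fraction=gc,
                    gc_class=classify_gc(gc, bin_edges),
                    ambiguous_fraction=amb_frac,
                )
            )
    if n_dropped:
        logger.info("segment_genome: dropped %d windows over the N threshold", n_dropped)
    return segments


def _read_bed(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            try:
                records.append(GeneRecord(name, parts[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def _read_gff3(path: Path, feature_type: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        # GFF3 is 1-based inclusive; convert to 0-based half-open.
        records.append(
            GeneRecord(
                gene_id,
                feat.seqid,
                feat.start - 1,
                feat.end,
                feat.strand if feat.strand in "+-" else ".",
            )
        )
    return records


def read_gene_annotation(
    path: str | Path, format: str = "bed", feature_type: str = "gene"
) -> list[GeneRecord]:
    """Read gene intervals from a BED (0-based) or GFF3 (1-based) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "gff3":
        return _read_gff3(path, feature_type)
    raise ValueError(f"unknown annotation format {format!r} (expected 'bed' or 'gff3')")


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    """Tabulate segments for TSV output."""
    return pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "seq_id": [s.seq_id for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "gc_fraction": [s.gc_fraction for s in segments],
            "gc_class": [s.gc_class for s in segments],
            "ambiguous_fraction": [s.ambiguous_fraction for s in segments],
        }
    )
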