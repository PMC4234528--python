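"""Gene-to-segment assignment and functional-term enrichment of OP groups.

Each OP group's pooled gene list is tested for over-representation of
every functional term against the background of all genes in the same GC
class, with a one-tailed hypergeometric (Fisher) test and
Benjamini-Hochberg correction across the terms of the group.  Terms are
opaque labels: no ontology structure is assumed.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from compspec.clustering import OPGroup
from compspec.segmentation import GeneRecord, Segment

logger = logging.getLogger(__name__)

DEFAULT_MIN_TERM_GENES = 3


@dataclass(frozen=True)
class TermMap:
    """Functional term -> gene-set mapping over a gene universe."""

    terms: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} maps genes outside the universe")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TermMap":
        """Build from (gene_id, term_id) pairs."""
        terms: dict[str, set[str]] = {}
        universe: set[str] = set()
        for gene, term in pairs:
            terms.setdefault(term, set()).add(gene)
            universe.add(gene)
        return cls(
            terms={t: frozenset(g) for t, g in sorted(terms.items())},
            universe=frozenset(universe),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermMap":
        """Two-column TSV: gene_id <tab> term_id."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected gene<TAB>term")
                pairs.append((parts[0], parts[1]))
        if not pairs:
            raise ValueError(f"no gene-term pairs in {path}")
        return cls.from_pairs(pairs)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "TermMap":
        """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected term, description, genes")
                pairs.extend((gene, parts[0]) for gene in parts[2:] if gene)
        return cls.from_pairs(pairs)


@dataclass(frozen=True)
class EnrichmentResult:
    """One (group, term) over-representation test.

    2x2 margins: k of the group's n genes carry the term; K of the N
    background genes carry it.  ``involved_segments`` are the group
    segments holding at least one of the k contributing genes.
    """

    group_id: str
    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    genes: tuple[str, ...]
    involved_segments: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.N >= max(self.K, self.n)):
            raise ValueError("inconsistent 2x2 margins")


def assign_genes_to_segments(
    genes: Sequence[GeneRecord], segments: Sequence[Segment]
) -> dict[str, str]:
    """Map each gene to the retained segment containing its start.

    The start-coordinate rule makes the mapping a function: a gene
    spanning a segment boundary counts once, in the segment where it
    begins.  Genes starting in dropped or untiled regions stay unmapped.
    """
    by_seq: dict[str, list[tuple[int, int, str]]] = {}
    for seg in segments:
        by_seq.setdefault(seg.seq_id, []).append((seg.start, seg.end, seg.segment_id))
    for intervals in by_seq.values():
        intervals.sort()

    mapping: dict[str, str] = {}
    unassigned = 0
    for gene in genes:
        intervals = by_seq.get(gene.seq_id, [])
        starts = [iv[0] for iv in intervals]
        idx = bisect_right(starts, gene.start) - 1
        if idx >= 0 and gene.start < intervals[idx][1]:
            mapping[gene.gene_id] = intervals[idx][2]
        else:
            unassigned += 1
    if unassigned:
        logger.info("assign_genes_to_segments: %d genes unassigned", unassigned)
    return mapping


def collect_group_genes(group: OPGroup, mapping: Mapping[str, str]) -> list[str]:
    """All genes mapped to the group's segments, deduplicated and sorted."""
    members = group.segment_ids
    return sorted({g for g, seg in mapping.items() if seg in members})


def benjamini_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    group_genes: Sequence[str],
    background_genes: Sequence[str],
    terms: TermMap,
    min_term_genes: int = DEFAULT_MIN_TERM_GENES,
    group_id: str = "",
    gene_to_segment: Mapping[str, str] | None = None,
    ease_penalty: bool = False,
) -> list[EnrichmentResult]:
    """One-tailed hypergeometric over-representation of every term in one
    gene group against its background.

    p_raw = P(X >= k) for X ~ Hypergeom(N, K, n).  With ``ease_penalty``
    one supporting gene is discounted (p = P(X >= k - 1) for k > 0), a
    conservative variant of the test.  Benjamini-Hochberg adjustment is
    applied across the tested terms of this group; results are ordered by
    raw p-value.
    """
    group = set(group_genes)
    background = set(background_genes)
    if not group <= background:
        raise ValueError("group genes must be a subset of the background")
    if not group:
        logger.info("fisher_enrichment[%s]: empty gene group", group_id)
        return []
    N = len(background)
    n = len(group)
    gene_to_segment = gene_to_segment or {}

    rows = []
    for term_id, term_genes in terms.terms.items():
        bg_term = term_genes & background
        K = len(bg_term)
        if K < min_term_genes:
            continue
        hit_genes = tuple(sorted(bg_term & group))
        k = len(hit_genes)
        k_eff = max(k - 1, 0) if ease_penalty else k
        p_raw = float(hypergeom.sf(k_eff - 1, N, K, n))  # P(X >= k_eff)
        involved = frozenset(
            gene_to_segment[g] for g in hit_genes if g in gene_to_segment
        )
        rows.append((term_id, k, K, p_raw, hit_genes, involved))
    if not rows:
        return []

    p_adj = benjamini_adjust([row[3] for row in rows])
    results = [
        EnrichmentResult(
            group_id=group_id,
            term_id=term_id,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p_raw,
            p_adj=float(q),
            genes=hit_genes,
            involved_segments=involved,
        )
        for (term_id, k, K, p_raw, hit_genes, involved), q in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_id": [r.group_id for r in results],
            "term_id": [r.term_id for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "genes": [",".join(r.genes) for r in results],
            "n_involved_segments": [len(r.involved_segments) for r in results],
        }
    )
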