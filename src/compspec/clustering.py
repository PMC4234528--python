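"""Spectrum distances, neighbor-joining trees and OP-group extraction.

The distance between two segments is d = 1 - r_s, where r_s is the
Spearman rank correlation between their compositional spectra; d ranges
over [0, 2] and is 0 for identical spectra.  Within each GC class the
pairwise distance matrix is clustered with neighbor joining (Saitou-Nei),
and organizational-pattern (OP) groups are read off the tree by cutting
the longest internal edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
import skbio
from scipy.stats import rankdata
from skbio.tree import TreeNode

logger = logging.getLogger(__name__)

DEFAULT_MIN_GROUP_SIZE = 20
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of pairwise spectrum distances."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=0.0):
            raise ValueError("distance matrix must be exactly symmetric")
        if np.any(np.diagonal(v) != 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0.0):
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class OPGroup:
    """A cluster of same-GC-class segments sharing an organizational pattern."""

    group_id: str
    gc_class: str
    segment_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.segment_ids)


def spearman_rho(f1: Sequence[float], f2: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties, computed as
    the Pearson correlation of the rank vectors."""
    x = np.asarray(f1, dtype=float)
    y = np.asarray(f2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        raise ValueError("undefined correlation: constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def cs_distance(s1, s2) -> float:
    """Spectrum distance d = 1 - r_s in [0, 2]; zero for identical spectra.

    Accepts :class:`~compspec.spectra.CompositionalSpectrum` objects or
    bare frequency vectors.
    """
    f1 = getattr(s1, "frequencies", s1)
    f2 = getattr(s2, "frequencies", s2)
    if f1 is None or f2 is None:
        raise ValueError("undefined spectrum (M = 0) has no distance")
    if len(f1) != len(f2):
        raise ValueError("spectra computed over different word sets")
    return max(0.0, 1.0 - spearman_rho(f1, f2))


def distance_matrix(spectra: Sequence) -> DistanceMatrix:
    """All pairwise spectrum distances, computed in one ranking pass."""
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    ids = tuple(s.segment_id for s in spectra)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate segment ids")
    freqs = np.vstack([s.frequencies for s in spectra])
    ranks = rankdata(freqs, axis=1)
    if np.any(np.ptp(ranks, axis=1) == 0.0):
        raise ValueError("undefined correlation: constant spectrum")
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # exact symmetry against fp noise
    return DistanceMatrix(ids=ids, values=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths are clamped to
    zero.  Leaves are processed in lexicographic id order so that ties in
    the Q-matrix break deterministically."""
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    order = np.argsort(np.asarray(dm.ids))
    sorted_ids = [dm.ids[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    skbio_dm = skbio.DistanceMatrix(values, ids=sorted_ids)
    tree = skbio.tree.nj(skbio_dm)
    clamped = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            clamped += -node.length
            node.length = 0.0
    if clamped:
        logger.info("neighbor_joining: clamped %.3g of negative branch length", clamped)
    return tree


def tree_to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def _internal_edges(tree: TreeNode) -> list[tuple[float, str, TreeNode]]:
    """Internal edges as (length, tiebreak-id, child-node).  The tiebreak
    id is the lexicographically smallest leaf name below the edge."""
    edges = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        length = node.length if node.length is not None else 0.0
        min_leaf = min(tip.name for tip in node.tips())
        edges.append((float(length), min_leaf, node))
    return edges


def _components(tree: TreeNode, cut_nodes: set[int]) -> list[set[str]]:
    """Leaf partition induced by cutting the edges above ``cut_nodes``:
    each leaf belongs to its nearest cut ancestor (or to the root)."""
    comp_of: dict[str, int] = {}
    components: dict[int, set[str]] = {id(tree): set()}
    for tip in tree.tips():
        node = tip
        holder = id(tree)
        while node.parent is not None:
            if id(node) in cut_nodes:
                holder = id(node)
                break
            node = node.parent
        components.setdefault(holder, set()).add(tip.name)
    return [leaves for leaves in components.values() if leaves]


def extract_op_groups(
    tree: TreeNode,
    gc_class: str,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
    n_groups: int | None = None,
    threshold: float | None = None,
) -> tuple[list[OPGroup], set[str]]:
    """Partition tree leaves into OP groups by cutting long internal edges.

    Either ``n_groups`` (cut the longest internal edges until that many
    components exist) or ``threshold`` (cut every internal edge at least
    that long) must be given.  Components smaller than ``min_size`` are
    pooled as unassigned.  Groups are labelled "{gc_class}-a", "-b", ... in
    decreasing size order (ties broken by smallest member id).

    Returns ``(groups, unassigned_leaf_ids)``.
    """
    if (n_groups is None) == (threshold is None):
        raise ValueError("give exactly one of n_groups or threshold")
    leaves = [tip.name for tip in tree.tips()]
    n_leaves = len(leaves)
    if n_groups is not None and n_groups > n_leaves:
        raise ValueError(f"n_groups ({n_groups}) exceeds leaf count ({n_leaves})")

    edges = sorted(_internal_edges(tree), key=lambda e: (-e[0], e[1]))
    if n_groups is not None:
        cut = edges[: max(0, n_groups - 1)]
    else:
        cut = [e for e in edges if e[0] >= threshold]
    parts = _components(tree, {id(node) for _, _, node in cut})

    kept = sorted(
        (p for p in parts if len(p) >= min_size), key=lambda p: (-len(p), min(p))
    )
    unassigned = set().union(*(p for p in parts if len(p) < min_size), set())
    groups = [
        OPGroup(
            group_id=f"{gc_class}-{_group_letter(i)}",
            gc_class=gc_class,
            segment_ids=frozenset(part),
        )
        for i, part in enumerate(kept)
    ]
    if unassigned:
        logger.info(
            "extract_op_groups[%s]: %d leaves unassigned (components under min_size=%d)",
            gc_class, len(unassigned), min_size,
        )
    return groups, unassigned


def _group_letter(index: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    if index < len(letters):
        return letters[index]
    return f"g{index + 1}"
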