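"""Non-randomness test: real OP groups versus size-matched random groups.

Within each GC class, segments are redistributed at random into groups of
the same sizes as the real OP groups; the redistribution is repeated
(10 times by default) and every random group runs through the identical
enrichment analysis.  Real and random groups are then compared on

* the proportion of groups enriched in at least one term (two-tailed
  Fisher exact test on the 2x2 group counts), and
* per-group characteristics — the -log10 adjusted p-values of enriched
  terms, the number of enriched terms, the number of "involved" segments
  (segments holding a gene that supports an enriched term) and the
  involved/total segment ratio — each compared with a tie-corrected
  Mann-Whitney U test.

Only "non-empty" groups (enriched in at least one term) enter the
characteristic distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, norm, rankdata

from compspec.clustering import OPGroup
from compspec.enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

DEFAULT_N_REPLICATES = 10
DEFAULT_ALPHA = 0.05

CHARACTERISTICS = ("neglog10_p", "n_go_terms", "n_involved_segments", "involved_ratio")


def make_random_groups(
    segments_by_gc: Mapping[str, Sequence[str]],
    group_sizes: Mapping[str, Sequence[int]],
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> list[list[OPGroup]]:
    """Size-matched random segment groups, ``n_replicates`` independent sets.

    Within each replicate and GC class the groups are disjoint (sampled
    without replacement); leftover segments go unused.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    for gc_class, sizes in group_sizes.items():
        available = len(segments_by_gc.get(gc_class, ()))
        if sum(sizes) > available:
            raise ValueError(
                f"{gc_class}: requested {sum(sizes)} segments but only {available} available"
            )
    replicates: list[list[OPGroup]] = []
    for rep in range(n_replicates):
        groups: list[OPGroup] = []
        for gc_class in sorted(group_sizes):
            pool = np.array(sorted(segments_by_gc[gc_class]))
            rng.shuffle(pool)
            offset = 0
            for gi, size in enumerate(group_sizes[gc_class]):
                members = frozenset(pool[offset : offset + size].tolist())
                offset += size
                groups.append(
                    OPGroup(
                        group_id=f"rep{rep}-{gc_class}-r{gi}",
                        gc_class=gc_class,
                        segment_ids=members,
                    )
                )
        replicates.append(groups)
    return replicates


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the table [[a, b], [c, d]], summing
    all same-margin tables no more probable than the observed one."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], continuity: bool = False
) -> tuple[float, float, float]:
    """Mann-Whitney U with the tie-corrected normal approximation.

    Returns ``(U, Z, p_two_tailed)`` with U = min(U_x, U_y).  Z is signed
    from U_x, so Z > 0 means x tends to exceed y.  The continuity
    correction is off by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    u_y = nx * ny - u_x
    u = min(u_x, u_y)

    n_tot = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = nx * ny / 12.0 * ((n_tot + 1) - tie_term / (n_tot * (n_tot - 1)))
    if var <= 0.0:
        return u, 0.0, 1.0
    diff = u_x - nx * ny / 2.0
    if continuity and diff != 0.0:
        diff -= 0.5 * math.copysign(1.0, diff)
    z = diff / math.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return u, float(z), min(p, 1.0)


@dataclass(frozen=True)
class GroupCharacteristics:
    """Per-group summary of the enrichment outcome at level alpha."""

    group_id: str
    n_segments: int
    enriched: bool
    neglog10_p: tuple[float, ...]  # -log10(p_adj) of each enriched term
    n_go_terms: int
    n_involved_segments: int
    involved_ratio: float


def summarize_group_characteristics(
    groups: Sequence[OPGroup],
    enrichments: Sequence[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
) -> list[GroupCharacteristics]:
    """Per-group characteristics; a group counts as enriched when at least
    one term reaches adjusted p <= alpha.  Involved segments are the union
    over enriched terms of segments holding a supporting gene."""
    by_group: dict[str, list[EnrichmentResult]] = {}
    for res in enrichments:
        by_group.setdefault(res.group_id, []).append(res)

    out = []
    for group in groups:
        hits = [
            r for r in by_group.get(group.group_id, []) if r.p_adj <= alpha
        ]
        involved: set[str] = set()
        for r in hits:
            involved |= r.involved_segments
        out.append(
            GroupCharacteristics(
                group_id=group.group_id,
                n_segments=group.size,
                enriched=bool(hits),
                neglog10_p=tuple(-math.log10(max(r.p_adj, 1e-300)) for r in hits),
                n_go_terms=len(hits),
                n_involved_segments=len(involved),
                involved_ratio=len(involved) / group.size if group.size else 0.0,
            )
        )
    return out


@dataclass(frozen=True)
class MWRecord:
    """One Mann-Whitney comparison of a group characteristic."""

    characteristic: str
    mean_real: float | None
    se_real: float | None
    mean_random: float | None
    se_random: float | None
    U: float | None
    Z: float | None
    p: float | None
    skipped: bool = False


@dataclass(frozen=True)
class ComparisonReport:
    """Real-vs-random comparison: Fisher 2x2 on enriched-group counts and
    Mann-Whitney tests on the per-group characteristics."""

    n_real_groups: int
    n_real_enriched: int
    n_random_groups: int
    n_random_enriched: int
    fisher_p_two_tailed: float
    mw_tests: tuple[MWRecord, ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mw_tests"] = [asdict(t) for t in self.mw_tests]
        return d


def _characteristic_values(
    chars: Sequence[GroupCharacteristics], name: str
) -> list[float]:
    enriched = [c for c in chars if c.enriched]
    if name == "neglog10_p":
        return [v for c in enriched for v in c.neglog10_p]
    return [float(getattr(c, name)) for c in enriched]


def _mean_se(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return mean, se


def compare_real_vs_random(
    real_chars: Sequence[GroupCharacteristics],
    random_chars: Sequence[GroupCharacteristics],
    continuity: bool = False,
) -> ComparisonReport:
    """Compare real OP groups with pooled random groups.

    Characteristic values from all random replicates are pooled into a
    single random-side distribution, matching the one-shot real-vs-random
    design.  A characteristic with fewer than 2 values on either side is
    skipped and flagged.
    """
    n_real = len(real_chars)
    n_random = len(random_chars)
    enr_real = sum(c.enriched for c in real_chars)
    enr_random = sum(c.enriched for c in random_chars)
    fisher_p = fisher_2x2(
        enr_real, n_real - enr_real, enr_random, n_random - enr_random
    )

    mw_records = []
    for name in CHARACTERISTICS:
        xs = _characteristic_values(real_chars, name)
        ys = _characteristic_values(random_chars, name)
        mean_x, se_x = _mean_se(xs)
        mean_y, se_y = _mean_se(ys)
        if len(xs) < 2 or len(ys) < 2:
            logger.info("compare_real_vs_random: %s skipped (too few values)", name)
            mw_records.append(
                MWRecord(name, mean_x, se_x, mean_y, se_y, None, None, None, skipped=True)
            )
            continue
        u, z, p = mann_whitney_u(xs, ys, continuity=continuity)
        mw_records.append(MWRecord(name, mean_x, se_x, mean_y, se_y, u, z, p))

    return ComparisonReport(
        n_real_groups=n_real,
        n_real_enriched=enr_real,
        n_random_groups=n_random,
        n_random_enriched=enr_random,
        fisher_p_two_tailed=fisher_p,
        mw_tests=tuple(mw_records),
    )
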