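"""Random group sampling, exact tests and the real-vs-random comparison."""

import itertools
from math import comb

import numpy as np
import pytest
import scipy.stats

from compspec.clustering import OPGroup
from compspec.enrichment import EnrichmentResult
from compspec.randomization import (
    compare_real_vs_random,
    fisher_2x2,
    make_random_groups,
    mann_whitney_u,
    summarize_group_characteristics,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive minimum-likelihood two-tailed Fisher p: sum the
    probabilities of all same-margin tables no more probable than the
    observed one (relative tolerance 1e-7)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def mw_u_oracle(x, y):
    """U statistic by brute-force pair counting (ties count one half)."""
    u_x = sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)
    return min(u_x, len(x) * len(y) - u_x)


class TestMakeRandomGroups:
    SEGMENTS = {"L2": [f"s{i}" for i in range(10)], "H1": [f"t{i}" for i in range(6)]}
    SIZES = {"L2": [3, 2], "H1": [4]}

    def test_sizes_and_disjointness(self):
        reps = make_random_groups(self.SEGMENTS, self.SIZES, n_replicates=4, seed=1)
        assert len(reps) == 4
        for rep in reps:
            by_class = {}
            for g in rep:
                by_class.setdefault(g.gc_class, []).append(g)
            assert sorted(g.size for g in by_class["L2"]) == [2, 3]
            used = set()
            for g in rep:
                assert not (g.segment_ids & used)
                used |= g.segment_ids
                assert g.segment_ids <= set(self.SEGMENTS[g.gc_class])

    def test_ten_replicates_of_31_groups_give_310(self):
        segments = {"L2": [f"s{i}" for i in range(200)]}
        sizes = {"L2": [5] * 31}
        reps = make_random_groups(segments, sizes, n_replicates=10, seed=0)
        assert sum(len(rep) for rep in reps) == 310

    def test_deterministic_under_seed(self):
        a = make_random_groups(self.SEGMENTS, self.SIZES, 3, seed=9)
        b = make_random_groups(self.SEGMENTS, self.SIZES, 3, seed=9)
        assert [[g.segment_ids for g in rep] for rep in a] == [
            [g.segment_ids for g in rep] for rep in b
        ]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="available"):
            make_random_groups({"L2": ["s1", "s2"]}, {"L2": [2, 1]}, 1, seed=0)


class TestFisher2x2:
    def test_symmetric_table(self):
        assert fisher_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_complete_separation(self):
        assert fisher_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-9)

    def test_printed_group_counts(self):
        # 13/31 real vs 65/310 random enriched groups; standard two-tailed
        # value, cross-checked against R's fisher.test
        assert fisher_2x2(13, 18, 65, 245) == pytest.approx(0.012722, abs=5e-7)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(150):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-7
            )

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)


class TestMannWhitneyU:
    def test_complete_separation(self):
        u, z, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert z < 0  # x below y

    def test_interleaved_pairs(self):
        u, _, _ = mann_whitney_u([1, 3], [2, 4])
        assert u == 1.0

    def test_identical_samples(self):
        u, z, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert z == 0.0
        assert p == 1.0

    def test_u_matches_pair_counting_oracle(self, rng):
        for _ in range(60):
            nx = int(rng.integers(1, 51))
            ny = int(rng.integers(1, 51))
            x = rng.integers(0, 10, size=nx).astype(float)  # heavy ties
            y = rng.integers(0, 10, size=ny).astype(float)
            u, _, _ = mann_whitney_u(x, y)
            assert u == pytest.approx(mw_u_oracle(x, y), abs=1e-9)

    def test_z_and_p_match_scipy_tie_corrected(self, rng):
        for _ in range(25):
            x = rng.integers(0, 6, size=12).astype(float)
            y = rng.integers(0, 6, size=15).astype(float)
            _, z, p = mann_whitney_u(x, y)
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _result(group_id, term_id, p_adj, involved, n=10, N=100):
    k = len(involved) or 1
    return EnrichmentResult(
        group_id=group_id, term_id=term_id, k=k, K=max(k, 5), n=n, N=N,
        p_raw=p_adj / 2, p_adj=p_adj,
        genes=tuple(f"g{i}" for i in range(k)),
        involved_segments=frozenset(involved),
    )


class TestSummarizeGroupCharacteristics:
    def test_neglog10_of_enriched_term(self):
        group = OPGroup("L2-a", "L2", frozenset(f"s{i}" for i in range(40)))
        res = _result("L2-a", "T1", 0.001, {"s1", "s2"})
        (chars,) = summarize_group_characteristics([group], [res], alpha=0.05)
        assert chars.enriched
        assert chars.neglog10_p == pytest.approx((3.0,))
        assert chars.n_go_terms == 1
        assert chars.n_involved_segments == 2
        assert chars.involved_ratio == pytest.approx(0.05)

    def test_involved_segments_union_over_terms(self):
        group = OPGroup("L2-a", "L2", frozenset(f"s{i}" for i in range(10)))
        results = [
            _result("L2-a", "T1", 0.01, {"s1", "s2"}),
            _result("L2-a", "T2", 0.02, {"s2", "s3"}),
            _result("L2-a", "T3", 0.50, {"s9"}),  # not enriched at 0.05
        ]
        (chars,) = summarize_group_characteristics([group], results, alpha=0.05)
        assert chars.n_go_terms == 2
        assert chars.n_involved_segments == 3

    def test_group_without_enrichment(self):
        group = OPGroup("H1-a", "H1", frozenset({"s1", "s2"}))
        (chars,) = summarize_group_characteristics([group], [], alpha=0.05)
        assert not chars.enriched
        assert chars.neglog10_p == ()


class TestCompareRealVsRandom:
    def _chars(self, flags, values, prefix):
        groups, results = [], []
        for i, (flag, val) in enumerate(zip(flags, values)):
            gid = f"{prefix}{i}"
            groups.append(OPGroup(gid, "L2", frozenset({f"{gid}-s1", f"{gid}-s2"})))
            if flag:
                results.append(_result(gid, "T", val, {f"{gid}-s1"}))
        return summarize_group_characteristics(groups, results, alpha=0.05)

    def test_printed_flag_counts(self):
        real = self._chars([True] * 13 + [False] * 18, [0.01] * 31, "r")
        random = self._chars([True] * 65 + [False] * 245, [0.01] * 310, "q")
        report = compare_real_vs_random(real, random)
        assert report.n_real_enriched == 13
        assert report.n_random_enriched == 65
        assert report.fisher_p_two_tailed == pytest.approx(0.012722, abs=5e-7)

    def test_identical_distributions_give_null_z(self):
        vals = [0.001, 0.002, 0.005, 0.01] * 2
        real = self._chars([True] * 8, vals, "r")
        random = self._chars([True] * 8, vals, "q")
        report = compare_real_vs_random(real, random)
        mw = {t.characteristic: t for t in report.mw_tests}
        assert mw["neglog10_p"].Z == pytest.approx(0.0, abs=1e-12)
        assert mw["neglog10_p"].p == pytest.approx(1.0)

    def test_sparse_side_is_skipped(self):
        real = self._chars([True, False], [0.01, 0.5], "r")
        random = self._chars([True] * 4, [0.01] * 4, "q")
        report = compare_real_vs_random(real, random)
        assert all(t.skipped for t in report.mw_tests)

    def test_report_serializes(self):
        real = self._chars([True] * 3, [0.01, 0.02, 0.03], "r")
        random = self._chars([True] * 3, [0.01, 0.02, 0.03], "q")
        d = compare_real_vs_random(real, random).to_dict()
        assert d["n_real_groups"] == 3
        assert len(d["mw_tests"]) == 4
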