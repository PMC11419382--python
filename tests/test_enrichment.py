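import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratecov import (
    PairScoreRecord,
    focal_pairs,
    occurrence_enrichment,
    signed_fold_change,
    top_quantile,
)


def _records(scores, prefix="p"):
    return [
        PairScoreRecord(gene_a=f"{prefix}{i:06d}", gene_b=f"q{i:06d}", fterc=float(s))
        for i, s in enumerate(scores)
    ]


class TestTopQuantile:
    def test_single_max_from_100(self):
        rng = np.random.default_rng(0)
        recs = _records(rng.permutation(100))
        top = top_quantile(recs, q=0.01)
        assert top.T == 1
        assert top.records[0].fterc == 99.0

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=4000),
        q=st.floats(min_value=1e-4, max_value=0.999),
    )
    def test_ceiling_rule(self, n, q):
        recs = _records(np.arange(n))
        assert top_quantile(recs, q).T == math.ceil(q * n)

    def test_every_included_geq_every_excluded(self):
        rng = np.random.default_rng(1)
        recs = _records(rng.normal(size=500))
        top = top_quantile(recs, q=0.05)
        included = {r.key for r in top.records}
        mn = min(r.fterc for r in top.records)
        mx_excluded = max(r.fterc for r in recs if r.key not in included)
        assert mn >= mx_excluded

    def test_tie_break_deterministic_oracle(self):
        """5 records tied at the cutoff: selection matches an independent
        sort by (-score, pair id)."""
        scores = list(range(200))
        for i in range(5):
            scores[i] = 195  # ties with the real 195
        recs = _records(scores)
        top = top_quantile(recs, q=0.03)  # T = 6
        oracle = sorted(recs, key=lambda r: (-r.fterc, r.gene_a, r.gene_b))[:6]
        assert [r.key for r in top.records] == [r.key for r in oracle]

    def test_empty_and_bad_q(self):
        with pytest.raises(ValueError):
            top_quantile([], 0.01)
        with pytest.raises(ValueError):
            top_quantile(_records([1.0]), 1.5)


class TestSignedFold:
    def test_equal_is_one(self):
        assert signed_fold_change(189.5, 189.5) == 1.0

    def test_never_in_open_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            o = float(rng.integers(0, 50))
            e = float(rng.uniform(0.5, 50))
            f = signed_fold_change(o, e)
            assert f >= 1.0 or f <= -1.0

    def test_depletion_sentinel(self):
        assert signed_fold_change(0, 10.0) == float("-inf")


class TestOccurrenceEnrichment:
    def _top_with_counts(self, counts, extra_pairs=0):
        """Build a top set whose focal proteins appear with given counts."""
        recs = []
        k = 0
        for protein, c in counts.items():
            for _ in range(c):
                recs.append(
                    PairScoreRecord(
                        gene_a=protein, gene_b=f"z{k:06d}", fterc=10.0
                    )
                )
                k += 1
        from ratecov.enrichment import TopQuantileSet

        return TopQuantileSet(q=0.01, cutoff=10.0, records=recs, n_total=100 * len(recs))

    def test_paper_style_worked_example(self):
        """T=5685 over K=30: O=552 -> fold +2.91, O=526 -> +2.78, O=8 ->
        -(189.5/8) = -23.69 (2 d.p.)."""
        counts = {"PIGG": 552, "PIGW": 526, "PIGY": 8}
        rest = 5685 - sum(counts.values())
        others = {f"F{i:02d}": rest // 27 for i in range(27)}
        others["F00"] += rest - 27 * (rest // 27)
        counts.update(others)
        top = self._top_with_counts(counts)
        assert top.T == 5685
        res = occurrence_enrichment(top, list(counts))
        assert res.expected == pytest.approx(5685 / 30)
        row = res.for_protein("PIGG")
        assert round(row["fold"], 2) == 2.91
        assert row["direction"] == "over"
        assert round(res.for_protein("PIGW")["fold"], 2) == 2.78
        assert round(res.for_protein("PIGY")["fold"], 2) == -23.69
        assert res.for_protein("PIGY")["direction"] == "under"

    def test_observed_equal_expected(self):
        counts = {f"F{i}": 10 for i in range(5)}
        top = self._top_with_counts(counts)
        res = occurrence_enrichment(top, list(counts))
        row = res.for_protein("F0")
        assert row["fold"] == 1.0
        assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert row["direction"] == "ns"

    def test_chi2_one_vs_rest_formula(self):
        counts = {"A": 30, "B": 10}
        top = self._top_with_counts(counts)
        res = occurrence_enrichment(top, ["A", "B"])
        T, E = 40, 20.0
        for protein, o in counts.items():
            expect = (o - E) ** 2 / E + ((T - o) - (T - E)) ** 2 / (T - E)
            assert res.for_protein(protein)["chi2"] == pytest.approx(expect, rel=1e-12)

    def test_double_count_shared_pairs(self):
        recs = [
            PairScoreRecord(gene_a="A", gene_b="B", fterc=5.0),
            PairScoreRecord(gene_a="A", gene_b="x1", fterc=4.0),
        ]
        from ratecov.enrichment import TopQuantileSet

        top = TopQuantileSet(q=0.01, cutoff=4.0, records=recs, n_total=200)
        res = occurrence_enrichment(top, ["A", "B"])
        assert int(res.for_protein("A")["observed"]) == 2
        assert int(res.for_protein("B")["observed"]) == 1
        assert res.table["observed"].sum() == 3  # > T: both-focal pair counts twice

    def test_zero_occurrence_flagged(self):
        counts = {"A": 20, "B": 0}
        recs = self._top_with_counts({"A": 20})
        res = occurrence_enrichment(recs, ["A", "B"])
        row = res.for_protein("B")
        assert row["zero_flag"]
        assert row["fold"] == float("-inf")

    def test_nonfocal_top_pair_rejected(self):
        recs = [PairScoreRecord(gene_a="u1", gene_b="u2", fterc=5.0)]
        from ratecov.enrichment import TopQuantileSet

        top = TopQuantileSet(q=0.01, cutoff=5.0, records=recs, n_total=100)
        with pytest.raises(ValueError, match="no focal gene"):
            occurrence_enrichment(top, ["A", "B"])

    def test_calibrated_false_positive_rate(self):
        """With focal proteins exchangeable (occurrences multinomial-even),
        ~5% are called significant at p < 0.05."""
        rng = np.random.default_rng(6)
        K, reps, T = 20, 100, 2000
        flags = []
        from ratecov.enrichment import TopQuantileSet

        for _ in range(reps):
            assignment = rng.integers(0, K, size=T)
            counts = {f"F{i:02d}": int((assignment == i).sum()) for i in range(K)}
            top = self._top_with_counts(counts)
            res = occurrence_enrichment(top, list(counts))
            flags.extend(res.table["direction"] != "ns")
        rate = np.mean(flags)
        # binomial 99.9% band around 0.05 at n = K * reps
        assert 0.03 < rate < 0.075


class TestFocalPairs:
    def test_all_pairs_touch_focal(self, module_matrix):
        focal = [f"G{i:04d}" for i in range(1, 11)]
        pairs = focal_pairs(module_matrix, focal)
        fs = set(focal)
        assert pairs
        assert all({p.gene_a, p.gene_b} & fs for p in pairs)

    def test_top_enrichment_flows_from_matrix(self, module_matrix):
        focal = [f"G{i:04d}" for i in range(1, 11)]
        pairs = focal_pairs(module_matrix, focal)
        top = top_quantile(pairs, q=0.05)
        res = occurrence_enrichment(top, focal)
        assert res.T == math.ceil(0.05 * len(pairs))
        # module genes covary with each other, so every top pair touches
        # at least one focal gene by construction and counts sum >= T
        assert res.table["observed"].sum() >= res.T
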