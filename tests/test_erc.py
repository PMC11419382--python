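import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ratecov import (
    CladePairStat,
    RERMatrix,
    build_erc_matrix,
    clade_pair_stat,
    fisher_z,
    integrate_pair,
    significance_threshold,
)


def _rer_from_array(arr, clade="c", genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=genes, columns=[f"b{i}" for i in range(arr.shape[1])])
    df = df.sub(df.mean(axis=1, skipna=True), axis=0)  # RERs are row-centered
    return RERMatrix(clade_id=clade, rer=df, n_usable=df.notna().sum(axis=1))


class TestCladePairStat:
    def test_identical_vectors_r_one(self):
        v = np.sin(np.arange(20))
        rer = _rer_from_array([v, v])
        stat = clade_pair_stat(rer, "g0", "g1")
        assert stat.r == pytest.approx(1.0, abs=1e-12)
        assert stat.n == 20

    def test_orthogonal_blocks_r_zero(self):
        x = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        rer = _rer_from_array([x, y])
        stat = clade_pair_stat(rer, "g0", "g1")
        assert stat.r == pytest.approx(0.0, abs=1e-12)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 30))
        rer = _rer_from_array([x, y])
        r = clade_pair_stat(rer, "g0", "g1").r
        xc, yc = x - x.mean(), y - y.mean()
        expect = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_too_few_shared_branches_absent(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan])
        y = np.array([np.nan, 2.0, 1.0, 4.0, 1.0, np.nan])
        rer = _rer_from_array([x, y])
        assert clade_pair_stat(rer, "g0", "g1", n_min=5) is None

    def test_zero_variance_absent(self):
        rer = _rer_from_array([np.zeros(10), np.arange(10.0)])
        assert clade_pair_stat(rer, "g0", "g1") is None

    def test_unknown_gene_keyerror(self):
        rer = _rer_from_array([np.arange(6.0)])
        with pytest.raises(KeyError):
            clade_pair_stat(rer, "g0", "nope")


class TestFisherZ:
    def test_zero_r(self):
        assert fisher_z(CladePairStat("c", 0.0, 50)) == 0.0

    def test_closed_form(self):
        z = fisher_z(CladePairStat("c", 0.5, 12))
        assert z == pytest.approx(math.atanh(0.5) * 3, abs=1e-12)
        assert z == pytest.approx(1.64792, abs=1e-5)

    def test_clamped_perfect_correlation(self):
        # atanh(1 - 1e-6) * sqrt(25) = 7.254329 * 5
        z = fisher_z(CladePairStat("c", 1.0, 28))
        assert z == pytest.approx(36.27164, abs=1e-4)
        assert math.isfinite(z)

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            fisher_z(CladePairStat("c", 0.5, 3))

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(-0.95, 0.95, 21)
        zs = [fisher_z(CladePairStat("c", r, 20)) for r in rs]
        assert all(b > a for a, b in zip(zs, zs[1:]))
        ns = range(4, 40)
        zn = [fisher_z(CladePairStat("c", 0.4, n)) for n in ns]
        assert all(b > a for a, b in zip(zn, zn[1:]))


class TestIntegratePair:
    def test_sum(self):
        stats = [CladePairStat("a", math.tanh(1.2 / math.sqrt(7)), 10),
                 CladePairStat("b", math.tanh(-0.3 / math.sqrt(7)), 10),
                 CladePairStat("c", math.tanh(2.0 / math.sqrt(7)), 10)]
        assert integrate_pair(stats) == pytest.approx(2.9, abs=1e-9)

    def test_single_clade_passthrough(self):
        s = CladePairStat("a", 0.3, 15)
        assert integrate_pair([s]) == pytest.approx(fisher_z(s))

    def test_empty_is_absent_not_zero(self):
        assert integrate_pair([]) is None


class TestBuildMatrix:
    def test_complete_data_pair_count(self):
        rng = np.random.default_rng(1)
        rer = _rer_from_array(rng.normal(size=(10, 20)))
        m = build_erc_matrix([rer])
        assert m.pair_values().size == 45  # C(10, 2)

    def test_gene_absent_everywhere_scores_no_pairs(self):
        rng = np.random.default_rng(2)
        rer = _rer_from_array(rng.normal(size=(4, 20)))
        m = build_erc_matrix([rer], universe=[f"g{i}" for i in range(5)])
        assert "g4" in m
        assert np.isnan(m.fterc[m.index_of(["g4"])[0]]).all()

    def test_symmetry(self, module_matrix):
        f = module_matrix.fterc
        np.testing.assert_array_equal(f, f.T)
        assert module_matrix.erc("G0001", "G0002") == module_matrix.erc("G0002", "G0001")

    def test_compositional_oracle(self):
        """Matrix equals pair-by-pair clade_pair_stat + integrate_pair."""
        rng = np.random.default_rng(5)
        rers = []
        for c in range(3):
            arr = rng.normal(size=(15, 25))
            arr[rng.random(arr.shape) < 0.2] = np.nan
            rers.append(_rer_from_array(arr, clade=f"c{c}"))
        m = build_erc_matrix(rers, n_min=5)
        genes = m.genes
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                stats = []
                for rer in rers:
                    s = clade_pair_stat(rer, genes[i], genes[j], n_min=5)
                    if s is not None:
                        stats.append(s)
                expect = integrate_pair(stats)
                got = m.erc(genes[i], genes[j])
                if expect is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-9)

    def test_null_fterc_sd_scales_with_sqrt_clades(self):
        """Each clade z is ~standard normal under the null, so the
        integrated score's SD is ~sqrt(n_clades)."""
        rng = np.random.default_rng(9)
        rers = [
            _rer_from_array(rng.normal(size=(60, 50)), clade=f"c{c}")
            for c in range(5)
        ]
        m = build_erc_matrix(rers)
        sd = m.pair_values().std()
        assert sd == pytest.approx(math.sqrt(5), rel=0.1)


class TestThreshold:
    def test_printed_summary_value(self):
        """mean 0.12, SD 1.47 -> threshold 3.06 (the 'ERC >= 3' rule)."""
        rng = np.random.default_rng(0)
        rer = _rer_from_array(rng.normal(size=(40, 30)))
        m = build_erc_matrix([rer])
        vals = m.pair_values()
        # affinely standardize the scored values to the printed summary
        iu, ju = np.triu_indices(m.n_genes, k=1)
        z = (m.fterc - vals.mean()) / vals.std(ddof=1)
        m.fterc = 0.12 + 1.47 * z
        assert significance_threshold(m) == pytest.approx(3.06, abs=1e-9)

    def test_degenerate_equal_values(self):
        rer = _rer_from_array(np.random.default_rng(1).normal(size=(5, 12)))
        m = build_erc_matrix([rer])
        m.fterc = np.where(np.isnan(m.fterc), np.nan, 2.5)
        np.fill_diagonal(m.fterc, np.nan)
        assert significance_threshold(m) == pytest.approx(2.5)

    def test_too_few_pairs(self):
        rer = _rer_from_array(np.random.default_rng(1).normal(size=(2, 12)))
        m = build_erc_matrix([rer])
        with pytest.raises(ValueError):
            significance_threshold(m)
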