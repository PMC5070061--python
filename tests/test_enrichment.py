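from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossdx.enrichment import (
    concordance_table,
    hypergeometric_enrichment,
    select_deg_lists,
    set_enrichment_empirical,
    stouffer_combine,
)


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestStouffer:
    def test_equal_inputs_closed_form(self):
        z = stouffer_combine([_series([2.0]), _series([2.0])])
        assert z.iloc[0] == pytest.approx(4.0 / np.sqrt(2), abs=1e-15)

    def test_opposite_inputs_cancel(self):
        z = stouffer_combine([_series([1.0]), _series([-1.0])])
        assert z.iloc[0] == 0.0

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form(self, zs):
        combined = stouffer_combine([_series([z]) for z in zs])
        assert combined.iloc[0] == pytest.approx(sum(zs) / np.sqrt(len(zs)))

    def test_variance_preserved_for_independent_normals(self):
        rng = np.random.default_rng(12)
        a, b = rng.standard_normal(10000), rng.standard_normal(10000)
        z = stouffer_combine([_series(a), _series(b)])
        assert abs(z.std() - 1.0) < 0.03

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            stouffer_combine([_series([1.0])])


class TestDegLists:
    def test_threshold_partition(self):
        zA = _series([3.0, -3.0, 1.0])
        zB = _series([3.0, -3.0, 1.0])
        deg = select_deg_lists(zA, zB, threshold=2.2)
        assert set(deg.index) == {"g0", "g1"}
        assert deg.loc["g0", "direction"] == "up"
        assert deg.loc["g1", "direction"] == "down"

    def test_discordant_detected(self):
        deg = select_deg_lists(_series([3.0]), _series([-3.0]), threshold=2.2)
        assert deg.loc["g0", "direction"] == "discordant"

    def test_fixed_n_matches_threshold_list(self):
        rng = np.random.default_rng(5)
        zA, zB = _series(rng.standard_normal(500)), _series(rng.standard_normal(500))
        thr = select_deg_lists(zA, zB, threshold=1.5)
        fixed = select_deg_lists(zA, zB, threshold=None, fixed_n=len(thr))
        assert set(thr.index) == set(fixed.index)

    def test_fixed_n_too_large_rejected(self):
        with pytest.raises(ValueError, match="fixed_n"):
            select_deg_lists(_series([1.0]), _series([1.0]), fixed_n=5)


class TestHypergeometric:
    def test_complete_overlap_exact_probability(self):
        genes = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(
            genes[:5], genes, {"S": genes[:5]}, correction="BH"
        )
        assert res.loc["S", "p"] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(
            genes[:5], genes, {"S": genes[10:15]}, correction="BH"
        )
        assert res.loc["S", "p"] == pytest.approx(1.0)

    @staticmethod
    def _exact_upper_tail(M, K, n, k):
        """Exact-arithmetic enumeration of P(X >= k) for X ~ Hypergeom."""
        total = Fraction(0)
        for j in range(k, min(K, n) + 1):
            total += Fraction(comb(K, j) * comb(M - K, n - j), comb(M, n))
        return float(total)

    def test_matches_exact_enumeration_on_small_universes(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            M = int(rng.integers(5, 26))
            genes = [f"g{i}" for i in range(M)]
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            myset = list(rng.choice(genes, size=K, replace=False))
            lst = list(rng.choice(genes, size=n, replace=False))
            res = hypergeometric_enrichment(lst, genes, {"S": myset})
            k = len(set(lst) & set(myset))
            assert res.loc["S", "p"] == pytest.approx(
                self._exact_upper_tail(M, K, n, k), rel=1e-10
            )

    def test_bh_controls_false_discoveries_on_null_lists(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(300)]
        sets = {
            f"S{j}": list(rng.choice(genes, size=20, replace=False))
            for j in range(200)
        }
        n_flagged = []
        for rep in range(10):
            lst = list(rng.choice(genes, size=30, replace=False))
            res = hypergeometric_enrichment(lst, genes, sets, correction="BH")
            n_flagged.append(int((res["adjusted_p"] < 0.05).sum()))
        assert np.mean(n_flagged) <= 200 * 0.05

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment(["x"], ["g0"], {"S": ["g0"]})


class TestSetEnrichment:
    def test_whole_universe_set_statistic(self):
        rng = np.random.default_rng(3)
        combined = _series(rng.standard_normal(100))
        null = pd.DataFrame(
            rng.standard_normal((50, 100)), columns=combined.index
        )
        res = set_enrichment_empirical(
            combined, {"ALL": list(combined.index)}, null
        )
        expect = abs(combined.sum()) / np.sqrt(100)
        assert res.loc["ALL", "U"] == pytest.approx(expect)

    def test_small_sets_dropped(self):
        rng = np.random.default_rng(4)
        combined = _series(rng.standard_normal(50))
        null = pd.DataFrame(rng.standard_normal((20, 50)), columns=combined.index)
        sets = {"tiny": list(combined.index[:3]), "ok": list(combined.index[:10])}
        res = set_enrichment_empirical(combined, sets, null, min_size=5)
        assert list(res.index) == ["ok"]

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        combined = _series(rng.standard_normal(80))
        null = pd.DataFrame(rng.standard_normal((30, 80)), columns=combined.index)
        sets = {"A": list(combined.index[10:30]), "B": list(combined.index[40:60])}
        res1 = set_enrichment_empirical(combined, sets, null)
        perm = rng.permutation(combined.index)
        res2 = set_enrichment_empirical(
            combined.loc[perm], sets, null[perm]
        )
        pd.testing.assert_frame_equal(res1.sort_index(), res2.sort_index())

    def test_null_calibration_uniform_p(self):
        rng = np.random.default_rng(9)
        n_genes, B = 600, 400
        combined = _series(rng.standard_normal(n_genes))
        null = pd.DataFrame(
            rng.standard_normal((B, n_genes)),
            columns=combined.index,
        )
        sets = {
            f"S{j}": list(rng.choice(combined.index, size=15, replace=False))
            for j in range(500)
        }
        res = set_enrichment_empirical(combined, sets, null)
        from scipy import stats

        assert stats.kstest(res["empirical_p"], "uniform").pvalue > 0.01

    def test_empty_collection_rejected(self):
        combined = _series(np.ones(10))
        null = pd.DataFrame(np.ones((5, 10)), columns=combined.index)
        with pytest.raises(ValueError):
            set_enrichment_empirical(combined, {}, null)


class TestConcordance:
    def test_published_discordance_arithmetic(self):
        rng = np.random.default_rng(0)
        n_disc, total = 16, 191
        zA = _series(np.abs(rng.standard_normal(total)) + 2.3)
        signs = np.ones(total)
        signs[:n_disc] = -1
        zB = _series((np.abs(rng.standard_normal(total)) + 2.3) * signs)
        deg = select_deg_lists(zA, zB, threshold=2.2)
        table = concordance_table(deg)
        assert table["total"] == total
        assert table["discordant"] == n_disc
        assert table["discordant_pct"] == 8.4

    def test_all_concordant_zero_pct(self):
        deg = select_deg_lists(_series([3.0, -3.0]), _series([3.0, -3.0]), 2.2)
        assert concordance_table(deg)["discordant_pct"] == 0.0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(17)
        zA = _series(rng.standard_normal(400) * 2)
        zB = _series(rng.standard_normal(400) * 2)
        deg = select_deg_lists(zA, zB, threshold=1.0)
        table = concordance_table(deg)
        up = down = disc = 0
        for g in deg.index:
            a, b = zA[g], zB[g]
            if a > 0 and b > 0:
                up += 1
            elif a < 0 and b < 0:
                down += 1
            else:
                disc += 1
        assert (table["up"], table["down"], table["discordant"]) == (up, down, disc)
        assert table["total"] == up + down + disc

    def test_empty_list_zeros(self):
        deg = select_deg_lists(_series([0.1]), _series([0.1]), threshold=2.2)
        assert concordance_table(deg) == {
            "total": 0, "up": 0, "down": 0, "discordant": 0, "discordant_pct": 0.0
        }
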