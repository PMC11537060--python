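"""Local similarity analysis: DP vs exhaustive oracle, permutations, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongenet.lsa import (
    _batch_ls,
    bipartite_summary,
    local_similarity,
    lsa_all_pairs,
    replicate_series,
    standardize_series,
    timepoint_means,
)
from spongenet.table import AsvTable


def brute_force_ls(zx, zy, D):
    """Exhaustive maximum |window sum| over all contiguous aligned
    windows and offsets |d| <= D, with its sign; independent of the DP
    but sharing its tie rules (positive chains win exact magnitude
    ties; smaller |offset| considered first)."""
    n = len(zx)
    best = 0.0
    for d in sorted(range(-D, D + 1), key=lambda k: (abs(k), k)):
        if d >= 0:
            prod = zx[: n - d] * zy[d:]
        else:
            prod = zx[-d:] * zy[: n + d]
        m = len(prod)
        pos = neg = 0.0
        for i in range(m):
            total = 0.0
            for j in range(i, m):
                total += prod[j]
                pos = max(pos, total)
                neg = max(neg, -total)
        score = pos if pos >= neg else -neg
        if abs(score) > abs(best):
            best = score
    return best / n


class TestStandardize:
    def test_mean_zero_unit_sd(self, rng):
        z = standardize_series(rng.normal(size=9))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_monotone_in_ranks(self, rng):
        x = rng.normal(size=7)
        z1 = standardize_series(x)
        z2 = standardize_series(np.exp(3 * x))  # same ranks
        np.testing.assert_allclose(z1, z2)

    def test_reversal(self, rng):
        x = rng.normal(size=8)
        np.testing.assert_allclose(
            standardize_series(x[::-1]), standardize_series(x)[::-1]
        )

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_series(np.full(5, 3.0))


class TestLocalSimilarity:
    def test_self_similarity_is_one(self, rng):
        zx = standardize_series(rng.normal(size=8))
        ls, delay = local_similarity(zx, zx, D=0)
        assert ls == pytest.approx(1.0)
        assert delay == 0

    def test_negated_copy(self, rng):
        zx = standardize_series(rng.normal(size=8))
        ls, _ = local_similarity(zx, -zx, D=0)
        assert ls == pytest.approx(-1.0)

    def test_antisymmetry_in_y(self, rng):
        zx = standardize_series(rng.normal(size=7))
        zy = standardize_series(rng.normal(size=7))
        ls1, _ = local_similarity(zx, zy, D=1)
        ls2, _ = local_similarity(zx, -zy, D=1)
        assert ls1 == pytest.approx(-ls2)

    def test_symmetry_with_negated_delay(self, rng):
        for _ in range(20):
            zx = standardize_series(rng.normal(size=8))
            zy = standardize_series(rng.normal(size=8))
            ls_xy, d_xy = local_similarity(zx, zy, D=2)
            ls_yx, d_yx = local_similarity(zy, zx, D=2)
            assert ls_xy == pytest.approx(ls_yx)
            assert d_xy == -d_yx

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            local_similarity(np.ones(4), np.ones(5))

    @given(st.integers(0, 10_000), st.integers(4, 8), st.integers(0, 2))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_dp_equals_exhaustive_oracle(self, seed, n, D):
        rng = np.random.default_rng(seed)
        zx = standardize_series(rng.normal(size=n))
        zy = standardize_series(rng.normal(size=n))
        ls, _ = local_similarity(zx, zy, D=D)
        assert ls == pytest.approx(brute_force_ls(zx, zy, D), abs=1e-12)

    def test_batch_matches_scalar(self, rng):
        za = np.vstack([standardize_series(rng.normal(size=6)) for _ in range(5)])
        zb = np.vstack([standardize_series(rng.normal(size=6)) for _ in range(4)])
        ls, delay = _batch_ls(za, zb, D=1)
        for i in range(5):
            for j in range(4):
                ls_ij, d_ij = local_similarity(za[i], zb[j], D=1)
                assert ls[i, j] == pytest.approx(ls_ij)
                assert delay[i, j] == d_ij


class TestAllPairs:
    def _series(self, mat):
        return pd.DataFrame(mat, index=[f"a{i}" for i in range(len(mat))])

    def test_planted_lagged_pair_recovered(self):
        rng = np.random.default_rng(6)
        n = 10
        x = rng.normal(size=n)
        y = np.empty(n)
        y[1:] = x[:-1]  # y trails x by one step
        y[0] = rng.normal()
        others = rng.normal(size=(6, n))
        a = self._series([x])
        b = self._series(np.vstack([y, others]))
        b.index = ["lagged"] + [f"noise{i}" for i in range(6)]
        out = lsa_all_pairs(a, b, D=1, n_perm=999, seed=0)
        hit = out.results.set_index("asv_b").loc["lagged"]
        assert hit["delay"] == 1
        assert hit["q"] <= 0.05
        assert hit["ls"] > 0.8

    def test_type_one_error_roughly_nominal(self, rng):
        a = self._series([standardize_series(rng.normal(size=8)) for _ in range(25)])
        b = self._series([standardize_series(rng.normal(size=8)) for _ in range(25)])
        out = lsa_all_pairs(a, b, D=1, n_perm=199, seed=1)
        rate = (out.results["p"] <= 0.05).mean()
        assert 0.01 < rate < 0.12  # 625 correlated tests; loose band

    def test_seeded_runs_identical(self, rng):
        a = self._series(rng.normal(size=(4, 7)))
        b = self._series(rng.normal(size=(4, 7)))
        r1 = lsa_all_pairs(a, b, n_perm=99, seed=4).results
        r2 = lsa_all_pairs(a, b, n_perm=99, seed=4).results
        pd.testing.assert_frame_equal(r1, r2)

    def test_bh_q_monotone_and_at_least_p(self, rng):
        a = self._series(rng.normal(size=(6, 8)))
        b = self._series(rng.normal(size=(6, 8)))
        res = lsa_all_pairs(a, b, n_perm=99, seed=0).results
        assert (res["q"] >= res["p"] - 1e-12).all()
        by_p = res.sort_values("p")
        assert by_p["q"].is_monotonic_increasing

    def test_constant_series_dropped(self, rng):
        a = self._series(np.vstack([np.ones(6), rng.normal(size=6)]))
        b = self._series(rng.normal(size=(2, 6)))
        out = lsa_all_pairs(a, b, n_perm=9, seed=0)
        assert out.dropped_a == ["a0"]

    def test_mismatched_time_axes_error(self, rng):
        a = self._series(rng.normal(size=(2, 6)))
        b = self._series(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match="time axis"):
            lsa_all_pairs(a, b)


class TestSeriesLayouts:
    def _table_meta(self):
        counts = pd.DataFrame(
            {
                "m1r1": [5, 5],
                "m1r2": [7, 3],
                "m2r1": [1, 9],
                "m2r2": [3, 7],
                "m3r1": [8, 2],
                "m3r2": [6, 4],
            },
            index=["a", "b"],
        )
        month = {s: int(s[1]) for s in counts.columns}
        rep = {s: int(s[3]) for s in counts.columns}
        return AsvTable(counts), month, rep

    def test_timepoint_means_averages_replicates(self):
        t, month, _ = self._table_meta()
        series = timepoint_means(t, month)
        assert list(series.columns) == [1, 2, 3]
        assert series.loc["a", 1] == pytest.approx((0.5 + 0.7) / 2)

    def test_replicate_series_orders_by_month_then_replicate(self):
        t, month, rep = self._table_meta()
        series = replicate_series(t, month, rep)
        assert series.shape == (2, 6)
        np.testing.assert_allclose(
            series.loc["a"].to_numpy(), [0.5, 0.7, 0.1, 0.3, 0.8, 0.6]
        )


class TestBipartiteSummary:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["asv_a", "asv_b", "ls"])
        df["significant"] = True
        return df

    def test_all_positive(self):
        res = self._results([("s1", "w1", 0.9), ("s2", "w2", 0.5)])
        groups = {"s1": "sponge", "s2": "sponge", "w1": "seawater", "w2": "seawater"}
        out = bipartite_summary(res, groups)
        assert out["frac_positive"] == 1.0 and out["n_edges"] == 2

    def test_planted_antagonism_between_habitats(self):
        rows = (
            [("s1", "s2", 0.8), ("s3", "s4", 0.7), ("s1", "s3", -0.6)]  # within
            + [("s1", "w1", -0.9), ("s2", "w2", -0.8), ("s3", "w1", 0.5)]  # between
        )
        groups = {f"s{i}": "sponge" for i in range(1, 5)}
        groups.update({"w1": "seawater", "w2": "seawater"})
        out = bipartite_summary(self._results(rows), groups)
        hb = out["habitat_breakdown"]
        assert hb["between_habitat"]["frac_negative"] > hb["within_habitat"][
            "frac_negative"
        ]

    def test_empty_set(self):
        res = self._results([]).iloc[:0]
        out = bipartite_summary(res, {})
        assert out["n_edges"] == 0 and out["frac_positive"] == 0.0

    def test_unmapped_node_errors(self):
        res = self._results([("s1", "w1", 0.5)])
        with pytest.raises(ValueError, match="habitat"):
            bipartite_summary(res, {"s1": "sponge"})

    def test_per_phylum_counts(self):
        res = self._results([("s1", "w1", 0.5), ("s2", "w1", -0.2)])
        groups = {"s1": "sponge", "s2": "sponge", "w1": "seawater"}
        out = bipartite_summary(
            res, groups, phylum_of={"s1": "Chloroflexi", "w1": "Proteobacteria"}
        )
        assert out["per_phylum_edges"] == {
            "Chloroflexi": 1,
            "Proteobacteria": 2,
            "unassigned": 1,
        }
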