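"""ECDF sup-difference, KS p-values, triage, tail ratio, BH and scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magic.enrichment import (
    ListsError,
    bh_correct,
    ecdf_dsup,
    ks_pvalue,
    load_lists,
    permutation_pvalue,
    run_query,
    score,
    tail_ratio,
    target_genes,
    triage,
)
from magic.matrix_builder import MagicMatrix
from magic.synthetic import SyntheticScenario, make_matrix_fixture


def brute_force_dsup(b, q):
    """Oracle: scan B(c) - Q(c) at every distinct value plus a sub-minimum point."""
    b = np.asarray(b, float)
    q = np.asarray(q, float)
    grid = sorted(set(b) | {min(b) - 1.0})
    best, arg = -np.inf, None
    for c in grid:
        d = np.mean(b <= c) - np.mean(q <= c)
        if d > best + 1e-12:
            best, arg = d, c
    return best, arg


class TestEcdfDsup:
    def test_identical_distribution_gives_zero(self):
        b = [1.0, 2.0, 3.0, 4.0]
        assert ecdf_dsup(b, b) == (0.0, 0.0)

    def test_enriched_query(self):
        d, arg = ecdf_dsup([1, 2, 3, 4], [3, 4])
        assert d == 0.5 and arg == 2.0  # B(2)=0.5, Q(2)=0

    def test_depleted_query_is_zero(self):
        d, arg = ecdf_dsup([1, 2, 3, 4], [1, 2])
        assert d == 0.0  # B-Q <= 0 on the support; sup attained below min

    def test_tie_breaks_to_smallest_c(self):
        # D = 0.25 at both c=1 and c=3; smallest attaining c maximises targets
        d, arg = ecdf_dsup([1, 2, 3, 4], [2, 4])
        assert d == 0.25 and arg == 1.0

    def test_matches_bruteforce_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 1000))
            x = int(rng.integers(1, max(2, n // 4)))
            b = np.where(rng.random(n) < 0.5, 0.0, rng.lognormal(1, 1, n)).round(2)
            q = rng.choice(b, size=x, replace=False)
            d, arg = ecdf_dsup(b, q)
            d0, arg0 = brute_force_dsup(b, q)
            assert d == pytest.approx(max(d0, 0.0), abs=1e-12)
            if d0 > 0:
                assert arg == pytest.approx(arg0)

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=60),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_dsup_bounds_property(self, b, data):
        k = data.draw(st.integers(1, len(b)))
        idx = data.draw(
            st.lists(st.integers(0, len(b) - 1), min_size=k, max_size=k, unique=True)
        )
        q = [b[i] for i in idx]
        d, arg = ecdf_dsup(b, q)
        assert 0.0 <= d <= 1.0
        assert arg in set(b) | {0.0}


class TestKsPvalue:
    def test_null_and_extreme(self):
        assert ks_pvalue(40, 8, 0.0) == 1.0
        assert ks_pvalue(1000, 500, 1.0) < 1e-10
        assert ks_pvalue(40, 8, 0.0, mode="onesided") == 1.0

    def test_invalid_dsup_rejected(self):
        with pytest.raises(ValueError):
            ks_pvalue(10, 5, 1.5)
        with pytest.raises(ValueError):
            ks_pvalue(10, 5, -0.1)

    def test_onesided_is_half_of_twosided_tail(self):
        # for large lambda the alternating series is dominated by its first term
        n, x, d = 500, 100, 0.25
        assert ks_pvalue(n, x, d) == pytest.approx(
            2 * ks_pvalue(n, x, d, mode="onesided"), rel=1e-3
        )

    def test_permutation_reproducible_and_valid(self, rng):
        b = rng.lognormal(1, 1, 80)
        p1 = permutation_pvalue(b, 10, 0.3, 2000, np.random.default_rng(5))
        p2 = permutation_pvalue(b, 10, 0.3, 2000, np.random.default_rng(5))
        assert p1 == p2 and 0 < p1 <= 1
        # d=0 is always attained -> p = 1
        assert permutation_pvalue(b, 10, 0.0, 500, rng) == 1.0

    def test_permutation_tail_matches_direct_simulation(self, rng):
        """Vectorised D_sup null matches per-draw ecdf_dsup recomputation."""
        b = np.where(rng.random(40) < 0.4, 0.0, rng.lognormal(1, 1, 40)).round(1)
        d_obs, _ = ecdf_dsup(b, rng.choice(b, 8, replace=False))
        direct = []
        r = np.random.default_rng(7)
        for _ in range(4000):
            direct.append(ecdf_dsup(b, r.choice(b, 8, replace=False))[0])
        p_direct = (1 + sum(d >= d_obs - 1e-12 for d in direct)) / 4001
        p_vec = permutation_pvalue(b, 8, d_obs, 4000, np.random.default_rng(8))
        se = math.sqrt(p_direct * (1 - p_direct) / 4000)
        assert abs(p_vec - p_direct) < 4 * se


class TestTriage:
    @pytest.mark.parametrize("n_targets, expected", [(4, True), (5, False), (3, True)])
    def test_threshold_at_five_targets(self, n_targets, expected):
        targets = [(f"g{i}", 1.0) for i in range(n_targets)]
        assert triage(targets) is expected

    def test_zero_background_tail_triaged(self):
        targets = [(f"g{i}", 1.0) for i in range(9)]
        assert triage(targets, exp_tail_mean=0.0) is True


class TestTailRatio:
    @pytest.mark.parametrize("x, n", [(100, 5), (20, 1), (10, 1), (41, 3)])
    def test_tail_size_rounding(self, x, n):
        b = np.arange(1, 201, dtype=float)
        q = b[:x]
        assert tail_ratio(b, q).n_tail == n

    def test_identical_tails_ratio_one(self):
        b = np.arange(1.0, 21.0)
        q = np.array([1.0, 2.0, 20.0])  # top query signal equals top background
        t = tail_ratio(b, q)
        assert t.n_tail == 1 and t.ratio == 1.0

    def test_toy_tail_means(self):
        b = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 100.0])
        q = np.array([3, 8, 100, 7, 0, 1, 2, 4, 5, 6.0])  # X=10 -> n=1
        t = tail_ratio(b, q)
        assert (t.obs_tail_mean, t.exp_tail_mean, t.ratio) == (100.0, 100.0, 1.0)

    def test_zero_background_tail(self):
        t = tail_ratio(np.zeros(10), np.zeros(3))
        assert t.ratio == 0.0


class TestBH:
    def bh_oracle(self, p):
        """Hand-rolled step-up: p(i)·m/i with monotone cummin from the top."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * m / rank_from_top)
            adj[i] = running
        return adj

    def test_spec_examples(self):
        assert bh_correct([0.05]) == pytest.approx([0.05])
        np.testing.assert_allclose(bh_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_correct([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_oracle_random(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_correct(p), self.bh_oracle(p), atol=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.2])


class TestScore:
    @pytest.mark.parametrize(
        "p, r, s", [(1.0, 3.0, 0.0), (0.01, 2.0, 4.0), (0.1, 1.0, 1.0)]
    )
    def test_examples(self, p, r, s):
        assert score(p, r) == pytest.approx(s)

    def test_zero_p_floored_not_infinite(self):
        assert np.isfinite(score(0.0, 2.0))

    def test_monotonicity(self):
        assert score(0.01, 2.0) > score(0.02, 2.0)  # lower p, same r
        assert score(0.01, 3.0) > score(0.01, 2.0)  # higher r, same p


class TestTargets:
    def test_strictly_greater(self):
        sym = list("abcdef")
        sig = np.array([0, 2, 5, 7, 9, 11.0])
        assert [g for g, _ in target_genes(sym, sig, 5.0)] == ["d", "e", "f"]
        assert target_genes(sym, sig, 11.0) == []
        assert len(target_genes(sym, sig, -1.0)) == 6


class TestLoadLists:
    def write(self, tmp_path, text):
        p = tmp_path / "lists.txt"
        p.write_text(text)
        return p

    def test_filtering_and_triage(self, tmp_path, toy_matrix):
        p = self.write(
            tmp_path,
            "bg\tup\ng1\tg2\ng2\tg4\ng3\tg9\ng4\t\ng5\t\ng9\t\n",
        )
        ls = load_lists(p, toy_matrix)
        assert ls.background == ["g1", "g2", "g3", "g4", "g5"]
        assert ls.queries["up"] == ["g2", "g4"]
        assert ls.triaged_genes == {"bg": ["g9"], "up": ["g9"]}

    def test_duplicate_header_rejected(self, tmp_path, toy_matrix):
        p = self.write(tmp_path, "bg\tup\tup\ng1\tg2\tg3\n")
        with pytest.raises(ListsError, match="unique names"):
            load_lists(p, toy_matrix)

    def test_query_outside_background_dropped(self, tmp_path, toy_matrix):
        p = self.write(tmp_path, "bg\tup\ng1\tg1\ng2\tg5\ng3\t\n")
        ls = load_lists(p, toy_matrix)  # g5 in matrix but not background
        assert ls.queries["up"] == ["g1"]

    def test_empty_query_raises(self, tmp_path, toy_matrix):
        p = self.write(tmp_path, "bg\tup\ng1\tg9\ng2\t\n")
        with pytest.raises(ListsError, match="'up'"):
            load_lists(p, toy_matrix)

    def test_duplicates_deduplicated(self, tmp_path, toy_matrix):
        p = self.write(tmp_path, "bg\tup\ng1\tg2\ng2\tg2\ng3\t\ng1\t\n")
        ls = load_lists(p, toy_matrix)
        assert ls.background == ["g1", "g2", "g3"]
        assert ls.queries["up"] == ["g2"]


class TestRunQuery:
    def test_planted_factor_ranked_first(self):
        hits = 0
        for seed in range(8):
            m, lists = make_matrix_fixture(
                SyntheticScenario(n_genes=800, n_tracks=20, query_size=60, seed=seed)
            )
            rep = run_query(m, lists, "query")
            if rep.results and rep.results[0].track_id == "TF000_synthetic":
                hits += 1
        assert hits >= 7

    def test_null_rarely_significant(self):
        sig = 0
        total = 0
        for seed in range(10):
            m, lists = make_matrix_fixture(
                SyntheticScenario(
                    n_genes=500, n_tracks=10, query_size=50, effect=0.0, seed=seed
                )
            )
            rep = run_query(m, lists, "query")
            sig += len(rep.significant_results())
            total += len(rep.results)
        assert sig <= 0.1 * total

    def test_summary_keeps_best_track_per_factor(self, rng):
        genes = [f"g{i}" for i in range(100)]
        base = rng.lognormal(1, 1, 100)
        shifted = base.copy()
        query_idx = np.arange(10)
        shifted[query_idx] *= 5
        values = pd.DataFrame(
            {"FAC_weak": base, "FAC_strong": shifted, "OTHER_x": base[::-1]},
            index=genes,
        )
        m = MagicMatrix(values=values)
        from magic.enrichment import GeneListSet

        lists = GeneListSet(background=genes, queries={"q": [genes[i] for i in query_idx]})
        rep = run_query(m, lists, "q")
        summary = rep.summary()
        assert sorted(r.factor_name for r in summary) == ["FAC", "OTHER"]
        fac = next(r for r in summary if r.factor_name == "FAC")
        assert fac.track_id == "FAC_strong"
        scores = {r.track_id: r.score for r in rep.results}
        assert scores["FAC_strong"] == max(scores.values())

    def test_sorted_by_score_then_p_then_id(self):
        m, lists = make_matrix_fixture(SyntheticScenario(n_genes=300, n_tracks=8, query_size=30, seed=1))
        rep = run_query(m, lists, "query")
        keys = [(-r.score, r.corrected_p, r.track_id) for r in rep.results]
        assert keys == sorted(keys)

    def test_unknown_query_and_empty_intersection(self, toy_matrix):
        from magic.enrichment import GeneListSet

        lists = GeneListSet(background=["zz"], queries={"q": ["zz"]})
        with pytest.raises(KeyError):
            run_query(toy_matrix, lists, "nope")
        with pytest.raises(ListsError, match="share no genes"):
            run_query(toy_matrix, lists, "q")
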