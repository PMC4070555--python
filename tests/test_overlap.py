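import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextnet.geneset_io import GeneSet, GeneSetCollection
from contextnet.overlap import (
    _hypergeom_sf_grid,
    all_pairwise_overlaps,
    bh_qvalues,
    hypergeom_tail,
)


def enumerate_tail_tables(N):
    """Exhaustive oracle: count[K][n][j] = number of n-subsets of {0..N-1}
    sharing exactly j elements with {0..K-1}, by enumerating all 2^N subsets."""
    counts = np.zeros((N + 1, N + 1, N + 1), dtype=np.int64)
    for s in range(1 << N):
        size = bin(s).count("1")
        for K in range(N + 1):
            j = bin(s & ((1 << K) - 1)).count("1")
            counts[K, size, j] += 1
    return counts


def bh_oracle(p):
    """Step-up q-values straight from the definition q_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestHypergeomTail:
    def test_full_overlap_small_universe(self):
        # single favourable draw out of C(10,5)=252
        assert hypergeom_tail(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(100, 30, 10, 0) == 1.0

    def test_matches_exhaustive_enumeration(self):
        from math import comb

        for N in (5, 8):
            counts = enumerate_tail_tables(N)
            for K in range(N + 1):
                for n in range(N + 1):
                    total = comb(N, n)
                    for x in range(min(K, n) + 1):
                        expected = counts[K, n, x:].sum() / total
                        assert hypergeom_tail(N, K, n, x) == pytest.approx(expected, abs=1e-12)

    def test_non_increasing_in_x(self):
        vals = [hypergeom_tail(50, 20, 15, x) for x in range(16)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 11, 5, 2)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 5, 5, 6)

    def test_fast_grid_matches_scalar(self, rng):
        N = 2000
        K = rng.integers(1, 500, size=12)
        n = rng.integers(1, 500, size=9)
        x = (np.minimum(K[:, None], n[None, :]) * rng.random((12, 9))).astype(np.int64)
        grid = _hypergeom_sf_grid(N, K, n, x)
        for i in range(12):
            for j in range(9):
                assert grid[i, j] == pytest.approx(
                    hypergeom_tail(N, int(K[i]), int(n[j]), int(x[i, j])), rel=1e-9, abs=1e-300
                )


class TestBhQvalues:
    def test_hand_computed_step_up(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert bh_qvalues([1.0]) == pytest.approx([1.0])

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.random(50))
        q = bh_qvalues(p)
        assert np.all(np.diff(q) >= -1e-12)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.2])

    @given(
        p=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12
        )
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_agrees_with_definition(self, p):
        assert bh_qvalues(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_false_discovery_control_under_null(self, rng):
        """Empirical FDR of BH at alpha=0.05 on uniform p-values stays near alpha."""
        alpha, m, reps = 0.05, 20, 1000
        fdr = []
        for _ in range(reps):
            q = bh_qvalues(rng.random(m))
            r = int(np.sum(q <= alpha))
            fdr.append(1.0 if r > 0 else 0.0)  # all hypotheses null: any rejection is false
        assert np.mean(fdr) <= alpha + 0.02


def _collections_for_pair_test(rng, n_genes=10_000, planted_overlap=30):
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    shared = genes[:planted_overlap]
    t_sets, f_sets = [], []
    t_sets.append(GeneSet("T_PLANTED", frozenset(shared) | frozenset(genes[100:170])))
    f_sets.append(GeneSet("F_PLANTED", frozenset(shared) | frozenset(genes[200:270])))
    for i in range(14):
        t_sets.append(GeneSet(f"T{i}", frozenset(rng.choice(genes, 100, replace=False))))
        f_sets.append(GeneSet(f"F{i}", frozenset(rng.choice(genes, 100, replace=False))))
    return GeneSetCollection(t_sets), GeneSetCollection(f_sets), genes


class TestAllPairwiseOverlaps:
    def test_identical_sets_retained(self, rng):
        universe = [f"G{i}" for i in range(10_000)]
        genes = frozenset(universe[:50])
        tfbs = GeneSetCollection([GeneSet("T", genes)])
        funcs = GeneSetCollection([GeneSet("F", genes)])
        out = all_pairwise_overlaps(tfbs, funcs, universe)
        assert len(out) == 1
        assert out[0].overlap_size == 50
        assert out[0].p_value < 1e-20

    def test_disjoint_sets_dropped(self):
        universe = [f"G{i}" for i in range(100)]
        tfbs = GeneSetCollection([GeneSet("T", frozenset(universe[:20]))])
        funcs = GeneSetCollection([GeneSet("F", frozenset(universe[50:80]))])
        assert all_pairwise_overlaps(tfbs, funcs, universe) == []

    def test_empty_universe_rejected(self, tiny_collections):
        tfbs, funcs = tiny_collections
        with pytest.raises(ValueError, match="universe"):
            all_pairwise_overlaps(tfbs, funcs, [])

    def test_symmetric_to_collection_order(self, rng):
        tfbs, funcs, genes = _collections_for_pair_test(rng)
        fwd = all_pairwise_overlaps(tfbs, funcs, genes)
        rev = all_pairwise_overlaps(funcs, tfbs, genes)
        assert {(o.tfbs_name, o.func_name, o.overlap_size) for o in fwd} == {
            (o.func_name, o.tfbs_name, o.overlap_size) for o in rev
        }
        assert sorted(o.p_value for o in fwd) == pytest.approx(sorted(o.p_value for o in rev))

    def test_planted_overlap_survives_fdr(self, rng):
        """One genuine 30-gene overlap among ~200 random pairs is recovered."""
        found = 0
        for seed in range(20):
            tfbs, funcs, genes = _collections_for_pair_test(np.random.default_rng(seed))
            out = all_pairwise_overlaps(tfbs, funcs, genes)
            names = {(o.tfbs_name, o.func_name) for o in out}
            if ("T_PLANTED", "F_PLANTED") in names:
                found += 1
        assert found >= 19  # >=95% of seeds

    def test_fields_are_consistent(self, rng):
        tfbs, funcs, genes = _collections_for_pair_test(rng)
        for o in all_pairwise_overlaps(tfbs, funcs, genes):
            assert o.overlap_size == len(o.overlap_genes)
            assert o.overlap_size <= min(o.tfbs_size, o.func_size)
            assert 0.0 <= o.p_value <= 1.0
            assert 0.0 <= o.q_value <= 1.0
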