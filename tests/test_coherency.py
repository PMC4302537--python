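import numpy as np
import pytest

from bicpam.coherency import (additive_align, align, calibrate_support_floors,
                              make_merge_guard, make_row_trimmer,
                              mine_coherent, multiplicative_align,
                              permute_columns, reconstruct_symbol,
                              symmetric_align)
from bicpam.core import Bicluster
from bicpam.mapping import ConfigError, ItemizedMatrix
from bicpam.mining import MiningConfig
from bicpam.synthetic import GeneratorConfig, generate
from bicpam.mapping import MappingConfig, discretize
from bicpam.evaluation import match_score


def _it(symbols, alphabet_size=None, zero_centered=False):
    arr = np.asarray(symbols, dtype=np.int64)
    L = alphabet_size or int(arr.max()) + 1
    return ItemizedMatrix(arr, L, zero_centered=zero_centered)


class TestAdditiveAlign:
    def test_shifted_rows_become_equal(self):
        it = _it([[1, 3, 2], [2, 4, 3]], alphabet_size=5)
        out, plan = additive_align(it, 0)
        np.testing.assert_array_equal(out.primary[0], out.primary[1])
        np.testing.assert_array_equal(out.primary[0], [2, 4, 3])
        assert plan.offsets.tolist() == [1, 0]

    def test_alphabet_bound(self):
        rng = np.random.default_rng(0)
        it = _it(rng.integers(0, 4, size=(10, 6)), alphabet_size=4)
        out, _ = additive_align(it, 2)
        assert out.primary.max() <= 2 * 4 - 2

    def test_empty_reference_column_errors(self):
        from bicpam.mapping import _NO_SYMBOL
        arr = np.array([[0, 1], [1, 2]], dtype=np.int64)
        arr[:, 0] = _NO_SYMBOL
        it = ItemizedMatrix(arr, 3)
        with pytest.raises(ConfigError, match="reference column"):
            additive_align(it, 0)


class TestMultiplicativeAlign:
    def test_scaled_rows_become_equal(self):
        # rows [1,2] and [2,4] on symbols 0-based: remapped to 1..L
        it = _it([[0, 1], [1, 3]], alphabet_size=4)
        out, plan = multiplicative_align(it, 0, delta=0.0)
        np.testing.assert_array_equal(out.primary[0], out.primary[1])
        assert plan.factors.tolist() == [2.0, 1.0]

    def test_equal_rows_are_identity(self):
        it = _it([[2, 1, 3]] * 4, alphabet_size=4)
        out, plan = multiplicative_align(it, 0, delta=0.0)
        assert (plan.factors == 1.0).all()
        for j in range(3):
            assert len(set(out.primary[:, j])) == 1

    def test_delta_grouping_gathers_close_values(self):
        from bicpam.coherency import _group_values
        vals = np.array([10.0, 10.5, 12.0])
        lookup, reps = _group_values(vals, delta=0.1)
        assert lookup[10.0] == lookup[10.5] != lookup[12.0]
        lookup0, _ = _group_values(vals, delta=0.0)
        assert len({lookup0[v] for v in vals}) == 3

    def test_delta_grouping_never_merges_distant_values(self):
        from bicpam.coherency import _group_values
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 50, size=200)
        lookup, reps = _group_values(vals, delta=0.1)
        for v in vals:
            assert abs(v - reps[lookup[v]]) <= 0.1 * max(v, reps[lookup[v]])


class TestSymmetricAlign:
    def test_sign_flip_recovers_constant(self):
        it = _it([[1, 2, 3], [-1, -2, -3]], alphabet_size=7,
                 zero_centered=True)
        out, plan = symmetric_align(it, 0)
        np.testing.assert_array_equal(out.primary[0], out.primary[1])
        assert plan.signs.tolist() == [1, -1]

    def test_zero_keeps_positive_sign(self):
        it = _it([[0, 2], [1, 2]], alphabet_size=5, zero_centered=True)
        _, plan = symmetric_align(it, 0)
        assert plan.signs[0] == 1

    def test_all_positive_is_identity(self):
        it = _it([[1, 2], [2, 1]], alphabet_size=5, zero_centered=True)
        out, plan = symmetric_align(it, 0)
        np.testing.assert_array_equal(out.primary, it.primary)

    def test_requires_zero_centered(self):
        it = _it([[1, 2], [2, 1]], alphabet_size=3)
        with pytest.raises(ConfigError, match="zero-centered"):
            symmetric_align(it, 0)


@pytest.mark.parametrize("coherency", ["additive", "multiplicative",
                                       "symmetric+constant"])
def test_reduction_correctness_on_noiseless_planted(coherency):
    """For a noiseless planted bicluster of each coherency, alignment on any
    in-bicluster reference column renders it exactly constant on rows, and
    the recorded model parameters reconstruct the itemized cells."""
    rng = np.random.default_rng(42)
    n, m, L = 30, 12, 7
    if coherency == "symmetric+constant":
        sym = rng.integers(-(L // 2), L // 2 + 1, size=(n, m))
        rows = np.arange(8)
        cols = np.array([1, 4, 7, 9])
        profile = rng.integers(1, L // 2 + 1, size=4)
        signs = rng.choice([-1, 1], size=8)
        sym[np.ix_(rows, cols)] = signs[:, None] * profile[None, :]
        it = ItemizedMatrix(sym, L, zero_centered=True)
    else:
        sym = rng.integers(0, L, size=(n, m))
        rows = np.arange(8)
        cols = np.array([1, 4, 7, 9])
        if coherency == "additive":
            beta = rng.integers(0, 3, size=4)
            alpha = rng.integers(0, L - 3, size=8)
            sym[np.ix_(rows, cols)] = alpha[:, None] + beta[None, :]
        else:
            beta = rng.integers(1, 3, size=4)     # 1-based values
            alpha = rng.integers(1, 4, size=8)
            sym[np.ix_(rows, cols)] = alpha[:, None] * beta[None, :] - 1
        it = ItemizedMatrix(sym, L)
    for ref in cols:
        aligned, plan = align(it, coherency, int(ref), delta=0.0)
        block = aligned.primary[np.ix_(rows, cols)]
        assert all(len(set(block[:, j])) == 1 for j in range(len(cols))), \
            f"{coherency}: not constant after aligning on {ref}"


def test_back_mapping_reconstructs_itemized_cells():
    rng = np.random.default_rng(3)
    n, m, L = 25, 10, 5
    sym = rng.integers(0, L, size=(n, m))
    rows, cols = np.arange(6), np.array([0, 3, 5, 8])
    beta = rng.integers(0, 2, size=4)
    alpha = rng.integers(0, 3, size=6)
    sym[np.ix_(rows, cols)] = alpha[:, None] + beta[None, :]
    it = ItemizedMatrix(sym, L)
    bics = mine_coherent(it, "additive",
                         MiningConfig(theta=5, min_cols=4,
                                      representation="closed"))
    target = next(b for b in bics if set(rows) <= set(b.rows)
                  and set(cols.tolist()) <= set(b.cols))
    for r in rows:
        for pos, c in enumerate(target.cols):
            got = reconstruct_symbol(target, int(r), pos)
            assert got == sym[r, c]


def test_constant_request_is_plain_mining():
    rng = np.random.default_rng(0)
    sym = rng.integers(0, 4, size=(20, 6))
    sym[:6, :3] = 2
    it = ItemizedMatrix(sym, 4)
    cfg = MiningConfig(theta=5, min_cols=3, representation="closed")
    from bicpam.mapping import build_transactions
    from bicpam.mining import mine_patterns, patterns_to_biclusters
    direct = patterns_to_biclusters(mine_patterns(
        build_transactions(it, "rows"), cfg), "rows", it)
    via = mine_coherent(it, "constant", cfg)
    assert {b.key() for b in via} == {b.key() for b in direct}


def test_constant_overall_mines_each_symbol_separately():
    rng = np.random.default_rng(6)
    sym = rng.integers(0, 5, size=(25, 8))
    sym[:8, :4] = 3  # one overall-constant block
    it = ItemizedMatrix(sym, 5)
    bics = mine_coherent(it, "constant_overall",
                         MiningConfig(theta=6, min_cols=3,
                                      representation="closed"))
    hit = [b for b in bics if set(range(8)) <= set(b.rows)
           and set(range(4)) <= set(b.cols)]
    assert hit and hit[0].coherency == "constant_overall"
    assert set(hit[0].profile) == {3}


def test_no_duplicate_keys_across_reference_columns():
    rng = np.random.default_rng(8)
    sym = rng.integers(0, 5, size=(30, 8))
    beta = rng.integers(0, 2, size=4)
    alpha = rng.integers(0, 3, size=10)
    sym[np.ix_(np.arange(10), np.array([0, 2, 4, 6]))] = \
        alpha[:, None] + beta[None, :]
    it = ItemizedMatrix(sym, 5)
    bics = mine_coherent(it, "additive",
                         MiningConfig(theta=6, min_cols=3,
                                      representation="closed"))
    keys = [b.key() for b in bics]
    assert len(keys) == len(set(keys))


def test_planted_additive_recovery_with_pipeline_machinery():
    """Planted additive blocks in a noisy background are recovered with high
    row-set Jaccard across seeds."""
    from bicpam import RunConfig, run_bicpam
    scores = []
    for seed in range(3):
        cfg = GeneratorConfig(n=80, m=25, n_biclusters=2, row_range=(14, 18),
                              col_range=(5, 6), coherency="additive",
                              alphabet_size=7, seed=seed)
        mx, hidden = generate(cfg)
        sol = run_bicpam(mx, RunConfig(coherency="additive"))
        scores.append(match_score(hidden.solution, sol))
    assert np.mean(scores) >= 0.85


class TestMergeGuardAndTrimmer:
    def _it(self):
        rng = np.random.default_rng(4)
        sym = rng.integers(0, 7, size=(30, 10))
        sym[:10, :5] = np.arange(5)[None, :] + 1  # constant block
        return ItemizedMatrix(sym, 7)

    def test_guard_accepts_true_block_rejects_hybrid(self):
        it = self._it()
        guard = make_merge_guard(it, "constant", tau_q=0.7)
        assert guard(Bicluster(rows=tuple(range(10)), cols=(0, 1, 2, 3, 4)))
        # fold in a background column: most rows disagree there
        assert not guard(Bicluster(rows=tuple(range(10)),
                                   cols=(0, 1, 2, 3, 4, 7)))

    def test_trimmer_drops_foreign_rows(self):
        it = self._it()
        trim = make_row_trimmer(it, "constant", h=0.75)
        grown = Bicluster(rows=tuple(range(12)), cols=(0, 1, 2, 3, 4))
        out = trim(grown)
        assert set(out.rows) == set(range(10))


def test_permutation_null_destroys_planted_structure():
    rng = np.random.default_rng(0)
    sym = rng.integers(0, 7, size=(40, 10))
    sym[:12, :5] = 3
    it = ItemizedMatrix(sym, 7)
    null = permute_columns(it, seed=1)
    # marginals preserved per column
    for j in range(10):
        assert sorted(null.primary[:, j]) == sorted(sym[:, j])
    floors = calibrate_support_floors(it, "constant",
                                      MiningConfig(min_cols=3))
    base = min(floors)
    # the planted 12-row block comfortably exceeds the null floor
    assert floors[base] < 12
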