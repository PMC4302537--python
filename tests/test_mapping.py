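import math

import numpy as np
import pytest

from bicpam import ExpressionMatrix
from bicpam.mapping import (ConfigError, MappingConfig, TransactionDatabase,
                            assign_boundary_items, build_transactions,
                            discretize, handle_missing, normalize)


def _mx(vals, **kw):
    vals = np.asarray(vals, dtype=float)
    return ExpressionMatrix(vals, [f"g{i}" for i in range(vals.shape[0])],
                            [f"c{j}" for j in range(vals.shape[1])], **kw)


class TestNormalize:
    def test_row_standardization(self):
        mx = _mx([[1, 2, 3]])
        out = normalize(mx, "row", zero_mean=True)
        np.testing.assert_allclose(out.values[0], [-1.2247, 0, 1.2247],
                                   atol=1e-4)

    def test_constant_row_maps_to_zeros_with_warning(self):
        mx = _mx([[5, 5, 5], [1, 2, 3]])
        with pytest.warns(UserWarning, match="zero dispersion"):
            out = normalize(mx, "row", zero_mean=True)
        assert (out.values[0] == 0).all()

    def test_missing_excluded_from_stats(self):
        mx = _mx([[1, np.nan, 3]])
        out = normalize(mx, "row", zero_mean=True)
        # mean/sigma over {1,3}: mean 2, population sigma 1
        np.testing.assert_allclose(out.values[0, [0, 2]], [-1, 1])
        assert math.isnan(out.values[0, 1])

    def test_outlier_mask_excluded(self):
        mask = np.array([[False, False, False, True]])
        mx = _mx([[1, 2, 3, 1000]], outlier_mask=mask)
        out = normalize(mx, "row", zero_mean=True)
        # stats over {1,2,3}; the outlier keeps a (transformed) value
        np.testing.assert_allclose(out.values[0, 1], 0, atol=1e-12)


class TestDiscretize:
    def test_fixed_range_on_small_integers(self):
        # four observed levels, four bins: symbols follow the values
        mx = _mx([[0, 1], [2, 3]])
        it = discretize(mx, MappingConfig(alphabet_size=4))
        np.testing.assert_array_equal(it.primary, [[0, 1], [2, 3]])

    def test_equal_depth_halves(self):
        vals = [[1, 1, 1, 1, 1, 100]]
        mx = _mx(vals)
        it = discretize(mx, MappingConfig(alphabet_size=2,
                                          discretizer="equal_depth"))
        # identical values never split: the five 1s stay together
        assert (it.primary[0][:5] == 0).all() and it.primary[0][5] == 1

    def test_gaussian_equal_probability_bins(self):
        rng = np.random.default_rng(0)
        mx = _mx(rng.normal(0, 1, size=(100, 100)))
        it = discretize(mx, MappingConfig(alphabet_size=5,
                                          discretizer="gaussian"))
        occ = np.bincount(it.primary.ravel(), minlength=5) / 10000
        assert np.all(np.abs(occ - 0.2) < 0.02)

    def test_errors(self):
        with pytest.raises(ConfigError):
            MappingConfig(alphabet_size=1)
        mx = _mx([[1, 1], [1, 2]])
        with pytest.raises(ConfigError, match="distinct"):
            discretize(mx, MappingConfig(alphabet_size=3))

    def test_monotone_in_values(self):
        rng = np.random.default_rng(3)
        mx = _mx(rng.uniform(0, 1, size=(20, 10)))
        for method in ("fixed_range", "equal_depth", "gaussian"):
            it = discretize(mx, MappingConfig(alphabet_size=5,
                                              discretizer=method))
            flat_v = mx.values.ravel()
            flat_s = it.primary.ravel()
            order = np.argsort(flat_v)
            assert (np.diff(flat_s[order]) >= 0).all()

    def test_zero_centered_relabelling(self):
        mx = _mx([[1, 2, 3, 4, 5]])
        it = discretize(mx, MappingConfig(alphabet_size=5, zero_centered=True))
        assert set(it.primary[0]) == {-2, -1, 0, 1, 2}


class TestBoundaryItems:
    def test_value_on_cutoff_gets_both_bins(self):
        mx = _mx([[0, 1, 2, 4]])
        it = discretize(mx, MappingConfig(alphabet_size=2))
        # cutoff at 2: value 2 goes to the lower bin (tie rule)
        assert it.primary[0, 2] == 0
        out = assign_boundary_items(it, mx, 0.1)
        assert out.symbols(0, 2) == (0, 1)

    def test_centroid_value_single_symbol(self):
        mx = _mx([[0, 1, 2, 4]])
        it = discretize(mx, MappingConfig(alphabet_size=2))
        out = assign_boundary_items(it, mx, 0.3)
        assert out.symbols(0, 1) == (0,)  # 1 is the lower-bin centroid

    def test_uniform_growth_matches_direct_count(self):
        rng = np.random.default_rng(1)
        mx = _mx(rng.uniform(0, 1, size=(50, 40)))
        cfg = MappingConfig(alphabet_size=10)
        it = discretize(mx, cfg)
        eps = 0.05
        out = assign_boundary_items(it, mx, eps)
        grown = out.total_items() - it.total_items()
        # direct scan: cells within eps*binwidth of an interior cutoff
        expect = 0
        edges = it.bin_edges
        w = np.diff(edges)
        for v, s in zip(mx.values.ravel(), it.primary.ravel()):
            k = int(s)
            if k > 0 and v - edges[k] <= eps * w[k]:
                expect += 1
            if k < 9 and edges[k + 1] - v <= eps * w[k]:
                expect += 1
        assert grown == expect
        # ~2*eps*(L-1)/L = 9% of cells near a boundary on uniform data
        assert 0.06 < grown / mx.values.size < 0.13

    def test_default_epsilon_growth_in_reported_band(self):
        # the noise-handling default is calibrated for 8-11% transaction
        # growth on uniform data
        rng = np.random.default_rng(5)
        mx = _mx(rng.uniform(0, 1, size=(100, 60)))
        cfg = MappingConfig(alphabet_size=7, boundary_multi_item=True)
        it = discretize(mx, cfg)
        out = assign_boundary_items(it, mx, cfg.epsilon)
        growth = out.total_items() / it.total_items() - 1
        assert 0.08 <= growth <= 0.11


class TestHandleMissing:
    def _with_missing(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 7, size=(12, 6))
        vals[0, 0] = np.nan
        vals[5, 3] = np.nan
        return _mx(vals)

    def test_restrictive_contributes_nothing(self):
        mx = self._with_missing()
        it = discretize(mx, MappingConfig(alphabet_size=5))
        out = handle_missing(it, mx, "restrictive")
        assert out.symbols(0, 0) == ()

    def test_relaxed_gets_full_alphabet(self):
        mx = self._with_missing()
        it = discretize(mx, MappingConfig(alphabet_size=5))
        out = handle_missing(it, mx, "relaxed")
        assert out.symbols(0, 0) == (0, 1, 2, 3, 4)

    def test_delta_replace_two_to_three_items(self):
        mx = self._with_missing()
        it = discretize(mx, MappingConfig(alphabet_size=5))
        out = handle_missing(it, mx, "delta_replace")
        for cell in ((0, 0), (5, 3)):
            assert 2 <= len(out.symbols(*cell)) <= 3

    def test_imputation_in_constant_column(self):
        # missing value in an otherwise-constant column: the 4-NN estimate
        # equals the constant and the assigned symbols bracket it
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 10, size=(10, 5))
        vals[:, 2] = 5.0
        vals[3, 2] = np.nan
        mx = _mx(vals)
        it = discretize(mx, MappingConfig(alphabet_size=5))
        out = handle_missing(it, mx, "delta_replace")
        syms = out.symbols(3, 2)
        true_sym = int(np.searchsorted(it.cutoffs, 5.0, side="left"))
        assert true_sym in syms


class TestTransactions:
    def test_basic_rows_orientation(self):
        it = discretize(_mx([[0, 3], [0, 3]]), MappingConfig(alphabet_size=2))
        db = build_transactions(it, "rows")
        assert db.n_transactions == 2
        assert db.decode(db.transactions[0]) == frozenset({(0, 0), (1, 1)})
        assert db.decode(db.transactions[1]) == frozenset({(0, 0), (1, 1)})

    def test_multi_symbol_cell_contributes_both(self):
        mx = _mx([[0, 1, 2, 4]])
        it = discretize(mx, MappingConfig(alphabet_size=2))
        it = assign_boundary_items(it, mx, 0.1)
        db = build_transactions(it, "rows")
        t = db.decode(db.transactions[0])
        assert (2, 0) in t and (2, 1) in t

    def test_columns_orientation_transposes_roles(self):
        it = discretize(_mx([[0, 3], [1, 2]]), MappingConfig(alphabet_size=4))
        db = build_transactions(it, "columns")
        assert db.n_transactions == 2  # one per column
        assert db.decode(db.transactions[0]) == frozenset({(0, 0), (1, 1)})

    def test_item_count_equals_observed_cells(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, size=(15, 8))
        vals[rng.uniform(size=vals.shape) < 0.1] = np.nan
        mx = _mx(vals)
        it = discretize(mx, MappingConfig(alphabet_size=4))
        db = build_transactions(it, "rows")
        assert db.total_items() == int((~np.isnan(vals)).sum())
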