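import numpy as np
import pytest

from bicpam.mapping import MappingConfig, TransactionDatabase, discretize
from bicpam.mining import (MiningConfig, adaptive_mine, estimate_mining_defaults,
                           max_support_at_size, mine_patterns,
                           patterns_to_biclusters, support_ladder, union_area)

from conftest import DEX_ITEMSETS, random_itemset_db
from oracles import brute_force_fim


class TestWorkedExample:
    """Frozen results of the six-transaction letter database."""

    def test_theta4_all(self, dex_db):
        pats = mine_patterns(dex_db, MiningConfig(theta=4, representation="all",
                                                  min_cols=1))
        assert {p.items for p in pats} == {
            frozenset("A"), frozenset("H"), frozenset("J"), frozenset("HJ")}

    def test_theta3_closed_and_maximal(self, dex_db):
        closed = mine_patterns(dex_db, MiningConfig(theta=3, min_cols=2,
                                                    representation="closed"))
        assert {p.items for p in closed} == {frozenset("AHJ"), frozenset("HJ")}
        maximal = mine_patterns(dex_db, MiningConfig(theta=3, min_cols=2,
                                                     representation="maximal"))
        assert {p.items for p in maximal} == {frozenset("AHJ")}

    def test_relative_support_of_BJ(self, dex_db):
        pats = mine_patterns(dex_db, MiningConfig(theta=2, min_cols=2,
                                                  representation="all"))
        bj = next(p for p in pats if p.items == frozenset("BJ"))
        assert bj.coverage == frozenset({1, 2})
        assert bj.relative_support(dex_db.n_transactions) == pytest.approx(1 / 3)

    def test_coverage_exact_by_scan(self, dex_db):
        pats = mine_patterns(dex_db, MiningConfig(theta=2, min_cols=1,
                                                  representation="all"))
        for p in pats:
            scan = {i for i, s in enumerate(DEX_ITEMSETS) if p.items <= s}
            assert p.coverage == frozenset(scan)


class TestOracleEquivalence:
    @pytest.mark.parametrize("representation", ["all", "closed", "maximal"])
    def test_matches_brute_force_on_random_databases(self, representation):
        rng = np.random.default_rng(2024)
        for _ in range(70):
            sets = random_itemset_db(rng)
            theta = int(rng.integers(1, len(sets) + 1))
            db = TransactionDatabase.from_itemsets(sets)
            expect = {frozenset(p): frozenset(c) for p, c in
                      brute_force_fim(sets, theta, representation).items()}
            for alg in ("fpgrowth", "eclat", "apriori"):
                got = {p.items: p.coverage for p in mine_patterns(
                    db, MiningConfig(theta=theta, representation=representation,
                                     algorithm=alg, min_cols=1))}
                assert got == expect

    def test_representation_nesting(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            sets = random_itemset_db(rng)
            theta = int(rng.integers(1, len(sets) + 1))
            db = TransactionDatabase.from_itemsets(sets)
            out = {}
            for rep in ("all", "closed", "maximal"):
                out[rep] = {p.items for p in mine_patterns(
                    db, MiningConfig(theta=theta, representation=rep, min_cols=1))}
            assert out["maximal"] <= out["closed"] <= out["all"]

    def test_anti_monotonicity(self):
        rng = np.random.default_rng(11)
        sets = random_itemset_db(rng)
        db = TransactionDatabase.from_itemsets(sets)
        pats = {p.items: p.support for p in mine_patterns(
            db, MiningConfig(theta=2, representation="all", min_cols=1))}
        for items, sup in pats.items():
            for x in items:
                sub = items - {x}
                if sub:
                    assert pats[sub] >= sup

    def test_max_support_at_size_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            sets = random_itemset_db(rng)
            db = TransactionDatabase.from_itemsets(sets)
            for size in (2, 3):
                freq = brute_force_fim(sets, 1, "all", min_size=size)
                expect = max((len(c) for p, c in freq.items()
                              if len(p) == size), default=0)
                got = max_support_at_size(db, size, lower_bound=1)
                assert got == expect


class TestBiclusterDerivation:
    def test_definition_mapping(self):
        db = TransactionDatabase.from_itemsets(
            [[(0, 1), (1, 2)], [(0, 9)], [(0, 1), (1, 2)], [(0, 1), (1, 2)]],
            t_ids=[0, 1, 2, 5])
        pats = mine_patterns(db, MiningConfig(theta=3, min_cols=2,
                                              representation="all"))
        bics = patterns_to_biclusters(pats, "rows")
        assert len(bics) == 1
        assert bics[0].rows == (0, 2, 5)
        assert bics[0].cols == (0, 1)
        assert bics[0].profile == (1, 2)

    def test_empty_patterns_give_empty_solution(self):
        assert patterns_to_biclusters([], "rows") == []

    def test_dex_closed_biclusters_row_sets(self):
        # the letter database with items encoded as (column, symbol) pairs
        letters = {c: i for i, c in enumerate("ABCDEFGHIJ")}
        db = TransactionDatabase.from_itemsets(
            [{(letters[c], 0) for c in s} for s in DEX_ITEMSETS])
        pats = mine_patterns(db, MiningConfig(theta=3, min_cols=2,
                                              representation="closed"))
        bics = patterns_to_biclusters(pats, "rows")
        assert sorted(len(b.rows) for b in bics) == [3, 4]
        assert sorted(len(b.cols) for b in bics) == [2, 3]


class TestAdaptiveMining:
    def _db(self, n=40, m=8, seed=0):
        rng = np.random.default_rng(seed)
        sets = [[(j, int(rng.integers(0, 4))) for j in range(m)]
                for _ in range(n)]
        # plant a block: rows 0..9 share the same symbols on cols 0..3
        for i in range(10):
            for j in range(4):
                sets[i][j] = (j, 9)
        return TransactionDatabase.from_itemsets(sets), (n, m)

    def test_stops_when_planted_block_reaches_target(self):
        db, shape = self._db()
        cfg = MiningConfig(representation="closed", min_cols=3,
                           coverage_target=0.05, support_floor=2)
        log = []
        bics = adaptive_mine(db, cfg, shape, log=log)
        covered = union_area(bics, *shape)
        assert covered > 0.05 * shape[0] * shape[1]
        assert any(b.rows == tuple(range(10)) for b in bics)

    def test_coverage_monotone_along_ladder(self):
        db, shape = self._db(seed=3)
        cfg = MiningConfig(representation="closed", min_cols=2,
                           coverage_target=1.0, support_floor=3)
        log = []
        adaptive_mine(db, cfg, shape, log=log)
        covs = [e["coverage"] for e in log if "coverage" in e]
        assert all(b >= a for a, b in zip(covs, covs[1:]))

    def test_equivalent_to_literal_loop(self):
        # the single-shot floor mining + rung subsets must equal literally
        # re-mining at every rung
        db, shape = self._db(seed=5)
        cfg = MiningConfig(representation="closed", min_cols=2,
                           coverage_target=0.2, support_floor=2)
        fast = adaptive_mine(db, cfg, shape)
        theta0 = max(cfg.support_floor, int(np.ceil(0.25 * db.n_transactions)))
        literal = None
        for t in support_ladder(theta0, cfg.support_floor, cfg.decay):
            pats = mine_patterns(db, MiningConfig(
                theta=int(np.ceil(t)), representation="closed", min_cols=2))
            literal = patterns_to_biclusters(pats, "rows")
            seen, uniq = set(), []
            for b in literal:
                if b.key() not in seen:
                    seen.add(b.key())
                    uniq.append(b)
            literal = uniq
            if union_area(literal, *shape) > 0.2 * shape[0] * shape[1]:
                break
        assert {b.key() for b in fast} == {b.key() for b in literal}

    def test_unstructured_data_terminates_at_floor(self):
        rng = np.random.default_rng(1)
        sets = [[(j, int(rng.integers(0, 50))) for j in range(6)]
                for _ in range(30)]
        db = TransactionDatabase.from_itemsets(sets)
        cfg = MiningConfig(representation="closed", min_cols=3,
                           coverage_target=0.05, support_floor=2)
        bics = adaptive_mine(db, cfg, (30, 6))
        assert union_area(bics, 30, 6) <= 0.2 * 30 * 6


def test_estimated_defaults_scale_with_noise_density():
    rng = np.random.default_rng(0)
    def make(n, L):
        sets = [[(j, int(rng.integers(0, L))) for j in range(20)]
                for _ in range(n)]
        return TransactionDatabase.from_itemsets(sets)
    mc_small, floor_small = estimate_mining_defaults(make(100, 7), 20)
    mc_big, floor_big = estimate_mining_defaults(make(100, 3), 20)
    assert 2 <= mc_small <= 4 and 2 <= mc_big <= 4
    # denser alphabets admit more chance agreement -> higher floor
    assert floor_big >= floor_small
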