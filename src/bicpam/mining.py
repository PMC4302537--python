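"""Frequent-itemset mining with exact coverage (transaction-set) tracing.

Biclusters are read off frequent itemsets directly: with one transaction per
matrix row and items ``(column, symbol)``, an itemset ``P`` with coverage
``phi(P)`` is the bicluster ``(phi(P), columns(P))`` — perfectly constant in
the itemized matrix.  Closed itemsets (no superset with equal support)
correspond to maximal biclusters: no row or column can be added without
breaking the pattern.

Three miners are provided; they return identical pattern sets and differ only
in how the search space is traversed:

``fpgrowth``
    Depth-first pattern growth over conditional databases, counting item
    frequencies inside each pattern's transaction set (the default; fastest
    here because the conditional counts are vectorized).
``eclat``
    Vertical tidset intersection.
``apriori``
    Level-wise candidate generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
from scipy.stats import poisson

from .core import Bicluster
from .mapping import ConfigError, ItemizedMatrix, TransactionDatabase


@dataclass(frozen=True)
class Pattern:
    """A frequent itemset together with the exact set of supporting
    transactions (its coverage)."""

    items: frozenset
    coverage: frozenset

    @property
    def support(self) -> int:
        return len(self.coverage)

    def relative_support(self, db_size: int) -> float:
        return len(self.coverage) / db_size


@dataclass
class MiningConfig:
    """Mining parameters.

    theta
        Minimum support: an int is an absolute transaction count, a float in
        (0, 1] a fraction of the database.  ``None`` lets the adaptive loop
        start at 25% of the transactions.
    representation
        ``all`` | ``closed`` | ``maximal``.
    min_cols
        Minimum itemset size (a 1-column bicluster is a cluster).
    decay / coverage_target / support_floor
        The adaptive loop multiplies the support threshold by ``decay`` until
        the biclusters cover ``coverage_target`` of the matrix area or the
        threshold falls below ``support_floor``.
    """

    theta: float | int | None = None
    representation: str = "closed"
    algorithm: str = "fpgrowth"
    min_cols: int = 2
    max_rows: int | None = None
    max_cols: int | None = None
    decay: float = 0.9
    coverage_target: float = 0.05
    support_floor: int = 2

    def __post_init__(self):
        if self.representation not in ("all", "closed", "maximal"):
            raise ConfigError(f"unknown representation {self.representation!r}")
        if self.algorithm not in ("fpgrowth", "eclat", "apriori"):
            raise ConfigError(f"unknown algorithm {self.algorithm!r}")
        if not (0.0 < self.decay < 1.0):
            raise ConfigError("decay must lie in (0, 1)")
        if self.support_floor < 1:
            raise ConfigError("support_floor must be >= 1")
        if self.min_cols < 1:
            raise ConfigError("min_cols must be >= 1")


def _absolute_theta(theta, n_transactions: int) -> int:
    if isinstance(theta, float) and not theta.is_integer():
        if not (0.0 < theta <= 1.0):
            raise ConfigError("relative support must lie in (0, 1]")
        return max(1, math.ceil(theta * n_transactions))
    t = int(theta)
    if t < 1:
        raise ConfigError("absolute support must be >= 1")
    return t


# ---------------------------------------------------------------------------
# Miners.  Each returns a list of (item_id_frozenset, row_index_array).

class _Vertical:
    """Shared vertical representation of a database."""

    def __init__(self, db: TransactionDatabase):
        self.n = db.n_transactions
        self.n_items = len(db.items)
        lens = np.fromiter((len(t) for t in db.transactions), dtype=np.int64,
                           count=self.n)
        self.member = np.zeros((self.n_items, self.n), dtype=bool)
        for t, arr in enumerate(db.transactions):
            self.member[arr, t] = True
        self.tidlists = [np.flatnonzero(self.member[i])
                         for i in range(self.n_items)]
        # transactions padded to equal length with an extra sentinel id, so a
        # conditional count is one fancy-index + one bincount
        w = int(lens.max()) if self.n else 0
        self.padded = np.full((self.n, w), self.n_items, dtype=np.int64)
        for t, arr in enumerate(db.transactions):
            self.padded[t, :len(arr)] = arr

    def counts_in(self, rows: np.ndarray) -> np.ndarray:
        """Item frequencies within the conditional database of ``rows``."""
        if rows.size == 0:
            return np.zeros(self.n_items, dtype=np.int64)
        return np.bincount(self.padded[rows].ravel(),
                           minlength=self.n_items + 1)[:-1]


def _mine_growth(db: TransactionDatabase, theta: int, max_len: int | None,
                 closed_only: bool):
    """Pattern growth with conditional counting.

    With ``closed_only`` the search jumps along closures (LCM-style): each
    node extends directly to the closure of prefix+item, and a branch is
    pruned when its closure contains an item below the extension item (the
    prefix-preserving test), so every closed itemset is generated exactly
    once.  Otherwise all frequent itemsets are enumerated by ordered
    extension.
    """
    V = _Vertical(db)
    out: list[tuple[frozenset, np.ndarray]] = []
    all_rows = np.arange(V.n)
    root_counts = V.counts_in(all_rows)

    if closed_only:
        def grow_closed(closure: set, rows: np.ndarray, counts: np.ndarray,
                        last: int):
            for j in np.flatnonzero(counts >= theta):
                j = int(j)
                if j <= last or j in closure:
                    continue
                new_rows = rows[V.member[j][rows]]
                sup = new_rows.size
                ncounts = V.counts_in(new_rows)
                full = np.flatnonzero(ncounts == sup)
                ok = True
                for f in full:
                    if f < j and int(f) not in closure:
                        ok = False
                        break
                if not ok:
                    continue
                new_closure = closure | {int(f) for f in full} | {j}
                if max_len is not None and len(new_closure) > max_len:
                    continue
                out.append((frozenset(new_closure), new_rows))
                grow_closed(new_closure, new_rows, ncounts, j)

        closure0 = {int(f) for f in np.flatnonzero(root_counts == V.n)}
        if closure0 and V.n >= theta and \
                (max_len is None or len(closure0) <= max_len):
            out.append((frozenset(closure0), all_rows))
        grow_closed(closure0, all_rows, root_counts, -1)
        return out

    def grow(prefix: tuple, rows: np.ndarray, counts: np.ndarray, last: int):
        if prefix:
            out.append((frozenset(prefix), rows))
        if max_len is not None and len(prefix) >= max_len:
            return
        for j in np.flatnonzero(counts >= theta):
            if j <= last:
                continue
            new_rows = rows[V.member[j][rows]]
            grow(prefix + (int(j),), new_rows, V.counts_in(new_rows), int(j))

    grow((), all_rows, root_counts, -1)
    return out


def _mine_eclat(db: TransactionDatabase, theta: int, max_len: int | None):
    V = _Vertical(db)
    out: list[tuple[frozenset, np.ndarray]] = []

    def recurse(prefix: tuple, rows: np.ndarray, candidates: list[int]):
        for idx, j in enumerate(candidates):
            new_rows = np.intersect1d(rows, V.tidlists[j], assume_unique=True) \
                if prefix else V.tidlists[j]
            if new_rows.size < theta:
                continue
            pat = prefix + (j,)
            out.append((frozenset(pat), new_rows))
            if max_len is None or len(pat) < max_len:
                recurse(pat, new_rows, candidates[idx + 1:])

    freq_items = [i for i in range(V.n_items) if V.tidlists[i].size >= theta]
    recurse((), np.arange(V.n), freq_items)
    return out


def _mine_apriori(db: TransactionDatabase, theta: int, max_len: int | None):
    V = _Vertical(db)
    out: list[tuple[frozenset, np.ndarray]] = []
    level = {(i,): V.tidlists[i] for i in range(V.n_items)
             if V.tidlists[i].size >= theta}
    for pat, rows in level.items():
        out.append((frozenset(pat), rows))
    k = 1
    while level and (max_len is None or k < max_len):
        nxt: dict[tuple, np.ndarray] = {}
        pats = sorted(level)
        for a in pats:
            for b in pats:
                if b <= a or a[:-1] != b[:-1]:
                    continue
                cand = a + (b[-1],)
                # all (k-1)-subsets must be frequent (anti-monotonicity)
                if k > 1 and any(cand[:i] + cand[i + 1:] not in level
                                 for i in range(k + 1)):
                    continue
                rows = np.intersect1d(level[a], level[b], assume_unique=True)
                if rows.size >= theta:
                    nxt[cand] = rows
        for pat, rows in nxt.items():
            out.append((frozenset(pat), rows))
        level = nxt
        k += 1
    return out


def max_support_at_size(db: TransactionDatabase, size: int,
                        lower_bound: int = 2) -> int:
    """Largest support of any itemset with exactly ``size`` items (by
    anti-monotonicity, also the largest support among itemsets with >= size
    items).  Branch-and-bound: a prefix whose support does not exceed the
    best full-size itemset found so far cannot improve it, so candidates
    are visited in decreasing support order and pruned aggressively."""
    if size < 1:
        return db.n_transactions
    V = _Vertical(db)
    best = lower_bound - 1

    def dfs(rows: np.ndarray, counts: np.ndarray, last: int, depth: int):
        nonlocal best
        idx = np.flatnonzero(counts > best)
        idx = idx[idx > last]
        if idx.size == 0:
            return
        order = np.argsort(counts[idx], kind="stable")[::-1]
        for j in idx[order]:
            if counts[j] <= best:
                continue
            new_rows = rows[V.member[j][rows]]
            if new_rows.size <= best:
                continue
            if depth + 1 == size:
                best = new_rows.size
            else:
                dfs(new_rows, V.counts_in(new_rows), int(j), depth + 1)

    all_rows = np.arange(V.n)
    dfs(all_rows, V.counts_in(all_rows), -1, 0)
    return best if best >= lower_bound else 0


def _closure(V: _Vertical, rows: np.ndarray) -> frozenset:
    counts = V.counts_in(rows)
    return frozenset(int(j) for j in np.flatnonzero(counts == rows.size))


def _filter_closed(db, raw):
    V = _Vertical(db)
    return [(p, rows) for p, rows in raw if _closure(V, rows) == p]


def _filter_maximal(closed):
    """Maximal = closed itemsets with no frequent proper superset; every
    frequent superset implies a closed superset, so checking within the
    closed set is sufficient."""
    out = []
    by_size = sorted(closed, key=lambda pr: len(pr[0]), reverse=True)
    kept: list[frozenset] = []
    for p, rows in by_size:
        if not any(p < q for q in kept):
            out.append((p, rows))
            kept.append(p)
    return out


def mine_patterns(db: TransactionDatabase, cfg: MiningConfig) -> list[Pattern]:
    """All itemsets with support >= theta and size >= min_cols, under the
    requested representation, each with its exact coverage."""
    if db.n_transactions == 0:
        raise ConfigError("empty transaction database")
    theta = _absolute_theta(cfg.theta if cfg.theta is not None else
                            max(cfg.support_floor, math.ceil(0.25 * db.n_transactions)),
                            db.n_transactions)
    if theta > db.n_transactions:
        return []
    max_len = cfg.max_cols
    if cfg.algorithm == "fpgrowth":
        raw = _mine_growth(db, theta, max_len,
                           closed_only=(cfg.representation != "all"))
        if cfg.representation == "all":
            pass
        elif cfg.representation == "maximal":
            raw = _filter_maximal(raw)
    else:
        miner = _mine_eclat if cfg.algorithm == "eclat" else _mine_apriori
        raw = miner(db, theta, max_len)
        if cfg.representation in ("closed", "maximal"):
            raw = _filter_closed(db, raw)
        if cfg.representation == "maximal":
            raw = _filter_maximal(raw)
    out = []
    for ids, rows in raw:
        if len(ids) < cfg.min_cols:
            continue
        if cfg.max_rows is not None and rows.size > cfg.max_rows:
            continue
        if cfg.max_cols is not None and len(ids) > cfg.max_cols:
            continue
        out.append(Pattern(db.decode(ids),
                           frozenset(db.t_ids[r] for r in rows)))
    # deterministic output order: by (-support, sorted items)
    out.sort(key=lambda p: (-p.support, sorted(map(repr, p.items))))
    return out


# ---------------------------------------------------------------------------
# Pattern -> bicluster

def patterns_to_biclusters(patterns: Iterable[Pattern],
                           orientation: str = "rows",
                           itemized: ItemizedMatrix | None = None) -> list[Bicluster]:
    """Map itemsets to biclusters: coverage becomes the row set and the
    pattern's columns the column set (roles swapped for ``columns``
    orientation).

    A pattern carrying two symbols for the same column (a multi-item
    artifact) keeps the column once with the symbol matching the majority of
    the covered rows' primary symbols (smaller symbol on ties, or when no
    itemized matrix is available).
    """
    if orientation not in ("rows", "columns"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    out = []
    for pat in patterns:
        per_col: dict[int, list] = {}
        for col, sym in pat.items:
            per_col.setdefault(col, []).append(sym)
        cols = sorted(per_col)
        profile = []
        for c in cols:
            syms = sorted(per_col[c])
            if len(syms) == 1:
                profile.append(syms[0])
                continue
            if itemized is None:
                profile.append(syms[0])
                continue
            votes = {s: 0 for s in syms}
            for r in pat.coverage:
                prim = (itemized.primary[r, c] if orientation == "rows"
                        else itemized.primary[c, r])
                if prim in votes:
                    votes[prim] += 1
            profile.append(max(syms, key=lambda s: (votes[s], -s)))
        rows = tuple(sorted(pat.coverage))
        if orientation == "rows":
            out.append(Bicluster(rows=rows, cols=tuple(cols),
                                 coherency="constant_rows",
                                 profile=tuple(profile)))
        else:
            out.append(Bicluster(rows=tuple(cols), cols=rows,
                                 coherency="constant_cols",
                                 profile=tuple(profile)))
    return out


def union_area(biclusters: Iterable[Bicluster], n: int, m: int) -> int:
    """Number of matrix cells covered by at least one bicluster."""
    mask = np.zeros((n, m), dtype=bool)
    for b in biclusters:
        mask[np.ix_(b.rows, b.cols)] = True
    return int(mask.sum())


def support_ladder(theta0: float, floor: float, decay: float) -> list[float]:
    """The decreasing support schedule theta0, theta0*decay, ... clipped at
    the floor (the floor itself is always the last rung)."""
    ladder = []
    t = float(theta0)
    while t > floor:
        ladder.append(t)
        t *= decay
    ladder.append(float(floor))
    return ladder


def floor_for_cols(floors: dict[int, int], c: int) -> int:
    """Applicable support floor for a pattern with ``c`` columns: the floor
    of the widest calibrated tier not exceeding ``c``."""
    keys = sorted(floors)
    best = floors[keys[0]]
    for k in keys:
        if k <= c:
            best = floors[k]
    return best


def adaptive_mine(db: TransactionDatabase, cfg: MiningConfig,
                  matrix_shape: tuple[int, int],
                  orientation: str = "rows",
                  itemized: ItemizedMatrix | None = None,
                  floor_by_cols: dict[int, int] | None = None,
                  log: list | None = None) -> list[Bicluster]:
    """Support-decay loop: lower the threshold by ``decay`` per step until the
    biclusters cover ``coverage_target`` of the matrix or the floor is hit.

    For the ``all`` and ``closed`` representations the result at every rung of
    the schedule is, by anti-monotonicity of support, exactly the subset of
    the floor-level patterns whose support clears that rung (closedness does
    not depend on the threshold).  The loop is therefore evaluated by mining
    once at the floor and walking the schedule over pattern supports, which
    is equivalent to re-mining at every rung.  ``maximal`` is
    threshold-dependent and falls back to literal re-mining.
    """
    n, m = matrix_shape
    area = n * m
    theta0 = _absolute_theta(cfg.theta if cfg.theta is not None else
                             max(cfg.support_floor, math.ceil(0.25 * db.n_transactions)),
                             db.n_transactions)
    floor = max(1, int(cfg.support_floor))
    theta0 = max(theta0, floor)
    ladder = support_ladder(theta0, floor, cfg.decay)
    target_cells = cfg.coverage_target * area

    if cfg.representation == "maximal":
        best: list[Bicluster] = []
        for t in ladder:
            sub_cfg = _with_theta(cfg, math.ceil(t))
            pats = mine_patterns(db, sub_cfg)
            best = _dedup(patterns_to_biclusters(pats, orientation, itemized))
            cov = union_area(best, n, m)
            if log is not None:
                log.append({"theta": math.ceil(t), "n_biclusters": len(best),
                            "coverage": cov / area})
            if cov > target_cells:
                return best
        return best

    floor_cfg = _with_theta(cfg, floor)
    pats = mine_patterns(db, floor_cfg)
    if floor_by_cols:
        pats = [p for p in pats
                if p.support >= floor_for_cols(floor_by_cols, _n_cols(p))]
    for t in ladder:
        t_abs = math.ceil(t)
        sub = [p for p in pats if p.support >= t_abs]
        bics = _dedup(patterns_to_biclusters(sub, orientation, itemized))
        cov = union_area(bics, n, m)
        if log is not None:
            log.append({"theta": t_abs, "n_biclusters": len(bics),
                        "coverage": cov / area})
        if cov > target_cells:
            return bics
    return bics  # floor-level (richest) set


def _n_cols(p: Pattern) -> int:
    cols = {i[0] for i in p.items if isinstance(i, tuple)}
    return len(cols) if cols else len(p.items)


def _with_theta(cfg: MiningConfig, theta: int) -> MiningConfig:
    return MiningConfig(theta=theta, representation=cfg.representation,
                        algorithm=cfg.algorithm, min_cols=cfg.min_cols,
                        max_rows=cfg.max_rows, max_cols=cfg.max_cols,
                        decay=cfg.decay, coverage_target=cfg.coverage_target,
                        support_floor=cfg.support_floor)


def _dedup(biclusters: list[Bicluster]) -> list[Bicluster]:
    seen = set()
    out = []
    for b in biclusters:
        if b.key() not in seen:
            seen.add(b.key())
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# Data-driven parameterization

def estimate_mining_defaults(db: TransactionDatabase, n_columns: int,
                             spurious_budget: float = 0.1,
                             node_budget: int = 500_000,
                             max_min_cols: int = 4) -> tuple[int, int]:
    """Estimate (min_cols, support_floor) from the database's own item
    frequencies, so that the expected number of chance patterns reaching the
    floor stays below ``spurious_budget`` while the mining search space stays
    below ``node_budget`` nodes.

    The background model treats cells as independent draws from the observed
    per-column symbol frequencies: a random pattern over ``c`` columns is
    matched by a row with probability ``q^c`` where ``q`` is the mean
    per-column collision probability.  Expected counts of chance patterns are
    Poisson-approximated and summed over candidate column sets.
    """
    n = db.n_transactions
    flat = (np.concatenate(db.transactions) if db.total_items()
            else np.empty(0, dtype=np.int64))
    counts = np.bincount(flat, minlength=len(db.items))
    per_col: dict = {}
    for idx, item in enumerate(db.items):
        col = item[0] if isinstance(item, tuple) else 0
        per_col.setdefault(col, []).append(counts[idx] / n)
    qs = [sum(p * p for p in ps) for ps in per_col.values()]
    # near-constant columns (collision probability > 0.5, e.g. an aligned
    # reference column) join any pattern almost for free: they are removed
    # from the background model and credited against the pattern length
    informative = [x for x in qs if x <= 0.5]
    free_cols = len(qs) - len(informative)
    q = float(np.mean(informative)) if informative else 0.5
    q = min(max(q, 1e-9), 0.999)
    m = max(n_columns, len(per_col)) - free_cols
    m = max(m, 1)

    def expected_patterns(c: int, theta: int) -> float:
        c_inf = max(1, c - free_cols)
        lam = n * q ** c_inf
        combos = math.comb(m, min(c_inf, m)) * (1.0 / q) ** c_inf
        return combos * float(poisson.sf(theta - 1, lam))

    def floor_for(c: int, budget: float) -> int:
        for theta in range(2, n + 2):
            e = sum(expected_patterns(cc, theta) for cc in range(c, c + 4)
                    if cc <= m)
            if e <= budget:
                return theta
        return n + 1

    def nodes_at(theta: int, out_cols: int) -> float:
        return sum(expected_patterns(cc, theta)
                   for cc in range(2, min(out_cols, m) + 1))

    floors = {}
    for c in range(2, max_min_cols + 1):
        t = floor_for(c, spurious_budget)
        while nodes_at(t, c) > node_budget and t <= n:
            t += 1
        floors[c] = t
    best_c = 2
    while best_c < max_min_cols:
        gain = floors[best_c] - floors[best_c + 1]
        if gain >= max(2, 0.1 * floors[best_c]):
            best_c += 1
        else:
            break
    return best_c, min(floors[best_c], n)
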