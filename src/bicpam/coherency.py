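"""Column alignments reducing non-constant coherencies to constant mining.

An additive (shifting) bicluster has ``a_ij = c + alpha_i + beta_j``, a
multiplicative (scaling) one ``a_ij = c' * alpha'_i * beta'_j``, and a
symmetric one flips whole rows in sign.  Each reduces to a constant-on-rows
pattern after a per-row adjustment computed against a reference column:

- additive: shift row ``i`` by ``max(y_j) - a_ij`` so that column ``j``
  becomes constant at its maximum; row offsets cancel for any additive
  bicluster containing ``j``;
- multiplicative: scale row ``i`` by ``max(y_j) / a_ij`` (on symbols remapped
  to 1..|L|); near-equal scaled values are gathered into one item by a
  relative ``delta``-error;
- symmetric: multiply rows negative in column ``j`` by -1 (requires a
  zero-centered alphabet; a zero reference symbol keeps sign +1).

Since the bicluster's columns are unknown a priori, the miner is applied once
per candidate reference column and the solutions are de-duplicated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import Bicluster
from .mapping import (ConfigError, ItemizedMatrix, TransactionDatabase,
                      _NO_SYMBOL, build_transactions)
from .mining import (MiningConfig, Pattern, adaptive_mine, mine_patterns,
                     patterns_to_biclusters)

COHERENT_MODES = ("additive", "multiplicative", "symmetric+constant",
                  "symmetric+additive", "symmetric+multiplicative")


@dataclass
class AlignmentPlan:
    """Record of one reference-column alignment, for back-mapping."""

    mode: str
    reference_column: int
    offsets: np.ndarray | None = None        # additive: per-row int shift
    factors: np.ndarray | None = None        # multiplicative: per-row scale
    signs: np.ndarray | None = None          # symmetric: per-row +-1
    group_values: list = field(default_factory=list)  # group id -> value
    expanded_alphabet_size: int = 0
    lcm_group_delta: float = 0.0

    def model_params(self, rows) -> dict:
        p: dict = {"reference_column": int(self.reference_column)}
        if self.offsets is not None:
            p["row_offsets"] = {int(r): int(self.offsets[r]) for r in rows}
        if self.factors is not None:
            p["row_factors"] = {int(r): float(self.factors[r]) for r in rows}
        if self.signs is not None:
            p["row_signs"] = {int(r): int(self.signs[r]) for r in rows}
        if self.group_values:
            p["group_values"] = [float(v) for v in self.group_values]
        return p


def _ref_column_primaries(it: ItemizedMatrix, j: int) -> np.ndarray:
    col = it.primary[:, j]
    if (col == _NO_SYMBOL).all():
        raise ConfigError(f"reference column {j} empty")
    return col


def _transform(it: ItemizedMatrix, fn: Callable[[int, int], int],
               alphabet_size: int,
               vectorized: Callable[[np.ndarray], np.ndarray] | None = None) -> ItemizedMatrix:
    """Apply ``fn(row, symbol) -> symbol`` to every symbol of every row.

    ``vectorized``, when given, maps the whole primary array at once (cells
    holding the no-symbol sentinel are restored afterwards); ``fn`` is always
    used for the sparse extra symbols.
    """
    mask = it.primary != _NO_SYMBOL
    if vectorized is not None:
        prim = np.where(mask, vectorized(it.primary), _NO_SYMBOL)
    else:
        prim = it.primary.copy()
        for i, j in zip(*np.nonzero(mask)):
            prim[i, j] = fn(int(i), int(prim[i, j]))
    extra = {}
    for (i, j), syms in it.extra.items():
        extra[(i, j)] = tuple(sorted({fn(i, int(s)) for s in syms}))
    return ItemizedMatrix(prim, alphabet_size, zero_centered=False,
                          cutoffs=None, bin_edges=None, extra=extra)


def additive_align(it: ItemizedMatrix, j: int) -> tuple[ItemizedMatrix, AlignmentPlan]:
    """Shift every row so the reference column hits its maximum symbol; the
    output alphabet spans at most ``2|L| - 1`` symbols."""
    col = _ref_column_primaries(it, j)
    present = col != _NO_SYMBOL
    M = int(col[present].max())
    offsets = np.zeros(it.n, dtype=np.int64)
    offsets[present] = M - col[present]
    out = _transform(it, lambda i, s: s + int(offsets[i]), 2 * it.alphabet_size - 1,
                     vectorized=lambda P: P + offsets[:, None])
    plan = AlignmentPlan("additive", j, offsets=offsets,
                         expanded_alphabet_size=2 * it.alphabet_size - 1)
    return out, plan


def _group_values(values: np.ndarray, delta: float):
    """Gather positive values into items of relative width ``delta`` by
    logarithmic binning (values within one bin differ by at most a factor
    ``1 + delta``); returns (value -> dense group id, representatives).

    Log bins are used instead of single-linkage chaining because chaining
    would collapse long runs of closely spaced ratios into one item."""
    uniq = np.unique(values)
    if delta <= 0:
        gids = np.arange(uniq.size)
    else:
        raw = np.floor(np.log(np.maximum(uniq, 1e-12)) / np.log1p(delta)).astype(np.int64)
        _, gids = np.unique(raw, return_inverse=True)
    reps = [float(np.mean(uniq[gids == g])) for g in range(int(gids.max()) + 1 if uniq.size else 0)]
    lookup = dict(zip(uniq.tolist(), (int(g) for g in gids)))
    return lookup, reps


def multiplicative_align(it: ItemizedMatrix, j: int,
                         delta: float = 0.1) -> tuple[ItemizedMatrix, AlignmentPlan]:
    """Scale every row so the reference column hits its maximum.

    Symbols are first remapped to positive integers ``1..|L|``; the scaled
    values are then gathered into items, merging values closer than the
    relative ``delta``-error (the scaled alphabet would otherwise explode
    into one item per distinct ratio).
    """
    if min(it.alphabet) < 0:
        raise ConfigError("multiplicative alignment requires a non-negative alphabet")
    base = 1 - min(it.alphabet)  # remap 0-based symbols to 1..|L|

    col = _ref_column_primaries(it, j)
    present = col != _NO_SYMBOL
    M = int(col[present].max()) + base
    factors = np.ones(it.n, dtype=float)
    factors[present] = M / (col[present].astype(float) + base)

    # collect every scaled value to build the grouped item alphabet
    mask = it.primary != _NO_SYMBOL
    scaled = (it.primary + base).astype(float) * factors[:, None]
    vals = scaled[mask].tolist()
    for (i, jj), syms in it.extra.items():
        for s in syms:
            vals.append((s + base) * factors[i])
    lookup, reps = _group_values(np.array(vals, dtype=float), delta)
    uniq = np.array(sorted(lookup), dtype=float)
    gid_of = np.array([lookup[v] for v in uniq.tolist()], dtype=np.int64)

    def fn(i: int, s: int) -> int:
        return int(lookup[(s + base) * factors[i]])

    def vec(P: np.ndarray) -> np.ndarray:
        sc = (P + base).astype(float) * factors[:, None]
        idx = np.clip(np.searchsorted(uniq, sc), 0, uniq.size - 1)
        return gid_of[idx]

    out = _transform(it, fn, len(reps), vectorized=vec)
    plan = AlignmentPlan("multiplicative", j, factors=factors,
                         group_values=reps, expanded_alphabet_size=len(reps),
                         lcm_group_delta=delta)
    return out, plan


def symmetric_align(it: ItemizedMatrix, j: int,
                    combined: bool = False) -> tuple[ItemizedMatrix, AlignmentPlan]:
    """Flip the sign of every row that is negative in the reference column.

    Requires a zero-centered alphabet (zero-mean normalization); a zero in
    the reference column, being its own symmetric, keeps sign +1.  With
    ``combined`` the caller composes the sign with an additive or
    multiplicative adjustment in the same pass.
    """
    if not it.zero_centered and min(it.alphabet) >= 0:
        raise ConfigError("symmetric alignment requires a zero-centered alphabet")
    col = _ref_column_primaries(it, j)
    present = col != _NO_SYMBOL
    signs = np.ones(it.n, dtype=np.int64)
    signs[present & (col < 0)] = -1
    out = _transform(it, lambda i, s: s * int(signs[i]), it.alphabet_size,
                     vectorized=lambda P: P * signs[:, None])
    out.zero_centered = it.zero_centered
    plan = AlignmentPlan("symmetric", j, signs=signs,
                         expanded_alphabet_size=it.alphabet_size)
    return out, plan


def align(it: ItemizedMatrix, coherency: str, j: int,
          delta: float = 0.1) -> tuple[ItemizedMatrix, AlignmentPlan]:
    """Dispatch one reference-column alignment, including the combined
    sign-plus-coherent modes (sign first, then shift/scale)."""
    if coherency == "additive":
        return additive_align(it, j)
    if coherency == "multiplicative":
        return multiplicative_align(it, j, delta)
    if coherency in ("symmetric", "symmetric+constant"):
        return symmetric_align(it, j)
    if coherency == "symmetric+additive":
        signed, plan_s = symmetric_align(it, j)
        out, plan_a = additive_align(signed, j)
        plan_a.signs = plan_s.signs
        plan_a.mode = "symmetric+additive"
        return out, plan_a
    if coherency == "symmetric+multiplicative":
        signed, plan_s = symmetric_align(it, j)
        # shift to a positive alphabet before scaling
        mn = min(min(signed.alphabet), int(signed.primary[signed.primary != _NO_SYMBOL].min(initial=0)))
        shift = -mn if mn < 0 else 0
        shifted = _transform(signed, lambda i, s: s + shift,
                             signed.alphabet_size + shift)
        out, plan_m = multiplicative_align(shifted, j, delta)
        plan_m.signs = plan_s.signs
        plan_m.mode = "symmetric+multiplicative"
        return out, plan_m
    raise ConfigError(f"unknown coherency {coherency!r}")


def _label(coherency: str) -> str:
    return coherency if coherency != "symmetric" else "symmetric+constant"


def permute_columns(it: ItemizedMatrix, seed: int = 0) -> ItemizedMatrix:
    """Independently permute each column's cells across rows: a null matrix
    with the same marginal item frequencies (and missing layout per column)
    but no row-wise structure."""
    rng = np.random.default_rng(seed)
    prim = np.empty_like(it.primary)
    invs = []
    for j in range(it.m):
        p = rng.permutation(it.n)
        prim[:, j] = it.primary[p, j]
        inv = np.empty(it.n, dtype=np.int64)
        inv[p] = np.arange(it.n)
        invs.append(inv)
    extra = {}
    for (i, j), syms in it.extra.items():
        extra[(int(invs[j][i]), j)] = syms
    out = it.copy()
    out.primary = prim
    out.extra = extra
    return out


def _null_max_support(db: TransactionDatabase, cfg: MiningConfig,
                      min_cols: int, lower_bound: int = 2) -> int:
    """Strongest pattern (with >= min_cols items) in a null database: by
    anti-monotonicity it equals the strongest pattern with exactly min_cols
    items, found by branch-and-bound without enumerating the chance flood."""
    from .mining import max_support_at_size
    return max_support_at_size(db, min_cols, max(2, lower_bound))


def calibrate_support_floors(it: ItemizedMatrix, coherency: str,
                             cfg: MiningConfig, delta: float = 0.1,
                             tune: Callable | None = None,
                             seed: int = 0, n_tiers: int = 2,
                             tier_sample_refs: int = 3) -> dict[int, int]:
    """Support floors from a permutation null, per pattern column count.

    Each column of the itemized matrix is permuted independently, the
    alignment/mining machinery is run on the null exactly as it will run on
    the data, and the floor for the base column count is set above the
    strongest pattern any null alignment produces (+2: the observed null
    maximum is one draw of an extreme-value statistic and typically sits a
    unit below the data's own chance maximum).  This captures every source
    of chance co-occurrence — item-frequency skew, multi-item growth, the
    adjustment correlations introduced by alignment — without
    distributional assumptions.

    Chance support drops steeply with the number of columns, so wider
    patterns deserve a lower floor: additional tiers (base+1, ...) are
    calibrated on a few sampled alignments with a +3 margin, and mining can
    then keep a wide pattern whose support clears its own tier even though
    it is below the base floor.  Returns ``{min_cols: floor}`` per tier.
    """
    null = permute_columns(it, seed)
    aligned_mode = coherency not in ("constant", "constant_rows",
                                     "constant_overall")
    if aligned_mode:
        nonempty = [j for j in range(it.m)
                    if not (it.primary[:, j] == _NO_SYMBOL).all()]
    else:
        nonempty = [None]

    # base tier: max over every alignment the real mining will perform
    base_c = None
    best = 0
    dbs = {}
    for j in nonempty:
        aligned = null if j is None else align(null, coherency, j, delta)[0]
        db = build_transactions(aligned, "rows")
        dbs[j] = db
        local = _tuned(cfg, db, tune)
        if base_c is None:
            base_c = local.min_cols
        got = _null_max_support(db, cfg, local.min_cols, best + 1)
        best = max(best, got)
    floors = {base_c: max(cfg.support_floor, 3, best + 2)}

    # deeper tiers on sampled alignments
    if aligned_mode and len(nonempty) > tier_sample_refs:
        idx = np.linspace(0, len(nonempty) - 1, tier_sample_refs).astype(int)
        sample = [nonempty[i] for i in idx]
    else:
        sample = list(nonempty)
    prev = floors[base_c]
    for t in range(1, n_tiers):
        c = base_c + t
        best_t = 0
        for j in sample:
            got = _null_max_support(dbs[j], cfg, c, best_t + 1)
            best_t = max(best_t, got)
        floor_t = max(cfg.support_floor, 3, best_t + 3)
        floor_t = min(floor_t, prev)
        if floor_t >= prev:
            break
        floors[c] = floor_t
        prev = floor_t
    return floors


def calibrate_support_floor(it: ItemizedMatrix, coherency: str,
                            cfg: MiningConfig, delta: float = 0.1,
                            tune: Callable | None = None,
                            seed: int = 0) -> int:
    """Base-tier support floor (see :func:`calibrate_support_floors`)."""
    floors = calibrate_support_floors(it, coherency, cfg, delta, tune,
                                      seed=seed, n_tiers=1)
    return next(iter(floors.values()))


def mine_coherent(it: ItemizedMatrix, coherency: str, cfg: MiningConfig,
                  delta: float = 0.1, adaptive: bool = False,
                  tune: Callable[[TransactionDatabase], tuple[int, int]] | None = None,
                  calibrate: bool = False,
                  min_ref_confirmations: int | None = None,
                  log: list | None = None) -> list[Bicluster]:
    """Iterate the constant-pattern miner over all reference columns for a
    non-constant coherency; de-duplicate solutions across iterations.

    ``constant`` degenerates to plain mining (no iteration).  For symmetric
    coherencies, reference columns producing an already-seen row-sign
    combination are skipped (every distinct sign assignment is still
    explored).  ``tune``, when given, maps each aligned database to
    data-driven ``(min_cols, support_floor)`` overrides.

    For shift/scale coherencies a genuine bicluster reappears under every
    reference column it contains (the aligned reference column is constant
    across all rows, so every closed pattern includes it), whereas a chance
    agreement is tied to one specific alignment.  ``min_ref_confirmations``
    (default 2 for additive/multiplicative in adaptive mode, else 1) keeps
    only biclusters confirmed by that many distinct reference columns,
    counting near-identical row sets (Jaccard >= 0.8 at equal columns)
    together.
    """
    n, m = it.n, it.m
    if coherency == "symmetric":
        coherency = "symmetric+constant"
    floors_null = None
    floor_min = 0
    if adaptive and calibrate:
        floors_null = calibrate_support_floors(it, coherency, cfg, delta, tune)
        floor_min = min(floors_null.values())
        if log is not None:
            log.append({"calibrated_floors": dict(floors_null)})
    if coherency in ("constant", "constant_rows"):
        db = build_transactions(it, "rows")
        cfg_l = _raise_floor(_tuned(cfg, db, tune), floor_min)
        if adaptive:
            return adaptive_mine(db, cfg_l, (n, m), itemized=it,
                                 floor_by_cols=floors_null, log=log)
        return patterns_to_biclusters(mine_patterns(db, cfg_l), "rows", it)
    if coherency == "constant_overall":
        # a bicluster constant overall is constant on rows within a single
        # symbol, so each symbol is mined separately
        out: list[Bicluster] = []
        seen: set = set()
        for s in it.alphabet:
            restricted = it.copy()
            restricted.primary = np.where(it.primary == s, it.primary,
                                          _NO_SYMBOL)
            restricted.extra = {k: (s,) for k, v in it.extra.items() if s in v}
            if (restricted.primary == _NO_SYMBOL).all() and not restricted.extra:
                continue
            db = build_transactions(restricted, "rows")
            if db.total_items() == 0:
                continue
            cfg_l = _raise_floor(_tuned(cfg, db, tune), floor_min)
            if adaptive:
                bics = adaptive_mine(db, cfg_l, (n, m), itemized=restricted,
                                     floor_by_cols=floors_null, log=log)
            else:
                bics = patterns_to_biclusters(mine_patterns(db, cfg_l),
                                              "rows", restricted)
            for b in bics:
                if b.key() not in seen:
                    seen.add(b.key())
                    out.append(Bicluster(rows=b.rows, cols=b.cols,
                                         coherency="constant_overall",
                                         profile=b.profile))
        return out
    if coherency == "symmetric":
        coherency = "symmetric+constant"
    if coherency not in COHERENT_MODES:
        raise ConfigError(f"unknown coherency {coherency!r}")

    if min_ref_confirmations is None:
        min_ref_confirmations = 2 if (adaptive and coherency in
                                      ("additive", "multiplicative")) else 1

    raw: list[tuple[Bicluster, int]] = []
    seen_signs: set = set()
    for j in range(m):
        col = it.primary[:, j]
        if (col == _NO_SYMBOL).all():
            continue
        aligned, plan = align(it, coherency, j, delta)
        if plan.signs is not None:
            sig = tuple(plan.signs.tolist())
            if coherency == "symmetric+constant" and sig in seen_signs:
                continue
            seen_signs.add(sig)
        db = build_transactions(aligned, "rows")
        cfg_l = _raise_floor(_tuned(cfg, db, tune), floor_min)
        if adaptive:
            bics = adaptive_mine(db, cfg_l, (n, m), itemized=aligned,
                                 floor_by_cols=floors_null, log=log)
        else:
            bics = patterns_to_biclusters(mine_patterns(db, cfg_l), "rows", aligned)
        for b in bics:
            raw.append((Bicluster(rows=b.rows, cols=b.cols,
                                  coherency=_label(coherency),
                                  profile=b.profile,
                                  model_params=plan.model_params(b.rows)), j))
    return _confirmed(raw, min_ref_confirmations)


def _confirmed(raw: list[tuple[Bicluster, int]], min_refs: int) -> list[Bicluster]:
    """Group near-identical biclusters across reference columns and keep one
    representative (the largest) per group seen from >= min_refs columns."""
    groups: dict[tuple, list[list]] = {}  # cols -> [rep_rowset, refs, best]
    for b, j in raw:
        placed = False
        for g in groups.setdefault(b.cols, []):
            rep = g[0]
            inter = len(rep & b.row_set)
            if inter / (len(rep) + len(b.rows) - inter) >= 0.8:
                g[1].add(j)
                if b.area > g[2].area:
                    g[2] = b
                placed = True
                break
        if not placed:
            groups[b.cols].append([b.row_set, {j}, b])
    out, seen = [], set()
    for cols in groups:
        for rep, refs, best in groups[cols]:
            if len(refs) >= min_refs and best.key() not in seen:
                seen.add(best.key())
                out.append(best)
    return out


def _raise_floor(cfg: MiningConfig, floor: int, exact: bool = True) -> MiningConfig:
    """With ``exact`` the calibrated floor overrides the analytic one (the
    permutation null is authoritative in both directions); otherwise the
    floor is only ever raised."""
    if floor <= 0 or (not exact and floor <= cfg.support_floor):
        return cfg
    return MiningConfig(theta=cfg.theta, representation=cfg.representation,
                        algorithm=cfg.algorithm, min_cols=cfg.min_cols,
                        max_rows=cfg.max_rows, max_cols=cfg.max_cols,
                        decay=cfg.decay, coverage_target=cfg.coverage_target,
                        support_floor=floor)


def _tuned(cfg: MiningConfig, db: TransactionDatabase,
           tune: Callable | None) -> MiningConfig:
    if tune is None:
        return cfg
    min_cols, floor = tune(db)
    return MiningConfig(theta=cfg.theta, representation=cfg.representation,
                        algorithm=cfg.algorithm, min_cols=min_cols,
                        max_rows=cfg.max_rows, max_cols=cfg.max_cols,
                        decay=cfg.decay, coverage_target=cfg.coverage_target,
                        support_floor=floor)


class _CoherenceChecker:
    """Re-aligns a candidate submatrix on one of its own columns according to
    the coherency model (identity for constant, per-row offset for additive,
    per-row scale for multiplicative, per-row sign for symmetric) and
    measures how well columns and rows agree with the modal aligned
    profile."""

    def __init__(self, it: ItemizedMatrix, coherency: str = "constant",
                 delta: float = 0.1):
        coh = "constant" if coherency in (
            "constant", "constant_rows", "constant_overall") else coherency
        if coh == "symmetric":
            coh = "symmetric+constant"
        self.it = it
        self.coh = coh
        self.delta = delta
        self.supported = coh in ("constant", "additive", "multiplicative",
                                 "symmetric+constant", "symmetric+additive")

    def _aligned_cell(self, i, c, adj):
        coh = self.coh
        out = []
        for s in self.it.symbols(i, c):
            if coh == "constant":
                out.append(s)
            elif coh == "additive":
                out.append(s + adj)
            elif coh == "multiplicative":
                out.append((s + 1 - min(self.it.alphabet)) * adj)
            elif coh == "symmetric+constant":
                out.append(s * adj)
            else:  # symmetric+additive
                out.append(s * adj[0] + adj[1])
        return out

    def _row_adjustment(self, i, ref, M):
        s = self.it.primary[i, ref]
        if s == _NO_SYMBOL:
            return None
        coh = self.coh
        if coh == "constant":
            return 0
        if coh == "additive":
            return M - int(s)
        if coh == "multiplicative":
            base = 1 - min(self.it.alphabet)
            return (M + base) / (int(s) + base)
        sign = -1 if s < 0 else 1
        if coh == "symmetric+constant":
            return sign
        return (sign, M - int(s) * sign)

    def _matches(self, a, b) -> bool:
        if self.coh == "multiplicative":
            return abs(a - b) <= self.delta * max(abs(a), abs(b), 1e-12)
        return a == b

    def agreement(self, bic: Bicluster, ref: int):
        """(per-column agreement fraction, per-row agreement fraction) under
        alignment on ``ref``; None when the reference column is empty."""
        it = self.it
        ref_syms = [int(it.primary[r, ref]) for r in bic.rows
                    if it.primary[r, ref] != _NO_SYMBOL]
        if not ref_syms:
            return None
        M = max(ref_syms)
        adjs = {r: self._row_adjustment(r, ref, M) for r in bic.rows}
        modal = {}
        col_frac = {}
        for c in bic.cols:
            vals = []
            for r in bic.rows:
                if adjs[r] is None:
                    continue
                vals.extend((r, v) for v in self._aligned_cell(r, c, adjs[r]))
            rows_with = {r for r, _ in vals}
            if not rows_with:
                modal[c] = None
                col_frac[c] = 1.0
                continue
            best_v, best_cnt = None, 0
            for v in sorted({v for _, v in vals}):
                cnt = len({r for r, u in vals if self._matches(u, v)})
                if cnt > best_cnt:
                    best_v, best_cnt = v, cnt
            modal[c] = best_v
            col_frac[c] = best_cnt / len(rows_with)
        row_frac = {}
        for r in bic.rows:
            if adjs[r] is None:
                row_frac[r] = 1.0
                continue
            hits = denom = 0
            for c in bic.cols:
                if modal[c] is None:
                    continue
                cell = self._aligned_cell(r, c, adjs[r])
                if not cell:
                    continue
                denom += 1
                if any(self._matches(v, modal[c]) for v in cell):
                    hits += 1
            row_frac[r] = hits / denom if denom else 1.0
        return col_frac, row_frac

    def refs(self, bic: Bicluster, n_tries: int):
        tried = 0
        for ref in bic.cols:
            if (self.it.primary[list(bic.rows), ref] == _NO_SYMBOL).all():
                continue
            yield ref
            tried += 1
            if tried >= n_tries:
                return


def make_merge_guard(it: ItemizedMatrix, coherency: str = "constant",
                     tau_q: float = 0.70, delta: float = 0.1,
                     n_ref_tries: int = 3):
    """Build a coherence check for merge candidates: the candidate passes if
    under some tried reference column every column's modal aligned symbol
    covers at least ``tau_q`` of its rows and every row agrees with the
    modal profile on at least ``tau_q`` of its columns.  This lets
    noise-split fragments of one bicluster rejoin while rejecting merges
    that would fold in a coincidentally-agreeing background row or column.
    """
    chk = _CoherenceChecker(it, coherency, delta)

    def guard(bic: Bicluster) -> bool:
        if not chk.supported:
            return True
        any_ref = False
        for ref in chk.refs(bic, n_ref_tries):
            any_ref = True
            res = chk.agreement(bic, ref)
            if res is None:
                continue
            col_frac, row_frac = res
            if all(f >= tau_q for f in col_frac.values()) and \
                    all(f >= tau_q for f in row_frac.values()):
                return True
        return not any_ref

    return guard


def make_row_trimmer(it: ItemizedMatrix, coherency: str = "constant",
                     h: float = 0.75, delta: float = 0.1,
                     n_ref_tries: int = 3):
    """Build a row-level filter: rows that match the bicluster's aligned
    modal profile on fewer than ``h`` of its columns under every tried
    reference column are removed.  Exactly coherent rows (and rows damaged
    in only a small column fraction) stay; rows recruited by a narrow
    fragment and inconsistent with the full column set are dropped."""
    chk = _CoherenceChecker(it, coherency, delta)

    def trim(bic: Bicluster) -> Bicluster:
        if not chk.supported or len(bic.rows) <= 2:
            return bic
        keep: set = set()
        saw = False
        for ref in chk.refs(bic, n_ref_tries):
            res = chk.agreement(bic, ref)
            if res is None:
                continue
            saw = True
            _, row_frac = res
            keep |= {r for r, f in row_frac.items() if f >= h}
        if not saw or len(keep) < 2 or len(keep) == len(bic.rows):
            return bic
        return Bicluster(rows=tuple(sorted(keep)), cols=bic.cols,
                         coherency=bic.coherency)

    return trim


def reconstruct_symbol(bic: Bicluster, row: int, col_pos: int,
                       alphabet_min: int = 0) -> float:
    """Invert the recorded alignment for one bicluster cell: returns the
    itemized symbol implied by (profile, model_params)."""
    prof = bic.profile[col_pos]
    p = bic.model_params or {}
    if bic.coherency == "additive":
        return prof - p["row_offsets"][row]
    if bic.coherency == "multiplicative":
        base = 1 - alphabet_min
        val = p["group_values"][prof] / p["row_factors"][row]
        return val - base
    if bic.coherency.startswith("symmetric"):
        s = p["row_signs"][row]
        if bic.coherency == "symmetric+constant":
            return prof * s
        if bic.coherency == "symmetric+additive":
            return (prof - p["row_offsets"][row]) * s
        raise NotImplementedError(bic.coherency)
    return prof
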