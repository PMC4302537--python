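"""Closing step: merging, containment filtering, extension, reduction and
composition of alternative biclustering structures.

Pattern miners deliver fragments: the items-boundary problem, missing values
and corrupted cells split one planted bicluster into several overlapping
pieces.  Merging rejoins pieces sharing a large area fraction; containment
filtering removes redundant sub-biclusters; extension re-admits rows/columns
lost to noise; reduction trims rows/columns that break a homogeneity floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .core import Bicluster, ExpressionMatrix
from .evaluation import msr_norm
from .mapping import ItemizedMatrix

Matrix = ExpressionMatrix


@dataclass
class ClosingConfig:
    """Post-processing thresholds.

    merge_overlap (tau_m)
        Two biclusters merge when their shared-element area is at least this
        fraction of the smaller one.
    filter_overlap (tau_f)
        A bicluster is dropped when it shares at least this fraction of its
        own area with a strictly larger one.
    homogeneity_min (h)
        Floor on ``1 - MSR_norm`` used by reduction and by extension
        acceptance.
    extension
        ``none`` | ``lower_support`` | ``statistical``.
    structure
        ``free`` | ``exhaustive`` | ``exclusive_rows`` | ``exclusive_cols``
        | ``exclusive``.
    """

    merge_overlap: float = 0.70
    filter_overlap: float = 0.30
    homogeneity_min: float = 0.75
    extension: str = "none"
    extension_support_decay: float = 0.9
    reduce: bool = False
    structure: str = "free"

    def __post_init__(self):
        for name in ("merge_overlap", "filter_overlap"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.filter_overlap > self.merge_overlap:
            warnings.warn("filter_overlap > merge_overlap: filtering runs on "
                          "what merging left and is usually the looser bound")
        if self.extension not in ("none", "lower_support", "statistical"):
            raise ValueError(f"unknown extension mode {self.extension!r}")
        if self.structure not in ("free", "exhaustive", "exclusive_rows",
                                  "exclusive_cols", "exclusive"):
            raise ValueError(f"unknown structure {self.structure!r}")


def _shared_area(a: Bicluster, b: Bicluster) -> int:
    return len(a.row_set & b.row_set) * len(a.col_set & b.col_set)


def make_significance_rank(floors: dict[int, int]):
    """Redundancy-resolution rank from calibrated chance floors.

    A bicluster's trustworthiness is its support relative to the chance
    floor for its column count (floors for column counts beyond the
    calibrated tiers are extrapolated geometrically — chance support decays
    roughly by a constant factor per extra column).  This puts both
    contaminant families below the genuine pattern: row-diluted narrow
    fragments have high support but face a high floor, and column-rich
    hybrids with few rows barely clear their low floor."""
    keys = sorted(floors)
    if len(keys) >= 2:
        ratio = max(0.3, min(0.95, floors[keys[-1]] / max(floors[keys[-2]], 1)))
    else:
        ratio = 0.7

    def floor_at(c: int) -> float:
        if c <= keys[-1]:
            best = floors[keys[0]]
            for k in keys:
                if k <= c:
                    best = floors[k]
            return max(best, 3)
        # a believable pattern never rests on fewer than 3 rows, however wide
        return max(floors[keys[-1]] * ratio ** (c - keys[-1]), 3.0)

    def rank(b: Bicluster) -> tuple:
        return (-(len(b.rows) / floor_at(len(b.cols))), -b.area, b.key())

    return rank


def _area_rank(b: Bicluster) -> tuple:
    return (-b.area, b.key())


def _merge_pair(a: Bicluster, b: Bicluster) -> Bicluster:
    coh = a.coherency if a.coherency == b.coherency else "constant_rows"
    return Bicluster(rows=tuple(sorted(a.row_set | b.row_set)),
                     cols=tuple(sorted(a.col_set | b.col_set)),
                     coherency=coh)


def dedup(biclusters: Iterable[Bicluster]) -> list[Bicluster]:
    seen, out = set(), []
    for b in biclusters:
        if b.key() not in seen:
            seen.add(b.key())
            out.append(b)
    return out


def merge(biclusters: Iterable[Bicluster], tau_m: float,
          matrix: Matrix | None = None,
          guard: Callable[[Bicluster], bool] | None = None) -> list[Bicluster]:
    """Iteratively replace the pair with the highest overlap ratio (shared
    area / smaller area >= tau_m) by its union, until a fixpoint.

    Pair choice is deterministic: descending ratio, then descending combined
    area, then insertion order.  ``guard``, when given, must accept the
    merged candidate (see :func:`bicpam.coherency.make_merge_guard`);
    rejected pairs stay split.
    """
    import heapq

    pool: dict[int, Bicluster] = {i: b for i, b in enumerate(dedup(biclusters))}
    next_id = len(pool)
    rejected: set = set()
    heap: list = []

    def push_pairs(i: int, others):
        a = pool[i]
        for j in others:
            if j == i:
                continue
            b = pool[j]
            sa = _shared_area(a, b)
            if sa == 0:
                continue
            ratio = sa / min(a.area, b.area)
            if ratio >= tau_m:
                lo, hi = min(i, j), max(i, j)
                heapq.heappush(heap, (-ratio, -(a.area + b.area), lo, hi))

    ids = list(pool)
    for k, i in enumerate(ids):
        push_pairs(i, ids[k + 1:])
    while heap:
        _, _, i, j = heapq.heappop(heap)
        if i not in pool or j not in pool or (i, j) in rejected:
            continue
        m = _merge_pair(pool[i], pool[j])
        if guard is not None and not guard(m):
            rejected.add((i, j))
            continue
        del pool[i], pool[j]
        if any(b.key() == m.key() for b in pool.values()):
            continue
        pool[next_id] = m
        push_pairs(next_id, list(pool))
        next_id += 1
    return list(pool.values())


def filter_contained(biclusters: Iterable[Bicluster], tau_f: float,
                     rank: Callable[[Bicluster], tuple] | None = None) -> list[Bicluster]:
    """Drop duplicates and biclusters whose own area is covered >= tau_f by
    higher-ranked surviving biclusters (by default: strictly larger ones,
    largest processed first; the pipeline ranks by calibrated significance
    instead, see :func:`make_significance_rank`).

    Coverage is taken against the union of the higher-ranked survivors,
    which subsumes the pairwise rule: redundant fragments of one bicluster
    are dropped, and so are chance patterns stitched from single columns of
    several biclusters."""
    rank = rank or _area_rank
    bics = dedup(biclusters)
    bics.sort(key=rank)
    kept: list[Bicluster] = []
    for b in bics:
        rows = list(b.rows)
        cols = list(b.cols)
        covered = np.zeros((len(rows), len(cols)), dtype=bool)
        rpos = {r: i for i, r in enumerate(rows)}
        cpos = {c: i for i, c in enumerate(cols)}
        mine = rank(b)[:-1]
        for big in kept:
            if rank(big)[:-1] == mine:
                continue  # equal footing: neither can absorb the other
            ri = [rpos[r] for r in big.rows if r in rpos]
            ci = [cpos[c] for c in big.cols if c in cpos]
            if ri and ci:
                covered[np.ix_(ri, ci)] = True
        if covered.sum() < tau_f * b.area:
            kept.append(b)
    return kept


def filter_weak_support(biclusters: Iterable[Bicluster],
                        min_support: int | dict) -> list[Bicluster]:
    """Drop biclusters whose support is not independently significant.

    Rows that belong to a larger surviving bicluster sharing at least two
    columns with the candidate agree on those columns by construction, so
    they are discounted from the candidate's support; what remains must
    still reach ``min_support`` (the chance-pattern floor established during
    mining; a ``{min_cols: floor}`` dict applies per column count).  This
    removes patterns stitched from a slice of an established bicluster plus
    a few coincidental rows."""
    from .mining import floor_for_cols
    rank = (make_significance_rank(min_support)
            if isinstance(min_support, dict) else _area_rank)
    bics = sorted(dedup(biclusters), key=rank)
    kept: list[Bicluster] = []
    for b in bics:
        floor = (floor_for_cols(min_support, len(b.cols))
                 if isinstance(min_support, dict) else min_support)
        discount = 0
        for big in kept:
            if len(big.col_set & b.col_set) >= 2:
                discount = max(discount, len(big.row_set & b.row_set))
        if len(b.rows) - discount >= floor:
            kept.append(b)
    return kept


def reduce_bicluster(bic: Bicluster, matrix: Matrix, h: float) -> Bicluster:
    """Greedily remove the row or column whose removal most improves the
    homogeneity ``1 - MSR_norm`` until it reaches ``h`` (or the bicluster
    would fall below 2x2)."""
    cur = bic
    while len(cur.rows) > 2 or len(cur.cols) > 2:
        if 1.0 - msr_norm(cur, matrix) >= h:
            break
        best = None
        if len(cur.rows) > 2:
            for r in cur.rows:
                cand = Bicluster(tuple(x for x in cur.rows if x != r),
                                 cur.cols, cur.coherency)
                score = 1.0 - msr_norm(cand, matrix)
                if best is None or score > best[0]:
                    best = (score, cand)
        if len(cur.cols) > 2:
            for c in cur.cols:
                cand = Bicluster(cur.rows,
                                 tuple(x for x in cur.cols if x != c),
                                 cur.coherency)
                score = 1.0 - msr_norm(cand, matrix)
                if best is None or score > best[0]:
                    best = (score, cand)
        if best is None or best[0] <= 1.0 - msr_norm(cur, matrix):
            break
        cur = best[1]
    return cur


def _profile_match_fraction(bic: Bicluster, row: int,
                            itemized: ItemizedMatrix) -> float:
    if bic.profile is None:
        return 0.0
    hits = 0
    for pos, c in enumerate(bic.cols):
        if bic.profile[pos] in itemized.symbols(row, c):
            hits += 1
    return hits / len(bic.cols)


def extend(biclusters: Iterable[Bicluster], matrix: Matrix, mode: str,
           itemized: ItemizedMatrix | None = None,
           homogeneity: float = 0.75,
           remine: Callable[[], list[Bicluster]] | None = None) -> list[Bicluster]:
    """Re-admit rows/columns lost to noise.

    ``statistical``: a candidate row joins when its items match the
    bicluster's profile on at least ``homogeneity`` of the columns (columns
    symmetrically, via their majority symbol); the grown bicluster must keep
    ``1 - MSR_norm >= homogeneity`` on the real-valued matrix.  Applies to
    constant-on-rows biclusters, whose profile lives in the itemized symbol
    space.

    ``lower_support``: patterns re-mined under a decayed support threshold
    (the ``remine`` callable) donate their rows/columns to any bicluster they
    contain.
    """
    bics = dedup(biclusters)
    if mode == "none":
        return bics
    if mode == "lower_support":
        if remine is None:
            raise ValueError("lower_support extension needs a remine callable")
        relaxed = remine()
        out = []
        for b in bics:
            grown = b
            for r in relaxed:
                if r.row_set >= grown.row_set and r.col_set >= grown.col_set \
                        and r.area > grown.area:
                    cand = Bicluster(r.rows, r.cols, b.coherency)
                    if _homog_ok(cand, matrix, homogeneity):
                        grown = cand
            out.append(grown)
        return dedup(out)
    if mode != "statistical":
        raise ValueError(f"unknown extension mode {mode!r}")
    if itemized is None:
        raise ValueError("statistical extension needs the itemized matrix")

    out = []
    for b in bics:
        if b.coherency != "constant_rows" or b.profile is None:
            out.append(b)
            continue
        grown = b
        # rows
        cand_rows = []
        for r in range(itemized.n):
            if r in grown.row_set:
                continue
            f = _profile_match_fraction(grown, r, itemized)
            if f >= homogeneity:
                cand_rows.append((-f, r))
        for _, r in sorted(cand_rows):
            cand = Bicluster(grown.rows + (r,), grown.cols, grown.coherency,
                             grown.profile, grown.model_params)
            if _homog_ok(cand, matrix, homogeneity):
                grown = cand
        # columns, via the majority symbol over the grown row set
        for c in range(itemized.m):
            if c in grown.col_set:
                continue
            votes: dict = {}
            for r in grown.rows:
                for s in itemized.symbols(r, c):
                    votes[s] = votes.get(s, 0) + 1
            if not votes:
                continue
            sym, cnt = max(votes.items(), key=lambda kv: (kv[1], -abs(hash(kv[0]))))
            if cnt / len(grown.rows) >= homogeneity:
                pos = sum(1 for x in grown.cols if x < c)
                prof = grown.profile[:pos] + (sym,) + grown.profile[pos:]
                cand = Bicluster(grown.rows, grown.cols + (c,),
                                 grown.coherency, prof, grown.model_params)
                if _homog_ok(cand, matrix, homogeneity):
                    grown = cand
        out.append(grown)
    return dedup(out)


def _homog_ok(bic: Bicluster, matrix: Matrix, h: float) -> bool:
    if len(bic.rows) < 2 or len(bic.cols) < 2:
        return True
    try:
        return 1.0 - msr_norm(bic, matrix) >= h
    except ValueError:
        return False


def compose_structure(biclusters: Iterable[Bicluster], structure: str,
                      matrix: Matrix, tau_m: float = 0.70) -> list[Bicluster]:
    """Post-compose the solution structure.

    ``free`` keeps the arbitrary overlapping structure.  ``exhaustive``
    hierarchically merges the closest pair until every matrix cell is
    covered (or one bicluster remains).  The exclusive variants resolve any
    sharing on the protected axis by merging well-overlapping pairs and
    otherwise dropping the smaller bicluster.
    """
    bics = dedup(biclusters)
    if structure == "free" or not bics:
        return bics
    if structure == "exhaustive":
        total = matrix.n * matrix.m
        while len(bics) > 1:
            mask = np.zeros((matrix.n, matrix.m), dtype=bool)
            for b in bics:
                mask[np.ix_(b.rows, b.cols)] = True
            if mask.sum() == total:
                break
            best = None
            for i in range(len(bics)):
                for j in range(i + 1, len(bics)):
                    sa = _shared_area(bics[i], bics[j])
                    ratio = sa / min(bics[i].area, bics[j].area)
                    cand = (ratio, bics[i].area + bics[j].area, -i, -j)
                    if best is None or cand > best[0]:
                        best = (cand, i, j)
            _, i, j = best
            merged = _merge_pair(bics[i], bics[j])
            bics = [b for k, b in enumerate(bics) if k not in (i, j)] + [merged]
        return bics

    share_rows = structure in ("exclusive_rows", "exclusive")
    share_cols = structure in ("exclusive_cols", "exclusive")
    changed = True
    while changed:
        changed = False
        for i in range(len(bics)):
            for j in range(i + 1, len(bics)):
                a, b = bics[i], bics[j]
                conflict = (share_rows and a.row_set & b.row_set) or \
                           (share_cols and a.col_set & b.col_set)
                if not conflict:
                    continue
                sa = _shared_area(a, b)
                ratio = sa / min(a.area, b.area) if sa else 0.0
                if ratio >= tau_m:
                    repl = [_merge_pair(a, b)]
                else:
                    repl = [a if a.area >= b.area else b]
                bics = [x for k, x in enumerate(bics) if k not in (i, j)] + repl
                changed = True
                break
            if changed:
                break
    return bics


def close_solution(biclusters: Iterable[Bicluster], matrix: Matrix,
                   cfg: ClosingConfig,
                   itemized: ItemizedMatrix | None = None,
                   remine: Callable[[], list[Bicluster]] | None = None,
                   guard: Callable[[Bicluster], bool] | None = None,
                   min_support: int | dict | None = None,
                   row_trim: Callable[[Bicluster], Bicluster] | None = None) -> list[Bicluster]:
    """Full closing pipeline: merge -> filter -> extend -> reduce -> compose.

    ``guard``, when given, quality-checks every merge candidate (see
    :func:`bicpam.coherency.make_merge_guard`) so that noise-split fragments
    rejoin but foreign rows/columns are not folded in.  ``row_trim``
    removes rows inconsistent with the full aligned profile
    (:func:`bicpam.coherency.make_row_trimmer`); ``min_support`` enables the
    independent-support significance filter (:func:`filter_weak_support`)."""
    rank = (make_significance_rank(min_support)
            if isinstance(min_support, dict) else None)
    bics = merge(biclusters, cfg.merge_overlap, matrix, guard=guard)
    if row_trim is not None:
        bics = dedup([row_trim(b) for b in bics])
    if min_support is not None:
        bics = filter_weak_support(bics, min_support)
    bics = filter_contained(bics, cfg.filter_overlap, rank=rank)
    if cfg.extension != "none":
        bics = extend(bics, matrix, cfg.extension, itemized=itemized,
                      homogeneity=cfg.homogeneity_min, remine=remine)
        bics = merge(bics, cfg.merge_overlap, matrix, guard=guard)
        if row_trim is not None:
            bics = dedup([row_trim(b) for b in bics])
        bics = filter_contained(bics, cfg.filter_overlap, rank=rank)
    if cfg.reduce:
        bics = dedup([reduce_bicluster(b, matrix, cfg.homogeneity_min)
                      for b in bics])
    bics = compose_structure(bics, cfg.structure, matrix, cfg.merge_overlap)
    return dedup(bics)
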