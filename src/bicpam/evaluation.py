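"""Solution-versus-ground-truth metrics for bicluster sets.

- ``match_score`` (MS): mean, over one solution, of the best Jaccard
  similarity of each bicluster's row set against the other solution.
  MS(found, hidden) measures correctness of what was found; MS(hidden,
  found) measures how completely the hidden biclusters are recovered.
- ``fabia_consensus`` (FC): a one-to-one assignment (Hungarian method) of
  biclusters between the two solutions maximizing element overlap; the mean
  of the matched element-Jaccards divided by the larger set's size, so
  surplus biclusters in either solution are penalized.
- ``msr``: Cheng-Church mean squared residue, zero for perfectly constant or
  additive submatrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Bicluster, BiclusteringSolution, ExpressionMatrix

logger = logging.getLogger(__name__)


def _bics(sol) -> list[Bicluster]:
    if isinstance(sol, BiclusteringSolution):
        return list(sol.biclusters)
    return list(sol)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def _element_jaccard(b1: Bicluster, b2: Bicluster) -> float:
    ri = len(b1.row_set & b2.row_set)
    ci = len(b1.col_set & b2.col_set)
    inter = ri * ci
    union = b1.area + b2.area - inter
    return inter / union if union else 1.0


def match_score(B, H, mode: str = "rows") -> float:
    """MS(B, H): mean over B of the best Jaccard against H.

    ``rows`` compares row sets (the printed form); ``area`` compares element
    (cell) sets.  Empty ``B`` scores 0.
    """
    B, H = _bics(B), _bics(H)
    if not B:
        return 0.0
    if not H:
        return 0.0
    total = 0.0
    for b1 in B:
        if mode == "rows":
            best = max(_jaccard(b1.row_set, b2.row_set) for b2 in H)
        elif mode == "area":
            best = max(_element_jaccard(b1, b2) for b2 in H)
        else:
            raise ValueError(f"unknown match-score mode {mode!r}")
        total += best
    return total / len(B)


@dataclass
class ConsensusReport:
    fc: float
    matched_pairs: list[tuple[int, int]]  # (index in larger set, index in smaller)
    size_larger: int
    size_smaller: int


def fabia_consensus(B, H, report: bool = False):
    """Assignment-based consensus of two bicluster sets in [0, 1].

    S1 is the larger set; the optimal one-to-one assignment of its biclusters
    to the smaller set S2 (maximizing total element-overlap Jaccard) is found
    with the Hungarian method, and FC is the summed matched Jaccard divided
    by |S1| (unmatched biclusters contribute zero).
    """
    B, H = _bics(B), _bics(H)
    if not B and not H:
        logger.info("both solutions empty; consensus defined as 1")
        fc = 1.0
        rep = ConsensusReport(fc, [], 0, 0)
        return rep if report else fc
    if not B or not H:
        rep = ConsensusReport(0.0, [], max(len(B), len(H)), 0)
        return rep if report else 0.0
    S1, S2 = (B, H) if len(B) >= len(H) else (H, B)
    w = np.zeros((len(S1), len(S2)))
    for i, b1 in enumerate(S1):
        for j, b2 in enumerate(S2):
            w[i, j] = _element_jaccard(b1, b2)
    ri, cj = linear_sum_assignment(w, maximize=True)
    fc = float(w[ri, cj].sum() / len(S1))
    rep = ConsensusReport(fc, list(zip(ri.tolist(), cj.tolist())),
                          len(S1), len(S2))
    return rep if report else fc


def msr(bic: Bicluster, matrix: ExpressionMatrix) -> float:
    """Mean squared residue of the bicluster on the real-valued matrix:
    mean of ``(a_ij - rowMean_i - colMean_j + overallMean)^2`` over observed
    cells.  Missing cells are excluded from every mean and residue."""
    if len(bic.rows) < 2 or len(bic.cols) < 2:
        raise ValueError("MSR requires a bicluster of at least 2x2")
    sub = matrix.values[np.ix_(bic.rows, bic.cols)]
    obs = ~np.isnan(sub)
    if not obs.any():
        raise ValueError("bicluster has no observed cells")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(sub, axis=1, keepdims=True)
        col_mean = np.nanmean(sub, axis=0, keepdims=True)
        overall = np.nanmean(sub)
    resid = sub - row_mean - col_mean + overall
    return float(np.nanmean(resid ** 2))


def msr_norm(bic: Bicluster, matrix: ExpressionMatrix) -> float:
    """MSR scaled by the squared value range of the whole matrix, a unit-free
    homogeneity defect in [0, ~1]; ``1 - msr_norm`` is the homogeneity
    degree used by the closing filters."""
    r = matrix.value_range()
    if r == 0:
        return 0.0
    return msr(bic, matrix) / (r * r)
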