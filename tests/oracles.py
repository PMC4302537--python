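"""Independent brute-force oracles used to cross-check the miners.

These deliberately share no code with the package's mining path: itemsets
are enumerated exhaustively and coverage is computed by direct scan.
"""

import itertools


def brute_force_fim(itemsets, theta, representation="all", min_size=1):
    """All itemsets with support >= theta by exhaustive enumeration.

    Returns {frozenset(items): frozenset(transaction indices)}.
    """
    itemsets = [set(s) for s in itemsets]
    universe = sorted({x for s in itemsets for x in s}, key=repr)
    freq = {}
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            cov = frozenset(i for i, s in enumerate(itemsets)
                            if set(combo) <= s)
            if len(cov) >= theta:
                freq[frozenset(combo)] = cov
    if representation == "closed":
        freq = {p: c for p, c in freq.items()
                if not any(p < q and len(freq[q]) == len(c) for q in freq)}
    elif representation == "maximal":
        freq = {p: c for p, c in freq.items()
                if not any(p < q for q in freq)}
    elif representation != "all":
        raise ValueError(representation)
    return {p: c for p, c in freq.items() if len(p) >= min_size}


def brute_force_assignment(weights):
    """Best one-to-one assignment value by enumerating all permutations;
    rows >= cols assumed (pads implicitly by leaving rows unmatched)."""
    n_rows = len(weights)
    n_cols = len(weights[0]) if n_rows else 0
    best = 0.0
    for rows in itertools.permutations(range(n_rows), min(n_rows, n_cols)):
        total = sum(weights[r][c] for c, r in enumerate(rows))
        best = max(best, total)
    return best
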