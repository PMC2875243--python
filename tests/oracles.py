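"""Independent test-side oracles, deliberately naive.

These re-derive the quantities the package computes, by different
means: exhaustive route enumeration for the alignment optimum, a
textbook three-matrix affine-gap aligner (cost-minimizing Gotoh) for
the ε = 0 reduction, and the lattice-path recursion for route counts.
"""

from math import inf

from mtrap.aligner import enumerate_routes, route_difference, route_to_alignment


def delannoy(m: int, n: int) -> int:
    """Number of monotone lattice routes: R(i,j) = R(i-1,j) + R(i,j-1) + R(i-1,j-1)."""
    table = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        for j in range(n + 1):
            table[i][j] = 1 if i == 0 or j == 0 else (
                table[i - 1][j] + table[i][j - 1] + table[i - 1][j - 1]
            )
    return table[m][n]


def brute_force_minimum(a: str, b: str, params) -> float:
    """Minimum route difference over every route, by exhaustive enumeration."""
    best = inf
    for route in enumerate_routes(len(a), len(b)):
        alignment = route_to_alignment(route, a, b)
        best = min(best, route_difference(alignment, params))
    return best


def gotoh_min_cost(a: str, b: str, sub, w_open: float, w_extend: float) -> float:
    """Textbook cost-minimizing global affine-gap DP (terminal gaps charged).

    ``sub`` maps a residue pair to its substitution cost.  Independent
    of the package's three-state implementation: plain list-of-list
    tables, no transition terms, no traceback.
    """
    m, n = len(a), len(b)
    M = [[inf] * (n + 1) for _ in range(m + 1)]
    X = [[inf] * (n + 1) for _ in range(m + 1)]  # gap in b (consumes a)
    Y = [[inf] * (n + 1) for _ in range(m + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i > 0 and j > 0:
                M[i][j] = min(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub(
                    a[i - 1], b[j - 1]
                )
            if i > 0:
                X[i][j] = min(
                    M[i - 1][j] + w_open, X[i - 1][j] + w_extend, Y[i - 1][j] + w_open
                )
            if j > 0:
                Y[i][j] = min(
                    M[i][j - 1] + w_open, Y[i][j - 1] + w_extend, X[i][j - 1] + w_open
                )
    return min(M[m][n], X[m][n], Y[m][n])


def pairwise_q_by_ordinals(ref_a: str, ref_b: str, test_a: str, test_b: str) -> float:
    """Q for a pairwise alignment via the column-matching (n_ik) formulation."""

    def matched_ordinals(row_a: str, row_b: str) -> set[tuple[int, int]]:
        pairs = set()
        na = nb = 0
        for x, y in zip(row_a, row_b):
            if x != "-":
                na += 1
            if y != "-":
                nb += 1
            if x != "-" and y != "-":
                pairs.add((na, nb))
        return pairs

    ref_pairs = matched_ordinals(ref_a, ref_b)
    test_pairs = matched_ordinals(test_a, test_b)
    return len(ref_pairs & test_pairs) / len(ref_pairs)
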