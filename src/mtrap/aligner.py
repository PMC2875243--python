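"""The MTRAP alignment objective and its dynamic program.

An alignment of A (length m) and B (length n) is identified with a
monotone lattice "route" from (0, 0) to (m, n) built from unit right,
down and diagonal steps; each step emits one alignment column.  The
difference of A and B along a route with columns u_1 ... u_N is

    D(R) = Σ_k (1 - ε) · c(u_k)  +  Σ_{k≥2} ε · t̂(u_{k-1}, u_k)

where c(u) is the normalized substitution difference m̂(a, b) for a
residue column and the affine gap weight (w_open for the first column
of a gap run in its direction, w_extend for each further column) for a
gap column, and t̂ is the transition quantity between consecutive
columns.  ε ∈ [0, 1] is the degree of mixture between the classical
per-column objective (ε = 0) and the pure inter-site transition
objective (ε = 1).

The optimal route is found by a three-state affine-gap dynamic program
(states: gap-in-B / substitution / gap-in-A) that visits each of the
(m+1)(n+1) lattice points once.  Because the state of a cell fixes the
symbols of the column that produced it, the transition quantity between
a predecessor state and the current column is well defined and the
recursion stays O(mn).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np

from .alphabet import GAP, AlphabetError, pair_code, residue_index
from .substitution import NormalizedSubstitutionMatrix
from .transition import TransitionMatrix

# DP states, by the symbol pair their cell's last column carries
V, M, H = 0, 1, 2  # V: (a_i, -) vertical; M: (a_i, b_j) diagonal; H: (-, b_j) horizontal

#: tie-break preference: diagonal, then vertical, then horizontal
_STATE_ORDER = (M, V, H)

INF = float("inf")


@dataclasses.dataclass(frozen=True)
class AlignerParams:
    """Complete specification of the difference measure.

    ε weighs the transition term against the substitution/gap term;
    w_open and w_extend are gap costs already normalized into [0, 1]
    (raw gap scores go through f_s, see :func:`make_params`).
    """

    epsilon: float
    w_open: float
    w_extend: float
    M: NormalizedSubstitutionMatrix
    T: TransitionMatrix

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if not 0.0 <= self.w_extend <= self.w_open <= 1.0:
            raise ValueError(
                "gap weights must satisfy 0 <= w_extend <= w_open <= 1, got "
                f"w_open={self.w_open}, w_extend={self.w_extend}"
            )


def make_params(
    score_matrix,
    transition_matrix: TransitionMatrix | None = None,
    epsilon: float = 0.775,
    gap_open: float = -11.0,
    gap_extend: float = -0.3,
) -> AlignerParams:
    """Build AlignerParams from raw scores.

    The normalization domain is widened to cover the raw gap scores, so
    w_open = f_s(gap_open) and w_extend = f_s(gap_extend) land in
    [0, 1] with w_extend <= w_open for gap_extend >= gap_open.  The
    defaults are the measure's published operating point: ε = 0.775,
    gap-open score -11, gap-extend score -0.3.
    """
    from .substitution import f_s_normalize, normalize_matrix

    widened = score_matrix.widen_domain(gap_open, gap_extend)
    return AlignerParams(
        epsilon=epsilon,
        w_open=f_s_normalize(gap_open, widened),
        w_extend=f_s_normalize(gap_extend, widened),
        M=normalize_matrix(widened),
        T=transition_matrix if transition_matrix is not None else TransitionMatrix.neutral(),
    )


@dataclasses.dataclass(frozen=True)
class Alignment:
    """A pair of equal-length gapped sequences without gap-gap columns."""

    gapped_a: str
    gapped_b: str

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("alignment members differ in length")
        if any(a == GAP and b == GAP for a, b in zip(self.gapped_a, self.gapped_b)):
            raise ValueError("alignment contains a gap-gap column")

    def __len__(self) -> int:
        return len(self.gapped_a)

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.gapped_a, self.gapped_b))


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    alignment: Alignment
    difference: float  #: D_AB, the minimized route difference
    d_sub_part: float  #: Σ c(u_k) (unweighted substitution/gap component)
    d_trans_part: float  #: Σ t̂(u_{k-1}, u_k) (unweighted transition component)
    cells_visited: int  #: lattice points filled by the DP, (m+1)(n+1)


Route = tuple[tuple[int, int], ...]


def enumerate_routes(m: int, n: int, _guard: int = 14) -> Iterator[Route]:
    """Yield every monotone lattice route from (0, 0) to (m, n) once.

    Exhaustive enumeration explodes combinatorially (Delannoy numbers),
    so sizes with m + n above the guard are refused.
    """
    if m < 0 or n < 0:
        raise ValueError("sequence lengths must be non-negative")
    if m + n > _guard:
        raise ValueError(f"refusing to enumerate routes for m + n = {m + n} > {_guard}")

    def rec(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        if i == 0 and j == 0:
            yield ((0, 0),)
            return
        if i > 0 and j > 0:
            for prefix in rec(i - 1, j - 1):
                yield prefix + ((i, j),)
        if i > 0:
            for prefix in rec(i - 1, j):
                yield prefix + ((i, j),)
        if j > 0:
            for prefix in rec(i, j - 1):
                yield prefix + ((i, j),)

    return rec(m, n)


def route_to_alignment(route: Route, a: str, b: str) -> Alignment:
    """Materialize the gapped sequence pair a route induces."""
    cols_a, cols_b = [], []
    for (pi, pj), (qi, qj) in zip(route, route[1:]):
        di, dj = qi - pi, qj - pj
        if (di, dj) not in {(1, 0), (0, 1), (1, 1)}:
            raise ValueError(f"non-unit route step {(pi, pj)} -> {(qi, qj)}")
        cols_a.append(a[qi - 1] if di else GAP)
        cols_b.append(b[qj - 1] if dj else GAP)
    return Alignment("".join(cols_a), "".join(cols_b))


def route_difference(alignment: Alignment, params: AlignerParams) -> float:
    """Evaluate D(R) for a concrete alignment (route)."""
    total, _, _ = route_difference_parts(alignment, params)
    return total


def route_difference_parts(
    alignment: Alignment, params: AlignerParams
) -> tuple[float, float, float]:
    """D(R) together with its unweighted (Σc, Σt̂) components."""
    a_seq, b_seq = alignment.gapped_a.upper(), alignment.gapped_b.upper()
    sub_part = 0.0
    trans_part = 0.0
    prev: tuple[str, str] | None = None
    for a, b in zip(a_seq, b_seq):
        if a == GAP:
            sub_part += params.w_extend if prev is not None and prev[0] == GAP else params.w_open
        elif b == GAP:
            sub_part += params.w_extend if prev is not None and prev[1] == GAP else params.w_open
        else:
            sub_part += params.M.diff(a, b)
        if prev is not None:
            trans_part += params.T.quantity(pair_code(*prev), pair_code(a, b))
        prev = (a, b)
    total = (1.0 - params.epsilon) * sub_part + params.epsilon * trans_part
    return total, sub_part, trans_part


def align(a: str, b: str, params: AlignerParams) -> AlignmentResult:
    """Globally align A and B, minimizing the route difference.

    Returns the optimal alignment (deterministic under the
    diagonal-first tie-break) and its difference D_AB.  Runs in
    O(mn) time and memory; each lattice point is visited once.
    """
    a, b = a.upper(), b.upper()
    for ch in a + b:
        if ch == GAP:
            raise AlphabetError("input sequences to align() must be ungapped")
        residue_index(ch)  # raises AlphabetError on anything outside Ω
    m, n = len(a), len(b)
    if m == 0 and n == 0:
        return AlignmentResult(Alignment("", ""), 0.0, 0.0, 0.0, 1)

    eps = params.epsilon
    one_minus = 1.0 - eps
    w_open, w_ext = params.w_open, params.w_extend
    mhat = params.M.diffs
    tq = params.T.quantities
    ai = [residue_index(ch) for ch in a]
    bi = [residue_index(ch) for ch in b]
    gap_i = 20  # symbol index of the gap in pair codes

    def code_v(i: int) -> int:  # column (a_i, -)
        return ai[i - 1] * 21 + gap_i

    def code_m(i: int, j: int) -> int:  # column (a_i, b_j)
        return ai[i - 1] * 21 + bi[j - 1]

    def code_h(j: int) -> int:  # column (-, b_j)
        return gap_i * 21 + bi[j - 1]

    D = np.full((3, m + 1, n + 1), INF)
    back = np.full((3, m + 1, n + 1), -1, dtype=np.int8)
    D[M, 0, 0] = 0.0
    cells = 1

    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            cells += 1
            # (state, predecessor cell, current column code, substitution part)
            if i >= 1 and j >= 1:
                targets = ((M, i - 1, j - 1, code_m(i, j), mhat[ai[i - 1], bi[j - 1]]),)
            else:
                targets = ()
            if i >= 1:
                targets += ((V, i - 1, j, code_v(i), None),)
            if j >= 1:
                targets += ((H, i, j - 1, code_h(j), None),)
            for l, pi, pj, u, sub in targets:
                best, best_prev = INF, -1
                for lp in _STATE_ORDER:
                    d_prev = D[lp, pi, pj]
                    if d_prev == INF:
                        continue
                    if sub is None:  # gap column: open unless extending same direction
                        c = w_ext if lp == l else w_open
                    else:
                        c = sub
                    cand = d_prev + one_minus * c
                    if not (pi == 0 and pj == 0 and lp == M):  # start cell carries no column
                        if lp == M:
                            up = code_m(pi, pj)
                        elif lp == V:
                            up = code_v(pi)
                        else:
                            up = code_h(pj)
                        cand += eps * tq[up, u]
                    if cand < best:  # ties keep the earlier state in _STATE_ORDER
                        best, best_prev = cand, lp
                D[l, i, j] = best
                back[l, i, j] = best_prev

    end_state = _STATE_ORDER[0]
    for l in _STATE_ORDER[1:]:
        if D[l, m, n] < D[end_state, m, n]:
            end_state = l
    d_ab = float(D[end_state, m, n])

    # traceback
    cols_a: list[str] = []
    cols_b: list[str] = []
    l, i, j = end_state, m, n
    while not (i == 0 and j == 0):
        if l == M:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            lp, i, j = back[l, i, j], i - 1, j - 1
        elif l == V:
            cols_a.append(a[i - 1])
            cols_b.append(GAP)
            lp, i, j = back[l, i, j], i - 1, j
        else:
            cols_a.append(GAP)
            cols_b.append(b[j - 1])
            lp, i, j = back[l, i, j], i, j - 1
        l = int(lp)
    alignment = Alignment("".join(reversed(cols_a)), "".join(reversed(cols_b)))
    _, sub_part, trans_part = route_difference_parts(alignment, params)
    return AlignmentResult(alignment, d_ab, sub_part, trans_part, cells)
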