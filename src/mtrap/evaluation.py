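"""Alignment accuracy scoring: Q score, percent identity, identity bins.

The Q score (also known as the SPS or developer score) of a test
alignment against a structural reference alignment is the fraction of
the reference's aligned residue pairs that the test alignment
reproduces.  A residue pair (residue r of sequence i, residue s of
sequence j) counts as aligned when the two residues share a column.
For more than two sequences the count runs over all sequence pairs.
The score is 1 when every reference pair is reproduced and 0 when none
is.

Benchmarks conventionally stratify results by the reference's percent
identity; ``identity_bin_summary`` tabulates mean Q per identity bin.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd

from .alphabet import GAP, degap

DEFAULT_BIN_EDGES = (0.0, 15.0, 30.0, 45.0, 100.0)


class EvaluationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class QScoreReport:
    correct_pairs: int
    reference_pairs: int
    q: float
    identity: float | None = None  #: reference percent identity (pairwise refs only)
    bin: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise EvaluationError(f"q must lie in [0, 1], got {self.q}")


def residue_ordinals(row: str) -> list[int]:
    """1-based ordinal of each residue within its degapped sequence; 0 at gaps."""
    ordinals, k = [], 0
    for ch in row:
        if ch == GAP:
            ordinals.append(0)
        else:
            k += 1
            ordinals.append(k)
    return ordinals


def aligned_pair_set(rows: Sequence[str]) -> set[tuple[int, int, int, int]]:
    """All aligned residue pairs (i, j, n_ik, n_jk) of an alignment, i < j."""
    ordinals = [residue_ordinals(r) for r in rows]
    pairs = set()
    n = len(rows)
    for k in range(len(rows[0])):
        present = [(i, ordinals[i][k]) for i in range(n) if ordinals[i][k] > 0]
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                i, r = present[x]
                j, s = present[y]
                pairs.add((i, j, r, s))
    return pairs


def _match_rows(reference: Sequence[str], test: Sequence[str]) -> list[str]:
    """Reorder test rows so row i holds the same degapped sequence as reference row i."""
    remaining = list(test)
    ordered = []
    for ref_row in reference:
        target = degap(ref_row)
        for idx, cand in enumerate(remaining):
            if degap(cand) == target:
                ordered.append(remaining.pop(idx))
                break
        else:
            raise EvaluationError(
                "test alignment lacks a sequence matching the reference sequence "
                f"{target[:30]}..."
            )
    return ordered


def q_score(reference: Sequence[str], test: Sequence[str]) -> QScoreReport:
    """Fraction of reference aligned residue pairs reproduced by the test.

    Both alignments are given as equal-length gapped rows; the two must
    contain the same sequences (compared after gap removal), in any
    order.
    """
    reference = [r.upper() for r in reference]
    test = [t.upper() for t in test]
    if len(reference) < 2:
        raise EvaluationError("reference alignment needs at least 2 sequences")
    if len({len(r) for r in reference}) > 1 or len({len(t) for t in test}) > 1:
        raise EvaluationError("alignment rows must have equal lengths")
    if len(test) != len(reference):
        raise EvaluationError(
            f"sequence-set mismatch: {len(reference)} reference vs {len(test)} test rows"
        )
    test = _match_rows(reference, test)
    ref_pairs = aligned_pair_set(reference)
    if not ref_pairs:
        raise EvaluationError("reference alignment has no aligned residue pairs")
    test_pairs = aligned_pair_set(test)
    correct = len(ref_pairs & test_pairs)
    report = QScoreReport(correct, len(ref_pairs), correct / len(ref_pairs))
    if len(reference) == 2:
        ident = percent_identity(reference)
        report = dataclasses.replace(report, identity=ident)
    return report


def percent_identity(alignment: Sequence[str]) -> float:
    """Identical residue columns per column pairing two residues, as a percentage.

    The denominator excludes gap columns, so terminal-gap padding does
    not dilute the identity; 0 when no column pairs two residues.
    """
    if len(alignment) != 2:
        raise EvaluationError("percent identity is defined for pairwise alignments")
    a, b = (row.upper() for row in alignment)
    if len(a) != len(b):
        raise EvaluationError("alignment rows must have equal lengths")
    both = same = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                same += 1
    return 100.0 * same / both if both else 0.0


def assign_bin(identity: float, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> str:
    """Half-open bins [lo, hi); the last bin also includes its upper edge."""
    edges = list(bin_edges)
    if edges != sorted(edges) or len(edges) < 2:
        raise EvaluationError("bin edges must be sorted and at least two")
    for lo, hi in zip(edges, edges[1:]):
        last = hi == edges[-1]
        if lo <= identity < hi or (last and identity == hi):
            return f"{lo:g}-{hi:g}%"
    raise EvaluationError(f"identity {identity} outside bin range {edges[0]}-{edges[-1]}")


def identity_bin_summary(
    reports: Iterable[QScoreReport],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Count and mean Q per identity bin, plus an 'All' aggregate row."""
    reports = list(reports)
    if not reports:
        raise EvaluationError("no reports to summarize")
    rows = []
    for rep in reports:
        if rep.identity is None:
            raise EvaluationError("report lacks a reference percent identity")
        rows.append({"bin": assign_bin(rep.identity, bin_edges), "q": rep.q})
    df = pd.DataFrame(rows)
    edges = list(bin_edges)
    labels = [f"{lo:g}-{hi:g}%" for lo, hi in zip(edges, edges[1:])]
    out = []
    for label in labels:
        sub = df[df["bin"] == label]
        if len(sub):
            out.append({"bin": label, "count": len(sub), "mean_q": sub["q"].mean()})
    out.append({"bin": "All", "count": len(df), "mean_q": df["q"].mean()})
    return pd.DataFrame(out)
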