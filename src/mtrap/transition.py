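"""Estimation of the transition matrix T from reference alignments.

The measure treats an alignment as a chain of columns u_1, u_2, ... in
Γ* (symbol pairs without the gap-gap pair) and assumes the chain is
Markov: the cost of a column depends on the column before it.  T holds
the normalized transition quantity

    t̂(u, v) = f_t(log p(v|u); u),   f_t(x; u) = (t_max(u) - x) / (t_max(u) - t_min(u))

so the most probable successor of u has quantity 0 and the least
probable (observed) successor has 1.

p(v|u) is estimated from a corpus of pairwise reference alignments.
To damp redundancy, a sequence occurring N times in the corpus carries
weight N^(-1/2); an alignment of A with B contributes weight
w(A)·w(B) = (N_A N_B)^(-1/2) per adjacent column pair.  Counting is
order-symmetrized — every transition is also counted with both members
swapped — so aligning (A, B) and (B, A) score identically.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import (
    GAP,
    N_PAIRS,
    PAIR_LABELS,
    degap,
    pair_code,
    pair_code_from_label,
    swap_code,
)

PairAlignment = tuple[str, str]


class CorpusError(ValueError):
    """Malformed reference-alignment corpus."""


class TransitionMatrixError(ValueError):
    """Malformed transition-matrix payload."""


def _validate_alignment(a: str, b: str) -> PairAlignment:
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise CorpusError(f"alignment members differ in length: {len(a)} vs {len(b)}")
    if not degap(a) or not degap(b):
        raise CorpusError("alignment member is empty after removing gaps")
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            raise CorpusError("alignment contains a gap-gap column")
    return a, b


@dataclasses.dataclass(frozen=True)
class WeightedCorpus:
    """Pairwise alignments plus N^(-1/2) redundancy weights.

    ``multiplicity`` counts exact-string occurrences of each degapped
    sequence across the whole corpus; ``weight`` is its inverse square
    root.
    """

    alignments: tuple[PairAlignment, ...]
    multiplicity: dict[str, int]
    weight: dict[str, float]


def compute_sequence_weights(alignments: Iterable[PairAlignment]) -> WeightedCorpus:
    """Count degapped-sequence multiplicities and assign N^(-1/2) weights."""
    validated = tuple(_validate_alignment(a, b) for a, b in alignments)
    if not validated:
        raise CorpusError("empty corpus")
    multiplicity: Counter[str] = Counter()
    for a, b in validated:
        multiplicity[degap(a)] += 1
        multiplicity[degap(b)] += 1
    weight = {seq: n ** -0.5 for seq, n in multiplicity.items()}
    return WeightedCorpus(validated, dict(multiplicity), weight)


@dataclasses.dataclass(frozen=True)
class TransitionCounts:
    """Weighted frequencies n̂(u, v) of adjacent column pairs, (440, 440)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (N_PAIRS, N_PAIRS):
            raise TransitionMatrixError(f"expected {N_PAIRS}x{N_PAIRS} counts")
        if self.counts.min() < 0:
            raise TransitionMatrixError("negative transition count")


def count_transitions(corpus: WeightedCorpus) -> TransitionCounts:
    counts = np.zeros((N_PAIRS, N_PAIRS))
    for a, b in corpus.alignments:
        w = corpus.weight[degap(a)] * corpus.weight[degap(b)]
        codes = [pair_code(x, y) for x, y in zip(a, b)]
        for u, v in zip(codes, codes[1:]):
            counts[u, v] += w
            counts[swap_code(u), swap_code(v)] += w
    return TransitionCounts(counts)


@dataclasses.dataclass(frozen=True)
class TransitionProbabilities:
    """Row-conditional p(v|u); rows outside the support are all zero.

    The support is the set of source pairs with at least one raw
    (weighted) observation; pseudocount smoothing spreads mass inside a
    supported row but does not create support.
    """

    probs: np.ndarray  # (440, 440)
    support: np.ndarray  # (440,) bool
    pseudocount: float


def estimate_transition_probabilities(
    counts: TransitionCounts, pseudocount: float = 1.0
) -> TransitionProbabilities:
    """p(v|u) = (n̂(u,v) + c) / Σ_v' (n̂(u,v') + c) on supported rows."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    support = counts.counts.sum(axis=1) > 0
    smoothed = counts.counts + pseudocount
    probs = np.zeros_like(smoothed)
    totals = smoothed[support].sum(axis=1)
    probs[support] = smoothed[support] / totals[:, None]
    return TransitionProbabilities(probs, support, pseudocount)


@dataclasses.dataclass(frozen=True)
class TransitionMatrix:
    """Normalized transition quantities t̂(u, v) in [0, 1], (440, 440).

    Complete over (Γ* \\ gap-gap)²: unobserved source rows are filled
    with the maximal difference 1, uniform rows with 0.
    """

    quantities: np.ndarray
    metadata: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        q = self.quantities
        if q.shape != (N_PAIRS, N_PAIRS):
            raise TransitionMatrixError(
                f"expected a {N_PAIRS}x{N_PAIRS} transition matrix, got {q.shape}"
            )
        if q.min() < 0.0 or q.max() > 1.0:
            raise TransitionMatrixError("transition quantities must lie in [0, 1]")

    def quantity(self, u: int, v: int) -> float:
        return float(self.quantities[u, v])

    @classmethod
    def neutral(cls) -> "TransitionMatrix":
        """All-zero matrix: every transition equally unsurprising.

        With this matrix the measure reduces to the plain normalized
        substitution/gap objective for any ε.
        """
        return cls(np.zeros((N_PAIRS, N_PAIRS)), {"corpus": "neutral"})


def build_transition_matrix(
    probs: TransitionProbabilities, metadata: dict[str, str] | None = None
) -> TransitionMatrix:
    """Per-row normalization of t(u, v) = log p(v|u) onto [0, 1].

    For each supported row: successors with p > 0 are mapped affinely so
    the largest log-probability becomes 0 and the smallest becomes 1;
    a row whose positive probabilities are all equal is uninformative
    and maps to 0.  Successors with p = 0 and whole unobserved rows get
    the conservative maximal difference 1.
    """
    q = np.ones((N_PAIRS, N_PAIRS))
    for u in np.flatnonzero(probs.support):
        row = probs.probs[u]
        pos = row > 0
        t = np.log(row[pos])
        t_max, t_min = t.max(), t.min()
        if t_max - t_min < 1e-12:
            q[u, pos] = 0.0
        else:
            q[u, pos] = (t_max - t) / (t_max - t_min)
    meta = dict(metadata or {})
    meta.setdefault("pseudocount", repr(probs.pseudocount))
    return TransitionMatrix(q, meta)


def train_transition_matrix(
    alignments: Iterable[PairAlignment],
    pseudocount: float = 1.0,
    metadata: dict[str, str] | None = None,
) -> TransitionMatrix:
    """Full pipeline: weights -> counts -> probabilities -> quantities."""
    corpus = compute_sequence_weights(alignments)
    counts = count_transitions(corpus)
    probs = estimate_transition_probabilities(counts, pseudocount)
    return build_transition_matrix(probs, metadata)


def write_transition_matrix(t: TransitionMatrix, path: str | Path) -> None:
    """TSV with '#' metadata header and pair labels on both axes."""
    with open(path, "w") as fh:
        for key, value in t.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("pair\t" + "\t".join(PAIR_LABELS) + "\n")
        for u, label in enumerate(PAIR_LABELS):
            row = "\t".join(f"{x:.12g}" for x in t.quantities[u])
            fh.write(f"{label}\t{row}\n")


def read_transition_matrix(path: str | Path) -> TransitionMatrix:
    metadata: dict[str, str] = {}
    rows: dict[str, Sequence[str]] = {}
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            rows[fields[0]] = fields[1:]
    if header is None or not rows:
        raise TransitionMatrixError(f"no transition-matrix payload in {path}")
    if len(header) != N_PAIRS or len(rows) != N_PAIRS:
        raise TransitionMatrixError(
            f"expected {N_PAIRS} labels per axis, got {len(rows)} rows x {len(header)} columns"
        )
    col_order = [pair_code_from_label(lbl) for lbl in header]
    q = np.empty((N_PAIRS, N_PAIRS))
    for label, values in rows.items():
        u = pair_code_from_label(label)
        if len(values) != N_PAIRS:
            raise TransitionMatrixError(f"row {label!r} has {len(values)} values")
        q[u, col_order] = [float(v) for v in values]
    return TransitionMatrix(q, metadata)


def read_corpus_dir(directory: str | Path) -> list[PairAlignment]:
    """Load a directory of aligned-FASTA files, one pairwise alignment each.

    Files with other than exactly two records are rejected; expand
    multiple alignments to pairs externally.
    """
    from .io import read_fasta  # local import to avoid a cycle

    directory = Path(directory)
    paths = sorted(
        p
        for p in directory.iterdir()
        if p.suffix.lower() in {".fa", ".fasta", ".afa", ".faa"}
    )
    if not paths:
        raise CorpusError(f"no FASTA files found in {directory}")
    alignments = []
    for p in paths:
        records = read_fasta(p, aligned=True)
        if len(records) != 2:
            raise CorpusError(
                f"{p} holds {len(records)} records; corpus files must hold exactly "
                "2 (expand multiple alignments to pairs externally)"
            )
        alignments.append((records[0].letters, records[1].letters))
    return alignments
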