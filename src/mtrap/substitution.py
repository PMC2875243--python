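"""Substitution matrices and their normalized "difference" form.

A substitution matrix S = (s(a, b)) holds log-odds scores; larger is
more similar.  The alignment objective works instead with differences
in [0, 1]: scores are mapped through the affine normalizing function

    f_s(x) = (s_max - x) / (s_max - s_min)

so the best score becomes difference 0 and the worst becomes 1.  The
normalization domain [s_min, s_max] may be widened below the smallest
matrix entry so that raw gap scores (e.g. the default gap-open score
-11) also land inside [0, 1]; results are clamped as a guard.

The substitution component of the measure for an alignment is

    d_sub(A, B) = Σ_k m̂(a_k, b_k)

summed over columns pairing two residues; it is 0 for identical
sequences whenever every diagonal entry attains the matrix maximum.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import GAP, N_RESIDUES, RESIDUES, AlphabetError, residue_index

#: builtin name -> biopython dataset name
BUILTIN_MATRICES = {
    "BLOSUM62": "BLOSUM62",
    "PAM250": "PAM250",
    "GONNET250": "GONNET1992",
}


class MatrixError(ValueError):
    """Malformed or degenerate substitution matrix."""


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    """Raw symmetric scores s(a, b) over the 20-residue alphabet.

    ``s_min``/``s_max`` delimit the normalization domain of f_s.
    ``s_max`` is always the largest matrix entry; ``s_min`` defaults to
    the smallest entry but may sit below it when the domain has been
    widened to cover raw gap scores (see :meth:`widen_domain`).
    Ambiguity-code entries (B, Z, X, *) found in a file are kept in
    ``extras`` but never enter the domain.
    """

    name: str
    scores: np.ndarray  # (20, 20), residue order = alphabet.RESIDUES
    s_min: float
    s_max: float
    extras: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.shape != (N_RESIDUES, N_RESIDUES):
            raise MatrixError(f"expected a 20x20 score table, got {self.scores.shape}")
        if not np.array_equal(self.scores, self.scores.T):
            raise MatrixError("substitution matrix must be exactly symmetric")
        if not self.s_max > self.s_min:
            raise MatrixError("degenerate matrix: s_max must exceed s_min")
        if self.s_max != float(self.scores.max()):
            raise MatrixError("s_max must equal the largest matrix entry")
        if self.s_min > float(self.scores.min()):
            raise MatrixError("s_min must not exceed the smallest matrix entry")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[residue_index(a), residue_index(b)])

    def widen_domain(self, *raw_scores: float) -> "ScoreMatrix":
        """Return a copy whose s_min also covers the given raw scores.

        Used so that raw gap-open/extend scores normalize into [0, 1].
        """
        new_min = min(self.s_min, *map(float, raw_scores))
        return dataclasses.replace(self, s_min=new_min)


@dataclasses.dataclass(frozen=True)
class NormalizedSubstitutionMatrix:
    """The matrix M of differences m̂(a, b) = f_s(s(a, b)) in [0, 1]."""

    source: str
    diffs: np.ndarray  # (20, 20)

    def __post_init__(self) -> None:
        if self.diffs.shape != (N_RESIDUES, N_RESIDUES):
            raise MatrixError(f"expected a 20x20 table, got {self.diffs.shape}")
        if not np.array_equal(self.diffs, self.diffs.T):
            raise MatrixError("normalized matrix must be symmetric")
        if self.diffs.min() < 0.0 or self.diffs.max() > 1.0:
            raise MatrixError("normalized differences must lie in [0, 1]")

    def diff(self, a: str, b: str) -> float:
        return float(self.diffs[residue_index(a), residue_index(b)])


def _from_biopython(name: str, arr) -> ScoreMatrix:
    alpha = str(arr.alphabet)
    missing = [r for r in RESIDUES if r not in alpha]
    if missing:
        raise MatrixError(f"matrix lacks rows for residues: {', '.join(missing)}")
    scores = np.empty((N_RESIDUES, N_RESIDUES), dtype=float)
    for i, a in enumerate(RESIDUES):
        for j, b in enumerate(RESIDUES):
            scores[i, j] = float(arr[a, b])
    if not np.array_equal(scores, scores.T):
        raise MatrixError(f"matrix {name!r} is asymmetric")
    extras: dict[tuple[str, str], float] = {}
    for a in alpha:
        for b in alpha:
            if a not in RESIDUES or b not in RESIDUES:
                extras[(a, b)] = float(arr[a, b])
    return ScoreMatrix(
        name=name,
        scores=scores,
        s_min=float(scores.min()),
        s_max=float(scores.max()),
        extras=extras,
    )


def load_score_matrix(source: str | Path) -> ScoreMatrix:
    """Load a builtin (BLOSUM62 / PAM250 / GONNET250) or an NCBI-format file.

    The file format is the standard square text layout: '#' comment
    lines, a header row of residue letters, one row per residue.
    """
    name = str(source)
    if name in BUILTIN_MATRICES:
        return _from_biopython(name, substitution_matrices.load(BUILTIN_MATRICES[name]))
    path = Path(source)
    if not path.is_file():
        raise MatrixError(
            f"{name!r} is neither a builtin matrix name "
            f"({', '.join(sorted(BUILTIN_MATRICES))}) nor a readable file"
        )
    try:
        arr = substitution_matrices.read(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parser detail
        raise MatrixError(f"cannot parse substitution matrix {path}: {exc}") from exc
    return _from_biopython(path.stem, arr)


def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    """Serialize in the NCBI square text layout (round-trips with the loader)."""
    lines = [f"# {matrix.name}", "   " + "  ".join(RESIDUES)]
    for i, a in enumerate(RESIDUES):
        row = " ".join(f"{matrix.scores[i, j]:g}" for j in range(N_RESIDUES))
        lines.append(f"{a}  {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def f_s_normalize(x: float, matrix: ScoreMatrix) -> float:
    """Affine score-to-difference map, clamped to [0, 1].

    Strictly decreasing on the domain; f_s(s_max) = 0 and
    f_s(s_min) = 1 exactly.
    """
    span = matrix.s_max - matrix.s_min
    if span <= 0:
        raise MatrixError("degenerate matrix: s_max equals s_min")
    return float(min(1.0, max(0.0, (matrix.s_max - x) / span)))


def normalize_matrix(matrix: ScoreMatrix) -> NormalizedSubstitutionMatrix:
    """Map every score through f_s, yielding the difference matrix M."""
    span = matrix.s_max - matrix.s_min
    if span <= 0:
        raise MatrixError("degenerate matrix: s_max equals s_min")
    diffs = (matrix.s_max - matrix.scores) / span
    np.clip(diffs, 0.0, 1.0, out=diffs)
    return NormalizedSubstitutionMatrix(source=matrix.name, diffs=diffs)


def substitution_difference(
    aligned_a: str, aligned_b: str, m: NormalizedSubstitutionMatrix
) -> float:
    """d_sub: sum of m̂ over columns where both symbols are residues.

    Gap columns contribute nothing here; the aligner costs them with
    its affine gap weights.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(aligned_a)} vs {len(aligned_b)}"
        )
    total = 0.0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a == GAP and b == GAP:
            raise AlphabetError("alignment contains a gap-gap column")
        if a != GAP and b != GAP:
            total += m.diff(a, b)
    return total
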