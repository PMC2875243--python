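import numpy as np
import pytest

from mtrap.alphabet import N_PAIRS, N_RESIDUES, swap_code
from mtrap.aligner import AlignerParams
from mtrap.substitution import NormalizedSubstitutionMatrix, ScoreMatrix
from mtrap.transition import TransitionMatrix


def make_score_matrix(diag: float, off: float, name: str = "toy") -> ScoreMatrix:
    """Toy 20x20 matrix: one value on the diagonal, another off it."""
    scores = np.full((N_RESIDUES, N_RESIDUES), off, dtype=float)
    np.fill_diagonal(scores, diag)
    return ScoreMatrix(name, scores, float(scores.min()), float(scores.max()))


@pytest.fixture
def diag_max_matrix() -> ScoreMatrix:
    """Every diagonal entry attains the matrix maximum."""
    return make_score_matrix(diag=5.0, off=-2.0, name="diagmax")


@pytest.fixture
def two_value_matrix() -> ScoreMatrix:
    """Identity 2, mismatch -1: normalizes to m̂(a,a)=0, m̂(a,b)=1."""
    return make_score_matrix(diag=2.0, off=-1.0, name="twoval")


def random_normalized_matrix(rng: np.random.Generator) -> NormalizedSubstitutionMatrix:
    raw = rng.random((N_RESIDUES, N_RESIDUES))
    diffs = (raw + raw.T) / 2.0
    return NormalizedSubstitutionMatrix("random", diffs)


def random_transition_matrix(rng: np.random.Generator, symmetrized: bool = False) -> TransitionMatrix:
    q = rng.random((N_PAIRS, N_PAIRS))
    if symmetrized:
        codes = np.arange(N_PAIRS)
        swapped = np.array([swap_code(c) for c in codes])
        q = (q + q[np.ix_(swapped, swapped)]) / 2.0
    return TransitionMatrix(q)


def random_params(rng: np.random.Generator, epsilon: float, symmetrized_t: bool = False) -> AlignerParams:
    w_open = float(rng.uniform(0.3, 1.0))
    w_extend = float(rng.uniform(0.0, w_open))
    return AlignerParams(
        epsilon=epsilon,
        w_open=w_open,
        w_extend=w_extend,
        M=random_normalized_matrix(rng),
        T=random_transition_matrix(rng, symmetrized=symmetrized_t),
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    from mtrap.alphabet import RESIDUES

    return "".join(rng.choice(list(RESIDUES), size=length)) if length else ""


@pytest.fixture(scope="session")
def markov_truth_and_corpus():
    """Swap-symmetric 3-residue truth and a corpus with >= 1e5 transitions.

    Restricted to pairs over {A, C, D} so each conditional row is well
    resolved at this sample size; the truth is symmetric under member
    swap because the estimator symmetrizes pair order.
    """
    from mtrap.simulate import GeneratorSpec, synthetic_markov_corpus

    symbols = "ACD-"
    labels = [x + y for x in symbols for y in symbols if x + y != "--"]
    rng = np.random.default_rng(20100508)
    raw = {src: {dst: rng.random() + 0.05 for dst in labels} for src in labels}
    sym = {}
    for src in labels:
        row = {
            dst: (raw[src][dst] + raw[src[::-1]][dst[::-1]]) / 2.0 for dst in labels
        }
        total = sum(row.values())
        sym[src] = {dst: p / total for dst, p in row.items()}
    spec = GeneratorSpec(seed=101)
    alignments = synthetic_markov_corpus(spec, sym, n_alignments=500, length=201)
    return sym, alignments
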