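"""Seeded generators for sequences, homologous pairs and Markov corpora.

Everything every other module needs for testing and demonstration is
generated here, reproducibly from a seed, with no downloads: i.i.d.
random protein sequences, mutated descendants with a ground-truth
alignment (for accuracy scoring), and aligned-pair corpora whose
adjacent-column statistics follow a prescribed conditional
distribution (for checking the transition-matrix estimator).

Each generator draws from its own RNG stream derived from
(seed, generator-name), so adding a generator never shifts the streams
of existing ones.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import GAP, RESIDUES, degap, pair_code_from_label
from .io import SequenceRecord, write_fasta


class SimulationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-data generators.

    ``mutation_rate`` is the per-residue substitution probability;
    ``indel_rate`` the per-position probability of starting an
    insertion or deletion, whose length is geometric with mean
    ``indel_mean``.  ``composition`` gives residue frequencies in the
    order of the 20-letter alphabet (uniform when omitted).
    """

    seed: int = 0
    length: int = 100
    composition: tuple[float, ...] | None = None
    mutation_rate: float = 0.1
    indel_rate: float = 0.02
    indel_mean: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {rate}")
        if self.composition is not None:
            comp = np.asarray(self.composition, dtype=float)
            if comp.shape != (20,) or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
                raise SimulationError("composition must be 20 non-negative frequencies summing to 1")


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, generator-name)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


def _composition(spec: GeneratorSpec) -> np.ndarray:
    if spec.composition is None:
        return np.full(20, 1.0 / 20.0)
    return np.asarray(spec.composition, dtype=float)


def random_sequences(spec: GeneratorSpec, count: int) -> list[str]:
    """i.i.d. residues per the spec's composition, ``count`` sequences."""
    if count < 1:
        raise SimulationError("count must be positive")
    if spec.length < 1:
        raise SimulationError("length must be positive")
    rng = rng_for(spec.seed, "random_sequences")
    residues = np.array(list(RESIDUES))
    return [
        "".join(rng.choice(residues, size=spec.length, p=_composition(spec)))
        for _ in range(count)
    ]


@dataclasses.dataclass(frozen=True)
class MutatedPair:
    """Ground-truth alignment of an ancestor with its mutated descendant."""

    ancestor_aligned: str
    descendant_aligned: str
    descendant: str  #: the degapped descendant, ready for re-alignment


def mutate_pair(sequence: str, spec: GeneratorSpec) -> MutatedPair:
    """Mutate a sequence and keep the true alignment as ground truth.

    Substitutions replace a residue with a uniformly chosen different
    one; indels (insertions and deletions equally likely) start with
    probability ``indel_rate`` before each position and have geometric
    lengths.
    """
    if not sequence:
        raise SimulationError("cannot mutate an empty sequence")
    sequence = sequence.upper()
    rng = rng_for(spec.seed, "mutate_pair")
    comp = _composition(spec)
    residues = list(RESIDUES)
    p_geom = 1.0 / max(spec.indel_mean, 1.0)

    anc, desc = [], []
    i, n = 0, len(sequence)
    while i < n:
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            length = int(rng.geometric(p_geom))
            if rng.random() < 0.5:  # insertion into the descendant
                for _ in range(length):
                    anc.append(GAP)
                    desc.append(str(rng.choice(residues, p=comp)))
            else:  # deletion of up to `length` ancestor residues
                for _ in range(min(length, n - i)):
                    anc.append(sequence[i])
                    desc.append(GAP)
                    i += 1
                continue
        ch = sequence[i]
        if spec.mutation_rate > 0 and rng.random() < spec.mutation_rate:
            others = [r for r in residues if r != ch]
            anc.append(ch)
            desc.append(others[int(rng.integers(len(others)))])
        else:
            anc.append(ch)
            desc.append(ch)
        i += 1
    ancestor_aligned = "".join(anc)
    descendant_aligned = "".join(desc)
    if not degap(descendant_aligned):
        raise SimulationError(
            "mutation deleted the entire sequence; lower indel_rate or lengthen the input"
        )
    return MutatedPair(ancestor_aligned, descendant_aligned, degap(descendant_aligned))


def synthetic_markov_corpus(
    spec: GeneratorSpec,
    transition_probs: Mapping[str, Mapping[str, float]],
    n_alignments: int,
    length: int,
    out_dir: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Aligned pairs whose adjacent-column pairs follow a known Markov chain.

    ``transition_probs`` maps a source pair label (e.g. "AC", "A-") to
    a distribution over successor labels; every row must sum to 1 and
    no label may be the gap-gap pair.  Chains start from a uniformly
    chosen source pair.  With ``out_dir`` set, one aligned-FASTA file
    per pair is also written.
    """
    if n_alignments < 1 or length < 2:
        raise SimulationError("need at least 1 alignment of length >= 2")
    labels = sorted(transition_probs)
    for lbl in labels:
        pair_code_from_label(lbl)  # validates, rejects '--'
        row = transition_probs[lbl]
        total = sum(row.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"row {lbl!r} sums to {total}, expected 1")
        for succ in row:
            pair_code_from_label(succ)

    rng = rng_for(spec.seed, "synthetic_markov_corpus")
    rows = {
        lbl: (list(transition_probs[lbl]), np.array(list(transition_probs[lbl].values())))
        for lbl in labels
    }
    alignments: list[tuple[str, str]] = []
    attempts = 0
    while len(alignments) < n_alignments:
        attempts += 1
        if attempts > 50 * n_alignments:
            raise SimulationError("cannot generate alignments with non-empty members")
        state = labels[rng.integers(len(labels))]
        cols = [state]
        for _ in range(length - 1):
            succs, probs = rows.get(state, (None, None))
            if succs is None:  # successor outside the keyed rows: restart uniformly
                state = labels[rng.integers(len(labels))]
            else:
                state = succs[rng.choice(len(succs), p=probs)]
            cols.append(state)
        a = "".join(c[0] for c in cols)
        b = "".join(c[1] for c in cols)
        if degap(a) and degap(b):
            alignments.append((a, b))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, (a, b) in enumerate(alignments):
            write_fasta(
                [SequenceRecord(f"ref_{k:05d}_a", a), SequenceRecord(f"ref_{k:05d}_b", b)],
                out_dir / f"pair_{k:05d}.afa",
            )
    return alignments


def homologous_pair_corpus(
    spec: GeneratorSpec, n_pairs: int, out_dir: str | Path | None = None
) -> list[tuple[str, str]]:
    """Ground-truth pairwise alignments from the mutation model.

    Convenience wrapper used by ``train`` demonstrations and end-to-end
    tests: each pair is an ancestor aligned with its mutated
    descendant.
    """
    if n_pairs < 1:
        raise SimulationError("n_pairs must be positive")
    alignments = []
    for k in range(n_pairs):
        sub = dataclasses.replace(spec, seed=spec.seed + 1000 + k)
        ancestor = random_sequences(sub, 1)[0]
        pair = mutate_pair(ancestor, sub)
        alignments.append((pair.ancestor_aligned, pair.descendant_aligned))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, (a, b) in enumerate(alignments):
            write_fasta(
                [SequenceRecord(f"anc_{k:05d}", a), SequenceRecord(f"desc_{k:05d}", b)],
                out_dir / f"pair_{k:05d}.afa",
            )
    return alignments
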