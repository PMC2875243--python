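"""Symbol alphabet shared by every module.

The aligner works over the 20 standard amino acids Ω (ordered
alphabetically by one-letter code, so every matrix serialization is
reproducible) extended by a single gap symbol to Ω*.  An alignment
column is an ordered symbol pair in Γ* = Ω* x Ω* minus the gap-gap
pair, which no alignment column can be.
"""

from __future__ import annotations

RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
SYMBOLS: str = RESIDUES + GAP

N_RESIDUES: int = 20
N_SYMBOLS: int = 21
GAP_INDEX: int = 20

#: number of valid alignment columns (symbol pairs minus gap-gap)
N_PAIRS: int = N_SYMBOLS * N_SYMBOLS - 1

_RES_INDEX = {c: i for i, c in enumerate(RESIDUES)}
_SYM_INDEX = {c: i for i, c in enumerate(SYMBOLS)}


class AlphabetError(ValueError):
    """A symbol outside Ω* (or a residue outside Ω) was encountered."""


def residue_index(ch: str) -> int:
    try:
        return _RES_INDEX[ch]
    except KeyError:
        raise AlphabetError(f"not a standard amino-acid letter: {ch!r}") from None


def symbol_index(ch: str) -> int:
    try:
        return _SYM_INDEX[ch]
    except KeyError:
        raise AlphabetError(f"not an amino-acid letter or gap: {ch!r}") from None


def pair_code(a: str, b: str) -> int:
    """Dense code of the alignment column (a, b) in row-major symbol order.

    Codes run 0..439 over Γ* \\ {gap-gap}; the gap-gap pair would be 440
    and is rejected.
    """
    code = symbol_index(a) * N_SYMBOLS + symbol_index(b)
    if code == N_PAIRS:
        raise AlphabetError("gap-gap column is not a valid symbol pair")
    return code


def pair_label(code: int) -> str:
    """Two-character label of a pair code, e.g. 'AR', 'A-', '-Y'."""
    if not 0 <= code < N_PAIRS:
        raise AlphabetError(f"pair code out of range: {code}")
    return SYMBOLS[code // N_SYMBOLS] + SYMBOLS[code % N_SYMBOLS]


def pair_code_from_label(label: str) -> int:
    if len(label) != 2:
        raise AlphabetError(f"pair label must have two characters: {label!r}")
    return pair_code(label[0], label[1])


def swap_code(code: int) -> int:
    """Code of the order-swapped pair: (a, b) -> (b, a)."""
    if not 0 <= code < N_PAIRS:
        raise AlphabetError(f"pair code out of range: {code}")
    return (code % N_SYMBOLS) * N_SYMBOLS + code // N_SYMBOLS


#: labels of every valid pair in code order ("AA", "AC", ..., "-Y")
PAIR_LABELS: tuple[str, ...] = tuple(pair_label(c) for c in range(N_PAIRS))


def degap(seq: str) -> str:
    return seq.replace(GAP, "")
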