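"""Estimate a transition matrix from simulated reference alignments.

Generates a small corpus of ground-truth pairwise alignments with the
mutation model, estimates the transition quantities t̂(u, v) with
N^(-1/2) sequence weighting and pseudocount smoothing, and reports a
few entries.
"""

from mtrap.alphabet import pair_code_from_label
from mtrap.simulate import GeneratorSpec, homologous_pair_corpus
from mtrap.transition import train_transition_matrix

spec = GeneratorSpec(seed=42, length=120, mutation_rate=0.15, indel_rate=0.03)
alignments = homologous_pair_corpus(spec, n_pairs=30)
t = train_transition_matrix(alignments, pseudocount=1.0, metadata={"corpus": "simulated"})

print(f"trained on {len(alignments)} pairwise alignments")
for src, dst in [("AA", "AA"), ("AA", "A-"), ("L-", "L-"), ("WW", "CC")]:
    q = t.quantity(pair_code_from_label(src), pair_code_from_label(dst))
    print(f"t̂({src} -> {dst}) = {q:.4f}")
print(
    "0 marks the most expected successor of a column, 1 the least expected "
    "(or never observed); the aligner adds eps * t̂ per consecutive column pair."
)
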