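"""Align two protein sequences with the transition-probability measure.

Builds the default parameter set (GONNET250, ε = 0.775, raw gap scores
-11 / -0.3 normalized through f_s) with a neutral transition matrix and
aligns a classic textbook pair.
"""

from mtrap import align, load_score_matrix, make_params

params = make_params(load_score_matrix("GONNET250"))
result = align("HEAGAWGHEE", "PAWHEAE", params)

print(result.alignment.gapped_a)
print(result.alignment.gapped_b)
print(f"D_AB        = {result.difference:.6f}")
print(f"d_sub part  = {result.d_sub_part:.6f}  (substitution + gap weights, unmixed)")
print(f"d_trans part= {result.d_trans_part:.6f}  (transition quantities, unmixed)")
print(
    "D_AB is the minimized route difference: (1-eps) times the substitution/gap "
    "part plus eps times the transition part; smaller means more similar."
)
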