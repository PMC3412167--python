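"""The 20-letter amino-acid alphabet used throughout.

Index 20 is reserved for the erasure sentinel ``X`` (a masked residue that
scores as background everywhere).
"""

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_IDX = {a: i for i, a in enumerate(AA)}
MASK = "X"
MASK_IDX = 20
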