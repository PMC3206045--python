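"""The fixed 20-letter amino-acid alphabet used throughout the toolkit.

The order is the classic PAM/NCBI matrix order, so that scoring-matrix files
written here line up with files consumed by standard search tools.
"""

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

#: residue one-letter code -> row/column index
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP = "-"
UNKNOWN = "X"

#: characters legal inside an alignment column
ALIGNMENT_CHARS = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}
#: characters legal in an ungapped sequence
SEQUENCE_CHARS = frozenset(AMINO_ACIDS) | {UNKNOWN}
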