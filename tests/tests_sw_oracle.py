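"""Independent local-alignment oracle: three-state Gotoh DP in plain Python."""

import numpy as np

from bbtm.alphabet import AMINO_ACIDS


def sw_affine_oracle(a: str, b: str, scores, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score with affine gaps (length-k gap costs open + k*extend)."""
    idx = {c: i for i, c in enumerate(AMINO_ACIDS)}
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            sub = scores[idx[a[i - 1]], idx[b[j - 1]]]
            # local Gotoh recurrence: a match may follow either gap state
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + sub,
                X[i - 1][j - 1] + sub,
                Y[i - 1][j - 1] + sub,
            )
            best = max(best, M[i][j])
    return best
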