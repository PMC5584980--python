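"""BLOSUM62 target (joint substitution) frequencies.

The values below are the published BLOSUM62 target-frequency table
(the ``blosum62.qij`` file distributed with the BLAST toolkit), given to
four decimals as a lower-triangular matrix in the classical ordering
A R N D C Q E G H I L K M F P S T W Y V. The log-odds BLOSUM62 matrix
shipped by alignment libraries is derived from this table but does not
contain it, so the frequencies are stored here as a constant.

From the joint table f(A,B) we derive the conditional substitution
probabilities rho[B][A] = f(A,B) / sum_A f(A,B) used for pseudocounts.
Rows are renormalized exactly, absorbing the rounding of the published
four-decimal values.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AA_INDEX, N_AA

_QIJ_ORDER = "ARNDCQEGHILKMFPSTWYV"

_QIJ_LOWER = """
0.0215
0.0023 0.0178
0.0019 0.0020 0.0141
0.0022 0.0016 0.0037 0.0213
0.0016 0.0004 0.0004 0.0004 0.0119
0.0019 0.0025 0.0015 0.0016 0.0003 0.0073
0.0030 0.0027 0.0022 0.0049 0.0004 0.0035 0.0161
0.0058 0.0017 0.0029 0.0025 0.0008 0.0014 0.0019 0.0378
0.0011 0.0012 0.0014 0.0010 0.0002 0.0010 0.0014 0.0010 0.0093
0.0032 0.0012 0.0010 0.0012 0.0011 0.0009 0.0012 0.0014 0.0006 0.0184
0.0044 0.0024 0.0014 0.0015 0.0016 0.0016 0.0020 0.0021 0.0010 0.0114 0.0371
0.0033 0.0062 0.0024 0.0024 0.0005 0.0031 0.0041 0.0025 0.0012 0.0016 0.0025 0.0161
0.0013 0.0008 0.0005 0.0005 0.0004 0.0007 0.0007 0.0007 0.0004 0.0025 0.0049 0.0009 0.0040
0.0016 0.0009 0.0008 0.0008 0.0005 0.0005 0.0009 0.0012 0.0008 0.0030 0.0054 0.0009 0.0012 0.0183
0.0022 0.0010 0.0009 0.0012 0.0004 0.0008 0.0014 0.0014 0.0005 0.0010 0.0014 0.0016 0.0004 0.0005 0.0191
0.0063 0.0023 0.0031 0.0028 0.0010 0.0019 0.0030 0.0038 0.0011 0.0017 0.0024 0.0031 0.0009 0.0012 0.0017 0.0126
0.0037 0.0018 0.0022 0.0019 0.0009 0.0014 0.0020 0.0022 0.0007 0.0027 0.0033 0.0023 0.0010 0.0012 0.0014 0.0047 0.0125
0.0004 0.0003 0.0002 0.0002 0.0001 0.0002 0.0003 0.0004 0.0002 0.0004 0.0007 0.0003 0.0002 0.0008 0.0001 0.0003 0.0003 0.0065
0.0013 0.0009 0.0007 0.0006 0.0003 0.0007 0.0009 0.0008 0.0015 0.0014 0.0022 0.0010 0.0006 0.0042 0.0005 0.0010 0.0009 0.0009 0.0102
0.0051 0.0016 0.0012 0.0013 0.0014 0.0012 0.0017 0.0018 0.0006 0.0120 0.0095 0.0019 0.0023 0.0026 0.0012 0.0024 0.0036 0.0004 0.0015 0.0196
"""


def _build_joint() -> np.ndarray:
    joint = np.zeros((N_AA, N_AA), dtype=float)
    rows = [r.split() for r in _QIJ_LOWER.strip().splitlines()]
    for i, row in enumerate(rows):
        ai = AA_INDEX[_QIJ_ORDER[i]]
        for j, value in enumerate(row):
            aj = AA_INDEX[_QIJ_ORDER[j]]
            joint[ai, aj] = joint[aj, ai] = float(value)
    return joint


#: Symmetric 20x20 joint substitution frequencies, alphabetical indexing.
BLOSUM62_JOINT: np.ndarray = _build_joint()

#: Conditional substitution probabilities: BLOSUM62_CONDITIONAL[b, a] = P(a | b).
BLOSUM62_CONDITIONAL: np.ndarray = (
    BLOSUM62_JOINT / BLOSUM62_JOINT.sum(axis=1, keepdims=True)
)

#: Marginal residue frequencies implied by the joint table.
BLOSUM62_MARGINAL: np.ndarray = BLOSUM62_JOINT.sum(axis=1) / BLOSUM62_JOINT.sum()
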