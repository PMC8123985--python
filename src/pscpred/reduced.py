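"""Hydrophobicity-reduced 3-letter alphabet and its features.

The 20 residues partition into an internal (hydrophobic) group mapped to
``I``, an external (hydrophilic) group mapped to ``E``, and an ambivalent
group mapped to ``A``.  Content and position features are then computed
on the reduced sequence with k = 1, 2, giving a 24-dimensional block.
"""

from __future__ import annotations

import numpy as np

from pscpred.seqfeat import KmerIndex, feature_names, scf_vector, spf_vector

INTERNAL = frozenset("FILMV")
EXTERNAL = frozenset("DEHKNQR")
AMBIVALENT = frozenset("ACGPSTWY")

REDUCTION_MAP: dict[str, str] = {
    **{r: "I" for r in INTERNAL},
    **{r: "E" for r in EXTERNAL},
    **{r: "A" for r in AMBIVALENT},
}

#: Reduced alphabet, lexicographic (drives k-word ordering).
REDUCED_ALPHABET = "AEI"

_IDX1 = KmerIndex(REDUCED_ALPHABET, 1)
_IDX2 = KmerIndex(REDUCED_ALPHABET, 2)

REDUCED_FEATURE_NAMES: list[str] = (
    [f"r_{n}" for n in feature_names("scf", _IDX1)]
    + [f"r_{n}" for n in feature_names("scf", _IDX2)]
    + [f"r_{n}" for n in feature_names("spf", _IDX1)]
    + [f"r_{n}" for n in feature_names("spf", _IDX2)]
)


def reduce_sequence(seq: str) -> str:
    """Letter-wise map of a 20-letter sequence onto {I, E, A}."""
    out = []
    for i, residue in enumerate(seq, 1):
        mapped = REDUCTION_MAP.get(residue)
        if mapped is None:
            raise ValueError(
                f"position {i}: residue {residue!r} has no reduced-alphabet group"
            )
        out.append(mapped)
    return "".join(out)


def reduced_feature_vector(seq: str) -> np.ndarray:
    """scf1(3) + scf2(9) + spf1(3) + spf2(9) of the reduced sequence."""
    red = reduce_sequence(seq)
    return np.concatenate(
        [
            scf_vector(red, 1, _IDX1),
            scf_vector(red, 2, _IDX2),
            spf_vector(red, 1, _IDX1),
            spf_vector(red, 2, _IDX2),
        ]
    )
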