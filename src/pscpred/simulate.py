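"""Synthetic labeled datasets: (aa, ss, class) triples and planted matrices.

Secondary-structure strings are drawn from per-class segment grammars
(run types and geometric run lengths), then an amino-acid sequence is
emitted residue-by-residue from state-conditional propensity tables.
The grammars guarantee the qualitative class signatures the features
are designed to detect: helix-dominant all-alpha, strand-dominant
all-beta, frequent helix/strand alternation in alpha/beta, and a
segregated helix region followed by a strand region in alpha+beta.
"""

from __future__ import annotations

import numpy as np

from pscpred.assembly import FeatureMatrix
from pscpred.io_formats import AA_ALPHABET, CLASSES, Dataset, ProteinRecord

MIN_LENGTH = 30


def _propensity(favored: str, weight: float = 4.0) -> np.ndarray:
    w = np.array([weight if a in favored else 1.0 for a in AA_ALPHABET])
    return w / w.sum()


#: Residue emission probabilities per SS state.  Values are arbitrary but
#: fixed: helix-formers under H, beta-branched/aromatic under E, flexible
#: and turn-prone residues under C.
EMISSION: dict[str, np.ndarray] = {
    "H": _propensity("AELMQKRH"),
    "E": _propensity("VIYCWFT"),
    "C": _propensity("GNPSD"),
}


def _run(rng: np.random.Generator, mean: float) -> int:
    # geometric on {1, 2, ...} with the requested mean
    return int(rng.geometric(1.0 / mean))


def _ss_all_alpha(rng: np.random.Generator, length: int) -> str:
    parts = []
    while sum(len(p) for p in parts) < length:
        parts.append("C" * _run(rng, 3.0))
        elem = "E" if rng.random() < 0.05 else "H"
        mean = 4.0 if elem == "E" else 10.0
        parts.append(elem * _run(rng, mean))
    return "".join(parts)[:length]


def _ss_all_beta(rng: np.random.Generator, length: int) -> str:
    parts = []
    while sum(len(p) for p in parts) < length:
        parts.append("C" * _run(rng, 3.0))
        elem = "H" if rng.random() < 0.05 else "E"
        mean = 5.0 if elem == "H" else 6.0
        parts.append(elem * _run(rng, mean))
    return "".join(parts)[:length]


def _ss_alpha_slash_beta(rng: np.random.Generator, length: int) -> str:
    # strictly alternating H/E blocks separated by short coils
    parts = []
    elem = "H" if rng.random() < 0.5 else "E"
    while sum(len(p) for p in parts) < length:
        parts.append("C" * _run(rng, 2.0))
        mean = 8.0 if elem == "H" else 5.0
        parts.append(elem * _run(rng, mean))
        elem = "E" if elem == "H" else "H"
    return "".join(parts)[:length]


def _ss_alpha_plus_beta(rng: np.random.Generator, length: int) -> str:
    # helix-block region followed by a strand-block region: few alternations
    helix_len = int(length * rng.uniform(0.4, 0.6))
    parts = []
    while sum(len(p) for p in parts) < helix_len:
        parts.append("C" * _run(rng, 3.0))
        parts.append("H" * _run(rng, 9.0))
    head = "".join(parts)[:helix_len]
    parts = []
    while sum(len(p) for p in parts) < length - helix_len:
        parts.append("C" * _run(rng, 3.0))
        parts.append("E" * _run(rng, 6.0))
    return head + "".join(parts)[: length - helix_len]


_GRAMMARS = {
    "all-alpha": _ss_all_alpha,
    "all-beta": _ss_all_beta,
    "alpha/beta": _ss_alpha_slash_beta,
    "alpha+beta": _ss_alpha_plus_beta,
}

assert set(_GRAMMARS) == set(CLASSES)

_AA = np.array(list(AA_ALPHABET))


def _emit_aa(rng: np.random.Generator, ss: str) -> str:
    out = np.empty(len(ss), dtype="U1")
    ss_arr = np.array(list(ss))
    for state in "HEC":
        idx = np.nonzero(ss_arr == state)[0]
        if idx.size:
            out[idx] = rng.choice(_AA, size=idx.size, p=EMISSION[state])
    return "".join(out)


def simulate_protein_dataset(
    n_per_class: int,
    length_range: tuple[int, int],
    seed: int = 0,
) -> Dataset:
    """Balanced 4-class dataset of (aa, ss, label) records, seeded.

    Lengths are uniform over ``length_range`` (inclusive); the lower
    bound must be at least 30 so the segment grammars have room.
    """
    lo, hi = length_range
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if lo < MIN_LENGTH:
        raise ValueError(f"minimum length is {MIN_LENGTH}, got {lo}")
    if hi < lo:
        raise ValueError("length_range upper bound below lower bound")
    rng = np.random.default_rng(seed)
    records = []
    for cls in CLASSES:
        tag = cls.replace("/", "s").replace("+", "p").replace("-", "_")
        for i in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            ss = _GRAMMARS[cls](rng, length)
            aa = _emit_aa(rng, ss)
            records.append(
                ProteinRecord(
                    id=f"sim_{tag}_{i:04d}", aa_seq=aa, ss_seq=ss, label=cls
                )
            )
    return Dataset(records=records)


def planted_matrix(
    n: int,
    d: int,
    n_informative: int,
    effect: float,
    n_classes: int = 4,
    seed: int = 0,
) -> tuple[FeatureMatrix, list[str], list[int]]:
    """Gaussian noise matrix with ``n_informative`` class-shifted columns.

    Informative column j (at a seeded random position) adds ``effect``
    (in pooled-SD units, the noise SD being 1) to samples of class
    ``j mod n_classes``.  Returns the matrix, the balanced label list,
    and the informative column indices.
    """
    if n_informative > d:
        raise ValueError("n_informative must be <= d")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if n < 2 * n_classes:
        raise ValueError(f"need n >= {2 * n_classes} for {n_classes} classes")
    rng = np.random.default_rng(seed)
    class_names = [f"c{i}" for i in range(n_classes)]
    labels = [class_names[i % n_classes] for i in range(n)]
    values = rng.standard_normal((n, d))
    informative = sorted(rng.choice(d, size=n_informative, replace=False).tolist())
    for j, col in enumerate(informative):
        target = class_names[j % n_classes]
        mask = np.array([lab == target for lab in labels])
        values[mask, col] += effect
    fm = FeatureMatrix(
        ids=tuple(f"s{i:04d}" for i in range(n)),
        names=tuple(f"f{j:04d}" for j in range(d)),
        families=tuple("SYN" for _ in range(d)),
        values=values,
    )
    return fm, labels, informative
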