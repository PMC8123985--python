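"""k-word content and interval-distance position features.

Two families over a fixed alphabet:

* content features — overlapping k-word frequencies, ``c(w) / (m - k + 1)``;
* position features — for each k-word, the empirical distribution of gaps
  between successive occurrence start positions is summarized by its
  semi-mean and semi-variance, and the feature is the ratio
  ``semi_mean / semi_var``.

Words with fewer than two occurrences, or with zero gap variance, get a
position feature of 0 (the ratio is undefined there).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np


@dataclass(frozen=True)
class KmerIndex:
    """All ``|alphabet|^k`` k-words over an ordered alphabet, lexicographic."""

    alphabet: str
    k: int
    words: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet has repeated symbols")
        words = tuple(
            "".join(p) for p in itertools.product(self.alphabet, repeat=self.k)
        )
        object.__setattr__(self, "words", words)

    def __len__(self) -> int:
        return len(self.words)

    @property
    def word_to_idx(self) -> dict[str, int]:
        return _word_index(self.alphabet, self.k)


@lru_cache(maxsize=32)
def _word_index(alphabet: str, k: int) -> dict[str, int]:
    words = itertools.product(alphabet, repeat=k)
    return {"".join(w): i for i, w in enumerate(words)}


@dataclass(frozen=True)
class IntervalPMF:
    """Empirical pmf of gaps between successive k-word start positions."""

    support: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs):
            raise ValueError("support/probs length mismatch")
        if any(t < 1 for t in self.support):
            raise ValueError("support values must be >= 1")
        if self.support and abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def empty(self) -> bool:
        return not self.support


def kword_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Map each k-word in ``seq`` to its sorted 1-based start positions.

    Occurrences may overlap; the position lists cover all ``m - k + 1``
    windows.
    """
    m = len(seq)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} exceeds sequence length {m}")
    out: dict[str, list[int]] = {}
    for i in range(m - k + 1):
        out.setdefault(seq[i : i + k], []).append(i + 1)
    return out


def scf_vector(seq: str, k: int, index: KmerIndex) -> np.ndarray:
    """Overlapping k-word frequencies ``c(w)/(m-k+1)`` over ``index.words``."""
    pos = kword_positions(seq, k)
    n_windows = len(seq) - k + 1
    vec = np.zeros(len(index))
    lookup = index.word_to_idx
    for word, positions in pos.items():
        try:
            vec[lookup[word]] = len(positions) / n_windows
        except KeyError as exc:
            raise ValueError(f"word {word!r} not in the alphabet index") from exc
    return vec


def interval_pmf(positions: list[int] | np.ndarray) -> IntervalPMF:
    """Empirical pmf of successive-position gaps; < 2 positions -> empty."""
    positions = list(positions)
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be strictly increasing")
    if len(positions) < 2:
        return IntervalPMF(support=(), probs=())
    gaps = [b - a for a, b in zip(positions, positions[1:])]
    total = len(gaps)
    counts: dict[int, int] = {}
    for g in gaps:
        counts[g] = counts.get(g, 0) + 1
    support = tuple(sorted(counts))
    probs = tuple(counts[t] / total for t in support)
    return IntervalPMF(support=support, probs=probs)


def semi_moments(pmf: IntervalPMF) -> tuple[float, float]:
    """(semi-mean, semi-variance) of a gap pmf; empty pmf -> (0, 0)."""
    if pmf.empty:
        return 0.0, 0.0
    t = np.asarray(pmf.support, dtype=float)
    p = np.asarray(pmf.probs, dtype=float)
    mean = float(t @ p)
    var = float((t * t) @ p - mean * mean)
    return mean, max(var, 0.0)


def spf_vector(seq: str, k: int, index: KmerIndex) -> np.ndarray:
    """Per-word ``semi_mean / semi_var`` of occurrence gaps; degenerate -> 0."""
    pos = kword_positions(seq, k)
    vec = np.zeros(len(index))
    lookup = index.word_to_idx
    for word, positions in pos.items():
        try:
            j = lookup[word]
        except KeyError as exc:
            raise ValueError(f"word {word!r} not in the alphabet index") from exc
        mean, var = semi_moments(interval_pmf(positions))
        if var > 0.0:
            vec[j] = mean / var
    return vec


def feature_names(prefix: str, index: KmerIndex) -> list[str]:
    """Stable column names, e.g. ``scf2_AC`` for word AC at k=2."""
    return [f"{prefix}{index.k}_{w}" for w in index.words]
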