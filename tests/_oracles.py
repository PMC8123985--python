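"""Independent brute-force oracles used to cross-check the package.

Everything here is written from the definitions with exact Fraction
arithmetic and naive scans, deliberately sharing no code with pscpred.
"""

from __future__ import annotations

from fractions import Fraction


# -- k-word content / position ------------------------------------------------


def brute_scf(seq: str, k: int, words: list[str]) -> list[float]:
    n_windows = len(seq) - k + 1
    out = []
    for w in words:
        count = sum(1 for i in range(n_windows) if seq[i : i + k] == w)
        out.append(count / n_windows)
    return out


def brute_spf(seq: str, k: int, words: list[str]) -> list[float]:
    out = []
    for w in words:
        positions = [i + 1 for i in range(len(seq) - k + 1) if seq[i : i + k] == w]
        if len(positions) < 2:
            out.append(0.0)
            continue
        gaps = [b - a for a, b in zip(positions, positions[1:])]
        total = len(gaps)
        mean = Fraction(sum(gaps), total)
        var = Fraction(sum(g * g for g in gaps), total) - mean * mean
        out.append(float(mean / var) if var > 0 else 0.0)
    return out


# -- secondary-structure descriptors -----------------------------------------


def brute_runs(ss: str, element: str) -> list[int]:
    runs, current = [], 0
    for c in ss:
        if c == element:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def brute_content(ss: str) -> dict[str, float]:
    return {e: ss.count(e) / len(ss) for e in "HEC"}


def brute_cmv(ss: str, element: str, order: int) -> float:
    num = sum((i + 1) ** order for i, c in enumerate(ss) if c == element)
    den = 1
    for d in range(1, order + 1):
        den *= len(ss) - d
    return num / den


def brute_segment_stats(ss: str, element: str) -> tuple[float, float, float, float]:
    runs = brute_runs(ss, element)
    if not runs:
        return 0.0, 0.0, 0.0, 0.0
    n = len(ss)
    mx = max(runs)
    avg = sum(runs) / len(runs)
    return float(mx), mx / n, avg, avg / n


def brute_nalt(ss: str) -> float:
    no_coil = [c for c in ss if c != "C"]
    collapsed = []
    for c in no_coil:
        if not collapsed or c != collapsed[-1]:
            collapsed.append(c)
    return max(len(collapsed) - 1, 0) / len(ss)


# -- RI re-accumulation -------------------------------------------------------


def brute_ri_from_trees(trees, feature_names) -> dict[str, float]:
    """Walk stored trees and re-sum w * IG * n_node / n_root per feature."""
    scores = {name: 0.0 for name in feature_names}

    def walk(node, w, n_root):
        if node.left is None:
            return
        scores[node.feature] += w * node.info_gain * node.n_samples / n_root
        walk(node.left, w, n_root)
        walk(node.right, w, n_root)

    for tree in trees:
        walk(tree.root, tree.weighted_rate, tree.root.n_samples)
    return scores
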