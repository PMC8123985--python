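"""Descriptors of a 3-state secondary-structure string.

Per element (H, E, C): content, first- and second-order composition
moment vectors (CMV), and run-length statistics (longest run, mean run,
and their length-normalized variants); plus a single helix/strand
alternation frequency computed on the coil-removed segment sequence.
"""

from __future__ import annotations

import numpy as np

ELEMENTS = ("H", "E", "C")

#: Feature names for the full 22-feature layout.
FULL_NAMES: list[str] = (
    [f"ss_content_{e}" for e in ELEMENTS]
    + [f"ss_cmv1_{e}" for e in ELEMENTS]
    + [f"ss_cmv2_{e}" for e in ELEMENTS]
    + [f"ss_maxseg_{e}" for e in ELEMENTS]
    + [f"ss_nmaxseg_{e}" for e in ELEMENTS]
    + [f"ss_avgseg_{e}" for e in ELEMENTS]
    + [f"ss_navgseg_{e}" for e in ELEMENTS]
    + ["ss_nalt"]
)

#: Reduced 11-feature preset: H/E-only content, CMV1, CMV2, MaxSeg,
#: NMaxSeg, plus the alternation frequency.
ELEVEN_NAMES: list[str] = (
    [f"ss_content_{e}" for e in ("H", "E")]
    + [f"ss_cmv1_{e}" for e in ("H", "E")]
    + [f"ss_cmv2_{e}" for e in ("H", "E")]
    + [f"ss_maxseg_{e}" for e in ("H", "E")]
    + [f"ss_nmaxseg_{e}" for e in ("H", "E")]
    + ["ss_nalt"]
)

PRESETS = {"full": FULL_NAMES, "eleven": ELEVEN_NAMES}


def _check(ss: str) -> None:
    if not ss:
        raise ValueError("empty secondary-structure string")
    bad = set(ss) - set(ELEMENTS)
    if bad:
        raise ValueError(f"invalid SS symbols {sorted(bad)}")


def segments(ss: str) -> list[tuple[str, int, int]]:
    """Maximal runs as (element, 1-based start, length), in order."""
    _check(ss)
    out = []
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            out.append((ss[start], start + 1, i - start))
            start = i
    return out


def ss_content(ss: str) -> np.ndarray:
    """Fraction of each element (H, E, C); sums to 1."""
    _check(ss)
    n = len(ss)
    return np.array([ss.count(e) / n for e in ELEMENTS])


def cmv(ss: str, element: str, order: int) -> float:
    """Composition moment: sum of positions^order / prod_{d<=order}(N-d).

    Positions are 1-based occurrence indices of ``element``.  Requires
    ``N >= order + 1`` so every denominator factor is positive.
    """
    _check(ss)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n = len(ss)
    if n < order + 1:
        raise ValueError(f"sequence length {n} too short for order {order}")
    denom = 1.0
    for d in range(1, order + 1):
        denom *= n - d
    total = sum(
        (i + 1) ** order for i, c in enumerate(ss) if c == element
    )
    return total / denom


def segment_stats(ss: str, element: str) -> tuple[float, float, float, float]:
    """(MaxSeg, NMaxSeg, AvgSeg, NAvgSeg) of the element's runs.

    Absent element -> all four 0.
    """
    _check(ss)
    n = len(ss)
    runs = [length for e, _, length in segments(ss) if e == element]
    if not runs:
        return 0.0, 0.0, 0.0, 0.0
    max_seg = float(max(runs))
    avg_seg = sum(runs) / len(runs)
    return max_seg, max_seg / n, avg_seg, avg_seg / n


def nalt(ss: str) -> float:
    """Normalized helix/strand alternation frequency.

    Coil runs are deleted, the remaining H/E segment sequence is
    collapsed, adjacent unequal pairs are counted and divided by the
    full sequence length.  Always in [0, 1).
    """
    _check(ss)
    seq = [e for e, _, _ in segments(ss) if e != "C"]
    collapsed = [seq[0]] if seq else []
    for e in seq[1:]:
        if e != collapsed[-1]:
            collapsed.append(e)
    alternations = max(len(collapsed) - 1, 0)
    return alternations / len(ss)


def ss_feature_vector(ss: str, preset: str = "full") -> np.ndarray:
    """Named descriptor vector; ``preset`` is "full" (22) or "eleven" (11)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    content = dict(zip(ELEMENTS, ss_content(ss)))
    values = {f"ss_content_{e}": content[e] for e in ELEMENTS}
    for e in ELEMENTS:
        values[f"ss_cmv1_{e}"] = cmv(ss, e, 1)
        values[f"ss_cmv2_{e}"] = cmv(ss, e, 2)
        mx, nmx, avg, navg = segment_stats(ss, e)
        values[f"ss_maxseg_{e}"] = mx
        values[f"ss_nmaxseg_{e}"] = nmx
        values[f"ss_avgseg_{e}"] = avg
        values[f"ss_navgseg_{e}"] = navg
    values["ss_nalt"] = nalt(ss)
    return np.array([values[name] for name in PRESETS[preset]])
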