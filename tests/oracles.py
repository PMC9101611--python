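"""Independent brute-force oracles for the texture computations.

Deliberately naive (explicit Python loops, direct definitions) so they
share no code path with the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_glcm(levels: np.ndarray, ng: int, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by pixel-pair enumeration."""
    h, w = levels.shape
    dr, dc = offset
    counts = np.zeros((ng, ng), dtype=float)
    npairs = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = levels[r, c], levels[r2, c2]
                counts[i - 1, j - 1] += 1
                counts[j - 1, i - 1] += 1
                npairs += 2
    return counts / npairs


def naive_rlm(levels: np.ndarray, ng: int, direction: str) -> np.ndarray:
    """Run-length matrix by explicit line extraction and run scanning."""
    h, w = levels.shape
    nr = max(h, w)
    if direction == "horizontal":
        lines = [levels[r, :] for r in range(h)]
    elif direction == "vertical":
        lines = [levels[:, c] for c in range(w)]
    elif direction == "diag135":  # along (+1, +1)
        lines = [np.diagonal(levels, k) for k in range(-(h - 1), w)]
    elif direction == "diag45":  # along (-1, +1)
        flipped = levels[::-1, :]
        lines = [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    else:
        raise ValueError(direction)
    r_mat = np.zeros((ng, nr), dtype=int)
    for line in lines:
        line = list(line)
        start = 0
        for pos in range(1, len(line) + 1):
            if pos == len(line) or line[pos] != line[start]:
                r_mat[line[start] - 1, pos - start - 1] += 1
                start = pos
    return r_mat


def naive_entropy(p: np.ndarray) -> float:
    return -sum(x * math.log(x) for x in p.ravel() if x > 0)


def naive_difference_entropy(p: np.ndarray) -> float:
    ng = p.shape[0]
    q = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            q[abs(i - j)] += p[i, j]
    return -sum(x * math.log(x) for x in q if x > 0)


def naive_long_run_emphasis(r_mat: np.ndarray) -> float:
    num = 0.0
    den = 0.0
    for i in range(r_mat.shape[0]):
        for k in range(r_mat.shape[1]):
            num += (k + 1) ** 2 * r_mat[i, k]
            den += r_mat[i, k]
    return num / den
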