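"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities by naive enumeration (explicit
loops over voxel pairs, runs and score pairs) so they share no code with
the implementation they check.
"""

from __future__ import annotations

import numpy as np

DIRECTION_OFFSETS = {"H": (0, 1), "V": (1, 0), "Z": (-1, 1), "N": (-1, -1)}


def brute_glcm(levels: np.ndarray, mask: np.ndarray, direction: str, distance: int,
               n_levels: int, symmetric: bool = True) -> np.ndarray:
    """Co-occurrence probabilities by explicit enumeration of voxel pairs."""
    dr, dc = DIRECTION_OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((n_levels, n_levels))
    nrow, ncol, nslc = levels.shape
    for s in range(nslc):
        for r in range(nrow):
            for c in range(ncol):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r, c, s] and mask[r2, c2, s]:
                    i, j = levels[r, c, s] - 1, levels[r2, c2, s] - 1
                    counts[i, j] += 1
                    if symmetric:
                        counts[j, i] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def brute_runs(levels: np.ndarray, mask: np.ndarray, direction: str):
    """All maximal in-ROI runs (level, length) by walking each line cell by cell."""
    runs = []
    nrow, ncol, nslc = levels.shape
    for s in range(nslc):
        if direction == "H":
            lines = [[(r, c) for c in range(ncol)] for r in range(nrow)]
        elif direction == "V":
            lines = [[(r, c) for r in range(nrow)] for c in range(ncol)]
        elif direction == "N":  # 135 deg: main diagonals, steps (+1, +1)
            starts = [(r, 0) for r in range(nrow)] + [(0, c) for c in range(1, ncol)]
            lines = []
            for r0, c0 in starts:
                line = []
                r, c = r0, c0
                while r < nrow and c < ncol:
                    line.append((r, c))
                    r, c = r + 1, c + 1
                lines.append(line)
        elif direction == "Z":  # 45 deg: anti-diagonals, steps (+1, -1)
            starts = [(0, c) for c in range(ncol)] + [(r, ncol - 1) for r in range(1, nrow)]
            lines = []
            for r0, c0 in starts:
                line = []
                r, c = r0, c0
                while r < nrow and c >= 0:
                    line.append((r, c))
                    r, c = r + 1, c - 1
                lines.append(line)
        else:
            raise ValueError(direction)
        for line in lines:
            current = None
            length = 0
            for r, c in line:
                if mask[r, c, s]:
                    lv = levels[r, c, s]
                    if current == lv:
                        length += 1
                    else:
                        if current is not None:
                            runs.append((current, length))
                        current, length = lv, 1
                else:
                    if current is not None:
                        runs.append((current, length))
                    current, length = None, 0
            if current is not None:
                runs.append((current, length))
    return runs


def brute_rl_features(levels, mask, direction):
    """Run-length feature set from the brute-force run list."""
    runs = brute_runs(levels, mask, direction)
    n = len(runs)
    lengths = {}
    levels_count = {}
    for g, r in runs:
        lengths[r] = lengths.get(r, 0) + 1
        levels_count[g] = levels_count.get(g, 0) + 1
    n_vox = int(mask.sum())
    return {
        "ShrtREmp": sum(v / r ** 2 for r, v in lengths.items()) / n,
        "LngREmph": sum(v * r ** 2 for r, v in lengths.items()) / n,
        "GLevNonU": sum(v ** 2 for v in levels_count.values()) / n,
        "RLNonUni": sum(v ** 2 for v in lengths.values()) / n,
        "Fraction": n / n_vox,
    }


def brute_auc(scores, labels, positive) -> float:
    """AUC by counting concordant positive/negative pairs (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    count = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                count += 1.0
            elif p == q:
                count += 0.5
    return count / (len(pos) * len(neg))


def brute_pair_count(scores, labels, positive) -> float:
    """Concordant-pair count (ties half) without the normalization."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    count = 0.0
    for p in pos:
        for q in neg:
            count += 1.0 if p > q else (0.5 if p == q else 0.0)
    return count
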