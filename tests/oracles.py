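"""Independent brute-force oracles for texture-matrix construction.

Everything here is written as plain nested loops straight from the
matrix definitions, deliberately sharing no code with the package, and
is only fast enough for tiny grids.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def present_levels(levels: np.ndarray) -> list[int]:
    return sorted({int(v) for v in levels.ravel() if v > 0})


def brute_glcm(levels: np.ndarray, offset: tuple[int, int]) -> dict:
    """Symmetrized pair counts {(level_a, level_b): count}."""
    h, w = levels.shape
    dr, dc = offset
    counts: dict = {}
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = int(levels[r, c]), int(levels[r2, c2])
                if a > 0 and b > 0:
                    counts[(a, b)] = counts.get((a, b), 0) + 1
                    counts[(b, a)] = counts.get((b, a), 0) + 1
    return counts


def brute_glrlm(levels: np.ndarray, direction: tuple[int, int]) -> dict:
    """Run counts {(level, run_length): count} along one direction."""
    h, w = levels.shape
    dr, dc = direction
    counts: dict = {}
    # starting points: cells with no predecessor along (dr, dc)
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w:
                continue
            # walk the line, emitting maximal runs of equal nonzero level
            rr, cc = r, c
            run_val, run_len = 0, 0
            while 0 <= rr < h and 0 <= cc < w:
                v = int(levels[rr, cc])
                if v == run_val and v > 0:
                    run_len += 1
                else:
                    if run_val > 0:
                        counts[(run_val, run_len)] = counts.get((run_val, run_len), 0) + 1
                    run_val, run_len = v, (1 if v > 0 else 0)
                rr += dr
                cc += dc
            if run_val > 0:
                counts[(run_val, run_len)] = counts.get((run_val, run_len), 0) + 1
    return counts


def brute_glszm(levels: np.ndarray) -> dict:
    """Zone counts {(level, zone_size): count}; zones are 8-connected."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    counts: dict = {}
    for r in range(h):
        for c in range(w):
            if levels[r, c] <= 0 or seen[r, c]:
                continue
            v = int(levels[r, c])
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGHBORS_8:
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2] and int(levels[r2, c2]) == v:
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            counts[(v, size)] = counts.get((v, size), 0) + 1
    return counts


def brute_gldm(levels: np.ndarray, alpha: int = 0) -> dict:
    """Dependence counts {(level, d): count} with d = dependent neighbors."""
    h, w = levels.shape
    counts: dict = {}
    for r in range(h):
        for c in range(w):
            v = int(levels[r, c])
            if v <= 0:
                continue
            d = 0
            for dr, dc in NEIGHBORS_8:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    u = int(levels[r2, c2])
                    if u > 0 and abs(v - u) <= alpha:
                        d += 1
            counts[(v, d)] = counts.get((v, d), 0) + 1
    return counts


def brute_ngtdm(levels: np.ndarray) -> dict:
    """Per-level (n_i, s_i); pixels with no in-mask neighbor excluded."""
    h, w = levels.shape
    out: dict = {}
    for r in range(h):
        for c in range(w):
            v = int(levels[r, c])
            if v <= 0:
                continue
            nbrs = []
            for dr, dc in NEIGHBORS_8:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and int(levels[r2, c2]) > 0:
                    nbrs.append(int(levels[r2, c2]))
            if not nbrs:
                continue
            n, s = out.get(v, (0, 0.0))
            out[v] = (n + 1, s + abs(v - sum(nbrs) / len(nbrs)))
    return out


# --- adapters: package matrices -> the same sparse dict form ----------------

def glcm_matrix_to_dict(counts: np.ndarray, gray_levels: np.ndarray) -> dict:
    out = {}
    for i, a in enumerate(gray_levels):
        for j, b in enumerate(gray_levels):
            if counts[i, j]:
                out[(int(a), int(b))] = int(counts[i, j])
    return out


def indexed_matrix_to_dict(counts: np.ndarray, gray_levels: np.ndarray,
                           col_offset: int = 1) -> dict:
    """GLRLM/GLSZM (columns are lengths/sizes >= 1) or GLDM (col_offset=0)."""
    out = {}
    for i, a in enumerate(gray_levels):
        for j in range(counts.shape[1]):
            if counts[i, j]:
                out[(int(a), j + col_offset)] = int(counts[i, j])
    return out
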