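"""Independent brute-force oracles for the matrix-based texture features
and for Relief-F.

Everything here is written as plain per-pixel / per-pair Python loops with
its own restatement of the defining formulas, deliberately sharing no code
with the package implementation, so that agreement between the two is a
meaningful check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.ndimage import map_coordinates

_OFFSETS = {"H": (0, 1), "Z": (-1, 1), "V": (1, 0), "N": (1, 1)}


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_oracle(q: np.ndarray, ng: int) -> dict[str, float]:
    h, w = q.shape
    pairs: Counter = Counter()
    for dy, dx in _OFFSETS.values():
        for i in range(h):
            for j in range(w):
                i2, j2 = i + dy, j + dx
                if 0 <= i2 < h and 0 <= j2 < w:
                    pairs[(int(q[i, j]), int(q[i2, j2]))] += 1
                    pairs[(int(q[i2, j2]), int(q[i, j]))] += 1
    total = sum(pairs.values())
    p = {k: v / total for k, v in pairs.items()}

    px = [0.0] * ng
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * px[i] for i in range(ng))
    var = sum((i - mu) ** 2 * px[i] for i in range(ng))
    sig = math.sqrt(var)

    p_sum = [0.0] * (2 * ng - 1)
    p_dif = [0.0] * ng
    for (i, j), v in p.items():
        p_sum[i + j] += v
        p_dif[abs(i - j)] += v

    def ent(dist):
        return -sum(v * math.log2(v) for v in dist if v > 0)

    if sig > 0:
        correlat = sum((i - mu) * (j - mu) * v for (i, j), v in p.items()) / var
    else:
        correlat = 1.0
    sum_avg = sum(k * v for k, v in enumerate(p_sum))
    dif_avg = sum(k * v for k, v in enumerate(p_dif))
    return {
        "AngScMom": sum(v * v for v in p.values()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Correlat": correlat,
        "SumOfSqs": sum((i - mu) ** 2 * v for (i, j), v in p.items()),
        "InvDfMom": sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items()),
        "SumAverg": sum_avg,
        "SumVarnc": sum((k - sum_avg) ** 2 * v for k, v in enumerate(p_sum)),
        "SumEntrp": ent(p_sum),
        "Entropy": ent(p.values()),
        "DifVarnc": sum((k - dif_avg) ** 2 * v for k, v in enumerate(p_dif)),
        "DifEntrp": ent(p_dif),
    }


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def _oracle_lines(q: np.ndarray, direction: str) -> list[list[int]]:
    h, w = q.shape
    lines: dict[int, list[int]] = {}
    for i in range(h):
        for j in range(w):
            if direction == "H":
                key = i
            elif direction == "V":
                key = j
            elif direction == "Z":
                key = i + j
            elif direction == "N":
                key = i - j
            else:
                raise ValueError(direction)
            lines.setdefault(key, []).append(int(q[i, j]))
    # traversal within a line follows increasing j (row-major fill above)
    return list(lines.values())


def glrlm_oracle(q: np.ndarray, direction: str) -> dict[str, float]:
    runs: list[tuple[int, int]] = []  # (gray level, run length)
    for line in _oracle_lines(q, direction):
        idx = 0
        while idx < len(line):
            j = idx
            while j + 1 < len(line) and line[j + 1] == line[idx]:
                j += 1
            runs.append((line[idx], j - idx + 1))
            idx = j + 1
    c = len(runs)
    n_pix = q.size
    g: Counter = Counter(level for level, _ in runs)
    r: Counter = Counter(length for _, length in runs)
    glev = sum(v * v for v in g.values()) / c
    rln = sum(v * v for v in r.values()) / c
    return {
        "RLNonUni": rln,
        "GLevNonUn": glev,
        "LngREmph": sum(ln * ln for _, ln in runs) / c,
        "ShrtREmph": sum(1.0 / (ln * ln) for _, ln in runs) / c,
        "Fraction": c / n_pix,
        "NRLNonUni": rln / c,
        "NGLevNonUni": glev / c,
    }


# --------------------------------------------------------------------------
# LBP variants
# --------------------------------------------------------------------------

def lbp_oracle(a: np.ndarray) -> dict[str, float]:
    a = np.asarray(a, dtype=np.float64)
    h, w = a.shape
    out: dict[str, float] = {}

    # Oc4 / Tr4: 4-connected neighbours in E, N, W, S circular order
    oc_codes, tr_codes = [], []
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            c = a[i, j]
            nb = [a[i, j + 1], a[i - 1, j], a[i, j - 1], a[i + 1, j]]
            s = [1 if v >= c else 0 for v in nb]
            oc_codes.append(sum(s[b] << b for b in range(4)))
            tr_codes.append(
                sum((1 if s[b] != s[(b + 1) % 4] else 0) << b for b in range(4))
            )
    for name, codes, nbins in (("Oc4", oc_codes, 16), ("Tr4", tr_codes, 16)):
        hist = np.bincount(codes, minlength=nbins) / len(codes)
        for b in range(nbins):
            out[f"{name}n{b}"] = hist[b]

    # CsN: opposing pairs on circles, independent bilinear interpolation
    for n, radius, margin in ((4, 1.0, 1), (8, 1.0, 1), (12, 2.0, 2)):
        half = n // 2
        codes = []
        for i in range(margin, h - margin):
            for j in range(margin, w - margin):
                code = 0
                for b in range(half):
                    th1 = 2 * math.pi * b / n
                    th2 = 2 * math.pi * (b + half) / n
                    v1 = map_coordinates(
                        a, [[i - radius * math.sin(th1)], [j + radius * math.cos(th1)]],
                        order=1)[0]
                    v2 = map_coordinates(
                        a, [[i - radius * math.sin(th2)], [j + radius * math.cos(th2)]],
                        order=1)[0]
                    if v1 >= v2 - 1e-12:
                        code |= 1 << b
                codes.append(code)
        hist = np.bincount(codes, minlength=1 << half) / len(codes)
        for b in range(1 << half):
            out[f"Cs{n}n{b}"] = hist[b]
    return out


# --------------------------------------------------------------------------
# Relief-F (naive loops)
# --------------------------------------------------------------------------

def relieff_oracle(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).astype(int)
    m, nf = x.shape
    rng_w = x.max(axis=0) - x.min(axis=0)
    w = np.zeros(nf)
    for r in range(m):
        dists = []
        for o in range(m):
            d = sum(
                abs(x[r, f] - x[o, f]) / rng_w[f]
                for f in range(nf)
                if rng_w[f] > 0
            )
            dists.append((d, o))
        hits = sorted((d, o) for d, o in dists if y[o] == y[r] and o != r)[:k]
        misses = sorted((d, o) for d, o in dists if y[o] != y[r])[:k]
        for f in range(nf):
            if rng_w[f] == 0:
                continue
            for _, o in hits:
                w[f] -= abs(x[r, f] - x[o, f]) / rng_w[f] / (m * k)
            for _, o in misses:
                w[f] += abs(x[r, f] - x[o, f]) / rng_w[f] / (m * k)
    return w
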