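"""Naive brute-force reference implementations of the three descriptors.

These are deliberately slow direct-summation / pair-enumeration versions,
independent of the production code paths, used as oracles.
"""

import math

import numpy as np


def dct2_direct(block: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II by direct evaluation of the defining sum."""
    n = block.shape[0]
    out = np.zeros((n, n))
    for u in range(n):
        for v in range(n):
            a_u = math.sqrt(1.0 / n) if u == 0 else math.sqrt(2.0 / n)
            a_v = math.sqrt(1.0 / n) if v == 0 else math.sqrt(2.0 / n)
            s = 0.0
            for m in range(n):
                for k in range(n):
                    s += block[m, k] \
                        * math.cos(math.pi * (2 * m + 1) * u / (2 * n)) \
                        * math.cos(math.pi * (2 * k + 1) * v / (2 * n))
            out[u, v] = a_u * a_v * s
    return out


def zigzag_direct(n: int = 8):
    """Zigzag order by walking the grid cell by cell."""
    order, r, c = [], 0, 0
    up = True
    for _ in range(n * n):
        order.append((r, c))
        if up:
            if c == n - 1:
                r, up = r + 1, False
            elif r == 0:
                c, up = c + 1, False
            else:
                r, c = r - 1, c + 1
        else:
            if r == n - 1:
                c, up = c + 1, True
            elif c == 0:
                r, up = r + 1, True
            else:
                r, c = r + 1, c - 1
    return order


def jpeg_features_naive(image, n_coeffs=9, n_bins=16,
                        dc_range=(0.0, 2048.0), ac_range=(-1024.0, 1024.0)):
    img = np.asarray(image, dtype=np.float64)
    padded = np.pad(img, ((0, 4), (0, 4)), mode="edge")
    blocks = []
    for bi in range(4):
        for bj in range(4):
            blocks.append(dct2_direct(padded[bi * 8:(bi + 1) * 8,
                                             bj * 8:(bj + 1) * 8]))
    order = zigzag_direct(8)
    out = []
    for idx in range(n_coeffs):
        r, c = order[idx]
        lo, hi = dc_range if idx == 0 else ac_range
        width = (hi - lo) / n_bins
        hist = [0] * n_bins
        for b in blocks:
            k = int(math.floor((b[r, c] - lo) / width))
            hist[min(max(k, 0), n_bins - 1)] += 1
        out.extend(hist)
    return np.array(out, dtype=np.float64)


def correlogram_naive(image, levels=64, distances=(1, 3, 5, 7)):
    img = np.asarray(image)
    H, W = img.shape
    labels = np.minimum((img.astype(np.int64) * levels) // 256, levels - 1)
    values = np.zeros((levels, len(distances)))
    for di, d in enumerate(distances):
        if d >= min(H, W):
            continue
        numer = [0] * levels
        denom = [0] * levels
        for y in range(H):
            for x in range(W):
                c = labels[y, x]
                for dy in range(-d, d + 1):
                    for dx in range(-d, d + 1):
                        if max(abs(dy), abs(dx)) != d:
                            continue
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W:
                            denom[c] += 1
                            if labels[ny, nx] == c:
                                numer[c] += 1
        for c in range(levels):
            if denom[c]:
                values[c, di] = numer[c] / denom[c]
    return values.ravel()


def colour_layout_naive(image, n_y=6, n_c=3):
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape
    means = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            r0, r1 = (i * H) // 8, ((i + 1) * H) // 8
            c0, c1 = (j * W) // 8, ((j + 1) * W) // 8
            means[i, j] = img[r0:r1, c0:c1].mean()
    order = zigzag_direct(8)
    y_dct = dct2_direct(means)
    chroma_dct = dct2_direct(np.full((8, 8), 128.0))
    vec = [y_dct[r, c] for r, c in order[:n_y]]
    vec += [chroma_dct[r, c] for r, c in order[:n_c]] * 2
    return np.array(vec)
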