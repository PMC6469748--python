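"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (queues, explicit loops, textbook
formulas) and shares no code with the implementation paths it checks.
"""

from collections import deque

import numpy as np


def bfs_label(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling by explicit breadth-first search."""
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    nxt = 0
    for r in range(h):
        for c in range(w):
            if binary[r, c] and labels[r, c] == 0:
                nxt += 1
                q = deque([(r, c)])
                labels[r, c] = nxt
                while q:
                    i, j = q.popleft()
                    for di, dj in nbrs:
                        a, b = i + di, j + dj
                        if 0 <= a < h and 0 <= b < w and binary[a, b] \
                                and labels[a, b] == 0:
                            labels[a, b] = nxt
                            q.append((a, b))
    return labels


def euler_brute_force(binary: np.ndarray) -> int:
    """Objects (8-connected) minus holes (4-connected background components
    not touching the border), both counted by BFS."""
    n_obj = bfs_label(binary, 8).max()
    bg = bfs_label(~binary, 4)
    border_ids = set(bg[0]) | set(bg[-1]) | set(bg[:, 0]) | set(bg[:, -1])
    border_ids.discard(0)
    holes = bg.max() - len(border_ids)
    return int(n_obj - holes)


def glcm_pair_count(q: np.ndarray, offset, levels: int) -> np.ndarray:
    """Co-occurrence by explicit per-pixel loop; symmetric, normalized."""
    dr, dc = offset
    h, w = q.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[q[r, c], q[r2, c2]] += 1
    P = P + P.T
    return P / P.sum()


def haralick_textbook(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics straight from the textbook definitions,
    base-2 logs, written with explicit sums."""
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mx = sum(i * px[i] for i in range(L))
    my = sum(j * py[j] for j in range(L))
    sx = np.sqrt(sum((i - mx) ** 2 * px[i] for i in range(L)))
    sy = np.sqrt(sum((j - my) ** 2 * py[j] for j in range(L)))
    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]

    def ent(vals):
        return -sum(v * np.log2(v) for v in vals if v > 0)

    out = {}
    out["asm"] = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    out["correlation"] = (0.0 if sx == 0 or sy == 0 else
                          (sum(i * j * P[i, j] for i in range(L) for j in range(L))
                           - mx * my) / (sx * sy))
    out["variance"] = sum((i - mx) ** 2 * P[i, j]
                          for i in range(L) for j in range(L))
    out["idm"] = sum(P[i, j] / (1 + (i - j) ** 2)
                     for i in range(L) for j in range(L))
    f6 = sum(k * psum[k] for k in range(2 * L - 1))
    out["sum_average"] = f6
    out["sum_variance"] = sum((k - f6) ** 2 * psum[k] for k in range(2 * L - 1))
    out["sum_entropy"] = ent(psum)
    out["entropy"] = ent(P.ravel())
    mu_d = sum(k * pdiff[k] for k in range(L))
    out["difference_variance"] = sum((k - mu_d) ** 2 * pdiff[k] for k in range(L))
    out["difference_entropy"] = ent(pdiff)
    hxy = out["entropy"]
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(P[i, j] * np.log2(px[i] * py[j])
                for i in range(L) for j in range(L)
                if P[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * np.log2(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    if sx == 0 or sy == 0 or max(hx, hy) == 0:
        out["imc1"] = 0.0
        out["imc2"] = 0.0
    else:
        out["imc1"] = (hxy - hxy1) / max(hx, hy)
        out["imc2"] = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))))
    return out


def auc_concordant_pairs(scores, labels) -> float:
    """AUC as the fraction of concordant (positive, negative) score pairs,
    half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def otsu_exhaustive(gray_u8: np.ndarray) -> int:
    """Otsu threshold by exhaustive search over all 256 cut points,
    maximizing between-class variance."""
    vals = gray_u8.ravel().astype(float)
    best_t, best_var = 0, -1.0
    for t in range(1, 256):
        lo = vals[vals < t]
        hi = vals[vals >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def min_pixel_distance(labels: np.ndarray, a: int, b: int) -> float:
    """Minimum Euclidean distance between pixels of two labeled objects."""
    pa = np.argwhere(labels == a)
    pb = np.argwhere(labels == b)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min()))
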