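"""Independent brute-force reference implementations used to validate the
package's fast paths. Deliberately simple and slow."""

import numpy as np


def otsu_oracle(img8: np.ndarray) -> int:
    """Exhaustive search over all 8-bit cut points maximizing between-class
    variance. Returns the cut t such that foreground = img > t."""
    hist = np.bincount(img8.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        m1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def li_oracle(img: np.ndarray, tol: float = 1e-8) -> float:
    """Li & Tam fixed-point iteration for the minimum cross-entropy threshold,
    written directly from the update rule; starts at the image mean.

    The algorithm needs a positive background mean (log of the mean), so the
    image is shifted to zero minimum before iterating and the threshold is
    shifted back on return."""
    x = img.astype(float).ravel()
    shift = x.min()
    x = x - shift
    t = x.mean()
    for _ in range(500):
        low = x[x <= t]
        high = x[x > t]
        if len(low) == 0 or len(high) == 0:
            break
        m_low, m_high = low.mean(), high.mean()
        if m_low == 0:
            break
        t_new = (m_low - m_high) / (np.log(m_low) - np.log(m_high))
        if abs(t_new - t) < tol:
            return t_new + shift
        t = t_new
    return t + shift


def connected_components_oracle(binary: np.ndarray, connectivity: int = 8):
    """Pure-python flood fill; returns list of component sizes."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    seen = np.zeros_like(binary)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                sizes.append(size)
    return sizes


def knn_oracle(X: np.ndarray, k: int):
    """Brute-force k nearest neighbours (excluding self) per row."""
    n = len(X)
    out = []
    for i in range(n):
        d = np.linalg.norm(X - X[i], axis=1)
        d[i] = np.inf
        out.append(set(np.argsort(d, kind="stable")[:k]))
    return out
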