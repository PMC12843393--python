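"""Naive definition-based reference implementations used only by the tests.

Each oracle computes the quantity directly from its definition (double loops,
exhaustive scans), independent of the vectorized code paths it checks.
"""

from __future__ import annotations

import numpy as np


def naive_gaussian_rgb(img: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct 2-D convolution with a truncated Gaussian, symmetric padding."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    out = np.zeros(img.shape, dtype=np.float64)
    h, w, _ = img.shape
    for c in range(3):
        chan = np.pad(img[..., c].astype(np.float64), radius, mode="symmetric")
        for y in range(h):
            for x in range(w):
                out[y, x, c] = np.sum(kernel * chan[y : y + 2 * radius + 1, x : x + 2 * radius + 1])
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)


def naive_bilateral_rgb(
    img: np.ndarray, sigma_d: float, sigma_r: float, truncate: float = 2.0
) -> np.ndarray:
    """Double-loop color bilateral filter (Euclidean RGB range distance)."""
    radius = int(np.ceil(truncate * sigma_d))
    h, w, _ = img.shape
    rgb = img.astype(np.float64)
    prgb = np.pad(rgb, ((radius, radius), (radius, radius), (0, 0)), mode="symmetric")
    out = np.zeros_like(rgb)
    for y in range(h):
        for x in range(w):
            acc = np.zeros(3)
            norm = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    sw = np.exp(-(dy * dy + dx * dx) / (2 * sigma_d**2))
                    nb = prgb[y + radius + dy, x + radius + dx]
                    rw = np.exp(-np.sum((nb - rgb[y, x]) ** 2) / (2 * sigma_r**2))
                    wgt = sw * rw
                    norm += wgt
                    acc += wgt * nb
            out[y, x] = acc / norm
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)


def naive_glcm(window: np.ndarray, dr: int, dc: int, G: int) -> np.ndarray:
    """Pair counting by explicit double loop, symmetric, normalized."""
    h, w = window.shape
    P = np.zeros((G, G), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dr, x + dc
            if 0 <= y2 < h and 0 <= x2 < w:
                i, j = window[y, x], window[y2, x2]
                P[i, j] += 1
                P[j, i] += 1
    s = P.sum()
    return P / s if s else P


def naive_glcm_props(P: np.ndarray) -> tuple[float, float, float, float]:
    """Term-by-term summation of the four texture statistics."""
    G = P.shape[0]
    contrast = homog = energy = 0.0
    for i in range(G):
        for j in range(G):
            contrast += (i - j) ** 2 * P[i, j]
            homog += P[i, j] / (1 + abs(i - j))
            energy += P[i, j] ** 2
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = sum(i * pi[i] for i in range(G))
    mu_j = sum(j * pj[j] for j in range(G))
    var_i = sum((i - mu_i) ** 2 * pi[i] for i in range(G))
    var_j = sum((j - mu_j) ** 2 * pj[j] for j in range(G))
    if var_i <= 0 or var_j <= 0:
        corr = 1.0
    else:
        corr = sum(
            (i - mu_i) * (j - mu_j) * P[i, j] for i in range(G) for j in range(G)
        ) / np.sqrt(var_i * var_j)
    return contrast, homog, energy, corr


def exhaustive_otsu(values: np.ndarray, n_bins: int) -> float:
    """Scan every interior bin edge for the max between-class variance."""
    edge, _ = exhaustive_otsu_full(values, n_bins)
    return edge


def exhaustive_otsu_full(values: np.ndarray, n_bins: int) -> tuple[float, dict]:
    """As above, also returning the variance attained at every edge."""
    vals = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
    best_sigma, best_edge = -1.0, None
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    sigma_at_edge = {}
    for k in range(1, n_bins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        sigma_at_edge[float(edges[k])] = float(sigma)
        if sigma > best_sigma:
            best_sigma, best_edge = sigma, edges[k]
    return float(best_edge), sigma_at_edge


def naive_erode(mask: np.ndarray, fp: np.ndarray, border: bool) -> np.ndarray:
    """Definition-based erosion: all footprint pixels True (outside=border)."""
    r = fp.shape[0] // 2
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if not fp[dy + r, dx + r]:
                        continue
                    yy, xx = y + dy, x + dx
                    v = mask[yy, xx] if 0 <= yy < h and 0 <= xx < w else border
                    if not v:
                        ok = False
            out[y, x] = ok
    return out


def naive_dilate(mask: np.ndarray, fp: np.ndarray, border: bool) -> np.ndarray:
    """Definition-based dilation with the mirrored footprint."""
    r = fp.shape[0] // 2
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            hit = False
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if not fp[r - dy, r - dx]:  # reflected structuring element
                        continue
                    yy, xx = y + dy, x + dx
                    v = mask[yy, xx] if 0 <= yy < h and 0 <= xx < w else border
                    if v:
                        hit = True
            out[y, x] = hit
    return out


def loop_confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn
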