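"""Naive, loop-based reference implementations of the image operations.

These are deliberately written as plain Python loops over pixels so that
the vectorised pipeline can be checked against an independent
formulation of the same definitions.
"""

from __future__ import annotations

import math

import numpy as np


def naive_background(imgs: list[np.ndarray], margin: int) -> float:
    """Mean over interior pixels of each image, averaged across images."""
    means = []
    for img in imgs:
        h, w = img.shape
        vals = []
        for r in range(margin, h - margin):
            for c in range(margin, w - margin):
                vals.append(img[r, c])
        means.append(sum(vals) / len(vals))
    return sum(means) / len(means)


def naive_subtract(img: np.ndarray, bg: float):
    out = np.empty_like(img, dtype=float)
    clipped = 0
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            v = img[r, c] - bg
            if v < 0:
                clipped += 1
                v = 0.0
            out[r, c] = v
    return out, clipped


def naive_ratio_map(fp, sir, labels, eps):
    out = np.full(fp.shape, np.nan)
    excluded = 0
    for r in range(fp.shape[0]):
        for c in range(fp.shape[1]):
            if labels[r, c] > 0:
                if sir[r, c] > eps:
                    out[r, c] = fp[r, c] / sir[r, c]
                else:
                    excluded += 1
    return out, excluded


def naive_per_cell_means(values, labels, min_valid_fraction):
    """{label: (area, n_valid, mean)} for surviving labels."""
    out = {}
    for lab in sorted(set(labels.ravel().tolist()) - {0}):
        pix = []
        area = 0
        for r in range(labels.shape[0]):
            for c in range(labels.shape[1]):
                if labels[r, c] == lab:
                    area += 1
                    if math.isfinite(values[r, c]):
                        pix.append(values[r, c])
        if area == 0 or len(pix) / area < min_valid_fraction:
            continue
        out[int(lab)] = (area, len(pix), sum(pix) / len(pix))
    return out


def naive_fov_mean(values, margin):
    h, w = values.shape
    vals = []
    for r in range(margin, h - margin):
        for c in range(margin, w - margin):
            if math.isfinite(values[r, c]):
                vals.append(values[r, c])
    return sum(vals) / len(vals)


def naive_despeckle(img):
    """3x3 sliding median with edge replication."""
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            window = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    window.append(img[rr, cc])
            window.sort()
            out[r, c] = window[4]
    return out


def naive_flag_outliers(values, k_mad):
    x = sorted(values)
    n = len(x)

    def med(v):
        m = len(v)
        return v[m // 2] if m % 2 else (v[m // 2 - 1] + v[m // 2]) / 2.0

    median = med(x)
    mad = med(sorted(abs(v - median) for v in values))
    if mad > 0:
        return [abs(v - median) > k_mad * 1.4826 * mad for v in values]
    if all(v == values[0] for v in values):
        return [False] * n
    q1, q3 = np.percentile(np.asarray(values, dtype=float), [25, 75])
    iqr = q3 - q1
    return [v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr for v in values]
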