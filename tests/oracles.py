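"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain per-pixel / per-element Python loops,
deliberately ignoring the vectorized implementations in the package.
"""

from __future__ import annotations

import math

import numpy as np


def perimeter_loop(mask: np.ndarray) -> float:
    """4-direction Cauchy-Crofton boundary length by explicit loops."""
    m = np.pad(np.asarray(mask, dtype=bool), 1)
    h, w = m.shape
    c0 = c90 = c45 = c135 = 0
    for r in range(h):
        for c in range(w - 1):
            if m[r, c] != m[r, c + 1]:
                c0 += 1
    for r in range(h - 1):
        for c in range(w):
            if m[r, c] != m[r + 1, c]:
                c90 += 1
    for r in range(h - 1):
        for c in range(w - 1):
            if m[r, c] != m[r + 1, c + 1]:
                c45 += 1
            if m[r, c + 1] != m[r + 1, c]:
                c135 += 1
    per = math.pi / 8.0 * (c0 + c90 + (c45 + c135) / math.sqrt(2.0))
    if int(np.sum(mask)) == 1:
        return max(per, 4.0)
    return per


def sphericity_loop(mask: np.ndarray) -> float:
    area = int(np.sum(np.asarray(mask, dtype=bool)))
    per = perimeter_loop(mask)
    q = 4.0 * math.pi * area / per**2
    return min(max(q, 1e-12), 1.2)


def pos_loop(masks, image_area: int) -> float:
    """Union pixel count by explicit set arithmetic."""
    seen = set()
    for m in masks:
        ys, xs = np.nonzero(np.asarray(m, dtype=bool))
        for y, x in zip(ys.tolist(), xs.tolist()):
            seen.add((y, x))
    return len(seen) / image_area


def confusion_loop(pred: list[str], truth: list[str]) -> dict[str, float]:
    tp = fp = tn = fn = 0
    for a, b in zip(pred, truth):
        if b == "TUMOR":
            if a == "TUMOR":
                tp += 1
            else:
                fn += 1
        else:
            if a == "TUMOR":
                fp += 1
            else:
                tn += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "percent_agreement": (tp + tn) / len(truth),
    }


def pearson_loop(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def random_blob(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A random connected blob mask (thresholded smoothed noise)."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.random((size, size)), rng.uniform(2, 6))
    mask = field > np.percentile(field, rng.uniform(55, 85))
    lab, n = ndi.label(mask)
    if n == 0:
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, size // 2] = True
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))
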