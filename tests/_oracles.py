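"""Independent brute-force oracles used by the tests.

Everything here is written with explicit Python loops over pixels and
samples — no shared code with the package — so it can serve as an
independent check of the vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = ("N", "S", "E", "W", "NW", "NE", "SW", "SE")
STEPS = {
    "N": (-1, 0),
    "S": (1, 0),
    "E": (0, 1),
    "W": (0, -1),
    "NW": (-1, -1),
    "NE": (-1, 1),
    "SW": (1, -1),
    "SE": (1, 1),
}


def region_quantities(mask: np.ndarray, gray: np.ndarray) -> dict:
    """Per-nucleus quantities of a single binary region, pixel by pixel."""
    rows, cols = mask.shape
    pixels = [(r, c) for r in range(rows) for c in range(cols) if mask[r, c]]
    x_k = len(pixels)
    border = []
    for r, c in pixels:
        on_border = False
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < rows and 0 <= cc < cols) or not mask[rr, cc]:
                on_border = True
        if on_border:
            border.append((r, c))
    m = sum(p[0] for p in pixels) / x_k
    n = sum(p[1] for p in pixels) / x_k

    mi = int(round(m))
    ni = int(round(n))
    d = {}
    for D in DIRECTIONS:
        sr, sc = STEPS[D]
        if not mask[mi, ni]:
            d[D] = 0.0
            continue
        r, c = mi, ni
        while 0 <= r + sr < rows and 0 <= c + sc < cols and mask[r + sr, c + sc]:
            r, c = r + sr, c + sc
        d[D] = math.sqrt((r - mi) ** 2 + (c - ni) ** 2)

    rmin = min(p[0] for p in pixels)
    rmax = max(p[0] for p in pixels)
    cmin = min(p[1] for p in pixels)
    cmax = max(p[1] for p in pixels)
    AR_k = (rmax - rmin + 1) * (cmax - cmin + 1)

    J = [float(gray[r, c]) for r, c in pixels]
    I_k = sum(J) / x_k
    sigma_Ik = math.sqrt(sum((j - I_k) ** 2 for j in J) / x_k)
    RI_k = max(J) - min(J)
    return {
        "x_k": x_k,
        "P_k": len(border),
        "centroid": (m, n),
        "d_Dk": [d[D] for D in DIRECTIONS],
        "AR_k": AR_k,
        "I_k": I_k,
        "sigma_Ik": sigma_Ik,
        "RI_k": RI_k,
    }


def mutual_information_bits(x, y) -> float:
    """Double-loop plug-in MI over the joint table, in bits."""
    x = list(x)
    y = list(y)
    n = len(x)
    xs = sorted(set(x))
    ys = sorted(set(y))
    mi = 0.0
    for a in xs:
        for b in ys:
            p_ab = sum(1 for i in range(n) if x[i] == a and y[i] == b) / n
            if p_ab == 0:
                continue
            p_a = sum(1 for i in range(n) if x[i] == a) / n
            p_b = sum(1 for i in range(n) if y[i] == b) / n
            mi += p_ab * math.log2(p_ab / (p_a * p_b))
    return mi


def mrmr_order_naive(disc_columns: list, y, n_features: int) -> list[int]:
    """Greedy MID selection re-implemented naively over discrete columns."""
    selected: list[int] = []
    remaining = list(range(n_features))
    while remaining:
        best, best_score = None, -float("inf")
        for j in remaining:
            rel = mutual_information_bits(disc_columns[j], y)
            if selected:
                red = sum(
                    mutual_information_bits(disc_columns[j], disc_columns[s]) for s in selected
                ) / len(selected)
                crit = rel - red
            else:
                crit = rel
            if crit > best_score + 1e-12:  # same tie rule: lower index wins
                best, best_score = j, crit
        selected.append(best)
        remaining.remove(best)
    return selected


def auc_pair_counting(scores, labels, positive_label=1) -> float:
    """Mann-Whitney AUC: fraction of positive/negative pairs ranked
    correctly, ties counting 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == positive_label]
    neg = [s for s, l in zip(scores, labels) if l != positive_label]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def digital_disk(radius: int, pad: int = 2) -> np.ndarray:
    """Boolean digital disk: (dr^2 + dc^2) <= r^2."""
    size = 2 * (radius + pad) + 1
    c = radius + pad
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def digital_ellipse(a: int, b: int, pad: int = 2) -> np.ndarray:
    """Axis-aligned digital ellipse with semi-axes (a rows, b cols)...

    semi-axis ``a`` along columns (E-W), ``b`` along rows (N-S).
    """
    size_r = 2 * (b + pad) + 1
    size_c = 2 * (a + pad) + 1
    cr, cc = b + pad, a + pad
    rr, ccol = np.mgrid[0:size_r, 0:size_c]
    return ((rr - cr) / b) ** 2 + ((ccol - cc) / a) ** 2 <= 1.0
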