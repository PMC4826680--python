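"""Independent brute-force oracles shared across test modules.

These deliberately use naive loops, not the library code paths they check.
"""

import numpy as np


def lbp_code_bitloop(patch):
    """8-iteration bit loop over the clockwise-from-top-left neighbor ring."""
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    center = int(patch[1, 1])
    code = 0
    for n in range(8):
        dr, dc = offsets[n]
        if int(patch[1 + dr, 1 + dc]) - center >= 0:
            code += 2**n
    return code


def otsu_bruteforce(img):
    """Exhaustive between-class-variance scan over all 255 split points.

    Evaluates w0 w1 (m0 - m1)^2 as an exact Fraction per threshold so the
    scan is immune to floating-point near-ties; first maximum wins.
    """
    from fractions import Fraction

    hist = np.bincount(np.asarray(img).ravel(), minlength=256)
    best_t, best_v = 0, Fraction(-1)
    for t in range(255):
        w0 = int(hist[: t + 1].sum())
        w1 = int(hist[t + 1 :].sum())
        if w0 == 0 or w1 == 0:
            continue
        m0 = Fraction(int((np.arange(t + 1) * hist[: t + 1]).sum()), w0)
        m1 = Fraction(int((np.arange(t + 1, 256) * hist[t + 1 :]).sum()), w1)
        v = Fraction(w0) * Fraction(w1) * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def quantize_bruteforce(x, centroids):
    """Squared-distance scan over every word; first minimum wins."""
    best_i, best_d = 0, np.inf
    for i, c in enumerate(centroids):
        d = float(((np.asarray(x) - np.asarray(c)) ** 2).sum())
        if d < best_d:
            best_d, best_i = d, i
    return best_i


def flood_fill_components(mask, connectivity=8):
    """BFS flood fill returning the list of components (pixel lists)."""
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r, c in zip(*np.nonzero(mask)):
        if seen[r, c]:
            continue
        stack, comp = [(r, c)], []
        seen[r, c] = True
        while stack:
            y, x = stack.pop()
            comp.append((y, x))
            for dy, dx in offs:
                ny, nx = y + dy, x + dx
                if (
                    0 <= ny < mask.shape[0]
                    and 0 <= nx < mask.shape[1]
                    and mask[ny, nx]
                    and not seen[ny, nx]
                ):
                    seen[ny, nx] = True
                    stack.append((ny, nx))
        comps.append(comp)
    return comps
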