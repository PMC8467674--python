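"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (loops over pixels, all-pairs
distances, direct formula evaluation) and shares no code with the package.
"""

import numpy as np

# ---------------------------------------------------------------- metrics


def oracle_set_counts(gt, sr):
    n_gt = n_sr = n_inter = n_union = n_sr_only = 0
    for i in range(gt.shape[0]):
        for j in range(gt.shape[1]):
            g, s = bool(gt[i, j]), bool(sr[i, j])
            n_gt += g
            n_sr += s
            n_inter += g and s
            n_union += g or s
            n_sr_only += s and not g
    return n_gt, n_sr, n_inter, n_union, n_sr_only


def oracle_tp(gt, sr):
    n_gt, _, n_inter, _, _ = oracle_set_counts(gt, sr)
    return n_inter / n_gt


def oracle_fp(gt, sr):
    n_gt, _, _, _, n_sr_only = oracle_set_counts(gt, sr)
    return n_sr_only / n_gt


def oracle_dice(gt, sr):
    n_gt, n_sr, n_inter, _, _ = oracle_set_counts(gt, sr)
    return 2 * n_inter / (n_gt + n_sr)


def oracle_jaccard(gt, sr):
    _, _, n_inter, n_union, _ = oracle_set_counts(gt, sr)
    return n_inter / n_union


def oracle_contour(mask):
    """Boundary pixels: foreground with a 4-neighbor outside the mask
    (image border counts as outside)."""
    pts = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            on_border = i in (0, h - 1) or j in (0, w - 1)
            neighbors = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
            if on_border or any(not mask[a, b] for a, b in neighbors):
                pts.append((i, j))
    return pts


def oracle_hausdorff(gt, sr):
    """All-pairs symmetric Hausdorff distance on the contour point sets."""
    xs, ys = oracle_contour(gt), oracle_contour(sr)

    def directed(a_pts, b_pts):
        worst = 0.0
        for a in a_pts:
            best = min(np.hypot(a[0] - b[0], a[1] - b[1]) for b in b_pts)
            worst = max(worst, best)
        return worst

    return max(directed(xs, ys), directed(ys, xs))


def random_mask_pairs(rng, n, max_size=16, p_range=(0.2, 0.8)):
    """Random non-empty binary mask pairs up to max_size x max_size."""
    pairs = []
    while len(pairs) < n:
        h = int(rng.integers(2, max_size + 1))
        w = int(rng.integers(2, max_size + 1))
        p = rng.uniform(*p_range)
        gt = rng.random((h, w)) < p
        sr = rng.random((h, w)) < p
        if gt.any() and sr.any():
            pairs.append((gt, sr))
    return pairs

# ------------------------------------------------------------------ loss


def oracle_cross_entropy_sum(y, p, eps=1e-7):
    total = 0.0
    flat_y, flat_p = y.ravel(), p.ravel()
    for yi, pi in zip(flat_y, flat_p):
        pi = min(max(pi, eps), 1 - eps)
        total += -(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
    return total

# --------------------------------------------------------------- bicubic


def oracle_cubic_weight(s, a=-0.5):
    s = abs(s)
    if s <= 1:
        return (a + 2) * s ** 3 - (a + 3) * s ** 2 + 1
    if s < 2:
        return a * s ** 3 - 5 * a * s ** 2 + 8 * a * s - 4 * a
    return 0.0


def oracle_bicubic(img, target):
    """Direct per-pixel evaluation of the 16-coefficient cubic convolution
    with edge replication, the textbook definition."""
    h, w = img.shape
    th, tw = target
    out = np.zeros((th, tw))
    for oy in range(th):
        sy = (oy + 0.5) * h / th - 0.5
        by = int(np.floor(sy))
        ty = sy - by
        for ox in range(tw):
            sx = (ox + 0.5) * w / tw - 0.5
            bx = int(np.floor(sx))
            tx = sx - bx
            val = 0.0
            for i in range(-1, 3):
                for j in range(-1, 3):
                    wy = oracle_cubic_weight(ty - i)
                    wx = oracle_cubic_weight(tx - j)
                    yy = min(max(by + i, 0), h - 1)
                    xx = min(max(bx + j, 0), w - 1)
                    val += wy * wx * img[yy, xx]
            out[oy, ox] = min(max(val, 0.0), 1.0)
    return out

# ----------------------------------------------------- histogram equalize


def oracle_global_hist_eq(img, nbins=256):
    """Plain global histogram equalization with the cdf-min convention."""
    binned = np.minimum((img * nbins).astype(int), nbins - 1)
    hist = np.zeros(nbins)
    for v in binned.ravel():
        hist[v] += 1
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = (cdf[binned[i, j]] - cdf_min) / (cdf[-1] - cdf_min)
    return out

# ----------------------------------------------------- parameter counting


def oracle_unet_param_count(filters, in_ch=1, out_ch=1):
    """Analytic parameter count of the plain U-Net built from ConvBlocks
    (two 3x3 convs per level), 2x2 transposed-conv upsampling and a 1x1
    sigmoid head."""

    def conv(cin, cout, k):
        return cout * cin * k * k + cout

    total = 0
    prev = in_ch
    for f in filters:                      # encoder blocks
        total += conv(prev, f, 3) + conv(f, f, 3)
        prev = f
    deeper = filters[-1]
    for f in reversed(filters[:-1]):       # decoder: up + two convs
        total += conv(deeper, f, 2)        # transposed conv, same formula
        total += conv(2 * f, f, 3) + conv(f, f, 3)
        deeper = f
    total += conv(filters[0], out_ch, 1)   # head
    return total
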