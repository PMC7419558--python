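"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over pixels/pairs, deliberately
avoiding the vectorized code paths of the package.
"""

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(pixels, levels, d, angle):
    """O(N^2) pair enumeration over all pixel pairs; symmetric, normalized."""
    h, w = pixels.shape
    dr, dc = OFFSETS[angle][0] * d, OFFSETS[angle][1] * d
    counts = np.zeros((levels, levels))
    for r1 in range(h):
        for c1 in range(w):
            for r2 in range(h):
                for c2 in range(w):
                    if (r2 - r1, c2 - c1) in ((dr, dc), (-dr, -dc)):
                        counts[pixels[r1, c1], pixels[r2, c2]] += 1
    return counts / counts.sum()


def glcm_features_bruteforce(g):
    levels = g.shape[0]
    mu_x = sum((i + 1) * g[i, j] for i in range(levels) for j in range(levels))
    mu_y = sum((j + 1) * g[i, j] for i in range(levels) for j in range(levels))
    var_x = sum((i + 1 - mu_x) ** 2 * g[i, j] for i in range(levels) for j in range(levels))
    var_y = sum((j + 1 - mu_y) ** 2 * g[i, j] for i in range(levels) for j in range(levels))
    sx, sy = math.sqrt(var_x), math.sqrt(var_y)
    corr = float("nan")
    if sx * sy > 0:
        corr = (
            sum((i + 1) * (j + 1) * g[i, j] for i in range(levels) for j in range(levels))
            - mu_x * mu_y
        ) / (sx * sy)
    homog = sum(g[i, j] / (1 + abs(i - j)) for i in range(levels) for j in range(levels))
    energy = sum(g[i, j] ** 2 for i in range(levels) for j in range(levels))
    entropy = -sum(
        g[i, j] * math.log2(g[i, j])
        for i in range(levels)
        for j in range(levels)
        if g[i, j] > 0
    )
    return {
        "glcm_correlation": corr,
        "glcm_homogeneity": homog,
        "glcm_energy": energy,
        "glcm_entropy": entropy,
    }


def ngtdm_bruteforce(pixels, levels, n):
    """Per-pixel loop over complete neighborhoods."""
    h, w = pixels.shape
    d_vec = np.zeros(levels)
    counts = np.zeros(levels)
    n_centers = 0
    for r in range(n, h - n):
        for c in range(n, w - n):
            neigh = []
            for rr in range(r - n, r + n + 1):
                for cc in range(c - n, c + n + 1):
                    if (rr, cc) != (r, c):
                        neigh.append(float(pixels[rr, cc]))
            lvl = pixels[r, c]
            d_vec[lvl] += abs(float(pixels[r, c]) - sum(neigh) / len(neigh))
            counts[lvl] += 1
            n_centers += 1
    return d_vec, counts / n_centers, n_centers


def ngtdm_features_bruteforce(d_vec, p_vec, n_centers, eps=1e-12):
    levels = len(p_vec)
    present = [i for i in range(levels) if p_vec[i] > 0]
    ng = len(present)
    pd_sum = sum(p_vec[i] * d_vec[i] for i in present)
    coarseness = 1.0 / (pd_sum + eps)
    if ng < 2:
        return {
            "ngtdm_contrast": 0.0,
            "ngtdm_coarseness": coarseness,
            "ngtdm_busyness": float("nan"),
            "ngtdm_complexity": 0.0,
        }
    # grey values are 1-based in the feature formulas
    contrast = (
        sum(
            p_vec[i] * p_vec[j] * ((i + 1) - (j + 1)) ** 2
            for i in present
            for j in present
        )
        / (ng * (ng - 1))
    ) * (sum(d_vec[i] for i in present) / n_centers)
    denom = sum(
        abs((i + 1) * p_vec[i] - (j + 1) * p_vec[j]) for i in present for j in present
    )
    busyness = pd_sum / denom if denom > 0 else float("nan")
    complexity = sum(
        (abs(i - j) / (n_centers * (p_vec[i] + p_vec[j])))
        * (p_vec[i] * d_vec[i] + p_vec[j] * d_vec[j])
        for i in present
        for j in present
    )
    return {
        "ngtdm_contrast": contrast,
        "ngtdm_coarseness": coarseness,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
    }


def _lines_bruteforce(pixels, angle):
    h, w = pixels.shape
    lines = []
    if angle == 0:
        for r in range(h):
            lines.append([pixels[r, c] for c in range(w)])
    elif angle == 90:
        for c in range(w):
            lines.append([pixels[r, c] for r in range(h)])
    elif angle == 135:  # main diagonals (dr, dc) = (1, 1)
        for start in range(-h + 1, w):
            line = []
            for r in range(h):
                c = r + start
                if 0 <= c < w:
                    line.append(pixels[r, c])
            if line:
                lines.append(line)
    elif angle == 45:  # anti-diagonals (dr, dc) = (-1, 1): constant r + c
        for s in range(h + w - 1):
            line = []
            for c in range(max(0, s - h + 1), min(w, s + 1)):
                line.append(pixels[s - c, c])
            if line:
                lines.append(line)
    return lines


def rlm_bruteforce(pixels, levels, angle):
    max_run = max(pixels.shape)
    r_mat = np.zeros((levels, max_run), dtype=int)
    for line in _lines_bruteforce(pixels, angle):
        run_val, run_len = line[0], 1
        for v in line[1:]:
            if v == run_val:
                run_len += 1
            else:
                r_mat[run_val, run_len - 1] += 1
                run_val, run_len = v, 1
        r_mat[run_val, run_len - 1] += 1
    return r_mat


def rlm_features_bruteforce(r_mat, n_pixels):
    levels, max_run = r_mat.shape
    n = r_mat.sum()
    sre = sum(r_mat[i, j] / (j + 1) ** 2 for i in range(levels) for j in range(max_run)) / n
    lre = sum(r_mat[i, j] * (j + 1) ** 2 for i in range(levels) for j in range(max_run)) / n
    gln = sum(sum(r_mat[i, :]) ** 2 for i in range(levels)) / n
    rln = sum(sum(r_mat[:, j]) ** 2 for j in range(max_run)) / n
    return {
        "rlm_sre": sre,
        "rlm_lre": lre,
        "rlm_gln": gln,
        "rlm_rln": rln,
        "rlm_rp": n / n_pixels,
    }


def lroc_auc_bruteforce(trials, radius=15.0):
    """Double loop over (present, absent) pairs."""
    present = [t for t in trials if t.truth_present]
    absent = [t for t in trials if not t.truth_present]
    total = 0.0
    for p in present:
        correct = False
        if p.marked_location is not None and p.true_center is not None:
            dist = math.hypot(
                p.marked_location[0] - p.true_center[0],
                p.marked_location[1] - p.true_center[1],
            )
            correct = dist <= radius
        if not correct:
            continue
        for a in absent:
            if p.rating > a.rating:
                total += 1.0
            elif p.rating == a.rating:
                total += 0.5
    return total / (len(present) * len(absent))


def pearson_bruteforce(x, y):
    """Definitional formula accumulated with fsum (extended precision)."""
    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    cov = math.fsum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = math.fsum((xi - mx) ** 2 for xi in x)
    vy = math.fsum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def box_chord_length(p0, p1, box_max):
    """Analytic length of the segment p0-p1 inside [0, box_max]^3."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    amin, amax = 0.0, 1.0
    for ax in range(3):
        if d[ax] != 0:
            a0 = (0.0 - p0[ax]) / d[ax]
            a1 = (box_max[ax] - p0[ax]) / d[ax]
            amin = max(amin, min(a0, a1))
            amax = min(amax, max(a0, a1))
        elif not (0 <= p0[ax] <= box_max[ax]):
            return 0.0
    if amax <= amin:
        return 0.0
    return (amax - amin) * float(np.linalg.norm(d))
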