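"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops straight from the
textbook definitions, deliberately sharing no code with the package
implementation, so agreement between the two is meaningful.
"""

import math

import numpy as np

# ---------------------------------------------------------------------------
# co-occurrence

_DIR_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts_bruteforce(img, distance, angles_deg=(0, 45, 90, 135),
                           levels=None):
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    img = np.asarray(img)
    L = levels or int(img.max()) + 1
    h, w = img.shape
    mat = np.zeros((L, L), dtype=float)
    for ang in angles_deg:
        dr, dc = _DIR_STEPS[ang]
        dr, dc = dr * distance, dc * distance
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    mat[img[r, c], img[r2, c2]] += 1
                    mat[img[r2, c2], img[r, c]] += 1  # symmetric
    return mat


def glcm_features_bruteforce(P):
    """The 22 co-occurrence features from a normalized matrix, via loops."""
    L = P.shape[0]
    total = P.sum()
    if total <= 0:
        names = ["energy", "contrast", "correlation", "variance", "idm",
                 "sum_average", "sum_variance", "sum_entropy", "entropy",
                 "difference_variance", "difference_entropy", "imc1", "imc2",
                 "autocorrelation", "cluster_shade", "cluster_prominence",
                 "cluster_tendency", "dissimilarity", "maximum_probability",
                 "inverse_difference", "inverse_difference_normalized",
                 "inverse_variance"]
        return {n: 0.0 for n in names}
    P = P / total
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def ent(ps):
        return -sum(p * math.log2(p) for p in ps if p > 1e-12)

    out = {}
    out["energy"] = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * P[i, j]
                          for i in range(L) for j in range(L))
    if sig_x > 1e-12 and sig_y > 1e-12:
        out["correlation"] = sum((i - mu_x) * (j - mu_y) * P[i, j]
                                 for i in range(L) for j in range(L)) \
            / (sig_x * sig_y)
    else:
        out["correlation"] = 0.0
    out["variance"] = sum((i - mu_x) ** 2 * P[i, j]
                          for i in range(L) for j in range(L))
    out["idm"] = sum(P[i, j] / (1 + (i - j) ** 2)
                     for i in range(L) for j in range(L))
    sa = sum(k * p_sum[k] for k in range(2 * L - 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * p_sum[k]
                              for k in range(2 * L - 1))
    out["sum_entropy"] = ent(p_sum)
    hxy = ent(P.ravel())
    out["entropy"] = hxy
    da = sum(k * p_diff[k] for k in range(L))
    out["difference_variance"] = sum((k - da) ** 2 * p_diff[k]
                                     for k in range(L))
    out["difference_entropy"] = ent(p_diff)
    hxy1 = -sum(P[i, j] * math.log2(px[i] * py[j])
                for i in range(L) for j in range(L)
                if px[i] * py[j] > 1e-12)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(L) for j in range(L)
                if px[i] * py[j] > 1e-12)
    hx, hy = ent(px), ent(py)
    denom = max(hx, hy)
    out["imc1"] = (hxy - hxy1) / denom if denom > 1e-12 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    out["autocorrelation"] = sum(i * j * P[i, j]
                                 for i in range(L) for j in range(L))
    out["cluster_shade"] = sum((i + j - mu_x - mu_y) ** 3 * P[i, j]
                               for i in range(L) for j in range(L))
    out["cluster_prominence"] = sum((i + j - mu_x - mu_y) ** 4 * P[i, j]
                                    for i in range(L) for j in range(L))
    out["cluster_tendency"] = sum((i + j - mu_x - mu_y) ** 2 * P[i, j]
                                  for i in range(L) for j in range(L))
    out["dissimilarity"] = sum(abs(i - j) * P[i, j]
                               for i in range(L) for j in range(L))
    out["maximum_probability"] = float(P.max())
    out["inverse_difference"] = sum(P[i, j] / (1 + abs(i - j))
                                    for i in range(L) for j in range(L))
    out["inverse_difference_normalized"] = sum(
        P[i, j] / (1 + abs(i - j) / L) for i in range(L) for j in range(L))
    out["inverse_variance"] = sum(P[i, j] / (i - j) ** 2
                                  for i in range(L) for j in range(L)
                                  if i != j)
    return out


# ---------------------------------------------------------------------------
# run lengths

def _lines_bruteforce(img, ang):
    h, w = img.shape
    if ang == 0:
        return [list(img[r, :]) for r in range(h)]
    if ang == 90:
        return [list(img[:, c]) for c in range(w)]
    lines = []
    if ang == 45:
        # up-right diagonals
        for s in range(h + w - 1):
            line = [img[r, c] for r in range(h) for c in range(w)
                    if r + c == s]
            # order along the diagonal: decreasing row
            line = [img[r, s - r] for r in range(min(s, h - 1), -1, -1)
                    if 0 <= s - r < w]
            lines.append(line)
        return lines
    if ang == 135:
        for d in range(-(h - 1), w):
            line = [img[r, r + d] for r in range(h) if 0 <= r + d < w]
            lines.append(line)
        return lines
    raise ValueError(ang)


def glrlm_features_bruteforce(img, levels):
    """6 run-length features averaged over 4 directions, via loops."""
    img = np.asarray(img)
    n_pix = img.size
    acc = {k: 0.0 for k in ["short_run_emphasis", "long_run_emphasis",
                            "grey_level_nonuniformity",
                            "run_length_nonuniformity", "run_percentage",
                            "low_grey_run_emphasis"]}
    for ang in (0, 45, 90, 135):
        runs = []  # (level, length)
        for line in _lines_bruteforce(img, ang):
            if not line:
                continue
            cur, length = line[0], 1
            for v in line[1:]:
                if v == cur:
                    length += 1
                else:
                    runs.append((cur, length))
                    cur, length = v, 1
            runs.append((cur, length))
        n_runs = len(runs)
        by_len = {}
        by_lvl = {}
        for lv, ln in runs:
            by_len[ln] = by_len.get(ln, 0) + 1
            by_lvl[lv] = by_lvl.get(lv, 0) + 1
        acc["short_run_emphasis"] += sum(c / ln ** 2
                                         for ln, c in by_len.items()) / n_runs
        acc["long_run_emphasis"] += sum(c * ln ** 2
                                        for ln, c in by_len.items()) / n_runs
        acc["grey_level_nonuniformity"] += sum(c ** 2
                                               for c in by_lvl.values()) / n_runs
        acc["run_length_nonuniformity"] += sum(c ** 2
                                               for c in by_len.values()) / n_runs
        acc["run_percentage"] += n_runs / n_pix
        acc["low_grey_run_emphasis"] += sum(c / (lv + 1) ** 2
                                            for lv, c in by_lvl.items()) / n_runs
    return {k: v / 4.0 for k, v in acc.items()}


# ---------------------------------------------------------------------------
# windowed difference statistics

def glds_features_bruteforce(roi, window, bins=32):
    """Mean/contrast/energy/entropy/idm of |roi - local mean|, via loops."""
    roi = np.asarray(roi, dtype=float)
    h, w = roi.shape
    half = window // 2
    d = np.zeros_like(roi)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            n = 0
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    # reflect (symmetric) boundary
                    rr = r + dr
                    cc = c + dc
                    if rr < 0:
                        rr = -rr - 1
                    if rr >= h:
                        rr = 2 * h - rr - 1
                    if cc < 0:
                        cc = -cc - 1
                    if cc >= w:
                        cc = 2 * w - cc - 1
                    acc += roi[rr, cc]
                    n += 1
            d[r, c] = round(abs(roi[r, c] - acc / n), 12)
    dv = d.ravel()
    out = {"mean": float(dv.mean()), "contrast": float((dv ** 2).mean())}
    dmax = dv.max()
    if dmax < 1e-12:
        out.update(energy=1.0, entropy=0.0, idm=1.0)
        return out
    hist, edges = np.histogram(dv, bins=bins, range=(0.0, dmax))
    prob = hist / hist.sum()
    centres = 0.5 * (edges[:-1] + edges[1:])
    out["energy"] = float(sum(p ** 2 for p in prob))
    out["entropy"] = float(-sum(p * math.log2(p) for p in prob if p > 1e-12))
    out["idm"] = float(sum(p / (1 + c ** 2) for p, c in zip(prob, centres)))
    return out


# ---------------------------------------------------------------------------
# neighbourhood grey tone difference

def ngtdm_features_bruteforce(img, levels, radius):
    """Amadasun-King features over the valid interior, via loops."""
    img = np.asarray(img)
    h, w = img.shape
    if min(h, w) < 2 * radius + 1:
        return None
    n_i = np.zeros(levels)
    s_i = np.zeros(levels)
    N = 0
    for r in range(radius, h - radius):
        for c in range(w - radius)[radius:]:
            acc = 0.0
            cnt = 0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if dr == 0 and dc == 0:
                        continue
                    acc += img[r + dr, c + dc]
                    cnt += 1
            a = acc / cnt
            lv = img[r, c]
            n_i[lv] += 1
            s_i[lv] += abs(lv - a)
            N += 1
    p_i = n_i / N
    present = [i for i in range(levels) if n_i[i] > 0]
    ng = len(present)
    ps = sum(p_i[i] * s_i[i] for i in present)
    out = {"coarseness": min(1.0 / max(ps, 1e-12), 1e6)}
    if ng > 1:
        out["contrast"] = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                               for i in present for j in present)
                           / (ng * (ng - 1))) * (s_i.sum() / N)
        denom = sum(abs(i * p_i[i] - j * p_i[j])
                    for i in present for j in present)
        out["busyness"] = ps / denom if denom > 1e-12 else 0.0
        out["complexity"] = sum(abs(i - j) * (p_i[i] * s_i[i]
                                              + p_i[j] * s_i[j])
                                / (N * (p_i[i] + p_i[j]))
                                for i in present for j in present)
        out["strength"] = sum((p_i[i] + p_i[j]) * (i - j) ** 2
                              for i in present for j in present) \
            / max(s_i.sum(), 1e-12)
    else:
        out.update(contrast=0.0, busyness=0.0, complexity=0.0, strength=0.0)
    return out


# ---------------------------------------------------------------------------
# statistical feature matrix

def sfm_features_bruteforce(img, spacing):
    """Coarseness/contrast/periodicity/roughness via explicit shifts."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    if min(h, w) <= spacing:
        return None
    disps = []
    for dr in range(0, spacing + 1):
        for dc in range(-spacing, spacing + 1):
            if dr == 0 and dc <= 0:
                continue
            disps.append((dr, dc))
    dss, con = [], {}
    cheb = []
    for dr, dc in disps:
        vals_abs, vals_sq = [], []
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    diff = img[r, c] - img[r2, c2]
                    vals_abs.append(abs(diff))
                    vals_sq.append(diff ** 2)
        dss.append(float(np.mean(vals_abs)))
        con[(dr, dc)] = float(np.mean(vals_sq))
        cheb.append(max(abs(dr), abs(dc)))
    dss = np.array(dss)
    mean_dss = dss.mean()
    out = {"coarseness": min(len(dss) / max(dss.sum(), 1e-12), 1e6),
           "contrast": math.sqrt(np.mean([con[d] for d in
                                          [(0, 1), (1, 0), (1, 1), (1, -1)]])),
           "periodicity": ((mean_dss - dss.min()) / mean_dss
                           if mean_dss > 1e-12 else 0.0)}
    cheb = np.array(cheb)
    lag_means = [(lag, dss[cheb == lag].mean()) for lag in
                 range(1, spacing + 1)
                 if (cheb == lag).any() and dss[cheb == lag].mean() > 1e-12]
    if len(lag_means) >= 2:
        lx = np.log([l for l, _ in lag_means])
        ly = np.log([m for _, m in lag_means])
        out["roughness"] = 3.0 - float(np.polyfit(lx, ly, 1)[0])
    else:
        out["roughness"] = 0.0
    return out


# ---------------------------------------------------------------------------
# bounded-diameter complete linkage

def complete_linkage_bruteforce(points, max_distance):
    """Naive agglomerative complete linkage cut at the diameter bound.

    Starts from singletons and repeatedly merges the pair of clusters
    with the smallest complete-linkage distance (= merged diameter)
    while that distance is <= max_distance. O(n^3), explicit loops.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    clusters = [[i] for i in range(len(pts))]

    def clink(a, b):
        return max(float(np.hypot(*(pts[i] - pts[j])))
                   for i in a for j in b)

    while len(clusters) > 1:
        best = None
        best_d = None
        for x in range(len(clusters)):
            for z in range(x + 1, len(clusters)):
                d = clink(clusters[x], clusters[z])
                if best_d is None or d < best_d:
                    best_d, best = d, (x, z)
        if best_d is None or best_d > max_distance:
            break
        x, z = best
        merged = clusters[x] + clusters[z]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, z)]
        clusters.append(merged)
    return sorted([sorted(c) for c in clusters], key=lambda c: c[0])
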