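"""Matrix-based texture families: GLCM, GLRLM, GLSM, GLDS, NGTDM, SFM, fractal.

All matrix families operate on quantized ROIs (integer levels 0..L-1)
except GLDS and GLSM, which work on the real-valued prepared ROI. Counts
per family: GLCM 88 (22 features x 4 offsets), GLRLM 6, GLSM 6, GLDS 15
(5 statistics x 3 window sizes), NGTDM 15 (5 x 3 radii), SFM 8 (4 x 2
spacings), fractal 1.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.ndimage import uniform_filter

_EPS = 1e-12
_COARSENESS_CAP = 1e6


def _as_levels(qroi):
    """Accept a QuantizedROI or a plain integer array."""
    if hasattr(qroi, "array"):
        return np.asarray(qroi.array), int(qroi.levels)
    arr = np.asarray(qroi)
    return arr, int(arr.max()) + 1


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > _EPS]
    return float(-np.sum(nz * np.log2(nz)))


# ---------------------------------------------------------------------------
# GLCM

GLCM_FEATURE_NAMES = [
    # Haralick core
    "energy", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    # extended set
    "autocorrelation", "cluster_shade", "cluster_prominence",
    "cluster_tendency", "dissimilarity", "maximum_probability",
    "inverse_difference", "inverse_difference_normalized",
    "inverse_variance",
]

GLCM_ANGLES_DEG = (0, 45, 90, 135)


@dataclass
class GLCMConfig:
    """Offsets and directions of the co-occurrence analysis."""

    offsets: tuple = (1, 3, 5, 9)
    angles_deg: tuple = GLCM_ANGLES_DEG
    feature_names: tuple = field(default=tuple(GLCM_FEATURE_NAMES))


_GLCM_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix(qroi, distance: int, angles_deg=GLCM_ANGLES_DEG) -> np.ndarray:
    """Direction-summed symmetric co-occurrence probability matrix.

    Diagonal directions step ``distance`` pixels along *both* axes
    (chessboard offsets), the convention matrix-feature banks use for
    integer offsets.
    """
    arr, L = _as_levels(qroi)
    h, w = arr.shape
    mat = np.zeros((L, L), dtype=float)
    for ang in angles_deg:
        dr, dc = _GLCM_STEPS[ang]
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(-dr, 0), min(h - dr, h)
        c0, c1 = max(-dc, 0), min(w - dc, w)
        if r0 >= r1 or c0 >= c1:
            continue
        a = arr[r0:r1, c0:c1].ravel()
        b = arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L)
        mat += counts + counts.T  # symmetric accumulation
    total = mat.sum()
    return mat / total if total > 0 else mat


def glcm_features_from_matrix(P: np.ndarray,
                              flags: list | None = None,
                              prefix: str = "") -> OrderedDict:
    """The 22 co-occurrence features of one normalized matrix."""
    out: OrderedDict[str, float] = OrderedDict()
    L = P.shape[0]
    total = P.sum()
    if total <= 0:
        if flags is not None:
            flags.append(f"glcm{prefix}: empty co-occurrence matrix, zeros")
        for name in GLCM_FEATURE_NAMES:
            out[name] = 0.0
        return out
    P = P / total
    i = np.arange(L, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px, py = P.sum(axis=1), P.sum(axis=0)
    mu_x, mu_y = float((i * px).sum()), float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    p_sum = np.bincount((I + J).astype(int).ravel(), weights=P.ravel(),
                        minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(I - J).astype(int).ravel(), weights=P.ravel(),
                         minlength=L)
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    out["energy"] = float(np.sum(P ** 2))
    out["contrast"] = float(np.sum((I - J) ** 2 * P))
    if sig_x > _EPS and sig_y > _EPS:
        out["correlation"] = float(
            np.sum((I - mu_x) * (J - mu_y) * P) / (sig_x * sig_y))
    else:
        out["correlation"] = 0.0
        if flags is not None:
            flags.append(f"glcm{prefix}: correlation undefined, set to 0")
    out["variance"] = float(np.sum((I - mu_x) ** 2 * P))
    out["idm"] = float(np.sum(P / (1.0 + (I - J) ** 2)))
    sa = float((k_sum * p_sum).sum())
    out["sum_average"] = sa
    out["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy2(p_sum)
    hxy = _entropy2(P.ravel())
    out["entropy"] = hxy
    da = float((k_diff * p_diff).sum())
    out["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy2(p_diff)
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > _EPS, np.log2(np.maximum(pxpy, _EPS)), 0.0)
    hxy1 = float(-np.sum(P * log_pxpy))
    hxy2 = float(-np.sum(pxpy * log_pxpy))
    hx, hy = _entropy2(px), _entropy2(py)
    denom = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / denom) if denom > _EPS else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    out["autocorrelation"] = float(np.sum(I * J * P))
    cs = I + J - mu_x - mu_y
    out["cluster_shade"] = float(np.sum(cs ** 3 * P))
    out["cluster_prominence"] = float(np.sum(cs ** 4 * P))
    out["cluster_tendency"] = float(np.sum(cs ** 2 * P))
    out["dissimilarity"] = float(np.sum(np.abs(I - J) * P))
    out["maximum_probability"] = float(P.max())
    out["inverse_difference"] = float(np.sum(P / (1.0 + np.abs(I - J))))
    out["inverse_difference_normalized"] = float(
        np.sum(P / (1.0 + np.abs(I - J) / L)))
    off = np.abs(I - J) > 0
    out["inverse_variance"] = float(np.sum(P[off] / (I - J)[off] ** 2))
    return out


def glcm_features(qroi, config: GLCMConfig | None = None,
                  flags: list | None = None) -> OrderedDict:
    """88 co-occurrence features: 22 per offset, direction-averaged."""
    config = config or GLCMConfig()
    arr, _ = _as_levels(qroi)
    out: OrderedDict[str, float] = OrderedDict()
    for d in config.offsets:
        prefix = f"_d{d}"
        if d >= max(arr.shape):
            if flags is not None:
                flags.append(f"glcm: ROI thinner than offset {d}, zeros")
            feats = OrderedDict((n, 0.0) for n in config.feature_names)
        else:
            P = glcm_matrix(qroi, d, config.angles_deg)
            feats = glcm_features_from_matrix(P, flags, prefix)
        for name in config.feature_names:
            out[f"glcm_d{d}_{name}"] = feats[name]
    return out


# ---------------------------------------------------------------------------
# GLRLM

GLRLM_FEATURE_NAMES = [
    "short_run_emphasis", "long_run_emphasis", "grey_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage", "low_grey_run_emphasis",
]


def _direction_lines(arr: np.ndarray, angle_deg: int):
    h, w = arr.shape
    if angle_deg == 0:
        return [arr[r, :] for r in range(h)]
    if angle_deg == 90:
        return [arr[:, c] for c in range(w)]
    if angle_deg == 45:
        f = np.fliplr(arr)
        return [f.diagonal(k) for k in range(-(h - 1), w)]
    if angle_deg == 135:
        return [arr.diagonal(k) for k in range(-(h - 1), w)]
    raise ValueError(f"unsupported direction {angle_deg}")


def run_length_matrix(arr: np.ndarray, levels: int,
                      angle_deg: int) -> np.ndarray:
    """Run-length counts R[level, length-1] along one direction."""
    max_len = max(arr.shape)
    R = np.zeros((levels, max_len), dtype=float)
    for line in _direction_lines(arr, angle_deg):
        line = np.asarray(line)
        if line.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(line) != 0)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [line.size]))
        for s, e in zip(starts, ends):
            R[int(line[s]), e - s - 1] += 1
    return R


def glrlm_features(qroi, flags: list | None = None) -> OrderedDict:
    """6 run-length features averaged over the 4 principal directions."""
    arr, L = _as_levels(qroi)
    acc = {n: 0.0 for n in GLRLM_FEATURE_NAMES}
    n_pixels = arr.size
    for ang in (0, 45, 90, 135):
        R = run_length_matrix(arr, L, ang)
        n_runs = R.sum()
        j = np.arange(1, R.shape[1] + 1, dtype=float)
        lv = np.arange(1, L + 1, dtype=float)  # 1-based to avoid div by 0
        r_j = R.sum(axis=0)
        r_i = R.sum(axis=1)
        acc["short_run_emphasis"] += float((r_j / j ** 2).sum() / n_runs)
        acc["long_run_emphasis"] += float((r_j * j ** 2).sum() / n_runs)
        acc["grey_level_nonuniformity"] += float((r_i ** 2).sum() / n_runs)
        acc["run_length_nonuniformity"] += float((r_j ** 2).sum() / n_runs)
        acc["run_percentage"] += float(n_runs / n_pixels)
        acc["low_grey_run_emphasis"] += float((r_i / lv ** 2).sum() / n_runs)
    out = OrderedDict()
    for n in GLRLM_FEATURE_NAMES:
        out[f"glrlm_{n}"] = acc[n] / 4.0
    return out


# ---------------------------------------------------------------------------
# GLSM (grey level sharpness: gradient-magnitude map statistics)

GLSM_FEATURE_NAMES = ["mean", "variance", "skewness", "kurtosis",
                      "energy", "entropy"]


def glsm_features(roi: np.ndarray, flags: list | None = None) -> OrderedDict:
    """Sharpness statistics of the central-difference gradient magnitude."""
    arr = np.asarray(roi, dtype=float)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("GLSM needs at least a 3x3 ROI")
    gy, gx = np.gradient(arr)
    g = np.hypot(gy, gx).ravel()
    constant = g.std() < _EPS or np.ptp(g) < 1e-9 * (abs(g).max() + 1.0)
    if constant and flags is not None:
        flags.append("glsm: flat gradient map, moment features set to 0")
    if constant:
        prob = np.array([1.0])
    else:
        hist, _ = np.histogram(g, bins=32)
        prob = hist / hist.sum()
    out = OrderedDict()
    out["glsm_mean"] = float(g.mean())
    out["glsm_variance"] = float(g.var())
    out["glsm_skewness"] = 0.0 if constant else float(sps.skew(g))
    out["glsm_kurtosis"] = 0.0 if constant else float(sps.kurtosis(g))
    out["glsm_energy"] = float(np.mean(g ** 2))
    out["glsm_entropy"] = 0.0 if constant else _entropy2(prob)
    return out


# ---------------------------------------------------------------------------
# GLDS (grey level difference statistics, windowed)

GLDS_STAT_NAMES = ["mean", "contrast", "energy", "entropy", "idm"]
GLDS_WINDOWS = (3, 5, 7)
_GLDS_BINS = 32


def glds_features(roi: np.ndarray, flags: list | None = None) -> OrderedDict:
    """15 difference statistics: |ROI - local w x w mean|, w in {3,5,7}.

    Histogram statistics (energy, entropy, idm) use a 32-bin histogram
    of the difference map; ``idm`` weights bins by 1/(1+c^2) at bin
    centre c.
    """
    arr = np.asarray(roi, dtype=float)
    out = OrderedDict()
    for w in GLDS_WINDOWS:
        keyp = f"glds_w{w}_"
        if min(arr.shape) < w:
            if flags is not None:
                flags.append(f"glds: ROI smaller than {w}x{w} window, zeros")
            for n in GLDS_STAT_NAMES:
                out[keyp + n] = 0.0
            continue
        local = uniform_filter(arr, size=w, mode="reflect")
        # round to stabilize histogram bin assignment: integer-valued
        # inputs put deviations exactly on bin edges, where float noise
        # from the filter's summation order would flip bins
        d = np.round(np.abs(arr - local), 12).ravel()
        dmax = d.max()
        out[keyp + "mean"] = float(d.mean())
        out[keyp + "contrast"] = float(np.mean(d ** 2))
        if dmax < _EPS:
            out[keyp + "energy"] = 1.0
            out[keyp + "entropy"] = 0.0
            out[keyp + "idm"] = 1.0
            continue
        hist, edges = np.histogram(d, bins=_GLDS_BINS, range=(0.0, dmax))
        prob = hist / hist.sum()
        centres = 0.5 * (edges[:-1] + edges[1:])
        out[keyp + "energy"] = float(np.sum(prob ** 2))
        out[keyp + "entropy"] = _entropy2(prob)
        out[keyp + "idm"] = float(np.sum(prob / (1.0 + centres ** 2)))
    return out


# ---------------------------------------------------------------------------
# NGTDM (Amadasun-King)

NGTDM_STAT_NAMES = ["coarseness", "contrast", "busyness", "complexity",
                    "strength"]
NGTDM_RADII = (1, 2, 3)


def ngtdm_table(qroi, radius: int):
    """Per-level (n_i, p_i, s_i) over the valid interior at one radius."""
    arr, L = _as_levels(qroi)
    w = 2 * radius + 1
    if min(arr.shape) < w:
        return None
    f = arr.astype(float)
    win_mean = uniform_filter(f, size=w, mode="constant")
    interior = (slice(radius, arr.shape[0] - radius),
                slice(radius, arr.shape[1] - radius))
    centre = f[interior]
    # neighbourhood mean excluding the centre pixel
    a = (win_mean[interior] * w * w - centre) / (w * w - 1)
    levels = arr[interior]
    n_i = np.bincount(levels.ravel(), minlength=L).astype(float)
    s_i = np.bincount(levels.ravel(),
                      weights=np.abs(centre - a).ravel(), minlength=L)
    return n_i, n_i / n_i.sum(), s_i


def ngtdm_features(qroi, flags: list | None = None) -> OrderedDict:
    """15 neighbourhood grey-tone difference features (radii 1, 2, 3)."""
    out = OrderedDict()
    for r in NGTDM_RADII:
        keyp = f"ngtdm_r{r}_"
        tab = ngtdm_table(qroi, r)
        if tab is None:
            if flags is not None:
                flags.append(f"ngtdm: ROI too small for radius {r}, zeros")
            for n in NGTDM_STAT_NAMES:
                out[keyp + n] = 0.0
            continue
        n_i, p_i, s_i = tab
        N = n_i.sum()
        present = np.flatnonzero(n_i > 0)
        lv = present.astype(float)
        ng = len(present)
        ps = float((p_i * s_i).sum())
        out[keyp + "coarseness"] = float(min(1.0 / max(ps, _EPS),
                                             _COARSENESS_CAP))
        if ng > 1:
            pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
            li, lj = np.meshgrid(lv, lv, indexing="ij")
            out[keyp + "contrast"] = float(
                (pi * pj * (li - lj) ** 2).sum() / (ng * (ng - 1))
                * s_i.sum() / N)
            denom = float(np.abs(li * pi - lj * pj).sum())
            out[keyp + "busyness"] = (ps / denom) if denom > _EPS else 0.0
            si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")
            out[keyp + "complexity"] = float(
                (np.abs(li - lj) * (pi * si + pj * sj)
                 / (N * (pi + pj))).sum())
            out[keyp + "strength"] = float(
                ((pi + pj) * (li - lj) ** 2).sum() / max(s_i.sum(), _EPS))
        else:
            out[keyp + "contrast"] = 0.0
            out[keyp + "busyness"] = 0.0
            out[keyp + "complexity"] = 0.0
            out[keyp + "strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# SFM (statistical feature matrix)

SFM_STAT_NAMES = ["coarseness", "contrast", "periodicity", "roughness"]
SFM_SPACINGS = (4, 8)


def _sfm_displacements(L: int):
    out = []
    for dr in range(0, L + 1):
        for dc in range(-L, L + 1):
            if dr == 0 and dc <= 0:
                continue
            out.append((dr, dc))
    return out


def _shifted_stats(arr: np.ndarray, dr: int, dc: int):
    """Mean |diff| and mean squared diff between arr and its (dr,dc) shift."""
    h, w = arr.shape
    r0, r1 = max(dr, 0), min(h, h + dr)
    c0, c1 = max(dc, 0), min(w, w + dc)
    a = arr[r0 - dr if dr < 0 else 0:h - dr if dr > 0 else h,
            c0 - dc if dc < 0 else 0:w - dc if dc > 0 else w]
    b = arr[dr if dr > 0 else 0:h + dr if dr < 0 else h,
            dc if dc > 0 else 0:w + dc if dc < 0 else w]
    diff = a.astype(float) - b.astype(float)
    return float(np.mean(np.abs(diff))), float(np.mean(diff ** 2))


def sfm_features(qroi, flags: list | None = None) -> OrderedDict:
    """8 statistical-feature-matrix measures at spacings 4 and 8.

    For each displacement delta within the spacing window the
    dissimilarity DSS = E|f(x) - f(x+delta)| and contrast
    CON = E[(f(x) - f(x+delta))^2] are computed; coarseness is the
    reciprocal mean dissimilarity, contrast the RMS unit-lag CON,
    periodicity the relative depth of the DSS minimum, and roughness
    3 minus the log-log slope of DSS against Chebyshev lag (a variogram
    estimate of the fractal dimension of the surface).
    """
    arr, _ = _as_levels(qroi)
    out = OrderedDict()
    for Lsp in SFM_SPACINGS:
        keyp = f"sfm_l{Lsp}_"
        if min(arr.shape) <= Lsp:
            if flags is not None:
                flags.append(f"sfm: ROI not larger than spacing {Lsp}, zeros")
            for n in SFM_STAT_NAMES:
                out[keyp + n] = 0.0
            continue
        disps = _sfm_displacements(Lsp)
        dss, con, cheb = [], {}, []
        for dr, dc in disps:
            m_abs, m_sq = _shifted_stats(arr, dr, dc)
            dss.append(m_abs)
            con[(dr, dc)] = m_sq
            cheb.append(max(abs(dr), abs(dc)))
        dss = np.array(dss)
        cheb = np.array(cheb)
        mean_dss = float(dss.mean())
        out[keyp + "coarseness"] = float(
            min(len(dss) / max(dss.sum(), _EPS), _COARSENESS_CAP))
        unit = [(0, 1), (1, 0), (1, 1), (1, -1)]
        out[keyp + "contrast"] = float(np.sqrt(np.mean([con[d] for d in unit])))
        out[keyp + "periodicity"] = (
            float((mean_dss - dss.min()) / mean_dss) if mean_dss > _EPS else 0.0)
        # variogram slope over Chebyshev lags
        lag_means = []
        for lag in range(1, Lsp + 1):
            sel = dss[cheb == lag]
            if sel.size and sel.mean() > _EPS:
                lag_means.append((lag, sel.mean()))
        if len(lag_means) >= 2:
            lx = np.log([l for l, _ in lag_means])
            ly = np.log([m for _, m in lag_means])
            slope = float(np.polyfit(lx, ly, 1)[0])
            out[keyp + "roughness"] = 3.0 - slope
        else:
            if flags is not None:
                flags.append(f"sfm: roughness undefined at spacing {Lsp}")
            out[keyp + "roughness"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Fractal dimension (differential box counting)

FRACTAL_SCALES = (2, 4, 8, 16)


def fractal_dimension(roi: np.ndarray, flags: list | None = None,
                      scales=FRACTAL_SCALES) -> OrderedDict:
    """Differential box-counting dimension of the intensity surface.

    The ROI is rescaled to [0, 255]; at block side s the surface is
    covered with boxes of height s*256/n and the covering count is
    summed over blocks; the dimension is the least-squares slope of
    log(count) against log(n/s). A flat plane gives ~2, white noise
    approaches 3.
    """
    arr = np.asarray(roi, dtype=float)
    n = min(arr.shape)
    rng_v = arr.max() - arr.min()
    if rng_v < _EPS:
        if flags is not None:
            flags.append("fractal: constant ROI, dimension set to 2")
        return OrderedDict(fractal_dimension=2.0)
    z = (arr - arr.min()) / rng_v * 255.0
    usable = [s for s in scales if s <= n // 2]
    if len(usable) < len(scales) and flags is not None:
        flags.append(f"fractal: only scales {usable} usable for size {n}")
    pts = []
    for s in usable:
        h_box = s * 256.0 / n
        nb_r, nb_c = arr.shape[0] // s, arr.shape[1] // s
        crop = z[:nb_r * s, :nb_c * s]
        blocks = crop.reshape(nb_r, s, nb_c, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        n_boxes = np.floor(bmax / h_box) - np.floor(bmin / h_box) + 1.0
        pts.append((np.log(n / s), np.log(n_boxes.sum())))
    if len(pts) < 2:
        if flags is not None:
            flags.append("fractal: fewer than 2 usable scales, set to 0")
        return OrderedDict(fractal_dimension=0.0)
    lx = np.array([p[0] for p in pts])
    ly = np.array([p[1] for p in pts])
    slope = float(np.polyfit(lx, ly, 1)[0])
    return OrderedDict(fractal_dimension=slope)
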