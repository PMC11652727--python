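"""Filter-based families: Laws energies, Gabor bank, RFS/MR8, Fourier bands.

All convolutions use reflect (half-sample symmetric) boundary padding.
The Gabor bank is a single-scale even-symmetric bank at a carrier
wavelength of 4 px/cycle and orientations 0-150 deg in 30 deg steps;
each kernel is DC-corrected so constant regions give zero response.
The root filter set (RFS) holds 38 kernels: one Gaussian and one
Laplacian-of-Gaussian (both sigma = 10 px, rotationally symmetric) plus
edge (first-derivative) and bar (second-derivative) anisotropic
Gaussians at scales (sigma_x, sigma_y) in {(1,3), (2,6), (4,12)}, each
at the six orientations. Collapsing the oriented filters to their
maximum response across orientations leaves the 8 MR8 responses.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

ORIENTATIONS_DEG = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)


def _pad_symmetric(img: np.ndarray, pad_y: int, pad_x: int) -> np.ndarray:
    out = img
    while pad_y > 0 or pad_x > 0:
        py = min(pad_y, out.shape[0])
        px = min(pad_x, out.shape[1])
        out = np.pad(out, ((py, py), (px, px)), mode="symmetric")
        pad_y -= py
        pad_x -= px
    return out


def convolve_reflect(img: np.ndarray, kernel: np.ndarray,
                     flags: list | None = None,
                     family: str = "filter") -> np.ndarray:
    """FFT convolution with reflect padding; output has the input shape."""
    img = np.asarray(img, dtype=float)
    ky, kx = kernel.shape
    py, px = ky // 2, kx // 2
    if (ky > img.shape[0] or kx > img.shape[1]) and flags is not None:
        flags.append(f"{family}: kernel {kernel.shape} larger than ROI "
                     f"{img.shape}, reflect-padded")
    padded = _pad_symmetric(img, py, px)
    full = fftconvolve(padded, kernel, mode="same")
    return full[py:py + img.shape[0], px:px + img.shape[1]]


# ---------------------------------------------------------------------------
# Laws texture energy

_LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

#: symmetry-averaged map identifiers (9 maps, 2 statistics each = 18)
LAWS_MAP_NAMES = ["LE", "LS", "LR", "ES", "ER", "SR", "EE", "SS", "RR"]
_LAWS_ENERGY_WINDOW = 15


def _laws_kernel(a: str, b: str) -> np.ndarray:
    return np.outer(_LAWS_VECTORS[a], _LAWS_VECTORS[b])


def laws_features(roi: np.ndarray, flags: list | None = None) -> OrderedDict:
    """18 Laws texture energy measures (9 symmetry-averaged maps x mean/SD).

    Each 5x5 kernel output is rectified and smoothed with a 15x15 mean
    filter to form the energy map; symmetric kernel pairs (e.g. L5E5
    and E5L5) are averaged. All maps involve at least one zero-sum
    vector, so constant regions yield zero energy.
    """
    arr = np.asarray(roi, dtype=float)
    if min(arr.shape) < _LAWS_ENERGY_WINDOW and flags is not None:
        flags.append("laws: ROI smaller than 15x15 energy window, "
                     "statistics unstable")
    from scipy.ndimage import uniform_filter

    def energy_map(a, b):
        resp = convolve_reflect(arr, _laws_kernel(a, b), flags, "laws")
        return uniform_filter(np.abs(resp), size=_LAWS_ENERGY_WINDOW,
                              mode="reflect")

    out = OrderedDict()
    pair_map = {"LE": ("L5", "E5"), "LS": ("L5", "S5"), "LR": ("L5", "R5"),
                "ES": ("E5", "S5"), "ER": ("E5", "R5"), "SR": ("S5", "R5"),
                "EE": ("E5", "E5"), "SS": ("S5", "S5"), "RR": ("R5", "R5")}
    for name in LAWS_MAP_NAMES:
        a, b = pair_map[name]
        em = energy_map(a, b)
        if a != b:
            em = 0.5 * (em + energy_map(b, a))
        out[f"laws_{name}_mean"] = float(em.mean())
        out[f"laws_{name}_sd"] = float(em.std())
    return out


# ---------------------------------------------------------------------------
# Gabor bank

@dataclass
class GaborBankConfig:
    """Single-scale even-symmetric Gabor bank.

    The envelope SD follows a one-octave bandwidth (sigma ~ 0.56 x
    wavelength) with unit aspect ratio.
    """

    wavelength: float = 4.0
    orientations_deg: tuple = ORIENTATIONS_DEG
    sigma_factor: float = 0.56
    truncate: float = 3.0


def gabor_kernel_even(wavelength: float, orientation_deg: float,
                      sigma_factor: float = 0.56,
                      truncate: float = 3.0) -> np.ndarray:
    """DC-corrected even-phase (cosine) Gabor kernel."""
    sigma = sigma_factor * wavelength
    half = int(math.ceil(truncate * sigma))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    theta = math.radians(orientation_deg)
    env = np.exp(-(x ** 2 + y ** 2) / (2.0 * sigma ** 2))
    carrier = np.cos(2.0 * np.pi * (x * math.cos(theta) +
                                    y * math.sin(theta)) / wavelength)
    k = env * carrier
    # remove the DC leak inside the envelope so flat regions respond 0
    k -= env * (k.sum() / env.sum())
    return k


def gabor_features(roi: np.ndarray, config: GaborBankConfig | None = None,
                   flags: list | None = None) -> OrderedDict:
    """Mean absolute bank response per orientation (6 values)."""
    config = config or GaborBankConfig()
    arr = np.asarray(roi, dtype=float)
    out = OrderedDict()
    for th in config.orientations_deg:
        k = gabor_kernel_even(config.wavelength, th, config.sigma_factor,
                              config.truncate)
        resp = convolve_reflect(arr, k, flags, "gabor")
        out[f"gabor_l{config.wavelength:g}_t{int(th)}"] = float(
            np.mean(np.abs(resp)))
    return out


# ---------------------------------------------------------------------------
# RFS / MR8

RFS_SCALES = ((1.0, 3.0), (2.0, 6.0), (4.0, 12.0))
_RFS_SUPPORT = 49  # kernel side, odd

MR_FEATURE_NAMES = (
    ["mr_gaussian", "mr_log"]
    + [f"mr_edge_s{int(sx)}_{int(sy)}" for sx, sy in RFS_SCALES]
    + [f"mr_bar_s{int(sx)}_{int(sy)}" for sx, sy in RFS_SCALES]
)


@dataclass
class RFSBank:
    """The 38-kernel root filter set feeding the MR8 reduction."""

    gaussian: np.ndarray
    log: np.ndarray
    edge: dict  # (sx, sy) -> list of 6 oriented kernels
    bar: dict

    @property
    def n_kernels(self) -> int:
        return 2 + sum(len(v) for v in self.edge.values()) \
            + sum(len(v) for v in self.bar.values())

    def all_kernels(self) -> list:
        out = [self.gaussian, self.log]
        for sc in RFS_SCALES:
            out.extend(self.edge[sc])
        for sc in RFS_SCALES:
            out.extend(self.bar[sc])
        return out


def _l1_normalize(k: np.ndarray) -> np.ndarray:
    return k / np.sum(np.abs(k))


def _oriented_gaussian_derivative(sigma_x: float, sigma_y: float,
                                  orientation_deg: float, order: int,
                                  support: int = _RFS_SUPPORT) -> np.ndarray:
    """First/second derivative of an anisotropic Gaussian, rotated.

    The Gaussian is elongated along the filter orientation (SD sigma_y)
    and differentiated across it (SD sigma_x).
    """
    half = support // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    theta = math.radians(orientation_deg)
    u = x * math.cos(theta) + y * math.sin(theta)  # along orientation
    v = -x * math.sin(theta) + y * math.cos(theta)  # across
    g = np.exp(-(u ** 2 / (2 * sigma_y ** 2) + v ** 2 / (2 * sigma_x ** 2)))
    if order == 1:
        k = -v / sigma_x ** 2 * g
    elif order == 2:
        k = (v ** 2 / sigma_x ** 4 - 1.0 / sigma_x ** 2) * g
    else:
        raise ValueError("order must be 1 or 2")
    k -= k.mean()  # enforce zero mean
    return _l1_normalize(k)


def build_rfs_bank(support: int = _RFS_SUPPORT) -> RFSBank:
    """Construct the 38-filter root set (L1-normalized, zero-mean but
    for the Gaussian)."""
    half = support // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    r2 = x ** 2 + y ** 2
    sigma = 10.0
    gauss = np.exp(-r2 / (2 * sigma ** 2))
    gauss = gauss / gauss.sum()  # unit DC gain
    log = (r2 / sigma ** 4 - 2.0 / sigma ** 2) * np.exp(-r2 / (2 * sigma ** 2))
    log -= log.mean()
    log = _l1_normalize(log)
    edge = {sc: [_oriented_gaussian_derivative(sc[0], sc[1], th, order=1,
                                               support=support)
                 for th in ORIENTATIONS_DEG] for sc in RFS_SCALES}
    bar = {sc: [_oriented_gaussian_derivative(sc[0], sc[1], th, order=2,
                                              support=support)
                for th in ORIENTATIONS_DEG] for sc in RFS_SCALES}
    bank = RFSBank(gaussian=gauss, log=log, edge=edge, bar=bar)
    if bank.n_kernels != 38:
        raise RuntimeError(f"RFS bank has {bank.n_kernels} kernels, "
                           "expected 38")
    return bank


def mr8_response_maps(roi: np.ndarray, bank: RFSBank | None = None,
                      flags: list | None = None) -> OrderedDict:
    """The 8 maximum-response maps of an ROI (name -> 2-D array)."""
    bank = bank or build_rfs_bank()
    if bank.n_kernels != 38:
        raise ValueError("RFS bank must contain exactly 38 kernels")
    arr = np.asarray(roi, dtype=float)
    maps = OrderedDict()
    maps["mr_gaussian"] = convolve_reflect(arr, bank.gaussian, flags, "mr")
    maps["mr_log"] = convolve_reflect(arr, bank.log, flags, "mr")
    for kind, kernels in (("edge", bank.edge), ("bar", bank.bar)):
        for sc in RFS_SCALES:
            resp = np.stack([convolve_reflect(arr, k, flags, "mr")
                             for k in kernels[sc]])
            if kind == "edge":
                # odd filters: orientation is defined mod 180 deg, so the
                # response sign is arbitrary; retain the max magnitude
                picked = np.abs(resp).max(axis=0)
            else:
                # even filters: keep the signed value of the orientation
                # with the largest magnitude (the statistic must be
                # sign-preserving for the bar and LoG responses)
                idx = np.abs(resp).argmax(axis=0)
                picked = np.take_along_axis(resp, idx[None], axis=0)[0]
            maps[f"mr_{kind}_s{int(sc[0])}_{int(sc[1])}"] = picked
    return maps


def mr8_features(roi: np.ndarray, bank: RFSBank | None = None,
                 flags: list | None = None) -> OrderedDict:
    """Mean signed value of each of the 8 maximum-response maps."""
    maps = mr8_response_maps(roi, bank, flags)
    return OrderedDict((name, float(m.mean())) for name, m in maps.items())


# ---------------------------------------------------------------------------
# Fourier bands

_FOURIER_SPLIT = 0.125  # cycles/pixel = Nyquist / 4


def fourier_features(roi: np.ndarray, flags: list | None = None) -> OrderedDict:
    """Fractions of non-DC spectral power below/above Nyquist/4.

    The two fractions partition the non-DC power (they sum to 1 for any
    non-constant ROI and are both 0 for a constant one).
    """
    arr = np.asarray(roi, dtype=float)
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError("Fourier features need at least an 8x8 ROI")
    spec = np.abs(np.fft.fft2(arr)) ** 2
    fy = np.fft.fftfreq(arr.shape[0])[:, None]
    fx = np.fft.fftfreq(arr.shape[1])[None, :]
    fr = np.hypot(fy, fx)
    dc = fr == 0
    total = float(spec[~dc].sum())
    out = OrderedDict()
    if total <= 0:
        out["fourier_low_fraction"] = 0.0
        out["fourier_high_fraction"] = 0.0
        if flags is not None:
            flags.append("fourier: constant ROI, both band fractions 0")
        return out
    low = float(spec[(~dc) & (fr < _FOURIER_SPLIT)].sum())
    out["fourier_low_fraction"] = low / total
    out["fourier_high_fraction"] = (total - low) / total
    return out
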