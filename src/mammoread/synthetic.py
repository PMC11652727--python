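"""Synthetic dense-mammogram cohorts for end-to-end pipeline testing.

The study data behind this package (screening mammograms plus per-reader
annotations collected on a training platform) are not publicly available,
so every downstream stage is exercised against a generator that emulates
the statistical structure the analysis assumes:

* textured breast-like views (a smooth Gaussian random field inside a
  half-ellipse breast mask) for the standard CC and MLO projections;
* planted "suspicious" areas whose *difficult* class carries injected
  oriented high-frequency texture (a sinusoidal carrier at ~4 px/cycle,
  the wavelength the Gabor bank is tuned to) and heterogeneous grey
  levels, while the *easy* class does not;
* simulated reader cohorts with per-reader false-response rates,
  planted outlier readers with elevated false-positive rates, and
  Gaussian jitter on annotation placement.

Nothing here attempts photorealism; the generator's job is to give the
pipeline inputs with known ground truth (which areas are difficult,
which readers are outliers) at rates that are calibrated and checkable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

#: Canonical filter-bank orientations (degrees); injected texture uses one of these.
CANONICAL_ORIENTATIONS = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)

#: Lesion subtype vocabulary with sampling weights mirroring a 21-lesion
#: case mix (9 stellate, 2 architectural distortion, 2 calcification,
#: 5 discrete mass, 3 non-specific density).
LESION_SUBTYPES = (
    ("stellate", 9),
    ("architectural distortion", 2),
    ("calcification", 2),
    ("discrete mass", 5),
    ("non-specific density", 3),
)

VIEWS = ("CC", "MLO")


@dataclass
class SyntheticConfig:
    """Study-design parameters of a synthetic reading cohort.

    Defaults follow the emulated study design: 40 normal + 20 cancer
    cases, each with CC and MLO projections, read by a cohort of 16
    radiologists of whom 2 are planted high-false-positive outliers.
    """

    n_normal_cases: int = 40
    n_cancer_cases: int = 20
    image_size: tuple[int, int] = (256, 256)  # rows, cols
    pixel_spacing: float = 0.2  # mm / pixel
    n_readers: int = 16
    n_outlier_readers: int = 2
    base_fp_rate: float = 0.10  # per reader per easy normal area
    outlier_fp_multiplier: float = 4.0
    difficulty_fp_multiplier: float = 3.0
    base_fn_rate: float = 0.30  # per reader per easy cancer area
    difficulty_fn_multiplier: float = 2.5
    negative_mark_rate: float = 0.05  # non-responders leaving a rating<3 mark
    difficulty_effect: float = 2.0  # oriented texture amplitude in difficult areas
    difficulty_orientation: Optional[float] = None  # None -> one drawn per case set
    difficult_fraction: float = 0.35
    annotation_jitter_sd: float = 8.0  # pixels
    areas_per_normal_view: int = 1
    patch_size: int = 64  # planted-area side length, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outlier_readers >= self.n_readers:
            raise ValueError("n_outlier_readers must be < n_readers")
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image_size must be at least 64x64")
        for name in ("base_fp_rate", "base_fn_rate", "negative_mark_rate",
                     "difficult_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1]")
        if self.outlier_fp_multiplier < 1.0:
            raise ValueError("outlier_fp_multiplier must be >= 1")
        if self.difficulty_effect < 0.0:
            raise ValueError("difficulty_effect must be >= 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass
class SyntheticCaseSet:
    """Images plus ground-truth tables emitted by :func:`generate_case_set`.

    ``images`` maps ``(case_id, view, side)`` to a 2-D float array.
    ``lesion_truths`` and ``planted_area_truths`` are tidy tables keyed
    the same way; every cancer case carries at least one lesion truth.
    """

    images: dict
    pixel_spacing: float
    lesion_truths: pd.DataFrame
    planted_area_truths: pd.DataFrame
    config: SyntheticConfig = field(repr=False, default=None)


def generate_texture_patch(size: int, smoothness: float, oriented_energy: float,
                           orientation: float = 0.0, seed: int = 0,
                           isotropic_energy: float = 0.0) -> np.ndarray:
    """Breast-parenchyma-like texture patch with optional oriented carrier.

    The patch is a smoothed Gaussian random field (unit variance unless
    degenerate) plus ``oriented_energy`` times a sinusoidal carrier at
    ~4 px/cycle along ``orientation`` (degrees, image convention:
    0 deg = horizontal wave vector), amplitude-modulated by a smooth
    positive envelope so the oriented component is spatially
    heterogeneous rather than a clean grating. ``isotropic_energy``
    adds orientation-free high-frequency grain (real parenchyma is
    never band-limited); the case-set generator gives *every* planted
    area the same isotropic base so that difficulty is carried by the
    oriented component specifically, not by total high-frequency power
    alone.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if size < 16:
        raise ValueError("size must be at least 16 pixels")
    if oriented_energy < 0:
        raise ValueError("oriented_energy must be >= 0")
    if isotropic_energy < 0:
        raise ValueError("isotropic_energy must be >= 0")
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.standard_normal((size, size)), smoothness,
                           mode="reflect")
    sd = base.std()
    if sd > 1e-8:  # guard: near-infinite smoothness flattens the field
        base = base / sd
    patch = base
    if isotropic_energy > 0:
        noise = rng.standard_normal((size, size))
        grain = noise - gaussian_filter(noise, 1.0, mode="reflect")
        patch = patch + isotropic_energy * grain / max(grain.std(), 1e-8)
    if oriented_energy > 0:
        theta = math.radians(orientation)
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        carrier = np.cos(2.0 * np.pi * (xx * math.cos(theta) +
                                        yy * math.sin(theta)) / 4.0)
        envelope = gaussian_filter(rng.standard_normal((size, size)), 6.0,
                                   mode="reflect")
        env_sd = envelope.std()
        if env_sd > 1e-8:
            envelope = np.abs(envelope / env_sd)
            envelope = envelope / max(envelope.mean(), 1e-8)
        else:
            envelope = np.ones_like(envelope)
        patch = patch + oriented_energy * carrier * envelope
    return patch



def _smooth_envelope(rng, size: int) -> np.ndarray:
    env = gaussian_filter(rng.standard_normal((size, size)), 6.0,
                          mode="reflect")
    sd = env.std()
    if sd < 1e-8:
        return np.ones((size, size))
    env = np.abs(env / sd)
    return env / max(env.mean(), 1e-8)


def _carrier(orientation_deg: float, size: int) -> np.ndarray:
    theta = math.radians(orientation_deg)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return np.cos(2.0 * np.pi * (xx * math.cos(theta) +
                                 yy * math.sin(theta)) / 4.0)


def area_texture(rng, size: int, effect: float, difficult: bool,
                 main_orientation: float, smoothness: float = 3.0,
                 coherence: float = 0.8,
                 amplitude_jitter: tuple = (0.8, 1.2)) -> np.ndarray:
    """Planted-area texture: difficulty = orientation coherence.

    Every area carries the same expected power in the ~4 px/cycle
    texture band, spread as envelope-modulated carriers over the six
    canonical orientations. Easy areas split that power evenly across
    orientations; difficult areas concentrate a ``coherence`` fraction
    of it in the cohort's main orientation (an architectural-
    distortion-like coherent structure). Direction-averaged texture
    statistics therefore overlap between the classes by construction,
    while orientation-selective responses (the Gabor bank, the oriented
    maximum-response filters) carry the class signal. ``effect`` scales
    the band's RMS amplitude; 0 makes the classes exchangeable.
    """
    base = gaussian_filter(rng.standard_normal((size, size)), smoothness,
                           mode="reflect")
    sd = base.std()
    if sd > 1e-8:
        base = base / sd
    if effect <= 0:
        return base
    total_var = (effect * rng.uniform(*amplitude_jitter)) ** 2
    patch = base
    for th in CANONICAL_ORIENTATIONS:
        if difficult:
            share = coherence if th == main_orientation \
                else (1.0 - coherence) / (len(CANONICAL_ORIENTATIONS) - 1)
        else:
            share = 1.0 / len(CANONICAL_ORIENTATIONS)
        amp = math.sqrt(total_var * share)
        patch = patch + amp * _carrier(th, size) * _smooth_envelope(rng, size)
    return patch


def breast_mask(image_size: tuple[int, int]) -> np.ndarray:
    """Half-ellipse support approximating the breast region.

    The chest wall is the left image edge; the ellipse is centred on it
    vertically with semi-axes 0.48*rows and 0.92*cols.
    """
    rows, cols = image_size
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    a = 0.48 * rows
    b = 0.92 * cols
    return ((yy - rows / 2.0) / a) ** 2 + (xx / b) ** 2 <= 1.0


def _hann2d(size: int) -> np.ndarray:
    w = np.hanning(size)
    return np.outer(w, w)


def _sample_positions(rng, mask, half, n, min_sep):
    """Rejection-sample n patch centres with the patch box inside the mask.

    If the requested separation cannot be met (small images), the
    separation is halved up to three times before giving up, so planted
    lesions are essentially never dropped.
    """
    rows, cols = mask.shape
    sep = float(min_sep)
    for _ in range(4):
        out = []
        for _ in range(4000):
            if len(out) >= n:
                break
            y = rng.integers(half, rows - half)
            x = rng.integers(half, cols - half)
            corners = [(y - half, x - half), (y - half, x + half - 1),
                       (y + half - 1, x - half), (y + half - 1, x + half - 1)]
            if not all(mask[cy, cx] for cy, cx in corners):
                continue
            if any((y - py) ** 2 + (x - px) ** 2 < sep ** 2 for py, px in out):
                continue
            out.append((int(y), int(x)))
        if len(out) >= n:
            return out
        sep /= 2.0
    return out


def generate_case_set(config: SyntheticConfig) -> SyntheticCaseSet:
    """Generate a full synthetic case set: images plus truth tables.

    Each case has CC and MLO views (single breast, side "L"). Cancer
    cases carry one lesion each, except the first cancer case which
    carries two when there are at least two cancer cases (mirroring a
    case mix with one more lesion than cancer cases). Planted normal
    areas and cancer areas carry an easy/difficult truth label; the
    difficult class gets oriented texture of amplitude
    ``config.difficulty_effect`` injected at the cohort orientation.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows, cols = cfg.image_size
    mask = breast_mask(cfg.image_size)
    half = cfg.patch_size // 2
    window = _hann2d(cfg.patch_size)
    if cfg.difficulty_orientation is None:
        cohort_theta = float(rng.choice(CANONICAL_ORIENTATIONS))
    else:
        cohort_theta = float(cfg.difficulty_orientation)

    subtype_names = [s for s, _ in LESION_SUBTYPES]
    subtype_w = np.array([w for _, w in LESION_SUBTYPES], dtype=float)
    subtype_w /= subtype_w.sum()

    images = {}
    lesion_rows = []
    area_rows = []
    area_uid = 0

    n_cases = cfg.n_normal_cases + cfg.n_cancer_cases
    for ci in range(n_cases):
        case_id = f"case{ci + 1:03d}"
        is_cancer = ci >= cfg.n_normal_cases
        n_lesions = 0
        if is_cancer:
            first_cancer = ci == cfg.n_normal_cases
            n_lesions = 2 if (first_cancer and cfg.n_cancer_cases >= 2) else 1
        # lesion difficulty/subtype is a case property shared by both views
        lesion_props = []
        for _ in range(n_lesions):
            lesion_props.append({
                "subtype": str(rng.choice(subtype_names, p=subtype_w)),
                "difficult": bool(rng.random() < cfg.difficult_fraction),
            })
        for view in VIEWS:
            img = 0.5 * gaussian_filter(rng.standard_normal((rows, cols)), 8.0,
                                        mode="reflect")
            img = img / max(img.std(), 1e-8) * 0.3 + 1.0
            img[~mask] = 0.0
            n_plant = cfg.areas_per_normal_view + n_lesions
            centres = _sample_positions(rng, mask, half, n_plant,
                                        min_sep=1.8 * cfg.patch_size)
            if len(centres) < n_plant:
                logger.warning("could only place %d of %d areas in %s/%s",
                               len(centres), n_plant, case_id, view)
            li = 0
            for k, (cy, cx) in enumerate(centres):
                kind = "cancer" if k < n_lesions else "normal"
                if kind == "cancer":
                    props = lesion_props[li]
                    li += 1
                    difficult = props["difficult"]
                else:
                    difficult = bool(rng.random() < cfg.difficult_fraction)
                energy = cfg.difficulty_effect if difficult else 0.0
                patch = area_texture(rng, cfg.patch_size,
                                     cfg.difficulty_effect, difficult,
                                     cohort_theta)
                sl = (slice(cy - half, cy + half), slice(cx - half, cx + half))
                img[sl] += 0.6 * window * patch
                if kind == "cancer":
                    radius_mm = 12.5
                    sigma_px = radius_mm / cfg.pixel_spacing / 3.0
                    yy, xx = np.mgrid[sl].astype(float)
                    blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                  / (2 * sigma_px ** 2))
                    img[sl] += 1.2 * blob
                    lesion_rows.append({
                        "case_id": case_id, "view": view, "side": "L",
                        "x_px": cx, "y_px": cy, "radius_mm": radius_mm,
                        "subtype": props["subtype"],
                    })
                share = 0.8 if difficult else 1.0 / len(CANONICAL_ORIENTATIONS)
                area_rows.append({
                    "area_uid": area_uid, "case_id": case_id, "view": view,
                    "side": "L", "x_px": cx, "y_px": cy,
                    "patch_size": cfg.patch_size, "kind": kind,
                    "difficulty": "difficult" if difficult else "easy",
                    "oriented_energy": cfg.difficulty_effect * math.sqrt(share),
                    "orientation_deg": cohort_theta,
                })
                area_uid += 1
            images[(case_id, view, "L")] = img
    lesions = pd.DataFrame(lesion_rows, columns=[
        "case_id", "view", "side", "x_px", "y_px", "radius_mm", "subtype"])
    areas = pd.DataFrame(area_rows, columns=[
        "area_uid", "case_id", "view", "side", "x_px", "y_px", "patch_size",
        "kind", "difficulty", "oriented_energy", "orientation_deg"])
    return SyntheticCaseSet(images=images, pixel_spacing=cfg.pixel_spacing,
                            lesion_truths=lesions, planted_area_truths=areas,
                            config=cfg)


@dataclass
class ReaderSimulation:
    """Annotations plus the reader-level ground truth behind them."""

    annotations: pd.DataFrame  # reader_id, case_id, view, side, x_px, y_px, rating
    reader_truth: pd.DataFrame  # reader_id, is_outlier
    response_truth: pd.DataFrame  # reader_id x area_uid Bernoulli outcomes


def reader_ids(n_readers: int) -> list[str]:
    return [f"R{i + 1:02d}" for i in range(n_readers)]


def false_response_rate(kind: str, difficult: bool, is_outlier: bool,
                        cfg: SyntheticConfig) -> float:
    """Per-draw false-response probability of one reader on one area."""
    if kind == "normal":
        p = cfg.base_fp_rate
        if difficult:
            p *= cfg.difficulty_fp_multiplier
        if is_outlier:
            p *= cfg.outlier_fp_multiplier
    else:
        p = cfg.base_fn_rate
        if difficult:
            p *= cfg.difficulty_fn_multiplier
    return min(p, 0.95)


def simulate_response_matrix(n_normal_areas: int, config: SyntheticConfig,
                             n_cancer_areas: int = 0):
    """Reader x area false-response draws without rendering any images.

    A lightweight path for studying the reader-clustering stage alone:
    area difficulty truths are drawn per ``difficult_fraction`` and the
    same per-reader rate model as :func:`simulate_readers` drives the
    Bernoulli responses. Returns ``(values, readers, outlier_ids,
    area_truths)`` where ``values`` is the |readers| x |areas| binary
    matrix.
    """
    cfg = config
    ss = np.random.SeedSequence([cfg.seed, 40487])
    rng = np.random.default_rng(ss)
    readers = reader_ids(cfg.n_readers)
    outliers = set(rng.choice(readers, size=cfg.n_outlier_readers,
                              replace=False).tolist())
    kinds = (["normal"] * n_normal_areas) + (["cancer"] * n_cancer_areas)
    difficult = rng.random(len(kinds)) < cfg.difficult_fraction
    values = np.zeros((len(readers), len(kinds)), dtype=int)
    for j, (kind, diff) in enumerate(zip(kinds, difficult)):
        for i, reader in enumerate(readers):
            p = false_response_rate(kind, bool(diff), reader in outliers, cfg)
            values[i, j] = int(rng.random() < p)
    truths = pd.DataFrame({"area_uid": np.arange(len(kinds)), "kind": kinds,
                           "difficulty": np.where(difficult, "difficult",
                                                  "easy")})
    return values, readers, sorted(outliers), truths


def simulate_readers(case_set: SyntheticCaseSet,
                     config: SyntheticConfig) -> ReaderSimulation:
    """Simulate a reader cohort marking the planted areas.

    For every reader x planted area a single Bernoulli draw decides the
    false response. On normal areas the false-positive rate is
    ``base_fp_rate`` scaled by ``difficulty_fp_multiplier`` for
    difficult areas and ``outlier_fp_multiplier`` for planted outlier
    readers. On cancer areas the miss (false-negative) rate is
    ``base_fn_rate`` scaled by ``difficulty_fn_multiplier``; outlier
    status does not alter miss rates (the planted outliers are
    over-callers, not under-callers). Positive marks get a rating drawn
    uniformly from {3,4,5} at the area centre plus Gaussian jitter;
    non-marking readers occasionally leave a rating<3 mark. At most one
    annotation per reader per planted area is emitted.
    """
    cfg = config
    if abs(case_set.pixel_spacing - cfg.pixel_spacing) > 1e-9:
        raise ValueError("case_set pixel spacing differs from config")
    ss = np.random.SeedSequence([cfg.seed, 20177])
    rng = np.random.default_rng(ss)
    readers = reader_ids(cfg.n_readers)
    outliers = set(rng.choice(readers, size=cfg.n_outlier_readers,
                              replace=False).tolist())
    rows, cols = cfg.image_size
    ann_rows = []
    resp_rows = []
    n_clipped = 0
    for _, area in case_set.planted_area_truths.iterrows():
        difficult = area["difficulty"] == "difficult"
        for reader in readers:
            p = false_response_rate(area["kind"], difficult,
                                    reader in outliers, cfg)
            false_response = bool(rng.random() < p)
            resp_rows.append({"reader_id": reader,
                              "area_uid": int(area["area_uid"]),
                              "false_response": int(false_response)})
            # a cancer area draws a *positive* mark when NOT missed;
            # a normal area draws one when falsely called
            marks_positive = (false_response if area["kind"] == "normal"
                              else not false_response)
            if marks_positive:
                rating = int(rng.integers(3, 6))
            elif rng.random() < cfg.negative_mark_rate:
                rating = int(rng.integers(1, 3))
            else:
                continue
            x = area["x_px"] + rng.normal(0.0, cfg.annotation_jitter_sd)
            y = area["y_px"] + rng.normal(0.0, cfg.annotation_jitter_sd)
            xc = float(np.clip(x, 0, cols - 1))
            yc = float(np.clip(y, 0, rows - 1))
            if xc != x or yc != y:
                n_clipped += 1
            ann_rows.append({"reader_id": reader, "case_id": area["case_id"],
                             "view": area["view"], "side": area["side"],
                             "x_px": xc, "y_px": yc, "rating": rating})
    if n_clipped:
        logger.warning("%d jittered marks clipped to image bounds", n_clipped)
    annotations = pd.DataFrame(ann_rows, columns=[
        "reader_id", "case_id", "view", "side", "x_px", "y_px", "rating"])
    truth = pd.DataFrame({"reader_id": readers,
                          "is_outlier": [r in outliers for r in readers]})
    responses = pd.DataFrame(resp_rows)
    return ReaderSimulation(annotations=annotations, reader_truth=truth,
                            response_truth=responses)


def generate_labelled_patches(n_easy: int, n_difficult: int, size: int = 64,
                              difficulty_effect: float = 2.0,
                              smoothness: float = 3.0,
                              orientation: Optional[float] = None,
                              seed: int = 0):
    """ROI-level shortcut: labelled texture patches without full views.

    Returns ``(patches, labels, truth)`` where ``labels`` is 0 for easy
    and 1 for difficult, and ``truth`` records the injected orientation.
    All difficult patches in one call share a single orientation (drawn
    from the canonical six when ``orientation`` is None), emulating a
    cohort whose difficult areas share a texture signature; see
    :func:`area_texture` for how difficulty is encoded as orientation
    coherence at matched band power.
    """
    rng = np.random.default_rng(seed)
    if orientation is None:
        orientation = float(rng.choice(CANONICAL_ORIENTATIONS))
    patches, labels, rows = [], [], []
    n_ori = len(CANONICAL_ORIENTATIONS)
    for i in range(n_easy + n_difficult):
        difficult = i >= n_easy
        # recorded truth: expected amplitude share at the main orientation
        share = 0.8 if difficult else 1.0 / n_ori
        patch = area_texture(rng, size, difficulty_effect, difficult,
                             orientation, smoothness)
        patches.append(patch)
        labels.append(int(difficult))
        rows.append({"patch": i, "difficulty":
                     "difficult" if difficult else "easy",
                     "oriented_energy": difficulty_effect * math.sqrt(share),
                     "orientation_deg": orientation})
    return patches, np.array(labels), pd.DataFrame(rows)
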