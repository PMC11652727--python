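"""The 201-feature radiomic bank.

Families and cardinalities (asserted at import time):

====================  =====
first_order              28
glcm                     88
glrlm                     6
glsm                      6
glds                     15
ngtdm                    15
sfm                       8
fractal                   1
laws                     18
gabor                     6
mr                        8
fourier                   2
total                   201
====================  =====

``extract_all`` concatenates the families in this fixed order and
guarantees a finite, 201-element named vector; degenerate-input
conditions are recorded as flags rather than NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._firstorder import FIRST_ORDER_NAMES, first_order
from ._matrices import (
    GLCM_FEATURE_NAMES, GLCMConfig, GLDS_STAT_NAMES, GLDS_WINDOWS,
    GLRLM_FEATURE_NAMES, GLSM_FEATURE_NAMES, NGTDM_RADII, NGTDM_STAT_NAMES,
    SFM_SPACINGS, SFM_STAT_NAMES, fractal_dimension, glcm_features,
    glcm_features_from_matrix, glcm_matrix, glds_features, glrlm_features,
    glsm_features, ngtdm_features, run_length_matrix, sfm_features,
)
from ._filters import (
    LAWS_MAP_NAMES, MR_FEATURE_NAMES, ORIENTATIONS_DEG, GaborBankConfig,
    RFSBank, build_rfs_bank, convolve_reflect, fourier_features,
    gabor_features, gabor_kernel_even, laws_features, mr8_features,
    mr8_response_maps,
)

__all__ = [
    "FeatureVector", "extract_all", "feature_names", "feature_families",
    "FAMILY_COUNTS", "first_order", "glcm_features", "glcm_matrix",
    "glcm_features_from_matrix", "glrlm_features", "run_length_matrix",
    "glsm_features", "glds_features", "ngtdm_features", "sfm_features",
    "fractal_dimension", "laws_features", "gabor_features",
    "gabor_kernel_even", "build_rfs_bank", "mr8_features",
    "mr8_response_maps", "fourier_features", "convolve_reflect",
    "GLCMConfig", "GaborBankConfig", "RFSBank", "ORIENTATIONS_DEG",
]

FAMILY_COUNTS = {
    "first_order": 28,
    "glcm": 88,
    "glrlm": 6,
    "glsm": 6,
    "glds": 15,
    "ngtdm": 15,
    "sfm": 8,
    "fractal": 1,
    "laws": 18,
    "gabor": 6,
    "mr": 8,
    "fourier": 2,
}
FAMILY_ORDER = list(FAMILY_COUNTS)
TOTAL_FEATURES = 201


def _expected_names() -> dict[str, list[str]]:
    cfg = GLCMConfig()
    gcfg = GaborBankConfig()
    names = {
        "first_order": [f"fo_{n}" for n in FIRST_ORDER_NAMES],
        "glcm": [f"glcm_d{d}_{n}" for d in cfg.offsets
                 for n in cfg.feature_names],
        "glrlm": [f"glrlm_{n}" for n in GLRLM_FEATURE_NAMES],
        "glsm": [f"glsm_{n}" for n in GLSM_FEATURE_NAMES],
        "glds": [f"glds_w{w}_{n}" for w in GLDS_WINDOWS
                 for n in GLDS_STAT_NAMES],
        "ngtdm": [f"ngtdm_r{r}_{n}" for r in NGTDM_RADII
                  for n in NGTDM_STAT_NAMES],
        "sfm": [f"sfm_l{s}_{n}" for s in SFM_SPACINGS
                for n in SFM_STAT_NAMES],
        "fractal": ["fractal_dimension"],
        "laws": [f"laws_{m}_{s}" for m in LAWS_MAP_NAMES
                 for s in ("mean", "sd")],
        "gabor": [f"gabor_l{gcfg.wavelength:g}_t{int(t)}"
                  for t in gcfg.orientations_deg],
        "mr": list(MR_FEATURE_NAMES),
        "fourier": ["fourier_low_fraction", "fourier_high_fraction"],
    }
    return names


_NAMES_BY_FAMILY = _expected_names()

# count-conservation assertions: 28 + 139 + 34 = 201
for _fam, _n in FAMILY_COUNTS.items():
    assert len(_NAMES_BY_FAMILY[_fam]) == _n, (_fam, len(_NAMES_BY_FAMILY[_fam]))
assert sum(FAMILY_COUNTS.values()) == TOTAL_FEATURES
assert (FAMILY_COUNTS["glcm"] + FAMILY_COUNTS["glrlm"] + FAMILY_COUNTS["glsm"]
        + FAMILY_COUNTS["glds"] + FAMILY_COUNTS["ngtdm"]
        + FAMILY_COUNTS["sfm"] + FAMILY_COUNTS["fractal"]) == 139
assert (FAMILY_COUNTS["laws"] + FAMILY_COUNTS["gabor"] + FAMILY_COUNTS["mr"]
        + FAMILY_COUNTS["fourier"]) == 34


def feature_names() -> list[str]:
    """The 201 stable feature names in extraction order."""
    out = []
    for fam in FAMILY_ORDER:
        out.extend(_NAMES_BY_FAMILY[fam])
    return out


def feature_families() -> pd.Series:
    """Map feature name -> family tag."""
    data = {}
    for fam in FAMILY_ORDER:
        for n in _NAMES_BY_FAMILY[fam]:
            data[n] = fam
    return pd.Series(data)


@dataclass
class FeatureVector:
    """Named 201-element radiomic description of one ROI."""

    values: pd.Series
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) != TOTAL_FEATURES:
            raise ValueError(f"feature vector has {len(self.values)} entries, "
                             f"expected {TOTAL_FEATURES}")
        if not np.isfinite(self.values.to_numpy()).all():
            bad = self.values.index[~np.isfinite(self.values.to_numpy())]
            raise ValueError(f"non-finite features: {list(bad)}")


def extract_all(roi: np.ndarray, qroi=None,
                glcm_config: GLCMConfig | None = None,
                gabor_config: GaborBankConfig | None = None,
                rfs_bank: RFSBank | None = None) -> FeatureVector:
    """Extract the full 201-feature vector from one ROI.

    ``roi`` is the prepared (normalized) real-valued crop; ``qroi`` its
    quantized counterpart (computed with the default 64-level scheme
    when omitted). Both must come from the same bounding box.
    """
    from ..prep import quantize

    roi = np.asarray(roi, dtype=float)
    if qroi is None:
        qroi = quantize(roi)
    flags: list[str] = []
    values: dict[str, float] = {}
    fo = first_order(roi, flags)
    for n, v in fo.items():
        values[f"fo_{n}"] = v
    values.update(glcm_features(qroi, glcm_config, flags))
    values.update(glrlm_features(qroi, flags))
    values.update(glsm_features(roi, flags))
    values.update(glds_features(roi, flags))
    values.update(ngtdm_features(qroi, flags))
    values.update(sfm_features(qroi, flags))
    values.update(fractal_dimension(roi, flags))
    values.update(laws_features(roi, flags))
    values.update(gabor_features(roi, gabor_config, flags))
    values.update(mr8_features(roi, rfs_bank, flags))
    values.update(fourier_features(roi, flags))
    ordered = pd.Series({n: values[n] for n in feature_names()})
    return FeatureVector(values=ordered, flags=flags)


def extract_table(rois, qrois=None, ids=None, **kwargs) -> pd.DataFrame:
    """Feature table: one row per ROI, 201 named columns."""
    bank = kwargs.pop("rfs_bank", None) or build_rfs_bank()
    rows = []
    for k, roi in enumerate(rois):
        q = qrois[k] if qrois is not None else None
        fv = extract_all(roi, q, rfs_bank=bank, **kwargs)
        rows.append(fv.values)
    index = ids if ids is not None else range(len(rows))
    return pd.DataFrame(rows, index=index)
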