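"""Physiological index maps: StO2, NIR-PI, TWI, OHI.

Each index is a ratio of mean absorbances over two wavelength windows,
mapped through a fixed scaling interval onto [0, 1].  The windows follow
the band-ratio convention used by perfusion-oriented HSI camera software:

==========  =================  =================  =======================
index       numerator (nm)     denominator (nm)   sensitive to
==========  =================  =================  =======================
StO2        570-590            740-780            oxyhemoglobin fraction
NIR-PI      825-925            655-735            deep (NIR) perfusion
OHI         530-590            785-825            total hemoglobin
TWI         955-980            880-900            water content
==========  =================  =================  =======================

Indices are computed from the *raw* reflectance cube (never the SNV-
normalized one: SNV destroys the absolute absorbance scale the ratios
need).  Exact clinical formulas are proprietary, so the windows and the
scaling intervals are configuration; the meaningful output is ordinal —
recovery of programmed physiological orderings — not absolute values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsi_io import AnnotationMask, CLASS_NAMES, HyperCube

__all__ = [
    "IndexBandConfig",
    "DEFAULT_INDEX_CONFIGS",
    "PhysioMaps",
    "RegionSummary",
    "reflectance_to_absorbance",
    "band_ratio_index",
    "index_from_spectrum",
    "compute_physio_maps",
    "summarize_regions",
]

logger = logging.getLogger(__name__)

INDEX_NAMES = ("StO2", "NIR-PI", "TWI", "OHI")


@dataclass(frozen=True)
class IndexBandConfig:
    """One band-ratio index definition.

    ``scaling = (lo, hi)`` maps the raw absorbance ratio r onto [0, 1] via
    clip((r - lo) / (hi - lo), 0, 1); ratios at or below ``lo`` sit at the
    scaling floor.
    """

    name: str
    numerator_band: tuple
    denominator_band: tuple
    scaling: tuple

    def __post_init__(self) -> None:
        for lo, hi in (self.numerator_band, self.denominator_band, self.scaling):
            if not lo < hi:
                raise ValueError(f"{self.name}: interval ({lo}, {hi}) must have lo < hi")


#: default index definitions; scaling intervals chosen so the absorber-free
#: scattering baseline sits at the floor while phantom physiology spans the
#: interior without saturating.
DEFAULT_INDEX_CONFIGS: dict[str, IndexBandConfig] = {
    "StO2": IndexBandConfig("StO2", (570.0, 590.0), (740.0, 780.0), (0.5, 6.5)),
    "NIR-PI": IndexBandConfig("NIR-PI", (825.0, 925.0), (655.0, 735.0), (1.75, 4.0)),
    "OHI": IndexBandConfig("OHI", (530.0, 590.0), (785.0, 825.0), (0.25, 9.5)),
    "TWI": IndexBandConfig("TWI", (955.0, 980.0), (880.0, 900.0), (1.15, 3.2)),
}


def reflectance_to_absorbance(reflectance: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """A = -log10(max(R, floor)); the floor guard keeps zeros finite."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    r = np.asarray(reflectance, dtype=np.float64)
    return -np.log10(np.maximum(r, floor))


def _band_mean(values: np.ndarray, wavelengths: np.ndarray, band: tuple) -> np.ndarray:
    lo, hi = band
    sel = (wavelengths >= lo) & (wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    return values[..., sel].mean(axis=-1)


def band_ratio_index(absorbance: np.ndarray, wavelengths: np.ndarray,
                     config: IndexBandConfig,
                     denom_tolerance: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel scaled band-ratio index and its validity mask.

    Pixels whose denominator-band mean absorbance falls below
    ``denom_tolerance`` (essentially absorbance-free, e.g. specular or
    masked-out pixels) are flagged invalid and set to 0.
    """
    num = _band_mean(absorbance, wavelengths, config.numerator_band)
    den = _band_mean(absorbance, wavelengths, config.denominator_band)
    valid = den >= denom_tolerance
    ratio = np.where(valid, num / np.where(valid, den, 1.0), 0.0)
    lo, hi = config.scaling
    index = np.clip((ratio - lo) / (hi - lo), 0.0, 1.0)
    return np.where(valid, index, 0.0), valid


def index_from_spectrum(spectrum: np.ndarray, wavelengths: np.ndarray,
                        name: str, floor: float = 1e-4) -> float:
    """Convenience: one index value from a single reflectance spectrum."""
    absorb = reflectance_to_absorbance(spectrum, floor)
    value, valid = band_ratio_index(absorb[None, :], np.asarray(wavelengths),
                                    DEFAULT_INDEX_CONFIGS[name])
    return float(value[0])


@dataclass
class PhysioMaps:
    """The four index maps plus a joint validity mask."""

    maps: dict           # name -> H x W float map in [0, 1]
    valid: np.ndarray    # H x W bool

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def compute_physio_maps(cube: HyperCube,
                        configs: dict | None = None,
                        floor: float = 1e-4) -> PhysioMaps:
    """Compute all four index maps from a raw (non-SNV) reflectance cube."""
    configs = configs or DEFAULT_INDEX_CONFIGS
    wl = cube.wavelengths
    for cfg in configs.values():
        for lo, hi in (cfg.numerator_band, cfg.denominator_band):
            if lo < wl[0] or hi > wl[-1]:
                if not ((wl >= lo) & (wl <= hi)).any():
                    raise ValueError(
                        f"{cfg.name}: window [{lo}, {hi}] nm outside cube range "
                        f"[{wl[0]}, {wl[-1]}]")
    absorb = reflectance_to_absorbance(cube.reflectance, floor)
    maps: dict[str, np.ndarray] = {}
    valid = np.ones(cube.shape[:2], dtype=bool)
    for name, cfg in configs.items():
        maps[name], v = band_ratio_index(absorb, wl, cfg)
        valid &= v
    return PhysioMaps(maps, valid)


@dataclass
class RegionSummary:
    """Mean index values over one annotated region of one patient."""

    patient_id: str
    tissue_class: str
    tumor_stage: str
    means: dict  # index name -> mean over valid region pixels
    n_pixels: int


def summarize_regions(maps: PhysioMaps, mask: AnnotationMask,
                      patient_id: str = "", tumor_stage: str = "") -> list:
    """One RegionSummary per tissue class present in the mask.

    Only valid pixels enter the means; an annotated region with no valid
    pixel is skipped with a warning (it would otherwise poison the group
    statistics with undefined values).
    """
    summaries = []
    for label, cls_name in enumerate(CLASS_NAMES, start=1):
        region = (mask.labels == label) & maps.valid
        n = int(region.sum())
        if (mask.labels == label).any() and n == 0:
            logger.warning("patient %s: region %s has no valid pixels; skipped",
                           patient_id, cls_name)
            continue
        if n == 0:
            continue
        means = {name: float(m[region].mean()) for name, m in maps.maps.items()}
        summaries.append(RegionSummary(patient_id, cls_name, tumor_stage, means, n))
    return summaries


def summaries_to_frame(summaries: list) -> pd.DataFrame:
    """Flatten RegionSummary objects into a tidy DataFrame (one row per
    patient x tissue class, one column per index)."""
    rows = []
    for s in summaries:
        row = {"patient_id": s.patient_id, "tissue_class": s.tissue_class,
               "tumor_stage": s.tumor_stage, "n_pixels": s.n_pixels}
        row.update(s.means)
        rows.append(row)
    return pd.DataFrame(rows)
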