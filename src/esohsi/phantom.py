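"""Annotated hyperspectral phantom cohorts.

Synthetic esophagogastric specimens are rendered from a Beer-Lambert-style
reflectance model R(lambda) = S(lambda) * 10**(-A(lambda)), where the
absorbance A combines oxy-/deoxy-hemoglobin and water through smooth
Gaussian extinction templates and S is a power-law scattering baseline.
The templates place the hemoglobin structure in the 500-600 nm and
750-800 nm oxygenation regions and the dominant water band near 970 nm,
which is what the physiological indices and the classifier key on.

Spatial layout: esophageal mucosa on the left, gastric mucosa on the
right, a cancer ellipse straddling the junction (~7.5 % of pixels by
default, matching the order-of-magnitude class imbalance of surgical
specimen annotations).  Tumor stage is a per-patient label whose only
programmed physiological effect is a water-content increment in T3/T4
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hsi_io import (
    AnnotationMask,
    HyperCube,
    LABEL_CANCER,
    LABEL_ESOPHAGUS,
    LABEL_STOMACH,
)

__all__ = [
    "ChromophoreParams",
    "PhantomLayout",
    "PhantomSpec",
    "PhantomPatient",
    "PhantomCohort",
    "extinction_oxy",
    "extinction_deoxy",
    "extinction_water",
    "reflectance_template",
    "generate_phantom",
    "draw_patient_params",
    "generate_cohort",
    "DEFAULT_CLASS_PARAMS",
]


def _gauss(wl: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)


def extinction_oxy(wl: np.ndarray) -> np.ndarray:
    """Synthetic oxyhemoglobin extinction: twin Q-bands at 542/577 nm and a
    broad near-infrared bump around 900 nm."""
    wl = np.asarray(wl, dtype=np.float64)
    # the NIR shoulder is kept small so it does not swamp the 970 nm water
    # band in the short-wave-infrared windows
    return (_gauss(wl, 542.0, 12.0, 1.0)
            + _gauss(wl, 577.0, 10.0, 1.1)
            + _gauss(wl, 900.0, 40.0, 0.10))


def extinction_deoxy(wl: np.ndarray) -> np.ndarray:
    """Synthetic deoxyhemoglobin extinction: a single broad band at 555 nm
    and the characteristic 760 nm bump."""
    wl = np.asarray(wl, dtype=np.float64)
    return (_gauss(wl, 555.0, 20.0, 1.2)
            + _gauss(wl, 760.0, 22.0, 0.45))


def extinction_water(wl: np.ndarray) -> np.ndarray:
    """Synthetic water extinction: dominant 970 nm band, minor 740 nm band."""
    wl = np.asarray(wl, dtype=np.float64)
    return (_gauss(wl, 970.0, 35.0, 1.0)
            + _gauss(wl, 740.0, 25.0, 0.12))


@dataclass(frozen=True)
class ChromophoreParams:
    """Per-tissue chromophore and scattering parameters (arbitrary units).

    oxy_hb_fraction : hemoglobin oxygen saturation, in [0, 1]
    total_hb        : total hemoglobin concentration, >= 0
    water_fraction  : water content, in [0, 1]
    scatter_amplitude, scatter_slope : power-law scattering baseline
        S(lambda) = amplitude * (lambda/500)**(-slope)
    """

    oxy_hb_fraction: float
    total_hb: float
    water_fraction: float
    scatter_amplitude: float = 1.0
    scatter_slope: float = 0.7

    def __post_init__(self) -> None:
        vals = (self.oxy_hb_fraction, self.total_hb, self.water_fraction,
                self.scatter_amplitude, self.scatter_slope)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("chromophore parameters must be finite")
        if not 0.0 <= self.oxy_hb_fraction <= 1.0:
            raise ValueError("oxy_hb_fraction must be in [0,1]")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must be in [0,1]")
        if self.total_hb < 0 or self.scatter_amplitude < 0:
            raise ValueError("total_hb and scatter_amplitude must be >= 0")


#: default class parameters: cancer is blood-richer, wetter and more
#: oxygenated than the healthy mucosa, mirroring the perfusion physiology
#: of esophagogastric carcinomas.
DEFAULT_CLASS_PARAMS: dict[int, ChromophoreParams] = {
    LABEL_ESOPHAGUS: ChromophoreParams(0.55, 0.80, 0.35, 0.95, 0.75),
    LABEL_STOMACH: ChromophoreParams(0.65, 1.20, 0.45, 1.00, 0.85),
    LABEL_CANCER: ChromophoreParams(0.85, 1.60, 0.70, 0.95, 0.70),
}


def reflectance_template(wavelengths: np.ndarray, params: ChromophoreParams) -> np.ndarray:
    """Noise-free tissue reflectance spectrum for one parameter set.

    R(lambda) = S(lambda) * 10**(-A(lambda)) with
    A = total_hb * [f*eps_oxy + (1-f)*eps_deoxy] + water_fraction * eps_water.
    """
    wl = np.asarray(wavelengths, dtype=np.float64)
    if wl.size and (wl.min() < 400.0 or wl.max() > 1100.0):
        raise ValueError("wavelengths must lie within [400, 1100] nm")
    absorb = (params.total_hb
              * (params.oxy_hb_fraction * extinction_oxy(wl)
                 + (1.0 - params.oxy_hb_fraction) * extinction_deoxy(wl))
              + params.water_fraction * extinction_water(wl))
    scatter = params.scatter_amplitude * (wl / 500.0) ** (-params.scatter_slope)
    return scatter * 10.0 ** (-absorb)


@dataclass(frozen=True)
class PhantomLayout:
    """Default 3-region specimen geometry on the unit square.

    Pixels left of ``split`` are esophagus, the rest stomach, and an axis-
    aligned ellipse centered at (cx, cy) with relative semi-axes (rx, ry)
    overwrites both as cancer.  Defaults give ~7.5 % cancer pixels.
    """

    split: float = 0.42
    cx: float = 0.5
    cy: float = 0.5
    rx: float = 0.155
    ry: float = 0.155

    def render(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        # pixel centers on the unit square
        u = (xx + 0.5) / width
        v = (yy + 0.5) / height
        labels = np.where(u < self.split, LABEL_ESOPHAGUS, LABEL_STOMACH).astype(np.uint8)
        inside = ((u - self.cx) / self.rx) ** 2 + ((v - self.cy) / self.ry) ** 2 <= 1.0
        labels[inside] = LABEL_CANCER
        return labels


def default_wavelengths(n_bands: int = 100, lo: float = 500.0, hi: float = 1000.0) -> np.ndarray:
    return np.linspace(lo, hi, n_bands)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render one synthetic annotated specimen."""

    image_height: int = 64
    image_width: int = 64
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    class_params: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    layout: PhantomLayout = field(default_factory=PhantomLayout)
    pixel_jitter_sd: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        object.__setattr__(self, "wavelengths", wl)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pixel_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise SDs must be >= 0")


def generate_phantom(spec: PhantomSpec) -> tuple[HyperCube, AnnotationMask]:
    """Render one annotated phantom cube.

    Per-pixel physiology is jittered multiplicatively (log-normal on
    total_hb and water_fraction, clipped to valid ranges) to produce the
    large within-class spectral variance real mucosa shows; additive
    Gaussian reflectance noise is applied on top and the result clipped
    to >= 0.  Identical (spec, seed) yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    labels = spec.layout.render(h, w)
    present = np.unique(labels)
    missing = [int(c) for c in present if c != 0 and c not in spec.class_params]
    if missing:
        raise ValueError(f"layout produces classes without parameters: {missing}")

    cube = np.zeros((h, w, spec.wavelengths.size), dtype=np.float64)
    for cls in present:
        if cls == 0:
            continue
        base = spec.class_params[int(cls)]
        idx = np.nonzero(labels == cls)
        n = idx[0].size
        if spec.pixel_jitter_sd > 0:
            hb = base.total_hb * rng.lognormal(0.0, spec.pixel_jitter_sd, n)
            water = np.clip(base.water_fraction * rng.lognormal(0.0, spec.pixel_jitter_sd, n),
                            0.0, 1.0)
        else:
            hb = np.full(n, base.total_hb)
            water = np.full(n, base.water_fraction)
        eps_hb = (base.oxy_hb_fraction * extinction_oxy(spec.wavelengths)
                  + (1.0 - base.oxy_hb_fraction) * extinction_deoxy(spec.wavelengths))
        absorb = hb[:, None] * eps_hb[None, :] + water[:, None] * extinction_water(spec.wavelengths)[None, :]
        scatter = base.scatter_amplitude * (spec.wavelengths / 500.0) ** (-base.scatter_slope)
        cube[idx] = scatter[None, :] * 10.0 ** (-absorb)

    if spec.noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.noise_sd, cube.shape)
    np.clip(cube, 0.0, None, out=cube)
    return HyperCube(cube, spec.wavelengths), AnnotationMask(labels)


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class PhantomPatient:
    patient_id: str
    cube: HyperCube
    mask: AnnotationMask
    class_params: dict
    tumor_stage: str  # one of T1..T4


@dataclass
class PhantomCohort:
    patients: list

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient ids must be unique")

    @property
    def patient_ids(self) -> list:
        return [p.patient_id for p in self.patients]

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)


def draw_patient_params(base: ChromophoreParams, rng: np.random.Generator,
                        patient_jitter_sd: float = 0.10,
                        water_increment: float = 0.0) -> ChromophoreParams:
    """One patient-level draw around a class's base physiology.

    total_hb, water_fraction and scatter_amplitude receive independent
    log-normal multipliers; ``water_increment`` (stage effect) is added to
    water_fraction after the draw, then clipped to [0, 1].
    """
    hb = base.total_hb * rng.lognormal(0.0, patient_jitter_sd)
    water = base.water_fraction * rng.lognormal(0.0, patient_jitter_sd) + water_increment
    amp = base.scatter_amplitude * rng.lognormal(0.0, patient_jitter_sd)
    return replace(base, total_hb=hb, water_fraction=float(np.clip(water, 0.0, 1.0)),
                   scatter_amplitude=amp)


def _default_stage_assignment(i: int, n: int) -> str:
    # alternate early/advanced so both groups are populated at any n
    return ("T1", "T3", "T2", "T4")[i % 4]


def generate_cohort(n_patients: int,
                    base_spec: PhantomSpec | None = None,
                    stage_assignment=None,
                    seed: int = 0,
                    patient_jitter_sd: float = 0.10,
                    stage_water_increment: float = 0.15) -> PhantomCohort:
    """Generate a cohort of annotated phantom patients.

    Each patient gets independent parameter draws around ``base_spec``'s
    class physiology.  Patients staged T3/T4 receive ``stage_water_increment``
    extra water fraction in every tissue class (cancer and healthy alike),
    emulating the edema of advanced tumors.  Fully reproducible under
    ``seed``.
    """
    if n_patients < 5:
        raise ValueError("cohort needs >= 5 patients (LOPO: 1 test + 3 validation + training)")
    base_spec = base_spec or PhantomSpec()
    stage_assignment = stage_assignment or _default_stage_assignment
    rng = np.random.default_rng(seed)

    patients = []
    for i in range(n_patients):
        stage = stage_assignment(i, n_patients)
        if stage not in ("T1", "T2", "T3", "T4"):
            raise ValueError(f"invalid tumor stage {stage!r}")
        incr = stage_water_increment if stage in ("T3", "T4") else 0.0
        params = {cls: draw_patient_params(p, rng, patient_jitter_sd, water_increment=incr)
                  for cls, p in base_spec.class_params.items()}
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec_i = replace(base_spec, class_params=params, seed=sub_seed)
        cube, mask = generate_phantom(spec_i)
        pid = f"P{i:03d}"
        cube.patient_id = pid
        patients.append(PhantomPatient(pid, cube, mask, params, stage))
    return PhantomCohort(patients)


def write_cohort(cohort: PhantomCohort, outdir) -> "pandas.DataFrame":
    """Persist a cohort as ENVI cubes + PNG masks + a CSV manifest."""
    import pandas as pd
    from pathlib import Path

    from .hsi_io import write_cube, write_mask

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        cube_path = write_cube(p.cube, outdir / f"{p.patient_id}.raw")
        mask_path = write_mask(p.mask, outdir / f"{p.patient_id}_mask.png")
        rows.append({"patient_id": p.patient_id, "cube": cube_path.name,
                     "mask": mask_path.name, "stage": p.tumor_stage})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
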