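"""Synthetic FTIR tissue-microarray cohorts with known ground truth.

Real FTIR TMA datasets are rarely shareable, so every pipeline stage here is
exercised on simulated cores: a circular tissue disc on a substrate background,
filled with contiguous blobs of 2-4 tissue sub-types (epithelium, stroma,
lumen). Each sub-type has a Gaussian-band absorbance signature over the
fingerprint region (amide I ~1655, amide II ~1545, CH bending ~1450, amide
III/phosphate ~1240, C-O/phosphate ~1080 cm⁻¹), on top of which sit a smooth
Mie-like baseline (random low-order slope + slow sinusoid) and i.i.d. Gaussian
noise. A binary patient outcome modulates one designated band: for label-1
patients the amplitude of the effect band in epithelium pixels is multiplied by
(1 + effect_size), so effect_size = 0 yields an exact null in which labels are
independent of the cubes.

The generator is deterministic in (config, seed) and returns its ground truth
(region map, band parameters) so recovery tests have an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import (
    CohortTable,
    HyperspectralImage,
    ValidationError,
    WavenumberAxis,
    write_cohort,
    write_image,
)

import pandas as pd

__all__ = [
    "SynthConfig",
    "Band",
    "BandLibrary",
    "default_band_library",
    "generate_core",
    "generate_cohort",
    "reference_spectrum",
    "TISSUE_TYPES",
]

TISSUE_TYPES = ("epithelium", "stroma", "lumen")
SUBSTRATE = "substrate"


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: A·exp(-(ν-center)²/(2·width²))."""

    center: float  # cm^-1
    width: float  # cm^-1 (Gaussian sigma)
    amplitude: float  # AU

    def profile(self, wn: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wn - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class BandLibrary:
    """Band sets per tissue sub-type plus the substrate background.

    ``effect_band`` names the (tissue, band index) whose amplitude carries the
    label-dependent effect; by default the 1080 cm⁻¹ phosphate band of
    epithelium, a plausible proliferation-linked nucleic-acid marker.
    """

    bands: dict[str, tuple[Band, ...]]
    effect_tissue: str = "epithelium"
    effect_band_index: int = 4  # the 1080 cm^-1 band in the default library

    def __post_init__(self) -> None:
        for tissue, bb in self.bands.items():
            for b in bb:
                if b.amplitude < 0:
                    raise ValidationError(f"{tissue}: band amplitude must be >= 0")

    def validate_range(self, lo: float, hi: float) -> None:
        for tissue, bb in self.bands.items():
            if tissue == SUBSTRATE:
                continue
            for b in bb:
                if not (lo <= b.center <= hi):
                    raise ValidationError(
                        f"{tissue}: band center {b.center} outside [{lo}, {hi}]"
                    )

    def spectrum(self, tissue: str, wn: np.ndarray, effect_size: float = 0.0,
                 labelled: bool = False) -> np.ndarray:
        """Noise-free spectrum of a tissue type, with the label effect applied."""
        out = np.zeros_like(wn, dtype=np.float64)
        for i, b in enumerate(self.bands[tissue]):
            gain = 1.0
            if (labelled and tissue == self.effect_tissue
                    and i == self.effect_band_index):
                gain = 1.0 + effect_size
            out += gain * b.profile(wn)
        return out

    @property
    def effect_band(self) -> Band:
        return self.bands[self.effect_tissue][self.effect_band_index]


def default_band_library() -> BandLibrary:
    """Fingerprint-region band sets for the three tissue sub-types.

    Amplitudes follow the usual ordering of protein-rich epithelium over
    collagenous stroma over sparse lumen; the substrate has near-zero amide
    bands so a k=2 clustering separates it cleanly.
    """
    bands = {
        "epithelium": (
            Band(1655.0, 25.0, 0.80),  # amide I
            Band(1545.0, 22.0, 0.50),  # amide II
            Band(1450.0, 15.0, 0.20),  # CH2/CH3 bending
            Band(1240.0, 20.0, 0.22),  # amide III / asym PO2-
            Band(1080.0, 18.0, 0.30),  # sym PO2- / C-O (effect band)
        ),
        "stroma": (
            Band(1655.0, 27.0, 0.55),
            Band(1545.0, 24.0, 0.33),
            Band(1450.0, 15.0, 0.16),
            Band(1338.0, 18.0, 0.14),  # collagen CH2 wag
            Band(1205.0, 16.0, 0.10),
        ),
        "lumen": (
            Band(1655.0, 30.0, 0.35),
            Band(1545.0, 26.0, 0.20),
            Band(1100.0, 35.0, 0.22),
        ),
        SUBSTRATE: (
            Band(1120.0, 60.0, 0.03),
            Band(1650.0, 40.0, 0.005),
        ),
    }
    return BandLibrary(bands=bands)


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the simulated cohort.

    Defaults follow the real acquisition geometry where affordable: 106
    channels over 1000-1800 cm⁻¹ and 1-2 cores per patient; spatial size
    defaults to a 64×64 desk-scale core (full 256×256 available by config).
    ``recurrence_rate`` defaults to 29/139 ≈ 0.21, the recurrence fraction of
    the cohort this pipeline is modelled on.
    """

    n_patients: int = 20
    images_per_patient: int = 1
    recurrence_rate: float = 29 / 139
    rows: int = 64
    cols: int = 64
    n_channels: int = 106
    wn_range: tuple[float, float] = (1000.0, 1800.0)
    effect_size: float = 0.0
    noise_sd: float = 0.02
    baseline_amplitude: float = 0.1
    n_tissue_types: int = 3
    blob_smoothness: float = 6.0  # Gaussian-field sigma in pixels
    core_radius_frac: float = 0.42
    seed: int = 0
    bands: BandLibrary = field(default_factory=default_band_library)

    def __post_init__(self) -> None:
        if self.n_channels < 8:
            raise ValidationError("n_channels must be >= 8")
        if self.rows < 16 or self.cols < 16:
            raise ValidationError("rows and cols must be >= 16")
        if not (0.0 < self.recurrence_rate < 1.0):
            raise ValidationError("recurrence_rate must be in (0, 1)")
        if self.images_per_patient not in (1, 2):
            raise ValidationError("images_per_patient must be 1 or 2")
        if self.noise_sd < 0 or self.baseline_amplitude < 0 or self.effect_size < 0:
            raise ValidationError("noise_sd, baseline_amplitude, effect_size must be >= 0")
        if not (2 <= self.n_tissue_types <= 4):
            raise ValidationError("n_tissue_types must be in [2, 4]")
        self.bands.validate_range(*self.wn_range)

    @property
    def axis(self) -> WavenumberAxis:
        return WavenumberAxis(np.linspace(*self.wn_range, self.n_channels))


def _core_disc(rows: int, cols: int, radius_frac: float) -> np.ndarray:
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.ogrid[:rows, :cols]
    radius = radius_frac * min(rows, cols)
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def _tissue_regions(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous sub-type blobs: quantile-thresholded smoothed random field.

    Returns an int map: -1 substrate, 0..n_tissue_types-1 tissue sub-types.
    """
    field_ = gaussian_filter(rng.standard_normal((cfg.rows, cfg.cols)),
                             sigma=cfg.blob_smoothness)
    disc = _core_disc(cfg.rows, cfg.cols, cfg.core_radius_frac)
    regions = np.full((cfg.rows, cfg.cols), -1, dtype=np.int64)
    inside = field_[disc]
    # equal-mass quantile cuts -> every sub-type present
    qs = np.quantile(inside, np.linspace(0, 1, cfg.n_tissue_types + 1)[1:-1])
    regions[disc] = np.searchsorted(qs, inside, side="right")
    return regions


def generate_core(
    cfg: SynthConfig, patient_label: int, rng: np.random.Generator,
    image_id: str = "core", patient_id: str = "p0",
) -> tuple[HyperspectralImage, np.ndarray]:
    """Simulate one TMA core; returns (image, ground-truth region map).

    Region map codes: -1 substrate, 0 epithelium, 1 stroma, 2 lumen (... in the
    order of :data:`TISSUE_TYPES`). The mask of the returned image equals the
    constructed core disc exactly.
    """
    if patient_label not in (0, 1):
        raise ValidationError("patient_label must be 0 or 1")
    wn = cfg.axis.values
    regions = _tissue_regions(cfg, rng)
    cube = np.empty((cfg.rows, cfg.cols, cfg.n_channels), dtype=np.float64)

    pure = {}
    for t_idx, tissue in enumerate(TISSUE_TYPES[: cfg.n_tissue_types]):
        pure[t_idx] = cfg.bands.spectrum(
            tissue, wn, effect_size=cfg.effect_size, labelled=patient_label == 1
        )
    substrate = cfg.bands.spectrum(SUBSTRATE, wn)

    cube[regions == -1] = substrate
    for t_idx, spec in pure.items():
        cube[regions == t_idx] = spec

    if cfg.baseline_amplitude > 0:
        # smooth Mie-like confound: per-pixel slope + slow half-period cosines.
        # The family is low-order by construction so a correction with a small
        # polynomial + cosine basis can absorb it exactly.
        u = (wn - wn[0]) / (wn[-1] - wn[0])
        n_pix = cfg.rows * cfg.cols
        slope = rng.uniform(-1.0, 1.0, size=(n_pix, 1))
        harm = rng.uniform(-1.0, 1.0, size=(n_pix, 3))
        cosines = np.stack([np.cos(np.pi * j * u) for j in (1, 2, 3)])  # (3, channels)
        base = slope * (u[None, :] - 0.5) + harm @ cosines
        cube += cfg.baseline_amplitude * base.reshape(cfg.rows, cfg.cols, -1)

    if cfg.noise_sd > 0:
        cube += rng.normal(0.0, cfg.noise_sd, size=cube.shape)

    img = HyperspectralImage(
        cube=cube, axis=cfg.axis, mask=regions >= 0,
        image_id=image_id, patient_id=patient_id,
    )
    return img, regions


def generate_cohort(
    cfg: SynthConfig, out_dir=None,
) -> tuple[CohortTable, list[HyperspectralImage], dict]:
    """Simulate a patient cohort of TMA cores with known ground truth.

    Exactly ⌈n_patients · recurrence_rate⌉ patients are labelled 1; all images
    of a patient share its label. When ``out_dir`` is given, images are written
    as HDF5 plus a ``cohort.csv`` via :mod:`chemimage.core_io`.

    Returns (cohort, images, manifest); the manifest records the generator
    parameters and per-image ground-truth region maps.
    """
    n_pos = math.ceil(cfg.n_patients * cfg.recurrence_rate)
    if n_pos == 0 or n_pos == cfg.n_patients:
        raise ValidationError(
            f"recurrence_rate {cfg.recurrence_rate} leaves an empty class "
            f"for n_patients={cfg.n_patients}"
        )
    rng = np.random.default_rng(cfg.seed)
    labels = np.array([1] * n_pos + [0] * (cfg.n_patients - n_pos))
    rng.shuffle(labels)

    rows, images = [], []
    manifest: dict = {
        "config": {
            "n_patients": cfg.n_patients,
            "images_per_patient": cfg.images_per_patient,
            "recurrence_rate": cfg.recurrence_rate,
            "rows": cfg.rows, "cols": cfg.cols, "n_channels": cfg.n_channels,
            "wn_range": list(cfg.wn_range),
            "effect_size": cfg.effect_size,
            "noise_sd": cfg.noise_sd,
            "baseline_amplitude": cfg.baseline_amplitude,
            "seed": cfg.seed,
            "effect_tissue": cfg.bands.effect_tissue,
            "effect_band_center": cfg.bands.effect_band.center,
        },
        "regions": {},
        "labels": {},
    }
    for i, label in enumerate(labels):
        pid = f"patient{i:04d}"
        manifest["labels"][pid] = int(label)
        for j in range(cfg.images_per_patient):
            iid = f"{pid}_core{j}"
            img, regions = generate_core(cfg, int(label), rng, image_id=iid, patient_id=pid)
            images.append(img)
            manifest["regions"][iid] = regions
            rows.append({"patient_id": pid, "label": int(label), "image_id": iid})

    df = pd.DataFrame(rows)
    cohort = CohortTable(
        patients=df[["patient_id", "label"]].drop_duplicates().reset_index(drop=True),
        image_map=df[["image_id", "patient_id"]].reset_index(drop=True),
    )
    if out_dir is not None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img in images:
            write_image(img, out / f"{img.image_id}.h5")
        write_cohort(cohort, out / "cohort.csv")
        serializable = dict(manifest)
        serializable["regions"] = {k: v.tolist() for k, v in manifest["regions"].items()}
        (out / "manifest.json").write_text(json.dumps(serializable))
    return cohort, images, manifest


def reference_spectrum(axis: WavenumberAxis) -> np.ndarray:
    """Synthetic stand-in for an extracellular-matrix reference spectrum.

    A sum of broad bands loosely shaped like a protein-rich gel matrix; used as
    the default EMSC reference when no measured reference file is supplied.
    (A stand-in: the real reference is a measured Matrigel spectrum that is not
    distributable with this package.)
    """
    wn = axis.values
    bands = (
        Band(1650.0, 35.0, 1.00),
        Band(1550.0, 30.0, 0.60),
        Band(1450.0, 25.0, 0.25),
        Band(1240.0, 30.0, 0.20),
        Band(1080.0, 30.0, 0.25),
    )
    return np.sum([b.profile(wn) for b in bands], axis=0)
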