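"""Domain types and HDF5/CSV input-output for FTIR chemical images.

The central object is :class:`HyperspectralImage`: a dense cube of absorbance
spectra (rows × cols × wavenumber channels) with an explicit wavenumber axis in
cm⁻¹ and a boolean tissue mask. Images are bound to patients through a
:class:`CohortTable` read from a plain CSV, which is the unit of train/test
splitting throughout the pipeline.

File layout (HDF5, one file per image)::

    /cube        float32, rows × cols × channels
    /wavenumbers float64, channels
    /mask        uint8,   rows × cols
    attrs: image_id, patient_id

Cohort CSV: header ``patient_id,label,image_id``, one row per image.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "WavenumberAxis",
    "HyperspectralImage",
    "CohortTable",
    "RunConfig",
    "read_image",
    "write_image",
    "read_cohort",
    "write_cohort",
    "get_logger",
    "stage_timer",
]

_LOG = logging.getLogger("chemimage")


class FormatError(ValueError):
    """A file or container violates the expected on-disk layout."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


def get_logger(verbose: bool = False) -> logging.Logger:
    """Structured stderr logger shared by all pipeline stages."""
    if not _LOG.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        _LOG.addHandler(h)
    _LOG.setLevel(logging.DEBUG if verbose else logging.INFO)
    return _LOG


@contextmanager
def stage_timer(stage: str):
    """Log wall-clock time of a pipeline stage."""
    t0 = time.perf_counter()
    _LOG.info("stage %s: start", stage)
    try:
        yield
    finally:
        _LOG.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered spectral axis in cm⁻¹ (stored ascending)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("wavenumbers: need a 1-D axis of length >= 2")
        if not np.all(np.diff(v) > 0):
            raise ValidationError("wavenumbers: axis must be strictly increasing")
        if v[0] < 600.0 or v[-1] > 4000.0:
            raise ValidationError(
                f"wavenumbers: values outside the mid-IR range [600, 4000] cm^-1 "
                f"(got [{v[0]:g}, {v[-1]:g}])"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean channel selector for lo <= wavenumber <= hi."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass
class HyperspectralImage:
    """Absorbance cube with wavenumber axis and tissue mask.

    ``cube`` is rows × cols × channels (absorbance, AU); ``mask`` is True on
    tissue pixels. Spatial coordinates are 0-based (row, col), row-major.
    """

    cube: np.ndarray
    axis: WavenumberAxis
    mask: np.ndarray
    image_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.cube.ndim != 3:
            raise ValidationError("cube: expected rows x cols x channels")
        if self.cube.shape[2] != len(self.axis):
            raise ValidationError(
                f"cube: channel depth {self.cube.shape[2]} != axis length {len(self.axis)}"
            )
        if self.mask.shape != self.cube.shape[:2]:
            raise ValidationError(
                f"mask: shape {self.mask.shape} != cube spatial shape {self.cube.shape[:2]}"
            )
        if not np.all(np.isfinite(self.cube)):
            raise ValidationError("cube: contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape  # type: ignore[return-value]

    def tissue_spectra(self) -> np.ndarray:
        """All spectra under the mask as an (n_pixels, channels) matrix."""
        return self.cube[self.mask]

    def zero_outside_mask(self) -> None:
        """Pad non-tissue pixels with all-zero spectra, in place."""
        self.cube = self.cube.copy()
        self.cube[~self.mask] = 0.0


@dataclass
class CohortTable:
    """Patient-level metadata binding image ids to binary outcome labels."""

    patients: pd.DataFrame  # columns: patient_id (str), label (int)
    image_map: pd.DataFrame  # columns: image_id (str), patient_id (str)

    def __post_init__(self) -> None:
        p = self.patients
        if p["patient_id"].duplicated().any():
            raise ValidationError("cohort: duplicate patient_id")
        if not set(np.unique(p["label"])).issubset({0, 1}):
            raise ValidationError("cohort: labels must be 0 or 1")
        if self.image_map["image_id"].duplicated().any():
            dup = self.image_map.loc[self.image_map["image_id"].duplicated(), "image_id"].iloc[0]
            raise ValidationError(f"cohort: image {dup!r} listed more than once")
        unknown = set(self.image_map["patient_id"]) - set(p["patient_id"])
        if unknown:
            raise ValidationError(f"cohort: images reference unknown patients {sorted(unknown)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def label_of(self, patient_id: str) -> int:
        row = self.patients.loc[self.patients["patient_id"] == patient_id, "label"]
        if row.empty:
            raise KeyError(patient_id)
        return int(row.iloc[0])

    def labels(self) -> dict[str, int]:
        return dict(zip(self.patients["patient_id"], self.patients["label"].astype(int)))

    def images_of(self, patient_id: str) -> list[str]:
        m = self.image_map
        return list(m.loc[m["patient_id"] == patient_id, "image_id"])

    def require_both_classes(self) -> None:
        labels = set(self.patients["label"].astype(int))
        if labels != {0, 1}:
            raise ValidationError("cohort: both outcome classes must be present")


@dataclass
class RunConfig:
    """Training-protocol knobs shared by the CNN and PLSDA harnesses."""

    seed: int = 0
    batch_size: int = 8
    epochs: int = 200
    patience: int = 60
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_folds: int = 5
    use_batch_norm: bool = False
    learning_rate: float = 1e-3
    monitor: str = "train_loss"  # or "val_loss"
    standardize: bool = True  # per-channel z-scoring with training-set statistics

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValidationError("split_ratios must sum to 1")
        if not self.patience < self.epochs:
            raise ValidationError("patience must be < epochs")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# HDF5 image container
# ---------------------------------------------------------------------------

def write_image(img: HyperspectralImage, path, overwrite: bool = True) -> None:
    """Write one image to its HDF5 container (float32 cube, float64 axis)."""
    mode = "w" if overwrite else "w-"
    try:
        f = h5py.File(path, mode)
    except (FileExistsError, OSError) as e:
        if not overwrite:
            raise FileExistsError(f"{path}: exists and overwrite=False") from e
        raise IOError(f"{path}: cannot open for writing ({e})") from e
    with f:
        f.create_dataset("cube", data=img.cube.astype(np.float32))
        f.create_dataset("wavenumbers", data=img.axis.values.astype(np.float64))
        f.create_dataset("mask", data=img.mask.astype(np.uint8))
        f.attrs["image_id"] = img.image_id
        f.attrs["patient_id"] = img.patient_id


def read_image(path, image_id: str | None = None) -> HyperspectralImage:
    """Read and validate one image; a descending axis is reversed on read."""
    with h5py.File(path, "r") as f:
        for name in ("cube", "wavenumbers", "mask"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset /{name}")
        cube = np.asarray(f["cube"])
        wn = np.asarray(f["wavenumbers"], dtype=np.float64)
        mask = np.asarray(f["mask"]).astype(bool)
        iid = str(f.attrs.get("image_id", ""))
        pid = str(f.attrs.get("patient_id", ""))
    if cube.ndim != 3:
        raise FormatError(f"{path}: /cube must be 3-D, got shape {cube.shape}")
    if wn.ndim != 1 or wn.size != cube.shape[2]:
        raise FormatError(
            f"{path}: /wavenumbers length {wn.size} does not match cube depth {cube.shape[2]}"
        )
    if wn.size >= 2 and np.all(np.diff(wn) < 0):  # descending: flip to internal convention
        wn = wn[::-1].copy()
        cube = cube[:, :, ::-1].copy()
    if not np.all(np.diff(wn) > 0):
        raise FormatError(f"{path}: /wavenumbers must be strictly monotone")
    try:
        return HyperspectralImage(
            cube=cube, axis=WavenumberAxis(wn), mask=mask,
            image_id=image_id or iid, patient_id=pid,
        )
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def read_cohort(path) -> CohortTable:
    """Read the per-image cohort CSV and group it by patient."""
    df = pd.read_csv(path, dtype={"patient_id": str, "image_id": str})
    required = {"patient_id", "label", "image_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: cohort CSV needs columns {sorted(required)}")
    if df.duplicated(subset=["patient_id", "image_id"]).any():
        raise ValidationError(f"{path}: duplicate (patient_id, image_id) rows")
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any() or not set(labels.astype(int)).issubset({0, 1}):
        raise ValidationError(f"{path}: labels must be 0 or 1")
    if (labels != labels.astype(int)).any():
        raise ValidationError(f"{path}: labels must be integers 0 or 1")
    df["label"] = labels.astype(int)
    per_image_patients = df.groupby("image_id")["patient_id"].nunique()
    if (per_image_patients > 1).any():
        bad = per_image_patients[per_image_patients > 1].index[0]
        raise ValidationError(f"{path}: image {bad!r} listed under more than one patient")
    per_patient_labels = df.groupby("patient_id")["label"].nunique()
    if (per_patient_labels > 1).any():
        bad = per_patient_labels[per_patient_labels > 1].index[0]
        raise ValidationError(f"{path}: patient {bad!r} has conflicting labels")
    patients = df[["patient_id", "label"]].drop_duplicates().reset_index(drop=True)
    image_map = df[["image_id", "patient_id"]].reset_index(drop=True)
    return CohortTable(patients=patients, image_map=image_map)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort back to its one-row-per-image CSV form."""
    merged = cohort.image_map.merge(cohort.patients, on="patient_id")
    merged[["patient_id", "label", "image_id"]].to_csv(path, index=False)
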