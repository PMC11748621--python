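"""Spectral preprocessing: truncation, EMSC scatter correction, substrate masking.

The pipeline mirrors standard FTIR histopathology practice: (1) truncate the
axis to the biochemically informative fingerprint region (1000-1800 cm⁻¹);
(2) remove the smooth Mie-type scatter/baseline confound with a single-pass
extended multiplicative signal correction (EMSC) against a reference spectrum —
each pixel spectrum is modelled by ordinary least squares as

    s(ν) ≈ c·m(ν) + Σᵢ bᵢ·Pᵢ(ν) + Σⱼ gⱼ·Bⱼ(ν)

with reference m, polynomial baseline Pᵢ and optional smooth scatter basis Bⱼ,
and the corrected spectrum is (s − baseline − scatter)/c; (3) detect substrate
pixels around the core with a k=2 k-means on pixel spectra and pad them with
zeros.

The single-pass EMSC deliberately replaces the full iterative resonant-Mie
loop: one iteration is what the downstream stages assume, and the contract is
removal of a smooth confound plus reference normalisation, not a physical
scatter model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core_io import HyperspectralImage, ValidationError, WavenumberAxis

__all__ = [
    "EmscModel",
    "NumericalError",
    "DegenerateClusterError",
    "truncate_fingerprint",
    "emsc_correct",
    "correct_image",
    "tissue_mask",
    "preprocess_image",
    "load_reference_csv",
]

AMIDE_I_WINDOW = (1600.0, 1700.0)


class NumericalError(ArithmeticError):
    """A least-squares fit was singular or otherwise ill-posed."""


class DegenerateClusterError(RuntimeError):
    """k-means could not produce two distinct, non-empty clusters."""


def truncate_fingerprint(
    img: HyperspectralImage, lo: float = 1000.0, hi: float = 1800.0
) -> HyperspectralImage:
    """Restrict the image to channels with lo <= wavenumber <= hi."""
    keep = img.axis.window(lo, hi)
    if not keep.any():
        raise ValidationError(
            f"truncation range [{lo}, {hi}] does not overlap axis "
            f"[{img.axis.values[0]:g}, {img.axis.values[-1]:g}]"
        )
    if keep.all():
        return img
    return HyperspectralImage(
        cube=img.cube[:, :, keep],
        axis=WavenumberAxis(img.axis.values[keep]),
        mask=img.mask,
        image_id=img.image_id,
        patient_id=img.patient_id,
    )


@dataclass
class EmscModel:
    """EMSC design: reference spectrum + polynomial + smooth scatter basis.

    The design matrix is identical for every pixel, so a whole image is
    corrected with one pseudo-inverse. Column order: reference, polynomial
    degrees 0..poly_order (in the axis rescaled to [-1, 1] for conditioning),
    then the scatter basis columns. Default scatter basis: the first 3
    half-period cosines over the axis — a minimal family of slow oscillations.
    """

    axis: WavenumberAxis
    reference: np.ndarray
    poly_order: int = 2
    n_cosine: int = 3
    extra_basis: np.ndarray | None = None  # optional (n_channels, k) columns
    c_min: float = 0.1  # pixels with fitted c below this carry no tissue signal

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.reference.shape != (len(self.axis),):
            raise ValidationError("EMSC reference length must equal axis length")
        if self.poly_order < 0:
            raise ValidationError("poly_order must be >= 0")
        self._design, self._names = self._build_design()
        self._check_conditioning()
        self._pinv = np.linalg.pinv(self._design)

    def _build_design(self) -> tuple[np.ndarray, list[str]]:
        wn = self.axis.values
        u = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0
        cols = [self.reference]
        names = ["reference"]
        for d in range(self.poly_order + 1):
            cols.append(u**d)
            names.append(f"poly{d}")
        for j in range(1, self.n_cosine + 1):
            cols.append(np.cos(np.pi * j * (u + 1.0) / 2.0))
            names.append(f"cos{j}")
        if self.extra_basis is not None:
            eb = np.atleast_2d(np.asarray(self.extra_basis, dtype=np.float64))
            if eb.shape[0] != len(self.axis):
                eb = eb.T
            for j in range(eb.shape[1]):
                cols.append(eb[:, j])
                names.append(f"basis{j}")
        return np.column_stack(cols), names

    def _check_conditioning(self) -> None:
        D = self._design
        norms = np.linalg.norm(D, axis=0)
        if np.any(norms == 0):
            bad = [self._names[i] for i in np.where(norms == 0)[0]]
            raise NumericalError(f"EMSC design has zero columns: {bad}")
        r = np.linalg.matrix_rank(D)
        if r < D.shape[1]:
            # name offending columns via near-zero R diagonal of a pivot-free QR
            _, R = np.linalg.qr(D / norms)
            diag = np.abs(np.diag(R))
            bad = [self._names[i] for i in np.where(diag < 1e-10)[0]]
            raise NumericalError(
                f"EMSC design matrix is rank-deficient (rank {r} < {D.shape[1]}); "
                f"collinear columns: {bad or self._names}"
            )

    @property
    def n_coefficients(self) -> int:
        return self._design.shape[1]

    @property
    def coefficient_names(self) -> list[str]:
        return list(self._names)

    def fit_coefficients(self, spectra: np.ndarray) -> np.ndarray:
        """OLS coefficients for spectra of shape (..., n_channels)."""
        flat = np.asarray(spectra, dtype=np.float64).reshape(-1, len(self.axis))
        coef = flat @ self._pinv.T
        return coef.reshape(spectra.shape[:-1] + (self.n_coefficients,))

    def correct(self, spectra: np.ndarray, coef: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
        """Corrected spectra = (raw − baseline − scatter)/c; returns (corrected, coef).

        Pixels with fitted c <= c_min carry no meaningful reference-like
        contribution (substrate, holes, all-zero spectra): dividing them by a
        near-zero c would only amplify noise, so they are flagged and passed
        through unchanged. Flagged pixels are identified by
        coef[..., 0] <= c_min.
        """
        spectra = np.asarray(spectra, dtype=np.float64)
        if coef is None:
            coef = self.fit_coefficients(spectra)
        c = coef[..., :1]
        confound = coef[..., 1:] @ self._design[:, 1:].T
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = (spectra - confound) / c
        flagged = (coef[..., 0] <= self.c_min) | ~np.isfinite(coef[..., 0])
        corrected = np.where(flagged[..., None], spectra, corrected)
        return corrected, coef


def emsc_correct(spectrum: np.ndarray, model: EmscModel) -> tuple[np.ndarray, dict]:
    """Correct a single spectrum; returns (corrected, named coefficients)."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if spectrum.shape != (len(model.axis),):
        raise ValidationError("spectrum and EMSC model are on different axes")
    corrected, coef = model.correct(spectrum[None, :])
    named = dict(zip(model.coefficient_names, coef[0]))
    return corrected[0], named


def correct_image(img: HyperspectralImage, model: EmscModel) -> HyperspectralImage:
    """Apply EMSC per pixel to the tissue pixels of an image.

    Non-tissue pixels are passed through untouched (they are zeroed later by
    the masking stage). Pixels with non-positive fitted c are flagged and left
    unchanged; all-zero pixels therefore stay zero.
    """
    if len(img.axis) != len(model.axis) or not np.allclose(
        img.axis.values, model.axis.values
    ):
        raise ValidationError("image must be truncated to the EMSC model's axis")
    cube = img.cube.astype(np.float64).copy()
    tissue = img.mask
    corrected, _ = model.correct(cube[tissue])
    cube[tissue] = corrected
    if not np.all(np.isfinite(cube)):
        bad = np.argwhere(~np.isfinite(cube).all(axis=2))
        raise NumericalError(f"EMSC produced non-finite spectra at pixels {bad[:5].tolist()}")
    return HyperspectralImage(
        cube=cube, axis=img.axis, mask=img.mask,
        image_id=img.image_id, patient_id=img.patient_id,
    )


def tissue_mask(
    img: HyperspectralImage, k: int = 2, seed: int = 0, max_retries: int = 3
) -> HyperspectralImage:
    """Separate tissue from substrate with k=2 k-means and zero-pad substrate.

    The cluster with the lower mean absorbance in the amide I window
    (1600-1700 cm⁻¹; total absorbance if the window is absent from the axis)
    is labelled substrate. Returns a new image whose mask marks tissue and
    whose cube is zero outside it.
    """
    flat = img.cube.reshape(-1, len(img.axis)).astype(np.float64)
    scale = float(np.abs(flat).max())
    if scale == 0:
        raise DegenerateClusterError("image is identically zero")
    window = img.axis.window(*AMIDE_I_WINDOW)
    if not window.any():
        window = np.ones(len(img.axis), dtype=bool)

    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, n_init=10, tol=1e-6, max_iter=300,
                    random_state=seed + attempt)
        labels = km.fit_predict(flat)
        sizes = np.bincount(labels, minlength=k)
        centroid_sep = np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1:], axis=1).max() if k > 1 else 0.0
        if sizes.min() > 0 and centroid_sep > 1e-8 * scale:
            break
    else:
        raise DegenerateClusterError(
            f"k-means produced degenerate clusters after {max_retries} retries "
            "(image may contain a single spectral population)"
        )

    amide = np.array([
        flat[labels == c][:, window].sum(axis=1).mean() for c in range(k)
    ])
    tissue_cluster = int(np.argmax(amide))
    mask = (labels == tissue_cluster).reshape(img.cube.shape[:2])
    cube = img.cube.copy()
    cube[~mask] = 0.0
    return HyperspectralImage(
        cube=cube, axis=img.axis, mask=mask,
        image_id=img.image_id, patient_id=img.patient_id,
    )


def preprocess_image(
    img: HyperspectralImage,
    model: EmscModel | None = None,
    lo: float = 1000.0,
    hi: float = 1800.0,
    seed: int = 0,
    mask_first: bool = False,
) -> HyperspectralImage:
    """Full preprocessing chain: truncate → EMSC → substrate mask (zero pad).

    ``mask_first`` switches to masking before correction for users who prefer
    to exclude substrate pixels from the EMSC stage.
    """
    from .synthetic import reference_spectrum

    out = truncate_fingerprint(img, lo, hi)
    if model is None:
        model = EmscModel(axis=out.axis, reference=reference_spectrum(out.axis))
    if mask_first:
        out = tissue_mask(out, seed=seed)
        out = correct_image(out, model)
        out.cube[~out.mask] = 0.0
        return out
    out = correct_image(out, model)
    return tissue_mask(out, seed=seed)


def load_reference_csv(path, axis: WavenumberAxis) -> np.ndarray:
    """Load a two-column (wavenumber, absorbance) CSV reference and
    linearly interpolate it onto ``axis``."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("reference CSV must have two columns")
    wn = df.iloc[:, 0].to_numpy(dtype=np.float64)
    ab = df.iloc[:, 1].to_numpy(dtype=np.float64)
    order = np.argsort(wn)
    return np.interp(axis.values, wn[order], ab[order])
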