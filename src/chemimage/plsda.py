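"""PLS discriminant analysis of spectra (NIPALS PLS1) and spectral embedding.

Two roles:

* Per-cluster classification: spectra pooled from one segmentation cluster,
  labelled by patient outcome, are fit with PLS1 on mean-centered data; model
  complexity (number of latent variables, 1-50) is chosen by validation-set
  F1. NIPALS components are nested, so the per-LV sweep truncates a single
  lv_max fit instead of refitting.

* 3-LV embedding: a PLS model with exactly 3 latent variables maps every
  pixel spectrum to its 3 score values, converting a hyperspectral cube into
  a 3-channel image (substrate pixels → (0,0,0)) suitable for ordinary
  RGB-style 2D networks.

For a centered spectrum x, scores are t = Rᵀx with rotation
R = W (PᵀW)⁻¹ and predictions ŷ = ȳ + xᵀ B_k with per-LV coefficients
B_k = R[:, :k] q[:k].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .core_io import CohortTable, HyperspectralImage, ValidationError

__all__ = [
    "PlsdaModel",
    "pls_fit",
    "pls_predict",
    "select_lv",
    "pls_embed_image",
    "cluster_plsda_pipeline",
]

LV_MAX_DEFAULT = 50


@dataclass
class PlsdaModel:
    """Fitted NIPALS PLS1 discriminant model.

    Weights W have unit norm per component; scores T are mutually orthogonal;
    coefficients per LV count are nested truncations of the lv_max fit.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A)
    loadings: np.ndarray  # (p, A)
    q: np.ndarray  # (A,) y-loadings
    scores: np.ndarray  # (n, A) training scores
    coefficients: np.ndarray  # (p, A): column k-1 = coefficients using k LVs
    n_lv: int  # chosen complexity
    threshold: float = 0.5

    @property
    def lv_max(self) -> int:
        return self.weights.shape[1]

    def rotation(self, n_lv: int | None = None) -> np.ndarray:
        """R = W (PᵀW)⁻¹ restricted to the first n_lv components."""
        a = n_lv or self.n_lv
        W, P = self.weights[:, :a], self.loadings[:, :a]
        return W @ np.linalg.inv(P.T @ W)

    def transform(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Score matrix T for new spectra (mean-centered with training mean)."""
        X = np.asarray(X, dtype=np.float64)
        return (X - self.x_mean) @ self.rotation(n_lv)


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int,
            threshold: float = 0.5) -> PlsdaModel:
    """NIPALS PLS1 on mean-centered X and y ∈ {0,1}.

    ``n_lv`` is clamped (with a warning) to min(n-1, p, 50). Stores weights,
    loadings, scores and the nested per-LV regression coefficients.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if n < 2:
        raise ValidationError("pls_fit: need at least 2 samples")
    if y.shape[0] != n:
        raise ValidationError("pls_fit: X and y disagree in length")
    if np.unique(y).size < 2:
        raise ValidationError("pls_fit: y is constant (single class)")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    if not np.any(np.abs(Xc) > 0):
        raise ValidationError("pls_fit: X has zero variance")
    yc = y - y_mean

    cap = min(n - 1, p, LV_MAX_DEFAULT)
    if n_lv > cap:
        import warnings

        warnings.warn(f"pls_fit: clamping n_lv from {n_lv} to {cap}")
        n_lv = cap
    if n_lv < 1:
        raise ValidationError("pls_fit: n_lv must be >= 1")

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    Xres = Xc.copy()
    a_used = 0
    for a in range(n_lv):
        w = Xres.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * max(1.0, np.abs(Xc).max()):
            break  # residual X carries no covariance with y
        w /= nw
        t = Xres @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        pvec = Xres.T @ t / tt
        q[a] = float(yc @ t / tt)
        Xres = Xres - np.outer(t, pvec)
        W[:, a], P[:, a], T[:, a] = w, pvec, t
        a_used += 1
    if a_used == 0:
        raise ValidationError("pls_fit: no component could be extracted")
    W, P, T, q = W[:, :a_used], P[:, :a_used], T[:, :a_used], q[:a_used]

    R = W @ np.linalg.inv(P.T @ W)
    coef = np.cumsum(R * q[None, :], axis=1)  # column k-1: B using first k LVs
    return PlsdaModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, loadings=P, q=q,
        scores=T, coefficients=coef, n_lv=a_used, threshold=threshold,
    )


def pls_predict(model: PlsdaModel, X: np.ndarray,
                n_lv: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Continuous responses and thresholded binary labels for new spectra."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.x_mean.shape[0]:
        raise ValidationError(
            f"pls_predict: expected {model.x_mean.shape[0]} channels, got {X.shape}"
        )
    a = n_lv or model.n_lv
    if not (1 <= a <= model.lv_max):
        raise ValidationError(f"pls_predict: n_lv={a} outside [1, {model.lv_max}]")
    scores = model.y_mean + (X - model.x_mean) @ model.coefficients[:, a - 1]
    return scores, (scores >= model.threshold).astype(int)


def select_lv(
    Xtrain: np.ndarray, ytrain: np.ndarray,
    Xval: np.ndarray, yval: np.ndarray,
    lv_max: int = LV_MAX_DEFAULT,
) -> tuple[PlsdaModel, int, np.ndarray]:
    """Choose model complexity by validation F1 over truncations 1..lv_max.

    Fits once at lv_max and scores every truncation; returns
    (model with n_lv set to the argmax, best LV, F1 per LV). Ties break toward
    the smallest LV (np.argmax). Positive class = recurrence (label 1).
    """
    yval = np.asarray(yval).ravel()
    if yval.size == 0:
        raise ValidationError("select_lv: empty validation set")
    if np.unique(yval).size < 2:
        raise ValidationError("select_lv: validation set needs both classes")
    model = pls_fit(Xtrain, ytrain, n_lv=lv_max)
    f1s = np.zeros(model.lv_max)
    for a in range(1, model.lv_max + 1):
        _, labels = pls_predict(model, Xval, n_lv=a)
        f1s[a - 1] = f1_score(yval, labels, pos_label=1, zero_division=0.0)
    best = int(np.argmax(f1s)) + 1
    model.n_lv = best
    return model, best, f1s


def pls_embed_image(img: HyperspectralImage, model: PlsdaModel) -> np.ndarray:
    """Replace each tissue pixel by its 3 PLS scores; substrate → (0,0,0).

    The model must have been fitted with exactly 3 latent variables on
    training-set spectra only; the output has shape (rows, cols, 3).
    """
    if model.n_lv != 3 or model.lv_max < 3:
        raise ValidationError("pls_embed_image: model must use exactly 3 latent variables")
    out = np.zeros(img.cube.shape[:2] + (3,), dtype=np.float64)
    spectra = img.tissue_spectra()
    if spectra.size:
        out[img.mask] = model.transform(spectra, n_lv=3)
    return out


# ---------------------------------------------------------------------------
# per-cluster patient-outcome pipeline
# ---------------------------------------------------------------------------

def _gather_cluster_spectra(images, cluster_model, composite_id, patient_ids,
                            cohort, rng, cap_per_image):
    """Pool spectra of one composite cluster across the given patients."""
    off = cluster_model.composite_offset()
    spectra, labels, owners = [], [], []
    pid_of = dict(zip(cohort.image_map["image_id"], cohort.image_map["patient_id"]))
    lab = cohort.labels()
    for img in images:
        pid = pid_of.get(img.image_id)
        if pid not in patient_ids:
            continue
        amap = cluster_model.assignments[img.image_id]
        comp = np.full(amap.shape[:2], -1, dtype=np.int64)
        tissue = amap[:, :, 0] >= 0
        comp[tissue] = (
            np.array([off[int(a)] for a in amap[:, :, 0][tissue]]) + amap[:, :, 1][tissue]
        )
        sel = comp == composite_id
        s = img.cube[sel]
        if s.shape[0] == 0:
            continue
        if cap_per_image and s.shape[0] > cap_per_image:
            s = s[rng.choice(s.shape[0], cap_per_image, replace=False)]
        spectra.append(s)
        labels.append(np.full(s.shape[0], lab[pid]))
        owners.extend([pid] * s.shape[0])
    if not spectra:
        return None
    return np.concatenate(spectra), np.concatenate(labels), np.array(owners)


def cluster_plsda_pipeline(
    images: list[HyperspectralImage],
    cohort: CohortTable,
    cluster_model,
    n_repeats: int = 10,
    seed: int = 0,
    lv_max: int = LV_MAX_DEFAULT,
    cap_per_image: int = 200,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Per-cluster PLSDA against patient outcome, repeated over random splits.

    For each composite (level-1, level-2) cluster and each repetition: pool
    the cluster's member spectra, split patients 60:20:20 (stratified), select
    LV count by validation F1, and evaluate on test patients. The per-patient
    score is the ``aggregate`` (mean/median/max) of that patient's spectrum
    scores. Reports spectrum-level F1 and patient-level AUC, mean ± sd over
    repeats. Clusters missing from a split are recorded as not evaluable.
    """
    from .train_eval import make_split, roc_auc

    agg = {"mean": np.mean, "median": np.median, "max": np.max}[aggregate]
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        plan = make_split(cohort, seed=seed + rep)
        sets = {name: set(plan.patients_in(name)) for name in ("train", "val", "test")}
        for comp in range(cluster_model.n_composite):
            rec = {"repeat": rep, "cluster": comp, "evaluable": False,
                   "n_lv": np.nan, "f1_spectrum": np.nan, "auc_patient": np.nan}
            pools = {
                name: _gather_cluster_spectra(
                    images, cluster_model, comp, sets[name], cohort, rng, cap_per_image
                )
                for name in ("train", "val", "test")
            }
            ok = all(
                pools[name] is not None and np.unique(pools[name][1]).size == 2
                for name in ("train", "val", "test")
            )
            if ok:
                Xtr, ytr, _ = pools["train"]
                Xv, yv, _ = pools["val"]
                Xte, yte, owners = pools["test"]
                try:
                    model, best, _ = select_lv(Xtr, ytr, Xv, yv, lv_max=lv_max)
                except ValidationError:
                    model = None
                if model is not None:
                    s_te, l_te = pls_predict(model, Xte)
                    pids = pd.unique(owners)
                    p_scores = np.array([agg(s_te[owners == p]) for p in pids])
                    p_labels = np.array([cohort.label_of(p) for p in pids])
                    if np.unique(p_labels).size == 2:
                        rec.update(
                            evaluable=True, n_lv=best,
                            f1_spectrum=f1_score(yte, l_te, pos_label=1, zero_division=0.0),
                            auc_patient=roc_auc(p_scores, p_labels),
                        )
            rows.append(rec)
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep[per_rep["evaluable"]]
        .groupby("cluster")
        .agg(
            n_evaluable=("evaluable", "sum"),
            f1_mean=("f1_spectrum", "mean"), f1_sd=("f1_spectrum", "std"),
            auc_mean=("auc_patient", "mean"), auc_sd=("auc_patient", "std"),
            lv_median=("n_lv", "median"),
        )
        .reset_index()
    )
    summary.attrs["per_repeat"] = per_rep
    return summary
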