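"""Patient-level splitting, class-weighted training, and ROC-AUC evaluation.

Splitting is always at the patient level: every image of a patient lands in
the same set, and positive/negative patients are allocated to train/val/test
in a stratified 60:20:20 ratio (or to rotating test fifths in the 5-fold
protocol, with the remainder split 3:1 into train:val). Training minimises
class-weighted binary cross-entropy with Adam, halts early when the monitored
loss fails to improve for ``patience`` consecutive epochs, and restores the
parameters of the best epoch. Test performance is the patient-level ROC AUC
(patient score = mean over the patient's images), computed with the
rank-based Mann-Whitney statistic in which ties contribute 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core_io import CohortTable, HyperspectralImage, RunConfig, ValidationError
from .dscnn import ArchitectureSpec, build_architecture, realize
from .dscnn.network import Network

__all__ = [
    "SplitPlan",
    "TrainResult",
    "make_split",
    "make_kfold_plans",
    "class_weights",
    "roc_auc",
    "train",
    "kfold_evaluate",
    "Adam",
]

_LOG = logging.getLogger("chemimage")

SET_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class SplitPlan:
    """patient_id → {train, val, test} assignment; deterministic in seed."""

    assignment: dict[str, str]
    seed: int
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    fold: int | None = None

    def patients_in(self, set_name: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == set_name]

    def set_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def check_disjoint(self) -> None:
        sets = [set(self.patients_in(n)) for n in SET_NAMES]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (sets[i] & sets[j]), "patient sets overlap"


def _allocate(n: int, ratios: tuple[float, ...], min_each: int) -> list[int]:
    """Largest-remainder allocation of n items, with a floor of min_each."""
    raw = [n * r for r in ratios]
    counts = [int(np.floor(v)) for v in raw]
    rem = n - sum(counts)
    order = np.argsort([-(v - np.floor(v)) for v in raw], kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    # enforce the floor by taking from the largest bins
    for i in range(len(counts)):
        while counts[i] < min_each:
            donor = int(np.argmax(counts))
            if counts[donor] <= min_each:
                raise ValidationError("too few patients to cover every set")
            counts[donor] -= 1
            counts[i] += 1
    return counts


def make_split(
    cohort: CohortTable,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitPlan:
    """Stratified patient-level 60:20:20 split, deterministic in seed.

    Each class is allocated by floor + largest remainder with at least one
    patient per set, so both classes are present in every set; a class with
    fewer than 3 patients cannot cover the three sets and is an error.
    """
    cohort.require_both_classes()
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    labels = cohort.labels()
    for cls in (0, 1):
        members = sorted([p for p, l in labels.items() if l == cls])
        if len(members) < 3:
            raise ValidationError(
                f"class {cls} has {len(members)} patients; need >= 3 to stratify"
            )
        rng.shuffle(members)
        counts = _allocate(len(members), ratios, min_each=1)
        i = 0
        for set_name, c in zip(SET_NAMES, counts):
            for p in members[i : i + c]:
                assignment[p] = set_name
            i += c
    plan = SplitPlan(assignment=assignment, seed=seed, ratios=ratios)
    plan.check_disjoint()
    return plan


def make_kfold_plans(
    cohort: CohortTable, n_folds: int = 5, seed: int = 0
) -> list[SplitPlan]:
    """Rotating-test k-fold protocol built on the 60:20:20 machinery.

    Patients are dealt (stratified, seeded) into ``n_folds`` fifths; each fold
    uses one fifth as test and splits the remainder 3:1 into train:val.
    """
    cohort.require_both_classes()
    rng = np.random.default_rng(seed)
    labels = cohort.labels()
    folds_of: dict[str, int] = {}
    for cls in (0, 1):
        members = sorted([p for p, l in labels.items() if l == cls])
        if len(members) < n_folds:
            raise ValidationError(
                f"class {cls} has {len(members)} patients < n_folds={n_folds}"
            )
        rng.shuffle(members)
        for i, p in enumerate(members):
            folds_of[p] = i % n_folds
    plans = []
    for fold in range(n_folds):
        assignment: dict[str, str] = {}
        for cls in (0, 1):
            rest = sorted([p for p, l in labels.items()
                           if l == cls and folds_of[p] != fold])
            rng_f = np.random.default_rng(seed * 1000 + fold)
            rng_f.shuffle(rest)
            n_val = max(1, int(round(len(rest) * 0.25)))
            for p in rest[:n_val]:
                assignment[p] = "val"
            for p in rest[n_val:]:
                assignment[p] = "train"
            for p, l in labels.items():
                if l == cls and folds_of[p] == fold:
                    assignment[p] = "test"
        plan = SplitPlan(assignment=assignment, seed=seed, fold=fold)
        plan.check_disjoint()
        plans.append(plan)
    return plans


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights: w₁/w₀ = n₀/n₁, normalized to mean 1.

    With the reference cohort composition (110 negative, 29 positive) the
    positive:negative ratio is 110/29 ≈ 3.79.
    """
    labels = np.asarray(labels).astype(int)
    n0 = int((labels == 0).sum())
    n1 = int((labels == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValidationError("class_weights: both classes must be present")
    n = n0 + n1
    return {0: n / (2.0 * n0), 1: n / (2.0 * n1)}


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney ROC AUC: P(score⁺ > score⁻) with ties counting 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


class Adam:
    """Adaptive-moment estimation over a network's parameter registry."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {f"{i}/{n}": np.zeros_like(p) for i, n, p in net.parameters()}
        self.v = {f"{i}/{n}": np.zeros_like(p) for i, n, p in net.parameters()}

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.net.layers):
            for name, p in layer.params.items():
                key = f"{i}/{name}"
                g = layer.grads[name]
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    """One trained model: loss curves, best epoch, and test patient AUC."""

    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    stopped_early: bool
    test_auc: float
    val_auc: float
    fold: int | None
    config_hash: str


def _weighted_bce_and_grad(logits, y, weights):
    """Class-weighted binary cross-entropy on logits; returns (loss, dlogits)."""
    w = np.where(y == 1, weights[1], weights[0])
    # log(1+e^z) computed stably
    softplus = np.logaddexp(0.0, logits)
    loss = float(np.mean(w * (softplus - y * logits)))
    p = 1.0 / (1.0 + np.exp(-logits))
    dlogits = w * (p - y) / y.shape[0]
    return loss, dlogits


def _stack_images(images, ids, dtype=np.float32):
    lookup = {im.image_id: im for im in images}
    return np.stack([lookup[i].cube for i in ids]).astype(dtype)


def _patient_scores(net, images, cohort, patient_ids, aggregate=np.mean):
    mu, sd = getattr(net, "input_stats", (0.0, 1.0))
    scores, labels = [], []
    for pid in patient_ids:
        iids = cohort.images_of(pid)
        x = (_stack_images(images, iids) - mu) / sd
        scores.append(aggregate(net.predict_proba(x)))
        labels.append(cohort.label_of(pid))
    return np.asarray(scores), np.asarray(labels)


def train(
    arch: ArchitectureSpec,
    images: list[HyperspectralImage],
    cohort: CohortTable,
    plan: SplitPlan,
    cfg: RunConfig,
) -> tuple[Network, TrainResult]:
    """Train one model on the plan's training patients.

    Minimises class-weighted binary cross-entropy with Adam; early-stops when
    the monitored loss (training loss by default, per protocol) has not
    improved for ``cfg.patience`` consecutive epochs, and restores the
    parameter snapshot of the minimum recorded loss.
    """
    import hashlib
    import json

    plan.check_disjoint()
    net = realize(arch, seed=cfg.seed)
    opt = Adam(net, lr=cfg.learning_rate)
    net.input_stats = (0.0, 1.0)
    rng = np.random.default_rng(cfg.seed + 1)

    train_imgs = [i for p in plan.patients_in("train") for i in cohort.images_of(p)]
    val_imgs = [i for p in plan.patients_in("val") for i in cohort.images_of(p)]
    pid_of = dict(zip(cohort.image_map["image_id"], cohort.image_map["patient_id"]))
    lab = cohort.labels()
    X = _stack_images(images, train_imgs)
    y = np.array([lab[pid_of[i]] for i in train_imgs], dtype=np.float64)
    Xv = _stack_images(images, val_imgs)
    yv = np.array([lab[pid_of[i]] for i in val_imgs], dtype=np.float64)
    if np.unique(y).size < 2:
        raise ValidationError("training set must contain both classes")
    weights = class_weights(y)

    # per-channel standardization; statistics from training patients only
    if cfg.standardize:
        mu = X.mean(axis=(0, 1, 2))
        sd = X.std(axis=(0, 1, 2)) + 1e-8
    else:
        mu = np.zeros(X.shape[-1], dtype=X.dtype)
        sd = np.ones(X.shape[-1], dtype=X.dtype)
    X = (X - mu) / sd
    Xv = (Xv - mu) / sd
    net.input_stats = (mu, sd)

    cfg_hash = hashlib.sha256(
        json.dumps({"arch": arch.to_json(), "seed": cfg.seed, "lr": cfg.learning_rate,
                    "bs": cfg.batch_size, "epochs": cfg.epochs}).encode()
    ).hexdigest()[:12]

    n = X.shape[0]
    curve_tr: list[float] = []
    curve_va: list[float] = []
    best_loss = np.inf
    best_state = net.get_state()
    best_epoch = -1
    stopped_early = False
    since_improve = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = net.forward(X[idx], train=True)
            loss, dlogits = _weighted_bce_and_grad(logits, y[idx], weights)
            if not np.isfinite(loss):
                raise ArithmeticError(
                    f"non-finite loss at epoch {epoch}, batch {i // cfg.batch_size}, "
                    f"lr={cfg.learning_rate}"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        tr_loss = float(np.mean(losses))
        vz = np.empty(Xv.shape[0])
        for i in range(0, Xv.shape[0], cfg.batch_size):
            vz[i : i + cfg.batch_size] = net.forward(Xv[i : i + cfg.batch_size], train=False)
        va_loss, _ = _weighted_bce_and_grad(vz, yv, weights)
        curve_tr.append(tr_loss)
        curve_va.append(float(va_loss))
        monitored = tr_loss if cfg.monitor == "train_loss" else va_loss
        if monitored < best_loss:
            best_loss = monitored
            best_state = net.get_state()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                stopped_early = True
                break
        _LOG.debug("epoch %d train %.4f val %.4f", epoch, tr_loss, va_loss)

    net.set_state(best_state)
    curve = curve_tr if cfg.monitor == "train_loss" else curve_va
    assert np.isclose(curve[best_epoch], min(curve)), "restored epoch is not the curve minimum"

    val_pids = plan.patients_in("val")
    test_pids = plan.patients_in("test")
    sv, lv = _patient_scores(net, images, cohort, val_pids)
    st, lt = _patient_scores(net, images, cohort, test_pids)
    result = TrainResult(
        train_loss=curve_tr, val_loss=curve_va, best_epoch=best_epoch,
        stopped_early=stopped_early,
        test_auc=roc_auc(st, lt), val_auc=roc_auc(sv, lv),
        fold=plan.fold, config_hash=cfg_hash,
    )
    return net, result


def kfold_evaluate(
    arch_name: str,
    cohort: CohortTable,
    images: list[HyperspectralImage],
    cfg: RunConfig,
    input_shape: tuple[int, int, int] | None = None,
    arch: ArchitectureSpec | None = None,
) -> dict:
    """k-fold protocol: one model per fold, mean ± sd of test patient AUC."""
    if arch is None:
        if input_shape is None:
            input_shape = images[0].cube.shape
        arch = build_architecture(arch_name, input_shape,
                                  use_batch_norm=cfg.use_batch_norm)
    plans = make_kfold_plans(cohort, n_folds=cfg.n_folds, seed=cfg.seed)
    results: list[TrainResult] = []
    failures: list[str] = []
    for plan in plans:
        try:
            _, res = train(arch, images, cohort, plan, cfg)
            results.append(res)
            _LOG.info("fold %s: test AUC %.3f (best epoch %d)",
                      plan.fold, res.test_auc, res.best_epoch)
        except (ValidationError, ArithmeticError) as e:  # partial report
            failures.append(f"fold {plan.fold}: {e}")
    aucs = np.array([r.test_auc for r in results])
    return {
        "arch": arch.name,
        "auc_mean": float(aucs.mean()) if aucs.size else np.nan,
        "auc_sd": float(aucs.std(ddof=1)) if aucs.size > 1 else np.nan,
        "fold_aucs": aucs.tolist(),
        "results": results,
        "failures": failures,
    }
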