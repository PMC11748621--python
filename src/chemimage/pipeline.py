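"""One-call orchestration: synth → preprocess → {segment + PLSDA | CNN training}.

A :class:`PipelineConfig` (buildable from a strict YAML file) enables stages,
carries per-stage seeds and writes a reproducibility manifest: every file any
stage produced, the resolved configuration and its hash, and package versions.
A stage failure halts the run but preserves completed outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core_io import RunConfig, ValidationError, get_logger, stage_timer
from .synthetic import SynthConfig

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a full run."""

    out_dir: str
    synth: SynthConfig = field(default_factory=SynthConfig)
    run: RunConfig = field(default_factory=RunConfig)
    arch_name: str = "model2"
    do_synth: bool = True
    do_preprocess: bool = True
    do_segment: bool = False
    do_plsda: bool = False
    do_train: bool = False
    subsample: int = 20_000
    plsda_repeats: int = 10
    seed_preprocess: int = 1
    seed_segment: int = 2
    seed_plsda: int = 3
    verbose: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"].pop("bands", None)  # band library is code, not config
        return d


_ALLOWED_TOP = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path) -> PipelineConfig:
    """Load a strict YAML config; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _ALLOWED_TOP
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    synth_kw = raw.pop("synth", {}) or {}
    run_kw = raw.pop("run", {}) or {}
    for kw, cls in ((synth_kw, SynthConfig), (run_kw, RunConfig)):
        bad = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            raise ValidationError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    if "wn_range" in synth_kw:
        synth_kw["wn_range"] = tuple(synth_kw["wn_range"])
    if "split_ratios" in run_kw:
        run_kw["split_ratios"] = tuple(run_kw["split_ratios"])
    return PipelineConfig(synth=SynthConfig(**synth_kw), run=RunConfig(**run_kw), **raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the manifest."""
    log = get_logger(cfg.verbose)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    resolved = cfg.to_dict()
    hashed = {k: v for k, v in resolved.items() if k != "out_dir"}
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "config.json").write_text(json.dumps(resolved, indent=2))

    manifest: dict = {
        "config_hash": cfg_hash,
        "versions": {"python": sys.version.split()[0], "chemimage": __version__,
                     "numpy": np.__version__},
        "stages": [],
        "outputs": ["config.json"],
    }

    def _done(stage: str, files: list[str]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(files)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        cohort = images = None
        if cfg.do_synth:
            from .synthetic import generate_cohort

            with stage_timer("synth"):
                synth_dir = out / "images"
                cohort, images, _ = generate_cohort(cfg.synth, out_dir=synth_dir)
            _done("synth", [f"images/{i.image_id}.h5" for i in images]
                  + ["images/cohort.csv", "images/manifest.json"])

        if cfg.do_preprocess:
            from .preprocess import preprocess_image

            if images is None:
                raise ValidationError("preprocess stage needs the synth stage's images")
            with stage_timer("preprocess"):
                images = [preprocess_image(im, seed=cfg.seed_preprocess) for im in images]
            _done("preprocess", [])

        seg_model = None
        if cfg.do_segment:
            from .segmentation import double_segmentation

            with stage_timer("segment"):
                seg_model = double_segmentation(
                    images, subsample=cfg.subsample, seed=cfg.seed_segment
                )
            seg_path = out / "segmentation.json"
            seg_path.write_text(json.dumps({
                "k1": seg_model.k1,
                "pbm_level1": seg_model.pbm_level1,
                "k2": {str(c): seg_model.k2(c) for c in range(seg_model.k1)},
            }))
            _done("segment", ["segmentation.json"])

        if cfg.do_plsda:
            from .plsda import cluster_plsda_pipeline

            if seg_model is None:
                raise ValidationError("plsda stage needs the segment stage")
            with stage_timer("plsda"):
                table = cluster_plsda_pipeline(
                    images, cohort, seg_model,
                    n_repeats=cfg.plsda_repeats, seed=cfg.seed_plsda,
                )
            table.to_csv(out / "plsda_clusters.csv", index=False)
            _done("plsda", ["plsda_clusters.csv"])

        if cfg.do_train:
            from .train_eval import kfold_evaluate

            with stage_timer("train"):
                report = kfold_evaluate(cfg.arch_name, cohort, images, cfg.run)
            (out / "results.json").write_text(json.dumps({
                "arch": report["arch"],
                "auc_mean": report["auc_mean"],
                "auc_sd": report["auc_sd"],
                "fold_aucs": report["fold_aucs"],
                "failures": report["failures"],
            }, indent=2))
            _done("train", ["results.json"])
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.exception("pipeline halted; completed outputs preserved in %s", out)
        raise
    return manifest
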