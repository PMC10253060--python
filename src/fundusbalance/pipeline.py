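"""End-to-end reproducible runs: generate -> split -> train -> evaluate.

Two execution modes share one config:

* the two-stage protocol alone (``methods: [twostage]``): a single global
  threshold split, one binary pre-training pass on the excess
  majority-class images, then k-fold cross-validated fine-tuning over the
  balanced fine-tuning subset;
* the comparison mode (ROS / RUS arms requested): one stratified fold
  plan over the *full* corpus shared by every arm, validation/test folds
  thresholded to the fold's glaucoma cardinality, and per-iteration
  training of each arm (two-stage re-runs its split + pre-training inside
  each iteration's training folds so its evaluation data are never seen
  during pre-training).

Every random choice flows from config seeds; the summary JSON carries a
hash of the resolved config and no timestamps, so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus import CorpusManifest, threshold_split
from .evaluation import (CVSummary, aggregate, evaluate_predictions,
                         make_folds, roc_band)
from .labels import CLASSES, GLAUCOMA
from .preprocess import AugmentationConfig, PreprocessConfig
from .resampling import ros, rus, threshold_eval_fold
from .synthetic import SynthesisParams, generate_corpus
from .training import (BackboneSpec, TrainConfig, build_model, finetune,
                       predict_probs, pretrain)

__all__ = ["PipelineConfig", "run_pipeline"]

VALID_METHODS = ("twostage", "ros", "rus")


@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run."""

    counts: dict[str, int] = field(
        default_factory=lambda: {"NORMAL": 200, "GLAUCOMA": 40, "AMD": 20, "DR": 80}
    )
    image_size: int = 64
    synthesis_seed: int = 0
    threshold_class: str = GLAUCOMA
    split_seed: int = 0
    target_size: int = 32
    augment: bool = True
    backbone: str = "tiny-cnn"
    pretrain_freeze: float = 0.0
    finetune_freeze: float = 0.5
    batch_size: int = 32
    optimizer: str = "radam"
    pretrain_epochs: int = 20
    finetune_epochs: int = 40
    patience: int = 5
    k: int = 10
    eval_seed: int = 0
    ddof: int = 0
    methods: list[str] = field(default_factory=lambda: ["twostage"])
    train_seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ValueError(f"unknown method {m!r}; valid: {VALID_METHODS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _seed(*parts: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(parts)))


def _stage_cfgs(cfg: PipelineConfig, seed_offset: int) -> tuple[TrainConfig, TrainConfig]:
    common = dict(batch_size=cfg.batch_size, optimizer=cfg.optimizer,
                  patience=cfg.patience)
    pre = TrainConfig(max_epochs=cfg.pretrain_epochs,
                      seed=cfg.train_seed + seed_offset, **common)
    fine = TrainConfig(max_epochs=cfg.finetune_epochs,
                       seed=cfg.train_seed + seed_offset + 1, **common)
    return pre, fine


def _pretrained_model(split, cfg: PipelineConfig, pre_cfg, aug_cfg,
                      pre_tc: TrainConfig):
    """Stage-1 model: pre-trained on the excess subset when it contains both
    majority classes, otherwise a fresh random initialization (nothing to
    pre-train on, e.g. an already balanced corpus)."""
    spec = BackboneSpec(family=cfg.backbone, n_outputs=2,
                        freeze_fraction=cfg.pretrain_freeze)
    counts = split.pretrain.counts
    if counts["NORMAL"] > 0 and counts["DR"] > 0:
        model = pretrain(split.pretrain, spec, pre_tc, pre_cfg, aug_cfg).model
    else:
        model = build_model(spec, input_size=pre_cfg.target_size,
                            rng=np.random.default_rng(pre_tc.seed))
    model.freeze_fraction = cfg.finetune_freeze
    return model


def _train_twostage(train_m: CorpusManifest, cfg: PipelineConfig, pre_cfg, aug_cfg,
                    seed_offset: int):
    split = threshold_split(train_m, cfg.threshold_class,
                            rng=_seed(cfg.split_seed, seed_offset))
    pre_tc, fine_tc = _stage_cfgs(cfg, seed_offset)
    model = _pretrained_model(split, cfg, pre_cfg, aug_cfg, pre_tc)
    return split, model, fine_tc


def _train_resampled(method: str, train_m: CorpusManifest, val_m: CorpusManifest,
                     cfg: PipelineConfig, pre_cfg, aug_cfg, seed_offset: int):
    resampler = ros if method == "ros" else rus
    resampled = resampler(train_m, rng=_seed(cfg.split_seed, seed_offset, 7))
    _, fine_tc = _stage_cfgs(cfg, seed_offset)
    spec = BackboneSpec(family=cfg.backbone, n_outputs=4, freeze_fraction=0.0)
    model = build_model(spec, input_size=cfg.target_size,
                        rng=np.random.default_rng(fine_tc.seed))
    model.freeze_fraction = 0.0
    return finetune(model, resampled, val_m, fine_tc, pre_cfg, aug_cfg).model


def _comparison_mode(corpus, cfg, pre_cfg, aug_cfg):
    plan = make_folds(corpus, k=cfg.k, seed=cfg.eval_seed)
    results = {m: {"reports": [], "probs": [], "truths": []} for m in cfg.methods}
    for i in range(cfg.k):
        test_ids, val_ids, train_ids = plan.iteration(i)
        test_m = threshold_eval_fold(corpus.by_ids(test_ids), cfg.threshold_class,
                                     rng=_seed(cfg.eval_seed, i, 1))
        val_m = threshold_eval_fold(corpus.by_ids(val_ids), cfg.threshold_class,
                                    rng=_seed(cfg.eval_seed, i, 2))
        train_m = corpus.by_ids(train_ids)
        for mi, method in enumerate(cfg.methods):
            offset = 100 * i + 10 * mi
            if method == "twostage":
                split, model, fine_tc = _train_twostage(train_m, cfg, pre_cfg,
                                                        aug_cfg, offset)
                model = finetune(model, split.finetune, val_m, fine_tc,
                                 pre_cfg, aug_cfg).model
            else:
                model = _train_resampled(method, train_m, val_m, cfg, pre_cfg,
                                         aug_cfg, offset)
            probs, truths = predict_probs(model, test_m, pre_cfg, cfg.batch_size)
            results[method]["reports"].append(evaluate_predictions(probs, truths))
            results[method]["probs"].append(probs)
            results[method]["truths"].append(truths)
    return plan, results


def _twostage_protocol(corpus, cfg, pre_cfg, aug_cfg):
    """Paper-shaped protocol: one global split, one pre-training pass,
    k-fold CV over the fine-tuning subset."""
    split = threshold_split(corpus, cfg.threshold_class, rng=_seed(cfg.split_seed))
    pre_tc, fine_tc = _stage_cfgs(cfg, 0)
    stage1_model = _pretrained_model(split, cfg, pre_cfg, aug_cfg, pre_tc)
    pretrained_state = stage1_model.state_dict()
    spec = BackboneSpec(family=cfg.backbone, n_outputs=2,
                        freeze_fraction=cfg.pretrain_freeze)

    plan = make_folds(split.finetune, k=cfg.k, seed=cfg.eval_seed)
    results = {"twostage": {"reports": [], "probs": [], "truths": []}}
    for i in range(cfg.k):
        test_ids, val_ids, train_ids = plan.iteration(i)
        model = build_model(spec, input_size=cfg.target_size,
                            rng=np.random.default_rng(pre_tc.seed))
        model.load_state_dict(pretrained_state)
        model.freeze_fraction = cfg.finetune_freeze
        tc = replace(fine_tc, seed=fine_tc.seed + 100 * i)
        model = finetune(model, split.finetune.by_ids(train_ids),
                         split.finetune.by_ids(val_ids), tc, pre_cfg, aug_cfg).model
        probs, truths = predict_probs(model, split.finetune.by_ids(test_ids),
                                      pre_cfg, cfg.batch_size)
        results["twostage"]["reports"].append(evaluate_predictions(probs, truths))
        results["twostage"]["probs"].append(probs)
        results["twostage"]["truths"].append(truths)
    return plan, results


def _comparison_table(summaries: dict[str, CVSummary]) -> pd.DataFrame:
    frames = []
    for method, summary in summaries.items():
        t = summary.to_table().rename(columns={"value": method})
        frames.append(t.set_index(["class", "metric"]))
    return pd.concat(frames, axis=1).reset_index()


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute a full run; writes artifacts under ``out_dir`` and returns
    the in-memory results (fold reports, summaries, pooled predictions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    params = SynthesisParams(image_size=cfg.image_size, seed=cfg.synthesis_seed)
    corpus = generate_corpus(cfg.counts, params, cfg.synthesis_seed)
    corpus.to_csv(out / "manifest.csv")

    pre_cfg = PreprocessConfig(target_size=cfg.target_size)
    aug_cfg = AugmentationConfig() if cfg.augment else None

    comparison = any(m in ("ros", "rus") for m in cfg.methods)
    if comparison:
        plan, results = _comparison_mode(corpus, cfg, pre_cfg, aug_cfg)
    else:
        plan, results = _twostage_protocol(corpus, cfg, pre_cfg, aug_cfg)
    plan.to_csv(out / "fold_plan.csv")

    summaries = {m: aggregate(r["reports"], ddof=cfg.ddof) for m, r in results.items()}
    _comparison_table(summaries).to_csv(out / "comparison.csv", index=False)

    band_rows = []
    for method, r in results.items():
        for cname in CLASSES:
            curves = [rep.roc[cname] for rep in r["reports"] if cname in rep.roc]
            if len(curves) >= 2:
                grid, mean_tpr, std_tpr = roc_band(curves)
                band_rows.extend(
                    {"method": method, "class": cname, "fpr": f,
                     "mean_tpr": m_, "std_tpr": s}
                    for f, m_, s in zip(grid, mean_tpr, std_tpr)
                )
    pd.DataFrame(band_rows).to_csv(out / "roc_band.csv", index=False)

    summary = {
        "config_hash": cfg.hash(),
        "config": asdict(cfg),
        "corpus_counts": corpus.counts,
        "methods": {},
    }
    for method, r in results.items():
        s = summaries[method]
        summary["methods"][method] = {
            "fold_reports": [
                {
                    "confusion_matrix": rep.cm.tolist(),
                    "per_class": {
                        c: {k: v for k, v in m.items() if k != "degenerate"}
                        for c, m in rep.per_class.items()
                    },
                    "macro": rep.macro,
                    "overall_accuracy": rep.overall_accuracy,
                }
                for rep in r["reports"]
            ],
            "summary": {
                "per_class": s.per_class,
                "macro": s.macro,
                "overall_accuracy": s.overall_accuracy,
            },
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    results_out = {
        m: {
            "reports": r["reports"],
            "summary": summaries[m],
            "pooled_probs": np.concatenate(r["probs"]),
            "pooled_truths": np.concatenate(r["truths"]),
        }
        for m, r in results.items()
    }
    results_out["fold_plan"] = plan
    results_out["corpus"] = corpus
    return results_out
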