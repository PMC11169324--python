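"""End-to-end experiment pipeline: simulate → train → saliency → assess → report.

:func:`run_pipeline` executes the full study shape on a phantom dataset and
writes CSV/JSON analogues of a classification-performance table, the
per-variant consistency tables (S_o and S_h), area-ratio summaries,
bar-plot data of overall medians, the interobserver annotation-area tests,
and a manifest recording every seed.  A failure in any stage raises
:class:`StageError` naming the stage; outputs written so far are preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .classifier import ModelSpec, TrainConfig, evaluate, train
from .consistency import (ConsistencyRecord, aggregate, area_ratio_analysis,
                          make_record, records_to_frame)
from .dataset import DatasetBundle, MontageSettings, generate_dataset
from .errors import CamvalError, ConfigurationError
from .phantom import AnnotatorProfile, PhantomConfig, default_profiles
from .saliency import binarize_original, binarize_otsu, score_cam
from .stats import annotation_area_analysis


class StageError(CamvalError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """Structured configuration for the full run (YAML-loadable)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    montage: MontageSettings = field(default_factory=MontageSettings)
    model: ModelSpec = field(default_factory=lambda: ModelSpec())
    train: TrainConfig = field(default_factory=TrainConfig)
    n_pos: int = 130
    n_neg: int = 130
    split_ratio: float = 0.85
    n_test: tuple[int, int] | None = (30, 30)
    profiles: tuple[AnnotatorProfile, ...] = ()
    n_boot: int = 2000
    ci_level: float = 0.95
    saliency_layer: str = ""  # empty -> last conv block
    activation_floor: float = 0.0
    seed: int = 0

    def resolved_profiles(self) -> list[AnnotatorProfile]:
        return list(self.profiles) or default_profiles(self.seed)

    def resolved_layer(self) -> str:
        return self.saliency_layer or self.model.last_conv_layer


def _expected_input_size(cfg: PipelineConfig) -> tuple[int, int]:
    rows, cols = cfg.montage.layout
    return (rows * cfg.phantom.image_size, cols * cfg.phantom.image_size)


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Build a PipelineConfig from YAML (per-stage sections) plus overrides."""
    doc: dict[str, Any] = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        doc = {**doc, **{k: v for k, v in overrides.items() if v is not None}}

    seed = int(doc.get("seed", 0))
    ph = doc.get("phantom", {})
    from .phantom import _default_features

    feats = dict(_default_features())
    for kind, spec in (ph.get("features") or {}).items():
        if kind not in feats:
            raise ConfigurationError(f"unknown feature kind {kind!r}")
        updates = {k: tuple(v) for k, v in spec.items()}
        feats[kind] = dataclasses.replace(feats[kind], **updates)
    phantom = PhantomConfig(
        image_size=int(ph.get("image_size", 48)),
        slices_per_case=int(ph.get("slices_per_case", 30)),
        feature_params=feats,
        noise_sd=float(ph.get("noise_sd", 4.0)),
        seed=int(ph.get("seed", seed)),
    )
    mo = doc.get("montage", {})
    montage = MontageSettings(
        count=int(mo.get("count", 6)),
        interval=int(mo.get("interval", 5)),
        layout=tuple(mo.get("layout", (3, 2))),
        orientation=str(mo.get("orientation", "vertical")),
        train_montages_per_case=int(mo.get("train_montages_per_case", 1)),
        test_montages_per_case=int(mo.get("test_montages_per_case", 5)),
    )
    md = doc.get("model", {})
    rows, cols = montage.layout
    model = ModelSpec(
        backbone=str(md.get("backbone", "tiny")),
        h1=int(md.get("h1", 16)), h2=int(md.get("h2", 8)),
        input_size=tuple(md.get("input_size",
                                (rows * phantom.image_size,
                                 cols * phantom.image_size))),
        seed=int(md.get("seed", seed)),
    )
    tr = doc.get("train", {})
    td = TrainConfig()  # single source of the training defaults
    train_cfg = TrainConfig(
        learning_rate=float(tr.get("learning_rate", td.learning_rate)),
        lr_decay=float(tr.get("lr_decay", td.lr_decay)),
        decay_mode=str(tr.get("decay_mode", td.decay_mode)),
        patience=int(tr.get("patience", td.patience)),
        max_epochs=int(tr.get("max_epochs", td.max_epochs)),
        batch_size=int(tr.get("batch_size", td.batch_size)),
        val_fraction=float(tr.get("val_fraction", td.val_fraction)),
        max_restarts=int(tr.get("max_restarts", td.max_restarts)),
        restart_val_loss=float(tr.get("restart_val_loss", td.restart_val_loss)),
        seed=int(tr.get("seed", seed)),
    )
    ds = doc.get("dataset", {})
    profiles = tuple(
        AnnotatorProfile(
            annotator_id=str(p["annotator_id"]),
            area_scale=float(p.get("area_scale", 1.0)),
            boundary_jitter_sd=float(p.get("boundary_jitter_sd", 1.0)),
            omission_prob=float(p.get("omission_prob", 0.05)),
            empty_prob=float(p.get("empty_prob", 0.0)),
            # distinct per-annotator streams unless a seed is given
            seed=int(p.get("seed", seed + i)),
        )
        for i, p in enumerate(doc.get("annotators", []))
    )
    n_test = ds.get("n_test", (30, 30))
    sal = doc.get("saliency", {})
    return PipelineConfig(
        phantom=phantom, montage=montage, model=model, train=train_cfg,
        n_pos=int(ds.get("n_pos", 130)), n_neg=int(ds.get("n_neg", 130)),
        split_ratio=float(ds.get("split_ratio", 0.85)),
        n_test=None if n_test is None else tuple(int(v) for v in n_test),
        profiles=profiles,
        n_boot=int(doc.get("evaluate", {}).get("n_boot", 2000)),
        ci_level=float(doc.get("evaluate", {}).get("ci_level", 0.95)),
        saliency_layer=str(sal.get("layer", "")),
        activation_floor=float(sal.get("activation_floor", 0.0)),
        seed=seed,
    )


def assess_saliency(model, bundle: DatasetBundle, layer: str, model_id: str,
                    activation_floor: float = 0.0) -> list[ConsistencyRecord]:
    """Score-CAM every annotated positive test montage and score all masks.

    Saliency targets the true class of the image.  Records compare each
    binarized variant (S_o, S_h) with each annotator's mask.
    """
    from .montage import normalize_image

    annotated = sorted({mid for mid, _ in bundle.annotator_masks})
    by_id = {m.montage_id: m for m in bundle.test_montages}
    records: list[ConsistencyRecord] = []
    for mid in annotated:
        m = by_id[mid]
        smap = score_cam(model, normalize_image(m.image), target_class=m.label,
                         layer_name=layer, model_id=model_id)
        variants = [binarize_original(smap, activation_floor), binarize_otsu(smap)]
        for (mid2, annot), g in bundle.annotator_masks.items():
            if mid2 != mid:
                continue
            for b in variants:
                records.append(make_record(mid, annot, model_id, b.variant,
                                           b.mask, g))
    return records


def run_pipeline(config: PipelineConfig | str | Path | None = None,
                 outdir: str | Path = "camval_run") -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``."""
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, e) from e
        return deco

    @stage("simulate")
    def bundle() -> DatasetBundle:
        return generate_dataset(
            config.phantom, config.n_pos, config.n_neg,
            config.resolved_profiles(), split_ratio=config.split_ratio,
            seed=config.seed, montage_settings=config.montage,
            n_test=config.n_test,
        )

    @stage("train")
    def result():
        spec = dataclasses.replace(config.model,
                                   input_size=_expected_input_size(config))
        return train(spec, config.train, montages=bundle.train_montages)

    result.log.to_csv(outdir / "training_log.csv", index=False)

    @stage("evaluate")
    def metrics():
        return evaluate(result.model, montages=bundle.test_montages,
                        n_boot=config.n_boot, ci_level=config.ci_level,
                        seed=config.seed)

    cio.save_json(outdir / "classification_metrics.json", metrics.to_dict())
    report["classification"] = metrics.to_dict()

    model_id = config.model.backbone

    @stage("saliency")
    def records():
        return assess_saliency(result.model, bundle, config.resolved_layer(),
                               model_id, config.activation_floor)

    records_to_frame(records).to_csv(outdir / "consistency_records.csv", index=False)

    @stage("assess")
    def summaries():
        summary = aggregate(records)
        ratios = area_ratio_analysis(records)
        return summary, ratios

    summary, ratios = summaries
    summary.table.to_csv(outdir / "consistency_summary.csv", index=False)
    summary.excluded.to_csv(outdir / "consistency_exclusions.csv", index=False)
    ratios.to_csv(outdir / "area_ratios.csv", index=False)
    bars = summary.table[["model_id", "variant", "metric", "overall_median"]]
    bars.to_csv(outdir / "overall_median_bars.csv", index=False)
    report["consistency"] = {
        "overall_medians": {
            f"{r.variant}:{r.metric}": r.overall_median
            for r in summary.table.itertuples()
        },
        "n_records": len(records),
    }

    @stage("report")
    def variability():
        masks_by_annot: dict[str, list[np.ndarray]] = {}
        for (mid, annot), mask in sorted(bundle.annotator_masks.items()):
            masks_by_annot.setdefault(annot, []).append(mask)
        return annotation_area_analysis(masks_by_annot)

    var_out = {
        "omnibus": {"statistic": variability.omnibus.statistic,
                    "p_value": variability.omnibus.p_value,
                    "groups": list(variability.omnibus.groups)},
        "pairwise": [
            {"groups": list(r.groups), "z": r.statistic, "p_value": r.p_value}
            for r in variability.pairwise
        ],
        "flagged_annotators": variability.flagged,
        "median_area": {a: float(np.median(v))
                        for a, v in variability.areas.items()},
    }
    cio.save_json(outdir / "annotator_variability.json", var_out)
    report["annotator_variability"] = var_out

    manifest = dict(bundle.manifest)
    manifest["train_best_epoch"] = result.best_epoch
    manifest["model"] = config.model.to_dict()
    manifest["saliency_layer"] = config.resolved_layer()
    cio.save_json(outdir / "manifest.json", manifest)
    report["manifest"] = manifest
    cio.save_json(outdir / "report.json", report)
    return report
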