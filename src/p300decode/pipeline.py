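"""Seeded, configured, cached orchestration of the full analysis pipeline.

Stages: simulate -> (optional continuous round-trip) preprocess -> train ->
baseline -> saliency -> report. Each stage writes its outputs plus a config
hash under ``out/<stage>/``; re-running with an unchanged config reuses the
cached artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline as bl
from . import sim
from .epochs import EpochSet
from .nn import EEGNetConfig, TrainConfig
from .nn.train import accuracy_table, evaluate_loso, train_on
from .preprocess import preprocess_recording
from .saliency import (
    average_maps,
    latency_trend,
    most_varied_interval,
    saliency_for_epochs,
    spatial_profile,
    temporal_profile,
)
from .stats import component_amplitude, grand_average, paired_ttest

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "train", "baseline", "saliency", "report")


@dataclass
class AnalysisOptions:
    electrode: str = "Pz"
    window_width_ms: float = 100.0
    window_step_ms: float = 5.0
    window_statistic: str = "mean"
    saliency_class: int = 1


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation scale
    n_subjects: int = 2
    n_sessions: int = 2
    blocks_per_session: int = 2
    noise_sigma: float = 2.0
    channel_correlation: float = 0.1
    roundtrip_preprocess: bool = False  # re-derive epochs via continuous export
    # preprocessing options (used when roundtrip_preprocess is on)
    band_hz: tuple[float, float] | None = (2.0, 30.0)
    notch: bool = True
    censor: bool = False  # simulated exports are already schedule-complete
    # model / training
    model: EEGNetConfig = field(default_factory=EEGNetConfig)
    training: TrainConfig = field(default_factory=lambda: TrainConfig(max_epochs=10, patience=4, dtype="float32"))
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    # ------------------------------------------------------------------ yaml
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = EEGNetConfig(**d["model"])
        if "training" in d and isinstance(d["training"], dict):
            d["training"] = TrainConfig(**d["training"])
        if "analysis" in d and isinstance(d["analysis"], dict):
            d["analysis"] = AnalysisOptions(**d["analysis"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if d.get("band_hz") is not None:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def sim_config(self) -> sim.SimConfig:
        return sim.SimConfig(
            seed=self.seed,
            n_subjects=self.n_subjects,
            n_sessions=self.n_sessions,
            blocks_per_session=self.blocks_per_session,
            noise=sim.NoiseSpec(sigma=self.noise_sigma, channel_correlation=self.channel_correlation),
        )

    def config_hash(self, stage: str) -> str:
        payload = json.dumps({"stage": stage, "config": self.to_dict()}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    return Path(cfg.out_dir) / stage


def _is_cached(cfg: RunConfig, stage: str) -> bool:
    marker = _stage_dir(cfg, stage) / "stage.json"
    if not marker.exists():
        return False
    return json.loads(marker.read_text()).get("config_hash") == cfg.config_hash(stage)


def _mark_done(cfg: RunConfig, stage: str, seconds: float) -> None:
    d = _stage_dir(cfg, stage)
    d.mkdir(parents=True, exist_ok=True)
    (d / "stage.json").write_text(
        json.dumps({"config_hash": cfg.config_hash(stage), "seconds": round(seconds, 2)})
    )


# ------------------------------------------------------------------- stages --
def stage_simulate(cfg: RunConfig) -> EpochSet:
    sim_cfg = cfg.sim_config()
    dataset = sim.generate_dataset(sim_cfg)
    d = _stage_dir(cfg, "simulate")
    dataset.save(d)
    (d / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(sim_cfg), indent=2, default=lambda o: np.asarray(o).tolist())
    )
    return dataset


def stage_preprocess(cfg: RunConfig) -> EpochSet:
    """Round-trip the simulated epochs through the continuous-domain chain.

    When ``roundtrip_preprocess`` is off, the simulated epochs are used
    directly (they are already in the analysis window).
    """
    dataset = EpochSet.load(_stage_dir(cfg, "simulate"))
    if cfg.roundtrip_preprocess:
        parts = []
        for subj in np.unique(dataset.meta["subject"]):
            rec = sim.export_continuous(dataset.query(f"subject == {subj}"))
            parts.append(
                preprocess_recording(
                    rec,
                    notch=cfg.notch,
                    band=tuple(cfg.band_hz) if cfg.band_hz else None,
                    censor=cfg.censor,
                )
            )
        dataset = EpochSet.concatenate(parts)
    dataset.save(_stage_dir(cfg, "preprocess"))
    return dataset


def stage_train(cfg: RunConfig) -> pd.DataFrame:
    dataset = EpochSet.load(_stage_dir(cfg, "preprocess"))
    # all stage randomness descends from the single global seed
    tcfg = dataclasses.replace(cfg.training, seed=cfg.training.seed + 1009 * cfg.seed)
    metrics, models = evaluate_loso(dataset, cfg.model, tcfg)
    d = _stage_dir(cfg, "train")
    d.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(d / "metrics.tsv", sep="\t", index=False)
    for scenario in dataset.meta["scenario"].unique():
        accuracy_table(metrics, scenario).to_csv(d / f"accuracy_{scenario}.tsv", sep="\t")
    for subj, model in models.items():
        model.save(d / f"model_subject{subj}.npz")
        history = getattr(model, "history", None)
        if history is not None:
            history.to_csv(d / f"history_subject{subj}.tsv", sep="\t", index=False)
    return metrics

def stage_baseline(cfg: RunConfig) -> pd.DataFrame:
    dataset = EpochSet.load(_stage_dir(cfg, "preprocess"))
    metrics = bl.evaluate_loso_lr(dataset)
    d = _stage_dir(cfg, "baseline")
    d.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(d / "metrics.tsv", sep="\t", index=False)
    return metrics


def stage_saliency(cfg: RunConfig) -> dict:
    from .nn.model import EEGNet

    dataset = EpochSet.load(_stage_dir(cfg, "preprocess"))
    train_dir = _stage_dir(cfg, "train")
    opts = cfg.analysis
    maps = []
    for subj in np.unique(dataset.meta["subject"]):
        model = EEGNet.load(train_dir / f"model_subject{subj}.npz", cfg.model)
        held = dataset.query(f"subject == {subj}")
        maps.append(saliency_for_epochs(model, held, class_index=opts.saliency_class))
    avg = average_maps(maps)
    sp = spatial_profile(avg)
    tp = temporal_profile(avg)
    interval = most_varied_interval(
        avg,
        electrode=opts.electrode,
        width_ms=opts.window_width_ms,
        step_ms=opts.window_step_ms,
        statistic=opts.window_statistic,
    )
    d = _stage_dir(cfg, "saliency")
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(avg.values, index=list(avg.layout.names), columns=avg.times).to_csv(
        d / "saliency_map.tsv", sep="\t"
    )
    sp.rename("mean_abs_gradient").to_csv(d / "spatial_profile.tsv", sep="\t")
    tp.rename("mean_abs_gradient").rename_axis("time_ms").to_csv(d / "temporal_profile.tsv", sep="\t")
    result = {
        "spatial_argmax": str(sp.idxmax()),
        "temporal_peak_ms": float(tp.idxmax()),
        "interval": {"start_ms": interval.start_ms, "end_ms": interval.end_ms, "center_ms": interval.center_ms},
    }
    (d / "summary.json").write_text(json.dumps(result, indent=2))
    return result


def stage_report(cfg: RunConfig) -> dict:
    dataset = EpochSet.load(_stage_dir(cfg, "preprocess"))
    cnn = pd.read_csv(_stage_dir(cfg, "train") / "metrics.tsv", sep="\t")
    lr = pd.read_csv(_stage_dir(cfg, "baseline") / "metrics.tsv", sep="\t")
    sal = json.loads((_stage_dir(cfg, "saliency") / "summary.json").read_text())
    cnn_pooled = cnn[cnn["scenario"] == "all"]["accuracy"].to_numpy()
    lr_pooled = lr[lr["scenario"] == "all"]["accuracy"].to_numpy()
    comparison = {}
    if len(cnn_pooled) >= 2:
        t, df, p = bl.compare_models(cnn_pooled, lr_pooled)
        comparison = {"t": t, "df": df, "p": p}
    n_targets = int((dataset.labels == 1).sum())
    n_standards = int((dataset.labels == 0).sum())
    sanity = {
        "epoch_shape_ok": dataset.data.shape[1:] == (8, 201),
        "label_ratio": n_standards / max(n_targets, 1),
        "label_ratio_ok": n_standards == 7 * n_targets,
    }
    erp = {}
    try:
        target_wave = grand_average(dataset, cfg.analysis.electrode, "label == 1")
        p300 = component_amplitude(target_wave, "P300")
        erp = {"p300_peak_uv": p300.value, "p300_latency_ms": p300.peak_latency_ms}
    except ValueError:
        pass
    report = {
        "seed": cfg.seed,
        "cnn_mean_accuracy": float(np.mean(cnn_pooled)),
        "lr_mean_accuracy": float(np.mean(lr_pooled)),
        "model_comparison": comparison,
        "saliency": sal,
        "erp": erp,
        "sanity": sanity,
    }
    d = _stage_dir(cfg, "report")
    d.mkdir(parents=True, exist_ok=True)
    (d / "report.json").write_text(json.dumps(report, indent=2))
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "baseline": stage_baseline,
    "saliency": stage_saliency,
    "report": stage_report,
}

_STAGE_INPUTS = {
    "preprocess": ("simulate",),
    "train": ("preprocess",),
    "baseline": ("preprocess",),
    "saliency": ("preprocess", "train"),
    "report": ("train", "baseline", "saliency"),
}


def run(cfg: RunConfig, force: bool = False) -> dict:
    """Execute the enabled stages in order; returns the final report dict
    (or a per-stage status summary when the report stage is disabled)."""
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(Path(cfg.out_dir) / "config.yaml")
    status: dict[str, str] = {}
    report: dict = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            for dep_of in cfg.stages:
                if stage in _STAGE_INPUTS.get(dep_of, ()) and not _is_cached(cfg, stage):
                    raise RuntimeError(
                        f"stage '{dep_of}' needs disabled stage '{stage}' which has no cached output"
                    )
            status[stage] = "skipped"
            continue
        if not force and _is_cached(cfg, stage):
            status[stage] = "cached"
            continue
        t0 = time.time()
        logger.info("running stage %s", stage)
        out = _STAGE_FUNCS[stage](cfg)
        _mark_done(cfg, stage, time.time() - t0)
        status[stage] = f"done in {time.time() - t0:.1f}s"
        if stage == "report":
            report = out
    return report or {"stages": status}
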