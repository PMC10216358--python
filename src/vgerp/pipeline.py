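"""End-to-end orchestration: epochs -> averaged series -> visibility graphs
-> features -> screening -> PCA -> classifiers -> report bundle.

A :class:`PipelineConfig` (JSON or YAML on disk) fully determines a run;
every output file is regenerated identically from the same config and
seed.  The single global seed fans out to stage seeds by fixed offsets so
stages stay independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import ClassificationReport, EvalProtocol, evaluate
from .features import extract_features
from .preprocess import BAND_ORDER, AveragedCohort, preprocess_cohort
from .selection import SelectionResult, pca_fit_transform, ttest_screen
from .synth import EpochSet, ERPComponent, OscComponent, SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "RunBundle", "run_all", "run_generalization", "StageError"]

# fixed seed offsets per stage
_SYNTH_OFFSET = 0
_REF_OFFSET = 101
_EVAL_OFFSET = 1009


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable to/from JSON or YAML."""

    out_dir: str = "vgerp_run"
    epochs_path: str | None = None
    synth: SyntheticConfig | None = None
    bands: tuple = BAND_ORDER
    bin_s: float = 0.08
    crop: tuple = (-1.0, 2.0)
    pad_s: float = 2.0
    theta: float = 0.25
    alpha: float = 0.01
    select_pair: tuple = ("AD", "RNE")
    eval_pair: tuple | None = None
    protocol: EvalProtocol = field(default_factory=EvalProtocol)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_path is None and self.synth is None:
            raise ValueError("either epochs_path or a synth block is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth") is not None:
            s = dict(d["synth"])
            s["erp_components"] = tuple(
                ERPComponent(**{**c, "channels": _opt_tuple(c.get("channels")),
                                "conditions": _opt_tuple(c.get("conditions"))})
                for c in s.get("erp_components", ())
            )
            s["osc_components"] = tuple(
                OscComponent(**{**c, "channels": _opt_tuple(c.get("channels"))})
                for c in s.get("osc_components", ())
            )
            s["epoch_window"] = tuple(s.get("epoch_window", (-2.0, 2.0)))
            s["channels"] = tuple(s.get("channels", ()))
            s["conditions"] = tuple(s.get("conditions", ()))
            d["synth"] = SyntheticConfig(**s)
        if d.get("protocol") is not None and not isinstance(d["protocol"], EvalProtocol):
            d["protocol"] = EvalProtocol(**d["protocol"])
        for key in ("bands", "crop", "select_pair"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("eval_pair") is not None:
            d["eval_pair"] = tuple(d["eval_pair"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _opt_tuple(v):
    return None if v is None else tuple(v)


@dataclass
class RunBundle:
    """Objects and file paths produced by one pipeline run."""

    config: PipelineConfig
    epochs: EpochSet
    averaged: AveragedCohort
    features: "object"
    selection: SelectionResult
    report: ClassificationReport
    out_dir: Path


def _load_epochs(config: PipelineConfig) -> EpochSet:
    if config.synth is not None:
        synth = dataclasses.replace(
            config.synth, seed=(config.seed + _SYNTH_OFFSET) % (2**31)
        )
        return generate_cohort(synth)
    try:
        return EpochSet.load(config.epochs_path)
    except (OSError, KeyError) as err:
        raise StageError("load", err) from err


def run_all(config: PipelineConfig, write: bool = True) -> RunBundle:
    """Execute every stage and (optionally) write the report bundle.

    Outputs under ``config.out_dir``: the averaged-series container,
    feature matrix CSV, screening CSV, PCA JSON, classification report
    (JSON and rendered text table) and a manifest with the config, seeds
    and package version.
    """
    out = Path(config.out_dir)
    epochs = _load_epochs(config)

    try:
        averaged = preprocess_cohort(
            epochs, bands=list(config.bands), bin_s=config.bin_s,
            crop=config.crop, pad_s=config.pad_s,
        )
    except Exception as err:
        raise StageError("preprocess", err) from err

    try:
        feats, ref = extract_features(
            averaged, theta=config.theta, ref_seed=(config.seed + _REF_OFFSET) % (2**31)
        )
    except Exception as err:
        raise StageError("features", err) from err

    try:
        sel = ttest_screen(feats, *config.select_pair, alpha=config.alpha)
    except Exception as err:
        raise StageError("select", err) from err

    try:
        protocol = dataclasses.replace(
            config.protocol, seed=(config.seed + _EVAL_OFFSET) % (2**31)
        )
        report = evaluate(feats, sel, protocol, eval_pair=config.eval_pair)
    except Exception as err:
        raise StageError("classify", err) from err

    bundle = RunBundle(config, epochs, averaged, feats, sel, report, out)
    if write:
        _write_bundle(bundle, ref)
    return bundle


def run_generalization(
    config: PipelineConfig,
    select_pair: tuple = ("AD", "RNE"),
    eval_pair: tuple = ("pAD", "RNE"),
) -> RunBundle:
    """Screen on one group pair, evaluate the mask on another.

    This is the generalisation path: features discovered on the
    patient-vs-control comparison are reused unchanged to classify a third
    (e.g. prodromal) group against the controls.
    """
    cfg = dataclasses.replace(config, select_pair=tuple(select_pair), eval_pair=tuple(eval_pair))
    return run_all(cfg, write=False)


def _write_bundle(bundle: RunBundle, ref) -> None:
    out = bundle.out_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle.averaged.save(out / "averaged.h5")
    bundle.features.to_csv(out / "features.csv")
    bundle.selection.save(out / "selection.csv")
    bundle.report.to_json(out / "report.json")
    (out / "report.txt").write_text(bundle.report.render_table())

    # refit PCA once on all evaluated rows for the exported projection artifact
    pair = bundle.report.groups
    sub = bundle.features[bundle.features["group"].isin(pair)]
    cols = bundle.selection.selected_columns
    X = sub[cols].to_numpy(dtype=float)
    k = min(bundle.config.protocol.pca_k, X.shape[0] - 1,
            int(np.count_nonzero(X.var(axis=0) > 0)))
    coords, _, proj = pca_fit_transform(X, None, k=max(k, 1), scale=True)
    with open(out / "pca.json", "w") as fh:
        json.dump(proj.to_dict(), fh, sort_keys=True)
    scatter = sub[["group"]].copy()
    scatter["pc1"] = coords[:, 0]
    scatter["pc2"] = coords[:, 1] if coords.shape[1] > 1 else 0.0
    scatter.to_csv(out / "pca_scatter.csv")

    cfg_json = json.dumps(bundle.config.to_dict(), sort_keys=True)
    manifest = {
        "config": bundle.config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": bundle.config.seed,
        "stage_seeds": {
            "synth": (bundle.config.seed + _SYNTH_OFFSET) % (2**31),
            "small_world_ref": (bundle.config.seed + _REF_OFFSET) % (2**31),
            "evaluate": (bundle.config.seed + _EVAL_OFFSET) % (2**31),
        },
        "version": __version__,
        "n_feature_columns": int(bundle.features.shape[1] - 1),
        "n_selected": bundle.selection.n_selected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
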