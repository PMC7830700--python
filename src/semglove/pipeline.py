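"""End-to-end offline pipeline: synthesize -> filter -> featurize ->
train -> predict -> state-filter -> evaluate -> simulate pressure.

The pipeline mirrors the full system flow: single-motion training
trials feed the classifier; held-out alternating-motion sequences (RE,
RS and SF) are decoded window by window, cleaned by the state-exclusion
filter, scored against ground truth, and finally driven through the
simulated pneumatic plant.  Everything is a pure function of the
configuration and the global seed: per-stage seeds are spawned
deterministically from the global one, so re-running reproduces every
artifact bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as sio
from .control_sim import ControllerConfig, Mapping, PressureTrace, simulate_commands
from .errors import PipelineStageError
from .features import FeatureMatrix, rms_features
from .motions import MOTION_ORDER, Motion
from .preprocess import preprocess
from .recognizer import ClassifierConfig, TrainedModel, predict, split_dataset, train_classifier
from .recording import SemgRecording, concatenate
from .state_exclusion import (
    EvaluationReport,
    TransitionModel,
    apply_state_exclusion,
    count_loops,
    evaluate,
)
from .synth import (
    SequenceProtocol,
    SyntheticConfig,
    default_protocols,
    generate_dataset,
    generate_sequence,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full offline run."""

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    transitions: TransitionModel = field(default_factory=TransitionModel)
    apply_filters: bool = True  # band-pass + notch before featurization
    notch: bool = True
    window_ms: float = 500.0
    train_fraction: float = 0.7
    mapping: Mapping = "worn"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        if "synth" in raw:
            synth = dict(raw["synth"])
            if "amplitudes" in synth:
                synth["amplitudes"] = {
                    Motion(k): tuple(v) for k, v in synth["amplitudes"].items()
                }
            if "noise_band" in synth:
                synth["noise_band"] = tuple(synth["noise_band"])
            kwargs["synth"] = SyntheticConfig(**synth)
        if "classifier" in raw:
            clf = dict(raw["classifier"])
            if "hidden_sizes" in clf:
                clf["hidden_sizes"] = tuple(clf["hidden_sizes"])
            kwargs["classifier"] = ClassifierConfig(**clf)
        if "controller" in raw:
            ctl = dict(raw["controller"])
            for key in ("worn_pressure", "unloaded_pressure", "tolerance"):
                if key in ctl:
                    ctl[key] = {Motion(k): float(v) for k, v in ctl[key].items()}
            kwargs["controller"] = ControllerConfig(**ctl)
        if "transitions" in raw:
            pairs = frozenset(
                (Motion(p[0]), Motion(p[1])) for p in raw["transitions"]
            )
            kwargs["transitions"] = TransitionModel(pairs)
        for key in ("apply_filters", "notch", "window_ms", "train_fraction",
                    "mapping", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class SequenceResult:
    """Decoded, filtered and scored result for one test sequence."""

    protocol: SequenceProtocol
    truth: list[Motion]
    predicted_raw: list[Motion]
    predicted_filtered: list[Motion]
    loops: int
    trace: PressureTrace


@dataclass
class PipelineResult:
    """Everything the offline run produces."""

    model: TrainedModel
    holdout_report: EvaluationReport  # 30% held-out single-motion windows
    report_raw: EvaluationReport  # sequence windows, network only
    report_filtered: EvaluationReport  # sequence windows, after state exclusion
    sequences: dict[str, SequenceResult]
    timings_s: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Held-out single-motion windows (network only):",
            f"  mean accuracy = {self.holdout_report.mean_accuracy:.2f}%",
            "Sequence windows, network only:",
            self._indent(self.report_raw.to_text()),
            "Sequence windows, after state exclusion:",
            self._indent(self.report_filtered.to_text()),
            "Recognized loops per sequence: "
            + ", ".join(f"{k}={v.loops}" for k, v in self.sequences.items()),
        ]
        return "\n".join(lines)

    @staticmethod
    def _indent(text: str) -> str:
        return "\n".join("  " + line for line in text.splitlines())


def _stage(name: str, detail: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(
                    f"stage '{name}' failed" + (f" on {detail}" if detail else "")
                    + f": {exc}"
                ) from exc
            return False

    return _Ctx()


def run_pipeline(
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    write_recordings: bool = False,
) -> PipelineResult:
    """Execute the full offline pipeline for the three test protocols.

    With ``outdir`` set, features, label streams, pressure traces and a
    JSON + text summary are written there; ``write_recordings``
    additionally dumps every synthetic recording as CSV.
    """
    cfg = cfg or PipelineConfig()
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    dataset_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    split_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    net_seed = int(seeds[2].generate_state(1)[0] % (2**31))
    seq_seeds = seeds[3].spawn(3)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def clock(name: str, t0: float) -> None:
        timings[name] = time.perf_counter() - t0

    # 1. synthesize + preprocess + featurize the single-motion corpus
    t0 = time.perf_counter()
    with _stage("simulate-data"):
        dataset = generate_dataset(cfg.synth, dataset_seed)
    clock("simulate_data", t0)

    def prep(rec: SemgRecording) -> SemgRecording:
        if not cfg.apply_filters:
            return rec
        return preprocess(rec, notch_hz=50.0 if cfg.notch else None)

    t0 = time.perf_counter()
    with _stage("featurize"):
        per_motion_features = []
        for motion in MOTION_ORDER:
            trials = [prep(r) for r in dataset[motion]]
            feats = rms_features(concatenate(trials), cfg.window_ms)
            per_motion_features.append(feats)
        all_features = FeatureMatrix(
            np.vstack([f.values for f in per_motion_features]),
            np.concatenate([f.labels for f in per_motion_features]),
            cfg.window_ms,
            per_motion_features[0].samples_per_window,
        )
    clock("featurize", t0)
    if out is not None:
        sio.write_features(all_features, out / "features_single_motion.csv")

    # 2. split and train
    t0 = time.perf_counter()
    with _stage("train"):
        train, holdout = split_dataset(all_features, cfg.train_fraction, split_seed)
        model = train_classifier(train, replace(cfg.classifier, seed=net_seed))
    clock("train", t0)
    if out is not None:
        model.save(out / "model.json")

    with _stage("evaluate", "held-out single-motion windows"):
        holdout_pred, _ = predict(model, holdout)
        holdout_report = evaluate(holdout_pred, [Motion(l) for l in holdout.labels])

    # 3. decode, filter, score and drive each test sequence
    sequences: dict[str, SequenceResult] = {}
    raw_all: list[Motion] = []
    filt_all: list[Motion] = []
    truth_all: list[Motion] = []
    t0 = time.perf_counter()
    for protocol, seq_seed in zip(default_protocols(), seq_seeds):
        name = protocol.name
        with _stage("recognize", f"sequence {name}"):
            rec = generate_sequence(protocol, cfg.synth, seq_seed)
            feats = rms_features(prep(rec), cfg.window_ms)
            truth = [Motion(l) for l in feats.labels]
            pred_raw, _ = predict(model, feats)
        with _stage("filter-states", f"sequence {name}"):
            pred_filt = apply_state_exclusion(pred_raw, cfg.transitions)
            loops = count_loops(pred_filt, protocol)
        with _stage("simulate-control", f"sequence {name}"):
            trace = simulate_commands(pred_filt, cfg.controller, cfg.mapping)
        sequences[name] = SequenceResult(
            protocol, truth, pred_raw, pred_filt, loops, trace
        )
        raw_all += pred_raw
        filt_all += pred_filt
        truth_all += truth
        if out is not None:
            if write_recordings:
                sio.write_recording(rec, out / f"sequence_{name}.csv")
            sio.write_labels(pred_raw, out / f"labels_{name}_raw.txt")
            sio.write_labels(pred_filt, out / f"labels_{name}_filtered.txt")
            trace.to_frame().to_csv(
                out / f"trace_{name}.csv", index=False, float_format="%.6g"
            )
    clock("sequences", t0)

    with _stage("evaluate", "sequence windows"):
        report_raw = evaluate(raw_all, truth_all)
        report_filtered = evaluate(filt_all, truth_all)

    result = PipelineResult(
        model, holdout_report, report_raw, report_filtered, sequences, timings
    )
    if out is not None:
        if write_recordings:
            for motion, trials in dataset.items():
                for i, rec in enumerate(trials):
                    sio.write_recording(
                        rec, out / f"trial_{motion.value}_{i:02d}.csv"
                    )
        (out / "summary.txt").write_text(result.summary() + "\n")
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "holdout": holdout_report.to_dict(),
                    "sequence_raw": report_raw.to_dict(),
                    "sequence_filtered": report_filtered.to_dict(),
                    "loops": {k: v.loops for k, v in sequences.items()},
                    "timings_s": timings,
                    "seed": cfg.seed,
                },
                indent=2,
            )
        )
    return result
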