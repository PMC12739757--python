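"""Configuration, HDF5 containers, and end-to-end orchestration.

The pipeline runs simulate -> preprocess -> featurize -> cross-validated
training.  Stage artifacts are single-file HDF5 containers; every
artifact embeds the hash of the configuration slice that produced it,
and downstream stages refuse mismatched inputs.  Configuration is YAML
with strict (no-unknown-keys) validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .features import (
    EYE_FEATURE_NAMES,
    extract_de_sequence,
    extract_eye_features,
    extract_peripheral_sequence,
    peripheral_feature_names,
)
from .model import ModelConfig, default_model_config
from .preprocessing import (
    BandDefinition,
    DEAP_BANDS,
    bandpass,
    decompose_bands,
    remove_baseline,
)
from .synthetic import (
    EyeEventStream,
    MultimodalRecording,
    SimulationConfig,
    generate_dataset,
)
from .training import CVReport, FeaturizedDataset, TrainConfig, run_cv

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "plan",
    "save_recordings",
    "load_recordings",
    "featurize_recordings",
    "save_features",
    "load_features",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelKnobs:
    """Exposed architecture hyperparameters (full specs built from these)."""

    n_heads: int = 4
    model_dim: int = 64
    fc_hidden: int = 64
    dropout_rate: float = 0.3
    seed: int = 0

    def build(self, n_classes: int) -> ModelConfig:
        return default_model_config(
            n_classes=n_classes, seed=self.seed, dropout_rate=self.dropout_rate,
            n_heads=self.n_heads, model_dim=self.model_dim, fc_hidden=self.fc_hidden)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the pipeline end to end."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bands: tuple[BandDefinition, ...] = DEAP_BANDS
    broadband: BandDefinition | None = BandDefinition("broad", 4.0, 45.0)
    window_seconds: float = 4.0
    use_eye_features: bool = True
    model: ModelKnobs = field(default_factory=ModelKnobs)
    training: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        nyquist = self.simulation.eeg_rate / 2
        for band in self.bands + ((self.broadband,) if self.broadband else ()):
            if band.high >= nyquist:
                raise ValueError(
                    f"band {band.name!r} high edge {band.high} Hz >= Nyquist {nyquist} Hz"
                )
        n_windows = int(self.simulation.trial_seconds // self.window_seconds)
        t = n_windows
        for pool in (2, 2, 2):
            t //= pool
        if t < 1:
            raise ValueError(
                f"{n_windows} windows do not survive three pool-2 stages; "
                "increase trial_seconds or decrease window_seconds"
            )

    # -- config hashing ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "bands": [[b.name, b.low, b.high] for b in self.bands],
            "broadband": ([self.broadband.name, self.broadband.low, self.broadband.high]
                          if self.broadband else None),
            "window_seconds": self.window_seconds,
            "use_eye_features": self.use_eye_features,
            "model": dataclasses.asdict(self.model),
            "training": dataclasses.asdict(self.training),
        }

    def stage_hash(self, stage: str) -> str:
        """Hash of the configuration slice that determines a stage's output."""
        d = self.to_dict()
        slices = {
            "simulate": ["simulation"],
            "featurize": ["simulation", "bands", "broadband", "window_seconds",
                          "use_eye_features"],
            "train": ["simulation", "bands", "broadband", "window_seconds",
                      "use_eye_features", "model", "training"],
        }
        payload = {k: d[k] for k in slices[stage]}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


_TOP_KEYS = {"simulation", "bands", "broadband", "window_seconds",
             "use_eye_features", "model", "training"}


def _build_dataclass(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid {context} config: {err}") from err


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; missing keys take defaults.

    Unknown keys are an error (no silent typo tolerance); validation
    failures name the offending field.  An empty file yields the
    all-defaults configuration.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    if "simulation" in data:
        kwargs["simulation"] = _build_dataclass(SimulationConfig, data["simulation"],
                                                "simulation")
    if "bands" in data:
        kwargs["bands"] = tuple(BandDefinition(*b) for b in data["bands"])
    if "broadband" in data:
        bb = data["broadband"]
        kwargs["broadband"] = BandDefinition(*bb) if bb is not None else None
    if "window_seconds" in data:
        kwargs["window_seconds"] = float(data["window_seconds"])
    if "use_eye_features" in data:
        kwargs["use_eye_features"] = bool(data["use_eye_features"])
    if "model" in data:
        kwargs["model"] = _build_dataclass(ModelKnobs, data["model"], "model")
    if "training" in data:
        kwargs["training"] = _build_dataclass(TrainConfig, data["training"], "training")
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def plan(config: PipelineConfig) -> dict:
    """Planned shapes for a dry run — no data is generated."""
    sim = config.simulation
    n_trials = sim.n_subjects * sim.trials_per_subject
    n_windows = int(sim.trial_seconds // config.window_seconds)
    eeg_dim = sim.n_eeg_channels * len(config.bands)
    peri_dim = 3 * sim.n_peri_channels + (31 if config.use_eye_features else 0)
    t = n_windows
    for pool in (2, 2, 2):
        t //= pool
    return {
        "n_trials": n_trials,
        "n_windows": n_windows,
        "eeg_feature_dim": eeg_dim,
        "peri_feature_dim": peri_dim,
        "branch_output_windows": t,
        "fused_dim": 2 * config.model.model_dim,
        "n_classes": sim.n_classes,
        "simulate_hash": config.stage_hash("simulate"),
        "featurize_hash": config.stage_hash("featurize"),
    }


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def save_recordings(recordings: list[MultimodalRecording], path: str | Path,
                    config: PipelineConfig) -> None:
    """One group per subject, one subgroup per trial, signal datasets + attrs."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = config.stage_hash("simulate")
        fh.attrs["config_yaml"] = yaml.safe_dump(config.to_dict(), sort_keys=True)
        counters: dict[int, int] = {}
        for rec in recordings:
            trial_idx = counters.get(rec.subject_id, 0)
            counters[rec.subject_id] = trial_idx + 1
            grp = fh.require_group(f"subject_{rec.subject_id:02d}").create_group(
                f"trial_{trial_idx:03d}")
            grp.create_dataset("eeg", data=rec.eeg)
            grp.create_dataset("peripheral", data=rec.peripheral)
            grp.create_dataset("pupil", data=rec.eye_events.pupil)
            grp.create_dataset("fixations", data=rec.eye_events.fixations)
            grp.create_dataset("saccades", data=rec.eye_events.saccades)
            grp.create_dataset("blinks", data=rec.eye_events.blinks)
            grp.attrs.update({
                "label": rec.label,
                "subject_id": rec.subject_id,
                "eeg_rate": rec.eeg_rate,
                "peri_rate": rec.peri_rate,
                "pupil_rate": rec.eye_events.pupil_rate,
                "baseline_seconds": rec.baseline_seconds,
                "duration_seconds": rec.eye_events.duration_seconds,
            })


def load_recordings(path: str | Path,
                    expected_hash: str | None = None) -> list[MultimodalRecording]:
    recordings = []
    with h5py.File(path, "r") as fh:
        stored = fh.attrs.get("config_hash")
        if expected_hash is not None and stored != expected_hash:
            raise ValueError(
                f"recordings at {path} were produced by config {stored}, "
                f"expected {expected_hash}"
            )
        for subject_key in sorted(fh.keys()):
            for trial_key in sorted(fh[subject_key].keys()):
                grp = fh[subject_key][trial_key]
                eye = EyeEventStream(
                    fixations=grp["fixations"][()],
                    saccades=grp["saccades"][()],
                    blinks=grp["blinks"][()],
                    pupil=grp["pupil"][()],
                    pupil_rate=float(grp.attrs["pupil_rate"]),
                    duration_seconds=float(grp.attrs["duration_seconds"]),
                )
                recordings.append(MultimodalRecording(
                    eeg=grp["eeg"][()],
                    peripheral=grp["peripheral"][()],
                    eye_events=eye,
                    label=int(grp.attrs["label"]),
                    subject_id=int(grp.attrs["subject_id"]),
                    eeg_rate=float(grp.attrs["eeg_rate"]),
                    peri_rate=float(grp.attrs["peri_rate"]),
                    baseline_seconds=float(grp.attrs["baseline_seconds"]),
                ))
    return recordings


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def featurize_recordings(recordings: list[MultimodalRecording],
                         config: PipelineConfig) -> FeaturizedDataset:
    """Raw trials -> aligned EEG/peripheral feature tensors.

    EEG: baseline removal, broadband filtering, band decomposition, then
    windowed band-DE features.  Peripheral: baseline removal and windowed
    (mean, variance, DE) statistics; when enabled, the 31-entry eye
    vector is tiled across windows and concatenated to each peripheral
    row so both branches receive equal-length sequences.
    """
    X_eeg, X_peri, labels, subjects = [], [], [], []
    for i, rec in enumerate(recordings):
        try:
            eeg = remove_baseline(rec.eeg, rec.eeg_rate, rec.baseline_seconds)
            if config.broadband is not None:
                eeg = bandpass(eeg, rec.eeg_rate, config.broadband)
            decomp = decompose_bands(eeg, rec.eeg_rate, config.bands)
            eeg_seq = extract_de_sequence(decomp, config.window_seconds)

            peri = remove_baseline(rec.peripheral, rec.peri_rate, rec.baseline_seconds)
            peri_seq = extract_peripheral_sequence(peri, rec.peri_rate,
                                                   config.window_seconds)
            peri_values = peri_seq.values
            if config.use_eye_features:
                eye = extract_eye_features(rec.eye_events)
                tiled = np.tile(eye.values, (peri_values.shape[0], 1))
                peri_values = np.concatenate([peri_values, tiled], axis=1)
            if eeg_seq.n_windows != peri_values.shape[0]:
                raise ValueError(
                    f"window misalignment: EEG {eeg_seq.n_windows} vs "
                    f"peripheral {peri_values.shape[0]}"
                )
        except ValueError as err:
            raise ValueError(f"featurize failed on trial {i} "
                             f"(subject {rec.subject_id}): {err}") from err
        X_eeg.append(eeg_seq.values)
        X_peri.append(peri_values)
        labels.append(rec.label)
        subjects.append(rec.subject_id)
    return FeaturizedDataset(np.stack(X_eeg), np.stack(X_peri),
                             np.array(labels), np.array(subjects))


def feature_names(config: PipelineConfig) -> dict[str, list[str]]:
    eeg = [f"ch{ch:02d}_{b.name}_de"
           for ch in range(config.simulation.n_eeg_channels) for b in config.bands]
    peri = peripheral_feature_names(config.simulation.n_peri_channels)
    if config.use_eye_features:
        peri = peri + list(EYE_FEATURE_NAMES)
    return {"eeg": eeg, "peri": peri}


def save_features(dataset: FeaturizedDataset, path: str | Path,
                  config: PipelineConfig) -> None:
    names = feature_names(config)
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = config.stage_hash("featurize")
        fh.attrs["eeg_feature_names"] = json.dumps(names["eeg"])
        fh.attrs["peri_feature_names"] = json.dumps(names["peri"])
        fh.create_dataset("X_eeg", data=dataset.X_eeg)
        fh.create_dataset("X_peri", data=dataset.X_peri)
        fh.create_dataset("y", data=dataset.y)
        fh.create_dataset("subjects", data=dataset.subjects)


def load_features(path: str | Path, expected_hash: str | None = None) -> FeaturizedDataset:
    with h5py.File(path, "r") as fh:
        stored = fh.attrs.get("config_hash")
        if expected_hash is not None and stored != expected_hash:
            raise ValueError(
                f"features at {path} were produced by config {stored}, "
                f"expected {expected_hash}"
            )
        return FeaturizedDataset(fh["X_eeg"][()], fh["X_peri"][()],
                                 fh["y"][()], fh["subjects"][()])


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 *, shuffle_train_labels: bool = False) -> CVReport:
    """simulate -> featurize -> cross-validated training, with logging.

    When ``out_dir`` is given, stage artifacts (recordings.h5,
    features.h5, report.json, confusion_fold*.csv) are persisted there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    recordings = generate_dataset(config.simulation)
    logger.info("simulate: %d trials, seed %d (%.1f s)", len(recordings),
                config.simulation.seed, time.perf_counter() - t0)
    if out is not None:
        save_recordings(recordings, out / "recordings.h5", config)

    t0 = time.perf_counter()
    dataset = featurize_recordings(recordings, config)
    logger.info("featurize: X_eeg %s, X_peri %s (%.1f s)", dataset.X_eeg.shape,
                dataset.X_peri.shape, time.perf_counter() - t0)
    if out is not None:
        save_features(dataset, out / "features.h5", config)

    t0 = time.perf_counter()
    model_config = config.model.build(config.simulation.n_classes)
    report = run_cv(dataset, model_config, config.training,
                    shuffle_train_labels=shuffle_train_labels)
    logger.info("train: mean accuracy %.4f +- %.4f over %d folds (%.1f s)",
                report.mean_accuracy, report.sd_accuracy,
                config.training.n_folds, time.perf_counter() - t0)
    if out is not None:
        (out / "report.json").write_text(report.to_json(indent=2))
        for fold in report.folds:
            np.savetxt(out / f"confusion_fold{fold.fold_index}.csv",
                       fold.confusion, fmt="%d", delimiter=",")
    return report
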