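"""Record and configuration I/O.

The interchange format for EEG records is a plain CSV with a header row and
columns ``sample_index, ch1_counts, ch2_counts, label`` — one row per
sample, 0-based contiguous sample indices, integer ADC counts and task
labels spelled as the ``TaskLabel`` names.  Annotation intervals are
reconstructed from runs of identical labels (half-open [start, end)).

EDF reading is available when ``mne`` is installed; EDF export is not
provided (records round-trip losslessly through CSV).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import TrainingConfig
from .controller import ControllerConfig, DurationBands, ThresholdConfig
from .dsp import BandDefinition, FilterSpec, WindowSpec
from .synth import ADCSpec, EEGRecord, SynthConfig, TaskLabel

__all__ = [
    "read_record",
    "write_record",
    "read_features",
    "write_features",
    "RunConfig",
    "load_config",
    "save_config",
]

RECORD_COLUMNS = ["sample_index", "ch1_counts", "ch2_counts", "label"]


class RecordParseError(ValueError):
    pass


def write_record(record: EEGRecord, path: str | Path) -> None:
    labels = np.empty(record.n_samples, dtype=object)
    for start, end, label in record.annotations:
        labels[start:end] = label.value
    df = pd.DataFrame({
        "sample_index": np.arange(record.n_samples),
        "ch1_counts": record.counts[:, 0],
        "ch2_counts": record.counts[:, 1],
        "label": labels,
    })
    df.to_csv(path, index=False)


def _annotations_from_labels(labels: np.ndarray) -> list[tuple[int, int, TaskLabel]]:
    annotations = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            try:
                task = TaskLabel(labels[start])
            except ValueError:
                raise RecordParseError(
                    f"unknown task label {labels[start]!r} at sample {start}")
            annotations.append((start, i, task))
            start = i
    return annotations


def read_record(path: str | Path, fmt: str = "csv",
                sampling_rate: float = 256.0,
                adc: ADCSpec | None = None) -> EEGRecord:
    """Load an EEG record from CSV (or EDF if mne is available)."""
    if fmt == "edf":
        return _read_edf(path, sampling_rate, adc)
    if fmt != "csv":
        raise ValueError(f"unknown record format {fmt!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise RecordParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(f"{path}: missing column(s) {', '.join(missing)}")
    idx = df["sample_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        bad = int(np.flatnonzero(idx != np.arange(len(df)))[0])
        raise RecordParseError(
            f"{path}: non-monotone sample_index at data line {bad + 2}")
    counts = df[["ch1_counts", "ch2_counts"]].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        raise RecordParseError(f"{path}: ADC counts must be integers")
    annotations = _annotations_from_labels(df["label"].to_numpy())
    return EEGRecord(sampling_rate, counts, annotations, adc or ADCSpec())


def _read_edf(path: str | Path, sampling_rate: float,
              adc: ADCSpec | None) -> EEGRecord:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if abs(raw.info["sfreq"] - sampling_rate) > 1e-6:
        raise ValueError(
            f"{path}: EDF sampled at {raw.info['sfreq']} Hz, expected "
            f"{sampling_rate} Hz; resampling is refused")
    if len(raw.ch_names) < 2:
        raise RecordParseError(f"{path}: need two EEG channels")
    spec = adc or ADCSpec()
    uV = raw.get_data(picks=raw.ch_names[:2]).T * 1e6
    from .synth import quantize
    counts = quantize(uV, spec)
    labels = np.full(len(counts), TaskLabel.BASELINE.value, dtype=object)
    for ann in raw.annotations:
        try:
            task = TaskLabel(ann["description"])
        except ValueError:
            continue
        lo = int(round(ann["onset"] * sampling_rate))
        hi = lo + int(round(ann["duration"] * sampling_rate))
        labels[lo:hi] = task.value
    return EEGRecord(sampling_rate, counts, _annotations_from_labels(labels), spec)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise RecordParseError(f"{path}: feature CSV missing 'label' column")
    return df


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters, parseable from one YAML file.

    Defaults are the protocol values: 256 Hz, 1 s windows every 0.25 s,
    3-sample moving average, order-2 Butterworth 0.5–100 Hz, theta/alpha/
    beta bands, hidden sweep 4–20, equal train/validation/test thirds.
    """

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    bands: BandDefinition = field(default_factory=BandDefinition)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {(k.value if isinstance(k, TaskLabel) else k): _to_plain(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, TaskLabel):
        return obj.value
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: (tuple(v) if k in keys and isinstance(v, list) else v)
            for k, v in d.items()}


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    synth_d = dict(data.get("synth", {}))
    if "task_band_gains" in synth_d:
        synth_d["task_band_gains"] = {
            TaskLabel(k): tuple(tuple(ch) for ch in v)
            for k, v in synth_d["task_band_gains"].items()}
    if "adc" in synth_d:
        synth_d["adc"] = ADCSpec(**synth_d["adc"])
    ctrl_d = dict(data.get("controller", {}))
    if "threshold" in ctrl_d:
        ctrl_d["threshold"] = ThresholdConfig(**ctrl_d["threshold"])
    if "bands" in ctrl_d:
        ctrl_d["bands"] = DurationBands(**_tupled(ctrl_d["bands"],
                                                  ("mental_band", "ssvep_band")))
    bands_d = _tupled(dict(data.get("bands", {})), ("theta", "alpha", "beta"))
    training_d = _tupled(dict(data.get("training", {})), ("hidden_sweep",))
    return RunConfig(
        seed=data.get("seed", 0),
        synth=SynthConfig(**synth_d),
        window=WindowSpec(**data.get("window", {})),
        filter=FilterSpec(**data.get("filter", {})),
        bands=BandDefinition(**bands_d),
        training=TrainingConfig(**training_d),
        controller=ControllerConfig(**ctrl_d),
    )
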