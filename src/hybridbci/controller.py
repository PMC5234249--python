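"""Hybrid BCI decision layer: eyes-closed switching and command mapping.

The wheelchair-style controller runs on the 0.25 s window clock.  A raised
occipital-amplitude threshold on the raw ADC counts detects eyes closure;
the *duration* of a closure selects between operating modes:

* from ``NORMAL_OFF``, a sustained closure (>= ``on_duration``) wakes the
  system into ``BCI_CONTROL`` and emits the on/off command;
* from ``BCI_CONTROL``, a closure enters ``HYBRID_SELECTION``; on eye
  opening the accumulated closure length is mapped through configurable
  duration bands — ~1 s selects the mental-task BCI, ~2 s the SSVEP BCI,
  and a long closure turns the system off again;
* inside ``MENTAL_BCI`` / ``SSVEP_BCI`` the per-window classifier output
  is debounced over ``confirm_windows`` consecutive agreeing windows and
  then emitted as a steering command (left / forward / right).

Steering commands are never produced while the system is off; that safety
property is exercised exhaustively in the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dsp
from .classifier import ANNModel, predict_class
from .synth import EEGRecord, TaskLabel

__all__ = [
    "ControllerMode",
    "Command",
    "ThresholdConfig",
    "DurationBands",
    "ControllerConfig",
    "ControllerState",
    "WindowResult",
    "detect_eyes_closed_threshold",
    "calibrate_threshold",
    "step",
    "run_session",
    "SessionLog",
    "COMMAND_DISPLAY",
]


class ControllerMode(enum.Enum):
    NORMAL_OFF = "NORMAL_OFF"
    BCI_CONTROL = "BCI_CONTROL"
    HYBRID_SELECTION = "HYBRID_SELECTION"
    MENTAL_BCI = "MENTAL_BCI"
    SSVEP_BCI = "SSVEP_BCI"


class Command(enum.Enum):
    NONE = "NONE"
    ON_OFF = "ON_OFF"
    LEFT = "LEFT"
    FORWARD = "FORWARD"
    RIGHT = "RIGHT"


# LCD display strings for each intentional command
COMMAND_DISPLAY = {
    Command.ON_OFF: "O/F → On/Off",
    Command.LEFT: "L → Left",
    Command.FORWARD: "F → Forward",
    Command.RIGHT: "R → Right",
}

STEERING = (Command.LEFT, Command.FORWARD, Command.RIGHT)

# class -> steering command, applied to the 3-way classifier output in
# either BCI mode (mental tasks or SSVEP frequencies)
DEFAULT_COMMAND_MAP = {
    TaskLabel.ARITHMETIC.value: Command.LEFT,
    TaskLabel.ROTATION.value: Command.FORWARD,
    TaskLabel.LETTER.value: Command.RIGHT,
    TaskLabel.SSVEP_6.value: Command.LEFT,
    TaskLabel.SSVEP_13.value: Command.FORWARD,
    TaskLabel.SSVEP_16.value: Command.RIGHT,
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Count-domain eyes-closed detection threshold (per subject)."""

    eyes_closed_threshold: float | None = None
    calibration_percentile: float = 99.0
    channel: int = 1           # occipital CH2 (column index 1)

    def __post_init__(self) -> None:
        if self.eyes_closed_threshold is not None and not (
                0 <= self.eyes_closed_threshold <= 4095):
            raise ValueError("threshold outside 12-bit ADC range")


@dataclass(frozen=True)
class DurationBands:
    """Closure-duration routing, quantized to the 0.25 s update step.

    Half-open [lo, hi) bands centred on the nominal 1 s (mental) and 2 s
    (SSVEP) closures; ``off_min`` and ``on_duration`` govern switching the
    system off and on.
    """

    mental_band: tuple[float, float] = (0.75, 1.5)
    ssvep_band: tuple[float, float] = (1.5, 2.5)
    off_min: float = 2.5
    on_duration: float = 2.5

    def __post_init__(self) -> None:
        if not (self.mental_band[0] < self.mental_band[1]
                <= self.ssvep_band[0] < self.ssvep_band[1] <= self.off_min):
            raise ValueError("duration bands must be ordered and non-overlapping")


@dataclass(frozen=True)
class ControllerConfig:
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    bands: DurationBands = field(default_factory=DurationBands)
    dt: float = 0.25                # s, window step
    confirm_windows: int = 4        # consecutive agreeing windows per command
    latch_mode: bool = False        # stay in the BCI mode after a command
    eyes_rule: str = "and"          # combine threshold & ANN flags: and | or | threshold | ann

    def __post_init__(self) -> None:
        if self.eyes_rule not in ("and", "or", "threshold", "ann"):
            raise ValueError(f"unknown eyes_rule {self.eyes_rule!r}")
        if self.confirm_windows < 1:
            raise ValueError("confirm_windows must be >= 1")


@dataclass
class ControllerState:
    mode: ControllerMode = ControllerMode.NORMAL_OFF
    eyes_closed_run: float = 0.0    # s of consecutive eyes-closed updates
    last_command: Command = Command.NONE
    clock: float = 0.0              # s
    confirm_class: str | None = None
    confirm_count: int = 0
    await_open: bool = False        # ignore the closure that caused a switch


@dataclass(frozen=True)
class WindowResult:
    """Per-window detector outputs fed to the state machine."""

    threshold_flag: bool
    eyes_closed_ann_flag: bool = False
    mental_class: str | None = None
    ssvep_class: str | None = None


def detect_eyes_closed_threshold(raw_window: np.ndarray,
                                 config: ThresholdConfig) -> bool:
    """True iff the occipital channel's maximum count exceeds the threshold
    (strict inequality) within the 1 s window."""
    if config.eyes_closed_threshold is None:
        raise ValueError("no eyes-closed threshold set: run calibrate_threshold first")
    raw_window = np.asarray(raw_window)
    if raw_window.ndim != 2 or raw_window.shape[1] != 2:
        raise ValueError("expected a (n_samples, 2) count window")
    return bool(raw_window[:, config.channel].max() > config.eyes_closed_threshold)


def calibrate_threshold(baseline_record: EEGRecord,
                        eyes_closed_record: EEGRecord,
                        percentile: float = 99.0,
                        channel: int = 1,
                        min_margin_counts: float = 20.0) -> ThresholdConfig:
    """Midpoint threshold between eyes-open and eyes-closed count levels.

    Uses the baseline record's high percentile and the eyes-closed record's
    peak-region level (the same percentile of its per-second maxima); fails
    if the two distributions are not separated by ``min_margin_counts``.
    """
    for rec, name in ((baseline_record, "baseline"),
                      (eyes_closed_record, "eyes-closed")):
        if rec.duration < 5:
            raise ValueError(f"{name} record shorter than 5 s")
    fs = int(baseline_record.sampling_rate)
    base_high = float(np.percentile(baseline_record.counts[:, channel], percentile))
    ec = eyes_closed_record.counts[:, channel]
    n_sec = len(ec) // fs
    sec_max = ec[:n_sec * fs].reshape(n_sec, fs).max(axis=1)
    ec_peak = float(np.percentile(sec_max, 50))
    if ec_peak - base_high < min_margin_counts:
        raise ValueError(
            f"calibration failed: eyes-closed peaks ({ec_peak:.0f}) not "
            f"separable from baseline ({base_high:.0f})")
    return ThresholdConfig(eyes_closed_threshold=(base_high + ec_peak) / 2.0,
                           calibration_percentile=percentile, channel=channel)


# --------------------------------------------------------------------------
# State machine
# --------------------------------------------------------------------------

def _eyes_closed(result: WindowResult, cfg: ControllerConfig,
                 mode: ControllerMode) -> bool:
    # wake-up from off relies on the raw threshold alone; inside BCI modes
    # the ANN decision participates per the configured rule
    if mode is ControllerMode.NORMAL_OFF or cfg.eyes_rule == "threshold":
        return result.threshold_flag
    if cfg.eyes_rule == "ann":
        return result.eyes_closed_ann_flag
    if cfg.eyes_rule == "or":
        return result.threshold_flag or result.eyes_closed_ann_flag
    return result.threshold_flag and result.eyes_closed_ann_flag


def step(state: ControllerState, result: WindowResult,
         cfg: ControllerConfig = ControllerConfig(),
         dt: float = 0.25) -> tuple[ControllerState, Command]:
    """Advance the controller by one window update; returns the new state
    and the command emitted on this update (usually ``NONE``)."""
    if abs(dt - cfg.dt) > 1e-9:
        raise ValueError(f"dt {dt} does not match configured step {cfg.dt}")
    s = replace_state(state)
    s.clock += dt
    command = Command.NONE
    ec = _eyes_closed(result, cfg, s.mode)
    bands = cfg.bands

    if not ec:
        s.await_open = False

    if s.mode is ControllerMode.NORMAL_OFF:
        if ec and not s.await_open:
            s.eyes_closed_run += dt
            if s.eyes_closed_run >= bands.on_duration:
                s.mode = ControllerMode.BCI_CONTROL
                command = Command.ON_OFF
                s.eyes_closed_run = 0.0
                s.await_open = True
        else:
            s.eyes_closed_run = 0.0

    elif s.mode in (ControllerMode.BCI_CONTROL, ControllerMode.MENTAL_BCI,
                    ControllerMode.SSVEP_BCI):
        if ec and not s.await_open:
            # closure onset: begin accumulating a selection run
            s.mode = ControllerMode.HYBRID_SELECTION
            s.eyes_closed_run = dt
            s.confirm_class, s.confirm_count = None, 0
        elif s.mode in (ControllerMode.MENTAL_BCI, ControllerMode.SSVEP_BCI) and not ec:
            cls = (result.mental_class if s.mode is ControllerMode.MENTAL_BCI
                   else result.ssvep_class)
            if cls is not None and cls == s.confirm_class:
                s.confirm_count += 1
            else:
                s.confirm_class, s.confirm_count = cls, 1 if cls else 0
            if s.confirm_count >= cfg.confirm_windows and cls in DEFAULT_COMMAND_MAP:
                command = DEFAULT_COMMAND_MAP[cls]
                s.confirm_class, s.confirm_count = None, 0
                if not cfg.latch_mode:
                    s.mode = ControllerMode.BCI_CONTROL

    elif s.mode is ControllerMode.HYBRID_SELECTION:
        if ec:
            s.eyes_closed_run += dt
        else:
            run = s.eyes_closed_run
            s.eyes_closed_run = 0.0
            if run >= bands.off_min:
                s.mode = ControllerMode.NORMAL_OFF
                command = Command.ON_OFF
            elif bands.ssvep_band[0] <= run < bands.ssvep_band[1]:
                s.mode = ControllerMode.SSVEP_BCI
            elif bands.mental_band[0] <= run < bands.mental_band[1]:
                s.mode = ControllerMode.MENTAL_BCI
            else:
                s.mode = ControllerMode.BCI_CONTROL

    if command is not Command.NONE:
        s.last_command = command
    return s, command


def replace_state(state: ControllerState) -> ControllerState:
    return ControllerState(state.mode, state.eyes_closed_run,
                           state.last_command, state.clock,
                           state.confirm_class, state.confirm_count,
                           state.await_open)


# --------------------------------------------------------------------------
# Streaming session runner
# --------------------------------------------------------------------------

@dataclass
class SessionLog:
    """Window-by-window controller trace plus per-event scoring."""

    rows: pd.DataFrame                  # time_s, mode, command, true_label
    events: pd.DataFrame                # event-level scoring
    command_counts: dict

    def summary(self) -> pd.DataFrame:
        """Per-command correct counts, success % and latency range."""
        out = []
        for cmd in (Command.ON_OFF, *STEERING):
            ev = self.events[self.events.expected == cmd.value]
            if len(ev) == 0:
                continue
            correct = int(ev.correct.sum())
            lat = ev.loc[ev.correct, "latency_s"]
            out.append({
                "command": cmd.value,
                "events": len(ev),
                "correct": correct,
                "success_pct": 100.0 * correct / len(ev),
                "latency_min_s": float(lat.min()) if len(lat) else np.nan,
                "latency_max_s": float(lat.max()) if len(lat) else np.nan,
            })
        return pd.DataFrame(out)


def _erode_trailing(flags: np.ndarray, k: int) -> np.ndarray:
    """Clear the last ``k`` updates of every contiguous True run (runs no
    longer than ``k`` vanish entirely, acting as a debounce)."""
    if k <= 0:
        return flags
    out = flags.copy()
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            out[max(i, j - k):j] = False
            i = j
        else:
            i += 1
    return out


def _expected_events(record: EEGRecord, cfg: ControllerConfig):
    """Derive the intended command per annotated segment.

    An eyes-closed segment is intended as ON_OFF when its duration reaches
    the on/off threshold; mental/SSVEP segments are intended as their mapped
    steering command.  Baseline segments carry no intention.
    """
    fs = record.sampling_rate
    events = []
    for start, end, label in record.annotations:
        dur = (end - start) / fs
        if label is TaskLabel.EYES_CLOSED and dur >= cfg.bands.off_min:
            events.append({"start_s": start / fs, "end_s": end / fs,
                           "expected": Command.ON_OFF.value})
        elif label.value in DEFAULT_COMMAND_MAP and label is not TaskLabel.EYES_CLOSED:
            events.append({"start_s": start / fs, "end_s": end / fs,
                           "expected": DEFAULT_COMMAND_MAP[label.value].value})
    return events


def run_session(record: EEGRecord, models: dict, cfg: ControllerConfig,
                window: dsp.WindowSpec = dsp.WindowSpec(),
                filt: dsp.FilterSpec = dsp.FilterSpec(),
                bands: dsp.BandDefinition = dsp.BandDefinition(),
                *, grace_s: float = 2.0) -> SessionLog:
    """Stream a record window-by-window through dsp -> classifier -> step.

    ``models`` may contain ``"eyes"`` (binary eyes-closed vs baseline),
    ``"mental"`` (3 mental tasks) and ``"ssvep"`` (3 stimulus frequencies)
    classifiers; absent models contribute neutral flags.  Event scoring
    marks an intended command correct when it is emitted between the
    segment start and segment end + ``grace_s``.

    Because the threshold detector reports the *maximum* of the full 1 s
    window, it keeps firing for window_length - step after the eyes reopen;
    the trailing edge of each detected closure run is therefore eroded by
    that many updates (and isolated runs no longer than the erosion are
    dropped as spurious) so the accumulated run length tracks the true
    closure duration that the selection bands are calibrated against.
    """
    for name, model in models.items():
        if model is not None and model.n_inputs != 54:
            raise ValueError(f"model {name!r} expects {model.n_inputs} inputs, "
                             "records provide 54")
    fs = record.sampling_rate
    n_step, n_win = window.n_step, window.n_window
    state = ControllerState()
    rows, emitted = [], []
    eyes_model: ANNModel | None = models.get("eyes")
    mental_model: ANNModel | None = models.get("mental")
    ssvep_model: ANNModel | None = models.get("ssvep")

    starts = list(range(0, record.n_samples - n_win + 1, n_step))
    thr_flags = np.array([
        detect_eyes_closed_threshold(record.counts[lo:lo + n_win], cfg.threshold)
        for lo in starts])
    thr_flags = _erode_trailing(thr_flags, max(n_win // n_step - 1, 0))

    for i, lo in enumerate(starts):
        raw = record.counts[lo:lo + n_win]
        t = (lo + n_win) / fs
        thr = bool(thr_flags[i])
        feats = None

        def features():
            nonlocal feats
            if feats is None:
                uV = (raw - record.adc.mid_code) * record.adc.input_referred_lsb_uV
                feats = dsp.window_features(uV, filt, bands, fs).values
            return feats

        ann_flag = thr
        if eyes_model is not None and cfg.eyes_rule in ("and", "or", "ann"):
            ann_flag = predict_class(eyes_model, features()) == TaskLabel.EYES_CLOSED.value
        mental_cls = (predict_class(mental_model, features())
                      if mental_model is not None
                      and state.mode is ControllerMode.MENTAL_BCI else None)
        ssvep_cls = (predict_class(ssvep_model, features())
                     if ssvep_model is not None
                     and state.mode is ControllerMode.SSVEP_BCI else None)
        result = WindowResult(thr, ann_flag, mental_cls, ssvep_cls)
        state, command = step(state, result, cfg, cfg.dt)
        true_label = record.label_at(min(lo + n_win - 1, record.n_samples - 1))
        rows.append({"time_s": t, "mode": state.mode.value,
                     "command": command.value, "true_label": true_label.value})
        if command is not Command.NONE:
            emitted.append((t, command.value))

    log = pd.DataFrame(rows)
    events = []
    for ev in _expected_events(record, cfg):
        hit = [t for t, c in emitted
               if c == ev["expected"] and ev["start_s"] < t <= ev["end_s"] + grace_s]
        events.append({**ev, "correct": bool(hit),
                       "latency_s": (hit[0] - ev["start_s"]) if hit else np.nan})
    events_df = pd.DataFrame(events, columns=["start_s", "end_s", "expected",
                                              "correct", "latency_s"])
    counts = {c.value: int((log.command == c.value).sum())
              for c in Command if c is not Command.NONE}
    return SessionLog(log, events_df, counts)
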