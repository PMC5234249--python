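"""Synthetic two-channel EEG generation with a 12-bit ADC front-end model.

The generator emulates the signal classes a hybrid mental-task / SSVEP /
eyes-closed BCI discriminates, recorded from a bipolar montage at P3–T4
(channel 1, parietal) and O2–T3 (channel 2, occipital) at 256 Hz:

* baseline: zero-mean 1/f (or white) background noise on both channels;
* mental tasks (arithmetic, figure rotation, letter composing, counting):
  the same background with its theta/alpha/beta band content reshaped by
  per-task, per-channel gain triples;
* SSVEP at 6/13/16 Hz: a sinusoid at the stimulus frequency (plus optional
  harmonics), stronger on the occipital channel;
* eyes closed: an amplitude-modulated 10 Hz alpha oscillation on the
  occipital channel whose envelope excursion pushes the quantized counts
  above the eyes-open range, emulating the raised-amplitude "mind switch".

Analog microvolt signals are passed through a differential-ADC model
(full scale 1.2 V, 12 bits, total gain 2000, mid-code at 0 V) so every
downstream stage operates on the same integer count streams the hardware
would produce.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ADCSpec",
    "TaskLabel",
    "SynthConfig",
    "EEGRecord",
    "adc_lsb",
    "quantize",
    "dequantize",
    "generate_session",
    "generate_script",
    "DEFAULT_TASK_BAND_GAINS",
]


class ConfigurationError(ValueError):
    """Raised for invalid ADC or generator configuration."""


# --------------------------------------------------------------------------
# ADC model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ADCSpec:
    """Differential ADC front end: LSB = full_scale / 2**n_bits.

    ``gain`` is the total analog amplification ahead of the converter, so the
    input-referred resolution is ``lsb_volts / gain`` (0.15 uV for the
    default 1.2 V / 12 bit / x2000 chain).
    """

    full_scale: float = 1.2        # volts, differential span
    n_bits: int = 12
    gain: float = 2000.0
    mid_code: int = 2048           # count produced by a 0 V input

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ConfigurationError("n_bits must be positive")
        if self.full_scale <= 0:
            raise ConfigurationError("full_scale must be positive")
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")
        if not (0 <= self.mid_code <= 2 ** self.n_bits - 1):
            raise ConfigurationError("mid_code outside ADC code range")

    @property
    def n_codes(self) -> int:
        return 2 ** self.n_bits

    @property
    def lsb_volts(self) -> float:
        return self.full_scale / self.n_codes

    @property
    def input_referred_lsb_uV(self) -> float:
        """Microvolts at the electrode per ADC count."""
        return self.lsb_volts / self.gain * 1e6


def adc_lsb(spec: ADCSpec) -> float:
    """Least-significant-bit size in volts: FS / 2**n."""
    return spec.lsb_volts


def quantize(signal_uV: np.ndarray, spec: ADCSpec, *, return_stats: bool = False):
    """Convert an input-referred microvolt signal to ADC counts.

    count = round(v * gain / LSB) + mid_code, clipped to [0, 2**n - 1].
    Clipping is silent; pass ``return_stats=True`` to also get the fraction
    of saturated samples.
    """
    signal_uV = np.asarray(signal_uV, dtype=float)
    if not np.all(np.isfinite(signal_uV)):
        raise ValueError("signal contains non-finite values")
    raw = np.rint(signal_uV / spec.input_referred_lsb_uV) + spec.mid_code
    counts = np.clip(raw, 0, spec.n_codes - 1).astype(np.int64)
    if return_stats:
        saturated = float(np.mean((raw < 0) | (raw > spec.n_codes - 1)))
        return counts, saturated
    return counts


def dequantize(counts: np.ndarray, spec: ADCSpec) -> np.ndarray:
    """Inverse mapping: counts back to input-referred microvolts.

    Round-trips in-range signals to within +-0.5 input-referred LSB.
    """
    counts = np.asarray(counts, dtype=float)
    return (counts - spec.mid_code) * spec.input_referred_lsb_uV


# --------------------------------------------------------------------------
# Task labels
# --------------------------------------------------------------------------

class TaskLabel(enum.Enum):
    BASELINE = "BASELINE"
    ARITHMETIC = "ARITHMETIC"
    ROTATION = "ROTATION"
    LETTER = "LETTER"
    COUNTING = "COUNTING"
    SSVEP_6 = "SSVEP_6"
    SSVEP_13 = "SSVEP_13"
    SSVEP_16 = "SSVEP_16"
    EYES_CLOSED = "EYES_CLOSED"

    @property
    def stimulus_hz(self) -> float | None:
        """Flicker frequency for SSVEP labels, None otherwise."""
        if self.name.startswith("SSVEP_"):
            return float(self.name.split("_")[1])
        return None

    @property
    def is_mental(self) -> bool:
        return self in (TaskLabel.ARITHMETIC, TaskLabel.ROTATION,
                        TaskLabel.LETTER, TaskLabel.COUNTING)


# Per-task (theta, alpha, beta) multiplicative gains on band content,
# per channel: {task: ((th1, al1, be1), (th2, al2, be2))}.  Each class
# emphasises exactly one band on one channel (orthogonal signatures), a
# synthetic design choice that keeps the classes separable at the default
# background level without claiming physiological fidelity.
DEFAULT_TASK_BAND_GAINS: dict[TaskLabel, tuple[tuple[float, float, float],
                                               tuple[float, float, float]]] = {
    TaskLabel.ARITHMETIC: ((3.0, 1.0, 1.0), (1.0, 1.0, 1.0)),   # parietal theta
    TaskLabel.ROTATION:   ((1.0, 1.0, 3.0), (1.0, 1.0, 1.0)),   # parietal beta
    TaskLabel.LETTER:     ((1.0, 1.0, 1.0), (1.0, 1.0, 3.0)),   # occipital beta
    TaskLabel.COUNTING:   ((1.0, 1.0, 1.0), (3.0, 1.0, 1.0)),   # occipital theta
}

# EEG band edges in Hz (inclusive), 1 Hz bins
BAND_EDGES = {"theta": (4, 7), "alpha": (8, 13), "beta": (14, 30)}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Amplitudes are input-referred microvolts before amplification; the
    eyes-closed excursion is expressed in ADC counts so it can be placed
    directly against a count-domain detection threshold.
    """

    sampling_rate: float = 256.0
    session_length: float = 13.0       # s, recorded per session
    discard_prefix: float = 3.0        # s, preparation time dropped downstream
    background_amplitude: float = 5.0  # uV RMS of the unshaped noise floor
    rhythm_amplitude: float = 5.0      # uV RMS of the band-shaped EEG component
    ssvep_amplitude: float = 10.0      # uV, occipital stimulus response
    ssvep_harmonics: int = 1           # number of sinusoid components (1 = fundamental)
    alpha_burst_amplitude: float = 20.0   # uV, eyes-closed alpha carrier
    eyes_closed_baseline_shift: float = 250.0  # ADC counts of envelope excursion
    dc_offset_counts: float = 450.0    # electrode DC offset, in counts above mid-code
    task_band_gains: dict = field(default_factory=lambda: dict(DEFAULT_TASK_BAND_GAINS))
    noise_model: str = "one_over_f"    # or "white"
    seed: int = 0
    adc: ADCSpec = field(default_factory=ADCSpec)

    def __post_init__(self) -> None:
        if self.sampling_rate != 256:
            raise ConfigurationError("sampling_rate is fixed at 256 Hz")
        if self.session_length <= self.discard_prefix:
            raise ConfigurationError("session_length must exceed discard_prefix")
        for name in ("background_amplitude", "rhythm_amplitude",
                     "ssvep_amplitude", "alpha_burst_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise_model not in ("white", "one_over_f"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        if self.ssvep_harmonics < 1:
            raise ConfigurationError("ssvep_harmonics must be >= 1")


@dataclass
class EEGRecord:
    """Two-channel ADC-count time series with ground-truth task intervals.

    ``counts`` has shape (n_samples, 2): column 0 = CH1 (P3-T4), column 1 =
    CH2 (O2-T3).  ``annotations`` are half-open (start_sample, end_sample,
    TaskLabel) intervals that tile the record without overlap.
    """

    sampling_rate: float
    counts: np.ndarray
    annotations: list[tuple[int, int, TaskLabel]]
    adc: ADCSpec = field(default_factory=ADCSpec)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must have shape (n_samples, 2)")
        n = len(self.counts)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.adc.n_codes - 1:
            raise ValueError("counts outside ADC code range")
        last = 0
        for start, end, _ in self.annotations:
            if start != last or end <= start or end > n:
                raise ValueError("annotations must tile the record without gaps or overlap")
            last = end

    @property
    def n_samples(self) -> int:
        return len(self.counts)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def label_at(self, sample: int) -> TaskLabel:
        for start, end, label in self.annotations:
            if start <= sample < end:
                return label
        raise IndexError(f"sample {sample} outside record")

    def to_uV(self) -> np.ndarray:
        """Dequantized input-referred microvolt signal, shape (n, 2)."""
        return dequantize(self.counts, self.adc)


# --------------------------------------------------------------------------
# Signal synthesis
# --------------------------------------------------------------------------

def _shaped_noise(rng: np.random.Generator, n: int, fs: float, rms_uV: float,
                  model: str, band_gains: tuple[float, float, float] | None) -> np.ndarray:
    """Broadband background noise, optionally with theta/alpha/beta reshaping.

    Built in the frequency domain: a white complex spectrum weighted by the
    target amplitude profile (flat or 1/sqrt(f)) and by the per-band gains,
    then inverse-transformed and scaled to the requested RMS *before* the
    band gains (so gains > 1 raise the respective band power relative to a
    gain-1 background of the same seed).
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    spec[0] = 0.0
    weight = np.ones_like(freqs)
    if model == "one_over_f":
        with np.errstate(divide="ignore"):
            weight = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1e-9)), 0.0)
    base = spec * weight
    # normalize the unshaped background to the requested RMS
    ref = np.fft.irfft(base, n)
    scale = rms_uV / max(np.std(ref), 1e-12)
    if band_gains is not None:
        gains = np.ones_like(freqs)
        for (name, (lo, hi)), g in zip(BAND_EDGES.items(), band_gains):
            gains[(freqs >= lo) & (freqs <= hi + 1)] = g
        base = base * gains
    return np.fft.irfft(base, n) * scale


def _analog_segment(task: TaskLabel, n: int, t0_samples: int, config: SynthConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Input-referred microvolt signal for one task segment, shape (n, 2).

    ``t0_samples`` offsets the deterministic oscillators so concatenated
    segments share a continuous sample clock (no phase resets).
    """
    fs = config.sampling_rate
    t = (t0_samples + np.arange(n)) / fs
    gains = config.task_band_gains.get(task) if task.is_mental else None
    # two noise components per channel: a band-shaped EEG rhythm carrying the
    # task signature (fixed amplitude) and an unshaped floor whose amplitude
    # is the noise dial — raising it dilutes the signature.
    sig = np.empty((n, 2))
    for ch in range(2):
        bg = gains[ch] if gains is not None else None
        sig[:, ch] = _shaped_noise(rng, n, fs, config.rhythm_amplitude,
                                   config.noise_model, bg)
        sig[:, ch] += _shaped_noise(rng, n, fs, config.background_amplitude,
                                    config.noise_model, None)

    if task.stimulus_hz is not None:
        f0 = task.stimulus_hz
        resp = np.zeros(n)
        for h in range(1, config.ssvep_harmonics + 1):
            resp += (config.ssvep_amplitude / h) * np.sin(2 * np.pi * f0 * h * t)
        sig[:, 1] += resp            # occipital channel carries the response
        sig[:, 0] += 0.5 * resp
    elif task is TaskLabel.EYES_CLOSED:
        # 10 Hz alpha carrier whose amplitude is modulated by a 1.2 Hz
        # envelope; the excursion (in counts, converted to uV) keeps every
        # alpha cycle peaking above the eyes-open count range — detection
        # latency is bounded by one carrier cycle — while the 0.5 Hz
        # high-pass downstream still passes the oscillation (no DC step).
        shift_uV = config.eyes_closed_baseline_shift * config.adc.input_referred_lsb_uV
        envelope = config.alpha_burst_amplitude + shift_uV * (
            0.75 + 0.25 * np.sin(2 * np.pi * 1.2 * t))
        carrier = np.sin(2 * np.pi * 10.0 * t)
        sig[:, 1] += envelope * carrier
        sig[:, 0] += 0.3 * envelope * carrier
    elif not (task.is_mental or task is TaskLabel.BASELINE):
        raise ValueError(f"unknown task {task!r}")

    sig += config.dc_offset_counts * config.adc.input_referred_lsb_uV
    return sig


def _task_seed_key(task: TaskLabel) -> int:
    return list(TaskLabel).index(task)


def generate_session(task: TaskLabel, config: SynthConfig) -> EEGRecord:
    """One recording session of ``task`` (13 s by default), ADC-quantized.

    Output is fully determined by (task, config); the same seed produces a
    bit-identical record.
    """
    if not isinstance(task, TaskLabel):
        raise ValueError(f"unknown task {task!r}")
    n = int(round(config.session_length * config.sampling_rate))
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _task_seed_key(task), 0]))
    sig = _analog_segment(task, n, 0, config, rng)
    counts = quantize(sig, config.adc)
    return EEGRecord(config.sampling_rate, counts, [(0, n, task)], config.adc)


def generate_script(timeline: list[tuple[TaskLabel, float]],
                    config: SynthConfig) -> EEGRecord:
    """Concatenated record following a (task, duration_s) timeline.

    Segments share a continuous sample clock; annotations mark the exact
    ground-truth boundaries.
    """
    if not timeline:
        raise ValueError("timeline is empty")
    fs = config.sampling_rate
    pieces, annotations = [], []
    t0 = 0
    for idx, (task, dur) in enumerate(timeline):
        if dur <= 0:
            raise ValueError(f"segment {idx}: duration must be > 0")
        if not isinstance(task, TaskLabel):
            raise ValueError(f"unknown task {task!r}")
        n = int(round(dur * fs))
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _task_seed_key(task), 1, idx]))
        pieces.append(_analog_segment(task, n, t0, config, rng))
        annotations.append((t0, t0 + n, task))
        t0 += n
    counts = quantize(np.concatenate(pieces, axis=0), config.adc)
    return EEGRecord(fs, counts, annotations, config.adc)


def with_noise(config: SynthConfig, background_amplitude: float) -> SynthConfig:
    """Copy of ``config`` at a different background noise amplitude."""
    return replace(config, background_amplitude=background_amplitude)
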