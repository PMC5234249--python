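"""Signal processing and feature extraction for the two-channel EEG stream.

The chain mirrors a streaming embedded implementation: a 1 s window is
extracted every 0.25 s, smoothed with a 3-sample moving average, band-pass
filtered with a causal second-order Butterworth (0.5–100 Hz), transformed
with a 256-point FFT and squared into a one-sided PSD.  With fs = 256 Hz
each FFT bin is exactly 1 Hz wide, so the theta (4–7 Hz), alpha (8–13 Hz)
and beta (14–30 Hz) bands contribute 4 + 6 + 17 = 27 per-bin power values
per channel, 54 per window.  Delta (0–3 Hz, ocular artifacts) and
everything above 30 Hz are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .synth import EEGRecord, TaskLabel

__all__ = [
    "WindowSpec",
    "FilterSpec",
    "BandDefinition",
    "PSDFeatureVector",
    "segment",
    "window_count",
    "moving_average",
    "bandpass",
    "fft256",
    "psd",
    "band_features",
    "window_features",
    "extract_features",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window: 1 s of samples advanced every 0.25 s."""

    window_length: float = 1.0   # s
    step: float = 0.25           # s
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        n_win = self.window_length * self.sampling_rate
        n_step = self.step * self.sampling_rate
        if abs(n_win - round(n_win)) > 1e-9 or abs(n_step - round(n_step)) > 1e-9:
            raise ValueError("window_length and step must be whole numbers of samples")
        if self.step > self.window_length:
            raise ValueError("step must not exceed window_length")

    @property
    def n_window(self) -> int:
        return int(round(self.window_length * self.sampling_rate))

    @property
    def n_step(self) -> int:
        return int(round(self.step * self.sampling_rate))


@dataclass(frozen=True)
class FilterSpec:
    """Smoothing + band-pass stage applied to each extracted window."""

    moving_average_width: int = 3
    butterworth_order: int = 2
    band_low: float = 0.5    # Hz
    band_high: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if self.moving_average_width < 1 or self.moving_average_width % 2 == 0:
            raise ValueError("moving_average_width must be odd and >= 1")
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")


@dataclass(frozen=True)
class BandDefinition:
    """Inclusive integer-Hz band edges at 1 Hz bin width."""

    theta: tuple[int, int] = (4, 7)
    alpha: tuple[int, int] = (8, 13)
    beta: tuple[int, int] = (14, 30)

    def __post_init__(self) -> None:
        edges = [self.theta, self.alpha, self.beta]
        for lo, hi in edges:
            if lo > hi:
                raise ValueError("band edges must satisfy lo <= hi")
        for (_, hi), (lo, _) in zip(edges, edges[1:]):
            if lo <= hi:
                raise ValueError("bands must be disjoint and ordered")

    @property
    def bins(self) -> np.ndarray:
        """The selected integer-Hz bins, in feature order."""
        return np.concatenate([
            np.arange(lo, hi + 1) for lo, hi in (self.theta, self.alpha, self.beta)
        ])

    @property
    def n_per_channel(self) -> int:
        return len(self.bins)


@dataclass
class PSDFeatureVector:
    """54 band-binned power values: CH1 (theta, alpha, beta bins) then CH2."""

    values: np.ndarray
    source_window: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (54,):
            raise ValueError("feature vector must have exactly 54 values")
        if np.any(self.values < 0):
            raise ValueError("power values must be non-negative")


# --------------------------------------------------------------------------
# Windowing
# --------------------------------------------------------------------------

def window_count(analysis_span: float, spec: WindowSpec) -> int:
    """floor((span - window) / step) + 1 — e.g. 37 windows for 10 s."""
    if analysis_span < spec.window_length:
        raise ValueError(
            f"analysis span {analysis_span} s shorter than one "
            f"{spec.window_length} s window")
    return int(np.floor((analysis_span - spec.window_length) / spec.step + 1e-9)) + 1


def segment(record: EEGRecord, spec: WindowSpec, analysis_span: float,
            *, start: float = 0.0) -> np.ndarray:
    """Overlapping two-channel windows, shape (n_windows, n_window, 2).

    ``start`` (seconds) skips a prefix of the record — e.g. the 3 s
    preparation period of a 13 s session — before the span is windowed.
    """
    if spec.sampling_rate != record.sampling_rate:
        raise ValueError("window spec and record sampling rates differ")
    n0 = int(round(start * record.sampling_rate))
    n_span = int(round(analysis_span * record.sampling_rate))
    if n0 + n_span > record.n_samples:
        raise ValueError(
            f"record too short: need {n0 + n_span} samples "
            f"({start + analysis_span} s), have {record.n_samples}")
    n_win = window_count(analysis_span, spec)
    data = record.counts[n0:n0 + n_span]
    out = np.empty((n_win, spec.n_window, 2), dtype=data.dtype)
    for w in range(n_win):
        lo = w * spec.n_step
        out[w] = data[lo:lo + spec.n_window]
    return out


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def moving_average(x: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered moving average; edges use shrunken neighbourhoods."""
    if width % 2 == 0:
        raise ValueError("width must be odd (centering undefined otherwise)")
    x = np.asarray(x, dtype=float)
    if len(x) < width:
        raise ValueError("signal shorter than the averaging width")
    if width == 1:
        return x.copy()
    kernel = np.ones(width)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones(len(x)), kernel, mode="same")
    return sums / counts


def _design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.band_high >= fs / 2:
        raise ValueError(
            f"band_high {spec.band_high} Hz must be below Nyquist {fs / 2} Hz")
    sos = _sig.butter(spec.butterworth_order,
                      [spec.band_low, spec.band_high],
                      btype="bandpass", fs=fs, output="sos")
    # pole check: bilinear-transformed Butterworth must be strictly stable
    _, poles, _ = _sig.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise RuntimeError("unstable band-pass design (pole on/outside unit circle)")
    return sos


def bandpass(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Causal single-pass Butterworth band-pass, as a streaming system runs it."""
    sos = _design_bandpass(spec, fs)
    return _sig.sosfilt(sos, np.asarray(x, dtype=float))


# --------------------------------------------------------------------------
# Spectrum
# --------------------------------------------------------------------------

def fft256(window: np.ndarray) -> np.ndarray:
    """256-point DFT, X[k] = sum_t x[t] exp(-2*pi*i*k*t/256).

    At fs = 256 Hz bin k is exactly k Hz.  No taper is applied (rectangular
    window), matching a fixed-point radix-2 implementation.
    """
    window = np.asarray(window)
    if window.shape != (256,):
        raise ValueError(f"expected exactly 256 samples, got {window.shape}")
    return np.fft.fft(window)


def psd(spectrum: np.ndarray) -> np.ndarray:
    """One-sided power spectral density: P[k] = |X[k]|^2 for k = 0..128."""
    spectrum = np.asarray(spectrum)
    if spectrum.shape != (256,):
        raise ValueError("expected a 256-coefficient spectrum")
    return np.abs(spectrum[:129]) ** 2


def band_features(psd_ch1: np.ndarray, psd_ch2: np.ndarray,
                  bands: BandDefinition = BandDefinition(),
                  source_window: int = 0) -> PSDFeatureVector:
    """Select the theta/alpha/beta bins of both channels (27 + 27 values)."""
    psd_ch1 = np.asarray(psd_ch1, dtype=float)
    psd_ch2 = np.asarray(psd_ch2, dtype=float)
    if psd_ch1.shape != (129,) or psd_ch2.shape != (129,):
        raise ValueError("expected one-sided 129-bin PSDs")
    bins = bands.bins
    return PSDFeatureVector(np.concatenate([psd_ch1[bins], psd_ch2[bins]]),
                            source_window)


# --------------------------------------------------------------------------
# Full per-window chain and record-level extraction
# --------------------------------------------------------------------------

def window_features(window: np.ndarray, filt: FilterSpec = FilterSpec(),
                    bands: BandDefinition = BandDefinition(), fs: float = 256.0,
                    source_window: int = 0) -> PSDFeatureVector:
    """moving average -> band-pass -> FFT -> PSD -> band bins, per channel."""
    if window.ndim != 2 or window.shape[1] != 2:
        raise ValueError("expected a (n_samples, 2) window")
    psds = []
    for ch in range(2):
        x = moving_average(window[:, ch].astype(float), filt.moving_average_width)
        x = bandpass(x, filt, fs)
        psds.append(psd(fft256(x)))
    return band_features(psds[0], psds[1], bands, source_window)


def feature_columns(bands: BandDefinition = BandDefinition()) -> list[str]:
    """Stable, documented feature ordering: CH1 theta..beta bins, then CH2."""
    return [
        f"ch{c}_{name}_{hz}hz"
        for c in (1, 2)
        for name, (lo, hi) in (("theta", bands.theta), ("alpha", bands.alpha),
                               ("beta", bands.beta))
        for hz in range(lo, hi + 1)
    ]


FEATURE_COLUMNS = feature_columns()


def _window_label(record: EEGRecord, lo: int, hi: int) -> TaskLabel:
    """Annotation with the largest overlap with [lo, hi)."""
    best, best_overlap = None, -1
    for start, end, label in record.annotations:
        overlap = min(end, hi) - max(start, lo)
        if overlap > best_overlap:
            best, best_overlap = label, overlap
    return best


def extract_features(record: EEGRecord,
                     window: WindowSpec = WindowSpec(),
                     filt: FilterSpec = FilterSpec(),
                     bands: BandDefinition = BandDefinition(),
                     *, analysis_span: float | None = None,
                     start: float = 0.0) -> pd.DataFrame:
    """Feature matrix for a record: one row per window, 54 feature columns
    plus ``window_index`` and ``label``.

    Counts are dequantized to microvolts before filtering.  By default the
    whole record (from ``start``) is analysed; pass ``analysis_span`` to
    restrict it, e.g. ``start=3, analysis_span=10`` for the 13 s protocol.
    """
    if analysis_span is None:
        analysis_span = record.duration - start
    wins = segment(record, window, analysis_span, start=start)
    n0 = int(round(start * record.sampling_rate))
    rows, labels = [], []
    for w in range(len(wins)):
        uV = (wins[w] - record.adc.mid_code) * record.adc.input_referred_lsb_uV
        fv = window_features(uV, filt, bands, record.sampling_rate, w)
        rows.append(fv.values)
        lo = n0 + w * window.n_step
        labels.append(_window_label(record, lo, lo + window.n_window).value)
    df = pd.DataFrame(rows, columns=feature_columns(bands))
    df.insert(0, "window_index", np.arange(len(rows)))
    df["label"] = labels
    return df
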