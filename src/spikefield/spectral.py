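"""LFP spectral chain: preprocessing, Morlet spectrograms, band responses.

The chain mirrors standard intracranial practice: low-pass the wideband
voltage below 250 Hz (8th-order type-I Chebyshev), downsample to 500 Hz,
regress out line noise with sine/cosine regressors (harmonic regression),
estimate per-trial amplitude with an 8-cycle Morlet decomposition on a
quadratically spaced 2-200 Hz grid, convert each frequency to percent
change from the pre-stimulus baseline, and average within canonical bands
(theta 4-8, alpha 8-12, beta 13-30, gamma 30-50, high-gamma 50-150,
broadband 3-200 Hz).

Amplitude is normalized so that a unit-amplitude sinusoid at a grid
frequency reads ~1 away from edges; percent-change normalization is in any
case invariant to per-frequency gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BANDS",
    "TARGET_RATE",
    "VoltageRecording",
    "Spectrogram",
    "BandResponse",
    "preprocess_lfp",
    "frequency_grid",
    "morlet_spectrogram",
    "baseline_normalize",
    "band_average",
    "erp",
]

#: Canonical frequency bands, Hz (inclusive bounds).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
    "hga": (50.0, 150.0),
    "broadband": (3.0, 200.0),
}

TARGET_RATE = 500.0


@dataclass
class VoltageRecording:
    """Continuous multi-channel voltage with stimulus-onset sample indices."""

    samples: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    onsets: np.ndarray  # strictly increasing sample indices
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.onsets) and (
            np.any(np.diff(self.onsets) <= 0)
            or self.onsets[0] < 0
            or self.onsets[-1] >= self.samples.shape[1]
        ):
            raise ValueError("onsets must be strictly increasing and in range")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.samples.shape[0])]

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class Spectrogram:
    """Per-trial amplitude, (n_trials, n_channels, n_freqs, n_times)."""

    amplitude: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray  # ms relative to stimulus onset
    normalization: str = "raw"  # {"raw", "percent_change"}
    baseline_window: tuple[float, float] | None = None
    edge_valid: np.ndarray | None = None  # (n_freqs, n_times) bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.normalization not in ("raw", "percent_change"):
            raise ValueError("normalization must be 'raw' or 'percent_change'")


@dataclass
class BandResponse:
    """Band-averaged percent change: (n_channels, n_trials) or with a time axis."""

    value: np.ndarray
    band: tuple[float, float]
    band_name: str | None
    window_ms: tuple[float, float] | None
    times: np.ndarray | None = None  # present when no time window was collapsed


def _harmonic_regression(
    x: np.ndarray, fs: float, freqs: tuple[float, ...]
) -> np.ndarray:
    """Remove sinusoidal components by least squares per channel."""
    n = x.shape[-1]
    t = np.arange(n) / fs
    cols = []
    for f in freqs:
        cols.append(np.sin(2 * np.pi * f * t))
        cols.append(np.cos(2 * np.pi * f * t))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ coef).T


def preprocess_lfp(
    raw: VoltageRecording,
    line_freq: float = 60.0,
    n_harmonics: int = 1,
    ripple_db: float = 0.05,
) -> VoltageRecording:
    """Low-pass below 250 Hz, downsample to 500 Hz, remove line noise.

    The anti-alias filter is an 8th-order type-I Chebyshev applied
    zero-phase; line noise at ``line_freq`` (and ``n_harmonics - 1``
    further harmonics) is removed by harmonic regression.
    """
    fs = raw.sampling_rate
    if fs < TARGET_RATE:
        raise ValueError(f"input sampling rate {fs} Hz is below {TARGET_RATE} Hz")

    x = raw.samples
    if fs > TARGET_RATE:
        factor = fs / TARGET_RATE
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                "sampling rate must be an integer multiple of 500 Hz "
                f"(got {fs})"
            )
        factor = int(round(factor))
        sos = sps.cheby1(8, ripple_db, 250.0, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=-1)
        x = x[:, ::factor]
        onsets = raw.onsets // factor
    else:
        onsets = raw.onsets.copy()

    harmonics = tuple(line_freq * (k + 1) for k in range(n_harmonics))
    x = _harmonic_regression(x, TARGET_RATE, harmonics)
    return VoltageRecording(
        samples=x,
        sampling_rate=TARGET_RATE,
        onsets=onsets,
        channel_ids=list(raw.channel_ids),
    )


def frequency_grid(
    low: float = 2.0, high: float = 200.0, n: int = 50
) -> np.ndarray:
    """Quadratically spaced frequency grid: squares of linearly spaced
    square roots, spanning [low, high] Hz with successively wider gaps."""
    return np.linspace(np.sqrt(low), np.sqrt(high), n) ** 2


def _morlet_kernel(f: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet kernel normalized to unit response to a unit sinusoid."""
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-0.5 * (t / sigma_t) ** 2)
    kernel = envelope * np.exp(2j * np.pi * f * t)
    return 2.0 * kernel / envelope.sum()


def morlet_spectrogram(
    lfp: VoltageRecording,
    frequencies: np.ndarray | None = None,
    cycles: float = 8.0,
    epoch_ms: tuple[float, float] = (-300.0, 500.0),
) -> Spectrogram:
    """Per-trial Morlet amplitude around each stimulus onset.

    The transform runs on the continuous trace (mirror-padded by one
    kernel half-length) and is then cut into epochs.  ``edge_valid`` flags
    epoch samples that fall within one wavelet half-length of the ends of
    the recording for the slowest frequency analyzed.
    """
    if frequencies is None:
        frequencies = frequency_grid()
    frequencies = np.asarray(frequencies, dtype=float)
    fs = lfp.sampling_rate
    nyq = fs / 2.0
    too_high = frequencies[frequencies >= nyq]
    if too_high.size:
        raise ValueError(
            f"frequency {too_high[0]:g} Hz is at or above Nyquist ({nyq:g} Hz)"
        )
    if len(lfp.onsets) == 0:
        raise ValueError("recording has no stimulus onsets to epoch around")

    pre = int(round(-epoch_ms[0] / 1000.0 * fs))
    post = int(round(epoch_ms[1] / 1000.0 * fs))
    n_times = pre + post
    times = (np.arange(n_times) - pre) / fs * 1000.0

    n_samples = lfp.samples.shape[1]
    n_ch = lfp.n_channels
    n_f = len(frequencies)
    amp_full = np.empty((n_ch, n_f, n_samples))
    halves = np.empty(n_f, dtype=int)
    for k, f in enumerate(frequencies):
        kernel = _morlet_kernel(f, fs, cycles)
        half = (len(kernel) - 1) // 2
        halves[k] = half
        padded = np.pad(lfp.samples, ((0, 0), (half, half)), mode="reflect")
        for ch in range(n_ch):
            conv = np.convolve(padded[ch], kernel, mode="valid")
            amp_full[ch, k] = np.abs(conv)

    amplitude = np.empty((len(lfp.onsets), n_ch, n_f, n_times))
    edge_valid = np.ones((n_f, n_times), dtype=bool)
    for t_i, onset in enumerate(lfp.onsets):
        start, stop = onset - pre, onset + post
        if start < 0 or stop > n_samples:
            raise ValueError(
                f"epoch around onset {onset} extends outside the recording"
            )
        amplitude[t_i] = amp_full[:, :, start:stop]
        for k in range(n_f):
            lo = max(halves[k] - start, 0)
            hi = max(stop - (n_samples - halves[k]), 0)
            if lo:
                edge_valid[k, :lo] = False
            if hi:
                edge_valid[k, n_times - hi :] = False

    return Spectrogram(
        amplitude=amplitude,
        frequencies=frequencies,
        times=times,
        normalization="raw",
        edge_valid=edge_valid,
    )


def baseline_normalize(
    spec: Spectrogram, baseline_window: tuple[float, float] = (-200.0, 0.0)
) -> Spectrogram:
    """Percent change from the per-trial, per-frequency baseline mean.

    ``value(f, t) = 100 * (amp(f, t) - baseline(f)) / baseline(f)`` with the
    baseline averaged over ``baseline_window`` (half-open, ms).
    """
    if spec.normalization != "raw":
        raise ValueError("input spectrogram must be raw amplitude")
    mask = (spec.times >= baseline_window[0]) & (spec.times < baseline_window[1])
    if not mask.any():
        raise ValueError("baseline window contains no time samples")
    baseline = spec.amplitude[..., mask].mean(axis=-1, keepdims=True)
    zero = np.isclose(baseline, 0.0)
    if zero.any():
        bad_f = spec.frequencies[np.argwhere(zero)[0][-2]]
        raise ValueError(f"zero baseline amplitude at {bad_f:g} Hz")
    pct = 100.0 * (spec.amplitude - baseline) / baseline
    return Spectrogram(
        amplitude=pct,
        frequencies=spec.frequencies,
        times=spec.times,
        normalization="percent_change",
        baseline_window=tuple(baseline_window),
        edge_valid=spec.edge_valid,
    )


def band_average(
    spec: Spectrogram,
    band: str | tuple[float, float],
    window_ms: tuple[float, float] | None = None,
) -> BandResponse:
    """Mean percent change over a band's grid frequencies (inclusive
    bounds), optionally then over a time window (half-open, ms).

    Returns channel x trial values when a window is given, otherwise
    channel x trial x time courses.
    """
    if spec.normalization != "percent_change":
        raise ValueError("band_average expects a percent-change spectrogram")
    if isinstance(band, str):
        name, (low, high) = band, BANDS[band]
    else:
        name, (low, high) = None, (float(band[0]), float(band[1]))
    fmask = (spec.frequencies >= low) & (spec.frequencies <= high)
    if not fmask.any():
        raise ValueError(f"band [{low}, {high}] Hz contains no grid frequencies")
    course = spec.amplitude[:, :, fmask, :].mean(axis=2)  # trials x ch x time
    if window_ms is None:
        return BandResponse(
            value=np.moveaxis(course, 0, 1),
            band=(low, high),
            band_name=name,
            window_ms=None,
            times=spec.times,
        )
    tmask = (spec.times >= window_ms[0]) & (spec.times < window_ms[1])
    if not tmask.any():
        raise ValueError("time window contains no samples")
    value = course[..., tmask].mean(axis=-1)  # trials x ch
    return BandResponse(
        value=value.T,
        band=(low, high),
        band_name=name,
        window_ms=tuple(window_ms),
    )


def erp(lfp: VoltageRecording, epoch_ms: tuple[float, float] = (-300.0, 500.0)) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged voltage (no smoothing), per channel.

    Returns ``(times_ms, erp)`` with ``erp`` of shape (n_channels, n_times).
    """
    fs = lfp.sampling_rate
    pre = int(round(-epoch_ms[0] / 1000.0 * fs))
    post = int(round(epoch_ms[1] / 1000.0 * fs))
    times = (np.arange(pre + post) - pre) / fs * 1000.0
    epochs = np.stack(
        [lfp.samples[:, o - pre : o + post] for o in lfp.onsets], axis=0
    )
    return times, epochs.mean(axis=0)
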