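"""Forward simulation: spike counts, channel aggregates, voltage, behavior.

The rate model for neuron *i* on a trial is

    lambda_i = baseline_i * (1 + g_mem * (memorability - 0.5)) * gain_i(category)
               * (1 - s0 * exp(-(n_back - 1) / tau))   [repeated trials only]

Spike counts are Poisson in the count window.  The channel aggregate
("HGA proxy") is the pooling-weighted mean of the *true* rates — not the
realized counts — plus additive Gaussian noise, reflecting that a field
potential averages the activity of many more neurons than the few exported
as sorted units.  Voltage mode instead synthesizes a continuous trace per
channel (pooled spike trains convolved with a brief biphasic kernel, plus
1/f background and an optional 60 Hz contaminant) to exercise the spectral
chain end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import PopulationModel

__all__ = [
    "SessionData",
    "trial_rates",
    "simulate_responses",
    "simulate_voltage",
    "simulate_behavior",
]


@dataclass
class SessionData:
    """One simulated session: spike counts plus either a per-trial channel
    aggregate (rate mode) or a continuous voltage trace (voltage mode)."""

    trial_table: pd.DataFrame
    spike_counts: np.ndarray  # (n_units, n_trials) non-negative ints
    unit_to_channel: np.ndarray  # (n_units,) channel index per unit
    count_window_ms: float
    seed: int
    mode: str = "rate"
    hga_proxy: np.ndarray | None = None  # (n_channels, n_trials), Hz
    voltage: np.ndarray | None = None  # (n_channels, n_samples)
    sampling_rate: float | None = None
    onset_samples: np.ndarray | None = None
    session_id: str = "sim"

    def __post_init__(self) -> None:
        if self.mode not in ("rate", "voltage"):
            raise ValueError("mode must be 'rate' or 'voltage'")
        has_rate = self.hga_proxy is not None
        has_volt = self.voltage is not None
        if has_rate and has_volt:
            raise ValueError("rate mode and voltage mode are mutually exclusive")
        n_trials = len(self.trial_table)
        if self.spike_counts.shape[1] != n_trials:
            raise ValueError(
                f"spike_counts has {self.spike_counts.shape[1]} trials, "
                f"table has {n_trials}"
            )

    @property
    def n_units(self) -> int:
        return int(self.spike_counts.shape[0])

    @property
    def n_channels(self) -> int:
        if self.hga_proxy is not None:
            return int(self.hga_proxy.shape[0])
        if self.voltage is not None:
            return int(self.voltage.shape[0])
        return int(self.unit_to_channel.max()) + 1


def trial_rates(model: PopulationModel, trials: pd.DataFrame) -> np.ndarray:
    """True firing rate (Hz) of every neuron on every trial, (n_neurons, n_trials)."""
    mem = trials["memorability"].to_numpy(dtype=float)
    mem_gain = 1.0 + model.memorability_gain * (mem - 0.5)
    if np.any(mem_gain <= 0):
        raise ValueError("memorability gain drives rates non-positive")

    rates = model.baseline_rate[:, None] * mem_gain[None, :]

    if model.category_tuning is not None and "category" in trials:
        cats = trials["category"].to_numpy()
        cat_index = {c: k for k, c in enumerate(model.categories)}
        for t, c in enumerate(cats):
            if c is not None and not (isinstance(c, float) and np.isnan(c)):
                rates[:, t] *= model.category_tuning[:, cat_index[c]]

    repeated = (trials["exposure"] == "repeated").to_numpy()
    if repeated.any():
        factor = model.suppression_factor(
            trials.loc[repeated, "n_back"].to_numpy(dtype=float)
        )
        rates[:, repeated] *= factor[None, :]
    return rates


def simulate_responses(
    model: PopulationModel,
    trials: pd.DataFrame,
    seed: int = 0,
    pool: str = "rate",
) -> SessionData:
    """Rate-mode session: Poisson spike counts and channel aggregates.

    ``pool='rate'`` (default) pools the true underlying rates over every
    neuron in each channel's radius.  ``pool='counts'`` instead pools the
    realized spike counts of the *exported units only* — a degenerate
    configuration in which a channel carries exactly the information of its
    units, useful as a control where spike- and channel-based decoding
    should match.
    """
    if pool not in ("rate", "counts"):
        raise ValueError("pool must be 'rate' or 'counts'")
    rng = np.random.default_rng(seed)
    rates = trial_rates(model, trials)
    window_s = model.count_window_ms / 1000.0
    counts_all = rng.poisson(rates * window_s)
    spike_counts = counts_all[model.unit_indices]

    if pool == "rate":
        pooled = model.pooling_weights @ rates
    else:
        # per channel: mean realized rate (Hz) of its own exported units
        n_ch = model.n_channels
        pooled = np.zeros((n_ch, rates.shape[1]))
        unit_hz = spike_counts / window_s
        for ch in range(n_ch):
            members = model.unit_to_channel == ch
            if not members.any():
                raise ValueError(f"channel {ch} has no exported units to pool")
            pooled[ch] = unit_hz[members].mean(axis=0)
    noise = rng.normal(0.0, model.channel_noise_sd, size=pooled.shape)
    hga_proxy = pooled + noise

    return SessionData(
        trial_table=trials.reset_index(drop=True),
        spike_counts=spike_counts,
        unit_to_channel=model.unit_to_channel.copy(),
        count_window_ms=model.count_window_ms,
        seed=seed,
        mode="rate",
        hga_proxy=hga_proxy,
        session_id=str(trials["session_id"].iloc[0]) if len(trials) else "sim",
    )


def _biphasic_kernel(sampling_rate: float, width_ms: float = 2.0) -> np.ndarray:
    """Brief biphasic (derivative-of-Gaussian) spike-to-field kernel."""
    sd = width_ms / 1000.0
    t = np.arange(-4 * sd, 4 * sd, 1.0 / sampling_rate)
    k = -t / sd**2 * np.exp(-0.5 * (t / sd) ** 2)
    return k / np.abs(k).max()


def _pink_noise(
    n: int, rng: np.random.Generator, fs: float = 500.0, f_min: float = 1.0
) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, flattened below ``f_min`` Hz.

    The low-frequency cutoff keeps the background stationary on the scale
    of a trial (exact 1/f noise diverges at DC and would put a slow drift
    into every epoch); recording hardware high-passes in this range anyway.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(f, f_min))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def simulate_voltage(
    model: PopulationModel,
    trials: pd.DataFrame,
    sampling_rate: float = 1000.0,
    seed: int = 0,
    pre_ms: float = 400.0,
    post_ms: float = 500.0,
    evoked_gain: float = 2.0,
    spike_gain: float = 10.0,
    noise_sd: float = 1.0,
    line_amplitude: float = 0.0,
    line_freq: float = 60.0,
) -> SessionData:
    """Voltage-mode session for exercising the spectral chain.

    Trials are laid out back to back as epochs of ``pre_ms + post_ms``.
    Each neuron fires Poisson spikes at its baseline rate before stimulus
    onset and at ``evoked_gain`` times its trial rate in the count window
    after onset (the visual transient);
    each channel's trace is the pooling-weighted sum of spike trains
    convolved with a biphasic kernel, plus pink background noise and an
    optional line-frequency sinusoid.
    """
    if sampling_rate < 500:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz cannot support the 150 Hz "
            "band after decimation to 500 Hz; need >= 500 Hz"
        )
    rng = np.random.default_rng(seed)
    rates = trial_rates(model, trials)
    n_trials = rates.shape[1]
    epoch_samples = int(round((pre_ms + post_ms) / 1000.0 * sampling_rate))
    onset_offset = int(round(pre_ms / 1000.0 * sampling_rate))
    window_samples = int(round(model.count_window_ms / 1000.0 * sampling_rate))
    total = epoch_samples * n_trials
    dt = 1.0 / sampling_rate

    n_ch = model.n_channels
    drive = np.zeros((n_ch, total))
    window_s = model.count_window_ms / 1000.0
    spike_counts = np.zeros((model.n_units, n_trials), dtype=int)

    for t in range(n_trials):
        lam = np.tile(model.baseline_rate[:, None], (1, epoch_samples))
        stop = min(onset_offset + window_samples, epoch_samples)
        lam[:, onset_offset:stop] = evoked_gain * rates[:, t][:, None]
        spikes = rng.poisson(lam * dt).astype(float)
        sl = slice(t * epoch_samples, (t + 1) * epoch_samples)
        drive[:, sl] = model.pooling_weights @ spikes
        spike_counts[:, t] = spikes[model.unit_indices, onset_offset:stop].sum(axis=1)

    kernel = _biphasic_kernel(sampling_rate)
    from scipy.signal import fftconvolve

    voltage = np.empty_like(drive)
    for ch in range(n_ch):
        voltage[ch] = spike_gain * fftconvolve(drive[ch], kernel, mode="same")
        voltage[ch] += noise_sd * _pink_noise(total, rng, fs=sampling_rate)
    if line_amplitude > 0:
        tvec = np.arange(total) * dt
        voltage += line_amplitude * np.sin(2 * np.pi * line_freq * tvec)[None, :]

    onsets = np.arange(n_trials) * epoch_samples + onset_offset
    return SessionData(
        trial_table=trials.reset_index(drop=True),
        spike_counts=spike_counts,
        unit_to_channel=model.unit_to_channel.copy(),
        count_window_ms=model.count_window_ms,
        seed=seed,
        mode="voltage",
        voltage=voltage,
        sampling_rate=float(sampling_rate),
        onset_samples=onsets,
        session_id=str(trials["session_id"].iloc[0]) if len(trials) else "sim",
    )


def simulate_behavior(
    trials: pd.DataFrame,
    suppression_s0: float,
    suppression_tau: float,
    readout_noise: float = 0.1,
    criterion: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill behavioral choices from a noisy internal suppression signal.

    The internal signal on a repeated trial at n-back *n* is
    ``s0 * exp(-(n - 1) / tau)`` and 0 on novel trials; the subject reports
    "repeated" when signal + noise exceeds the criterion (default: s0 / 2).
    Hit rate therefore declines with n-back, mimicking temporal forgetting.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    if criterion is None:
        criterion = suppression_s0 / 2.0
    n = out["n_back"].to_numpy(dtype=float)
    repeated = (out["exposure"] == "repeated").to_numpy()
    signal = np.where(
        repeated, suppression_s0 * np.exp(-(n - 1.0) / suppression_tau), 0.0
    )
    noisy = signal + rng.normal(0.0, max(readout_noise, 1e-12), size=len(out))
    out["choice"] = np.where(noisy > criterion, "repeated", "novel")
    return out
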