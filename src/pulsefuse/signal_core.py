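"""Shared numeric primitives for pulse-signal processing.

Everything downstream (rPPG, rBCG, fusion, evaluation) trades in
:class:`Signal1D` — a uniformly sampled scalar series — and the spectral
statistics defined here: the band-limited power spectrum, the max-bin
signal-to-noise ratio used for component selection throughout the
pipeline, and the dominant-frequency heart-rate estimate
(``HR = 60 * f_dominant``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: Default analysis band in Hz: 0.75–2.5 Hz covers 45–150 bpm.
DEFAULT_BAND: tuple[float, float] = (0.75, 2.5)

#: Target spectral resolution after zero-padding, Hz (0.5 bpm).
SPECTRAL_RESOLUTION_HZ = 1.0 / 120.0


@dataclass(frozen=True)
class Signal1D:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    samples
        Sample values; stored as a float64 array.
    fs
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be 1-D with at least 2 values")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at 0."""
        return np.arange(len(self)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Signal1D":
        """A new signal with the same fs and different samples."""
        return Signal1D(samples, self.fs)


@dataclass(frozen=True)
class PowerSpectrum:
    """Power spectrum restricted to an analysis band."""

    freqs: np.ndarray
    power: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        power = np.asarray(self.power, dtype=np.float64)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D and equal length")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")
        lo, hi = self.band
        if freqs.size and (freqs[0] < lo - 1e-12 or freqs[-1] > hi + 1e-12):
            raise ValueError("freqs outside band")


@dataclass(frozen=True)
class HrEstimate:
    """A spectral heart-rate estimate: rate, dominant frequency, SNR."""

    bpm: float
    dominant_freq: float
    snr: float


def mean_center(s: Signal1D) -> Signal1D:
    """Subtract the signal mean (removes the static skin-tone component)."""
    return s.with_samples(s.samples - s.samples.mean())


def bandpass(
    s: Signal1D,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    order: int = 2,
) -> Signal1D:
    """Zero-phase Butterworth band-pass filter.

    A band-pass of the given design order is applied forward and backward
    (``sosfiltfilt``), so the pulse waveform keeps its timing while the
    effective magnitude response is squared.

    Raises
    ------
    ValueError
        If the band is infeasible for the sampling rate.
    """
    nyq = s.fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz infeasible for fs={s.fs} Hz"
        )
    if len(s) <= 3 * order:
        raise ValueError("signal too short for the filter order")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=s.fs, output="sos")
    return s.with_samples(sps.sosfiltfilt(sos, s.samples))


def clip_to_mean(s: Signal1D, k: float = 2.0) -> Signal1D:
    """Replace large-amplitude excursions by the signal mean.

    Samples deviating from the mean by more than ``k`` standard deviations
    are set to the mean. Both statistics come from the input signal and the
    replacement is a single pass — the correction is not iterated.
    Suppresses voluntary head-movement transients in motion trajectories.
    """
    x = s.samples
    m = x.mean()
    sd = x.std()
    if sd == 0:
        return s
    out = np.where(np.abs(x - m) > k * sd, m, x)
    return s.with_samples(out)


def power_spectrum(
    s: Signal1D, band: tuple[float, float] = DEFAULT_BAND
) -> PowerSpectrum:
    """Band-limited FFT power spectrum.

    The signal is mean-centered and zero-padded so that the bin spacing is
    at most 1/120 Hz (0.5 bpm), then the squared-magnitude FFT is restricted
    to bins inside ``band`` (inclusive). No taper is applied.
    """
    if len(s) < 64:
        raise ValueError("need at least 64 samples for a spectrum")
    lo, hi = band
    x = s.samples - s.samples.mean()
    min_bins = int(np.ceil(s.fs / SPECTRAL_RESOLUTION_HZ))
    nfft = 1 << int(np.ceil(np.log2(max(len(x), min_bins))))
    spec = np.fft.rfft(x, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / s.fs)
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError("no FFT bins inside the requested band")
    return PowerSpectrum(freqs[mask], np.abs(spec[mask]) ** 2, band)


def snr(ps: PowerSpectrum) -> float:
    """Max-bin signal-to-noise ratio of a power spectrum.

    ``SNR = max(PS) / (sum(PS) - max(PS))``: the power of the single
    strongest bin against the total power of every other bin. Used as the
    selection statistic for ICA/PCA components and trajectory pruning.

    Returns ``inf`` when all power sits in one bin; raises on an all-zero
    spectrum. Ties take the first (lowest-frequency) maximal bin once.
    """
    p = ps.power
    if p.size < 2:
        raise ValueError("need at least 2 bins")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero spectrum has no defined SNR")
    peak = p.max()
    rest = total - peak
    if rest <= 0:
        return np.inf
    return float(peak / rest)


def dominant_hr(
    s: Signal1D, band: tuple[float, float] = DEFAULT_BAND
) -> HrEstimate:
    """Heart rate from the dominant in-band spectral peak.

    ``HR = 60 * f_dominant`` where the dominant frequency is the in-band
    bin of maximal power (ties broken toward the lower frequency). The
    returned SNR is the max-bin statistic of the same band-limited spectrum.
    """
    ps = power_spectrum(s, band)
    i = int(np.argmax(ps.power))
    f = float(ps.freqs[i])
    return HrEstimate(bpm=60.0 * f, dominant_freq=f, snr=snr(ps))


#: Window length for the selection statistic, s. A time-varying heart
#: rate smears the whole-recording spectrum, penalizing exactly the
#: component carrying the pulse; within a half-minute window the pulse is
#: near-tonal, so the selection SNR is averaged over such windows.
SNR_WINDOW_S = 30.0


def windowed_snr(
    samples: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    window_s: float = SNR_WINDOW_S,
) -> float:
    """Mean max-bin SNR over consecutive non-overlapping windows.

    Falls back to the whole-signal statistic when the signal is shorter
    than one window; flat windows contribute an SNR of 0.
    """
    samples = np.asarray(samples, dtype=np.float64)
    win = int(round(window_s * fs))
    if win < 64 or samples.size < win:
        segments = [samples]
    else:
        n_win = samples.size // win
        segments = [samples[k * win : (k + 1) * win] for k in range(n_win)]
    values = []
    for seg in segments:
        try:
            values.append(snr(power_spectrum(Signal1D(seg, fs), band)))
        except ValueError:  # flat segment
            values.append(0.0)
    return float(np.mean(values))


def best_by_snr(
    components: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    tie_eps: float = 1e-9,
) -> Signal1D:
    """Pick the component series with the highest windowed max-bin SNR.

    ``components`` is (n_components, n_samples). The winner is returned
    zero-mean with unit standard deviation. Near-ties (SNR difference
    below ``tie_eps``) resolve to the component with the lower dominant
    frequency, keeping the selection deterministic.
    """
    comps = np.atleast_2d(np.asarray(components, dtype=np.float64))
    scored: list[tuple[float, float, int]] = []
    for i, row in enumerate(comps):
        sig = Signal1D(row, fs)
        try:
            ps = power_spectrum(sig, band)
            value = windowed_snr(row, fs, band)
            f = float(ps.freqs[np.argmax(ps.power)])
        except ValueError:  # flat/zero component
            value, f = -np.inf, np.inf
        scored.append((value, f, i))
    best = max(scored, key=lambda t: (t[0], -t[1]))
    # re-apply the tie rule explicitly for (near-)equal SNRs; the equality
    # branch also catches two infinite-SNR components
    candidates = [t for t in scored
                  if t[0] == best[0] or abs(t[0] - best[0]) < tie_eps]
    _, _, idx = min(candidates, key=lambda t: t[1])
    return standardize(Signal1D(comps[idx], fs))


def standardize(s: Signal1D) -> Signal1D:
    """Zero-mean, unit-variance scaling (no-op scale for constant input)."""
    x = s.samples - s.samples.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    return s.with_samples(x)
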