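"""Remote ballistocardiography: pulse extraction from head-motion traces.

Each heartbeat's blood ejection recoils the head vertically by a
fraction of a millimeter, visible as a sub-pixel oscillation of tracked
facial points. The vertical trajectory of each of the 80 grid points is
mean-centered, band-passed to 0.75–2.5 Hz, and cleaned of voluntary
head-movement transients by replacing samples beyond 2 standard
deviations with the mean. Channels corrupted by localized motion (e.g. a
smile moving the cheek points) are pruned by dropping every channel
whose max-bin SNR is below the channel mean. PCA over the survivors
yields up to five candidate source series; the one with the highest SNR
is the rBCG signal. Horizontal coordinates are tracked but only serve
the re-detection rule — the ballistocardiographic recoil is vertical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .geometry import TrajectoryBank
from .signal_core import (
    DEFAULT_BAND,
    Signal1D,
    bandpass,
    best_by_snr,
    clip_to_mean,
    power_spectrum,
    snr,
    windowed_snr,
)

log = logging.getLogger(__name__)

#: Number of principal components considered for selection.
N_PCA_COMPONENTS = 5


@dataclass
class SignalBank:
    """A stack of equally sampled channels (one per tracked point)."""

    channels: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channels.shape[0] < 1:
            raise ValueError("need at least one channel")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channels must be finite")
        if not self.channel_ids:
            self.channel_ids = tuple(range(self.channels.shape[0]))
        elif len(self.channel_ids) != self.channels.shape[0]:
            raise ValueError("channel_ids must match channel count")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


def y_signal_bank(traj: TrajectoryBank) -> SignalBank:
    """Mean-centered vertical trajectories, one channel per tracked point."""
    if traj.n_frames < 64:
        raise ValueError("need >= 64 frames of trajectories")
    ys = traj.ys - traj.ys.mean(axis=1, keepdims=True)
    return SignalBank(ys, traj.fps, tuple(range(traj.n_points)))


def condition_bank(
    bank: SignalBank,
    band: tuple[float, float] = DEFAULT_BAND,
    k_sigma: float = 2.0,
) -> SignalBank:
    """Band-pass each channel, then clamp large-amplitude excursions.

    The 2-sigma mean-replacement suppresses voluntary head-movement
    transients that survive the band-pass.
    """
    rows = np.empty_like(bank.channels)
    for i, row in enumerate(bank.channels):
        sig = bandpass(Signal1D(row, bank.fs), *band)
        rows[i] = clip_to_mean(sig, k=k_sigma).samples
    return SignalBank(rows, bank.fs, bank.channel_ids)


def _channel_snr(row: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    try:
        return windowed_snr(row, fs, band)
    except ValueError:  # flat channel: no spectral peak at all
        return 0.0


def prune_by_snr(
    bank: SignalBank, band: tuple[float, float] = DEFAULT_BAND
) -> SignalBank:
    """Drop channels whose max-bin SNR falls below the channel-mean SNR.

    Channels distorted by localized facial motion carry little cardiac
    power; at least one channel (the global best) always survives since
    the maximum is never below the mean.
    """
    if bank.n_channels < 2:
        return bank
    snrs = np.array([_channel_snr(r, bank.fs, band) for r in bank.channels])
    finite = snrs[np.isfinite(snrs)]
    threshold = finite.mean() if finite.size else 0.0
    keep = snrs >= threshold
    if not np.any(keep):  # all channels infinite/degenerate in the same way
        keep[int(np.argmax(snrs))] = True
    ids = tuple(cid for cid, k in zip(bank.channel_ids, keep) if k)
    return SignalBank(bank.channels[keep], bank.fs, ids)


def bcg_signal(
    bank: SignalBank,
    band: tuple[float, float] = DEFAULT_BAND,
    n_components: int = N_PCA_COMPONENTS,
) -> Signal1D:
    """PCA the channel bank and keep the component with the best SNR.

    Principal-component scores (projections of the samples onto the
    eigenvectors of the channel covariance) are the candidate signals;
    the component count is capped by the post-pruning channel count and
    the sample count. The winner is returned at unit variance.
    """
    k = min(n_components, bank.n_channels, bank.n_samples)
    if k < min(n_components, bank.n_channels):
        log.warning("rank-limited PCA: using %d component(s)", k)
    if bank.n_channels == 1:
        return best_by_snr(bank.channels, bank.fs, band)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(bank.channels.T)  # (n_samples, k)
    return best_by_snr(scores.T, bank.fs, band)


def rbcg_from_trajectories(
    traj: TrajectoryBank,
    band: tuple[float, float] = DEFAULT_BAND,
) -> Signal1D:
    """Full rBCG chain: center -> band-pass -> 2-sigma clamp -> prune -> PCA."""
    bank = y_signal_bank(traj)
    bank = condition_bank(bank, band=band)
    bank = prune_by_snr(bank, band=band)
    return bcg_signal(bank, band=band)
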