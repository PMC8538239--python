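"""Fusing the color (rPPG) and motion (rBCG) pulse signals.

The two modalities see the same cardiac source through different noise:
color is corrupted by illumination variance (high-frequency), motion by
head-movement artifacts (low-frequency). Three blind-source-separation
style combinations are offered: ensemble averaging
(``EA = (RPPG + RBCG) / 2``), and 2-component PCA or ICA with the
higher-SNR component selected. Inputs are expected standardized (zero
mean, unit variance) so neither modality's units dominate — the
extraction chains already return unit-variance signals.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .ppg import decompose
from .signal_core import DEFAULT_BAND, Signal1D, best_by_snr


class FusionMethod(str, Enum):
    """The three supported fusion schemes."""

    EA = "ea"
    PCA = "pca"
    ICA = "ica"


def align_sign(reference: Signal1D, other: Signal1D) -> Signal1D:
    """Flip ``other`` if it anti-correlates with ``reference``.

    Blind source separation recovers each pulse signal up to sign; an
    anti-phase pair would cancel its shared cardiac component under
    ensemble averaging, so the pipeline aligns signs before fusing.
    """
    _check_pair(reference, other)
    if np.dot(reference.samples - reference.samples.mean(),
              other.samples - other.samples.mean()) < 0:
        return other.with_samples(-other.samples)
    return other


def _check_pair(rppg: Signal1D, rbcg: Signal1D) -> None:
    if len(rppg) != len(rbcg):
        raise ValueError("rPPG and rBCG signals must have equal length")
    if rppg.fs != rbcg.fs:
        raise ValueError("rPPG and rBCG signals must share sampling rate")


def fuse_ea(rppg: Signal1D, rbcg: Signal1D) -> Signal1D:
    """Ensemble average: the element-wise mean of the two signals."""
    _check_pair(rppg, rbcg)
    return Signal1D((rppg.samples + rbcg.samples) / 2.0, rppg.fs)


def fuse_bss(
    rppg: Signal1D,
    rbcg: Signal1D,
    method: FusionMethod,
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int = 0,
) -> Signal1D:
    """PCA or ICA over the two signals; keep the higher-SNR component.

    Two components are extracted (the decomposition is applied to two
    signals); ICA falls back to PCA on non-convergence.
    """
    if method not in (FusionMethod.PCA, FusionMethod.ICA):
        raise ValueError(f"fuse_bss expects PCA or ICA, got {method}")
    _check_pair(rppg, rbcg)
    x = np.stack([rppg.samples, rbcg.samples], axis=1)
    if method is FusionMethod.ICA:
        sources = decompose(x, n_components=2, seed=seed)
    else:
        from sklearn.decomposition import PCA

        sources = PCA(n_components=2).fit_transform(x)
    return best_by_snr(sources.T, rppg.fs, band)


def fuse(
    rppg: Signal1D,
    rbcg: Signal1D,
    method: FusionMethod | str,
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int = 0,
) -> Signal1D:
    """Dispatch to the requested fusion scheme."""
    try:
        method = FusionMethod(method.lower() if isinstance(method, str) else method)
    except ValueError:
        raise ValueError(f"unknown fusion method {method!r}") from None
    if method is FusionMethod.EA:
        return fuse_ea(rppg, rbcg)
    return fuse_bss(rppg, rbcg, method, band=band, seed=seed)
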