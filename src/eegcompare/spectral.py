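"""Frequency-domain analysis: Welch PSD, Z-standardization, band power, ASSR SNR.

The 40 Hz auditory steady-state response is quantified as the PSD at the
40.0 Hz bin (4 s Hann windows, 75% overlap, 0.5 Hz resolution) and as an
SNR: the 40 Hz power divided by the standard deviation of the power over
the twenty flanking bins 35–39 and 41–45 Hz. Standardization z-scores the
PSD per channel across the frequency bins of the analysis range, which
makes the result invariant to per-channel affine spectral transforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .qc import BandSet, DEFAULT_BANDS, band_means

logger = logging.getLogger(__name__)

ASSR_RANGE = (35.0, 45.0)
EOEC_RANGE = (1.0, 48.0)
NOISE_BANDS = ((35.0, 39.0), (41.0, 45.0))


@dataclass
class PSDResult:
    """Per-channel power spectral density over a uniform frequency grid."""

    freqs: np.ndarray  # Hz
    power: np.ndarray  # channels x freqs, μV²/Hz
    channel_labels: list
    window_len: float  # s
    overlap: float  # fraction
    z: np.ndarray = None  # standardized twin, same shape as power

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape != (len(self.channel_labels), self.freqs.size):
            raise ValueError("power must be channels x freqs")
        # NaN rows mark missing channels (all segments rejected)
        if np.any(self.power[np.isfinite(self.power)] < -1e-12):
            raise ValueError("negative power")
        df = np.diff(self.freqs)
        if df.size and not np.allclose(df, df[0]):
            raise ValueError("frequency grid must be uniform")

    @property
    def resolution(self) -> float:
        """Frequency resolution in Hz (= 1 / window_len)."""
        return float(self.freqs[1] - self.freqs[0])

    def bin_index(self, freq: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - freq)))
        if abs(self.freqs[i] - freq) > self.resolution / 4:
            raise ValueError(f"{freq} Hz is not on the frequency grid")
        return i

    def restrict(self, low: float, high: float) -> "PSDResult":
        mask = (self.freqs >= low) & (self.freqs <= high)
        return replace(self, freqs=self.freqs[mask],
                       power=self.power[:, mask],
                       z=None if self.z is None else self.z[:, mask])

    def to_frame(self, standardized: bool = False) -> pd.DataFrame:
        values = self.z if standardized else self.power
        if values is None:
            raise ValueError("no standardized spectrum present")
        return pd.DataFrame(values, index=self.channel_labels,
                            columns=self.freqs)


def _regrid(freqs: np.ndarray, power: np.ndarray,
            freq_resolution: float | None):
    """Evaluate the PSD on an explicit coarser frequency grid.

    A T-second window natively yields 1/T Hz bin spacing; the analysis
    grid (e.g. 0.5 Hz from 4 s windows) keeps every k-th bin, which equals
    computing the Welch estimate at the requested frequencies directly.
    """
    if freq_resolution is None:
        return freqs, power
    native = freqs[1] - freqs[0]
    k = int(round(freq_resolution / native))
    if k < 1 or abs(k * native - freq_resolution) > 1e-9:
        raise ValueError(
            f"freq_resolution {freq_resolution} Hz is not a multiple of the "
            f"native {native} Hz spacing")
    return freqs[::k], power[..., ::k]


def welch_psd(segments, sample_rate: float, channel_labels,
              window_len: float = 4.0, overlap: float = 0.75,
              freq_resolution: float | None = None) -> PSDResult:
    """Hann-tapered Welch PSD averaged over segments.

    ``segments`` is a sequence of channels x samples arrays (e.g. surviving
    trials); each is Welch-averaged with ``window_len`` seconds windows and
    the given overlap fraction, then segments are averaged with equal
    weights. One-sided density scaling in μV²/Hz. ``freq_resolution``
    evaluates the estimate on a coarser explicit grid (0.5 Hz for the
    40 Hz-ASSR analysis).
    """
    segments = [np.atleast_2d(np.asarray(s, dtype=float)) for s in segments]
    if not segments:
        raise ValueError("no surviving segments")
    nperseg = int(round(window_len * sample_rate))
    noverlap = int(round(nperseg * overlap))
    freqs = None
    acc = None
    for seg in segments:
        if seg.shape[-1] < nperseg:
            raise ValueError("segment shorter than the PSD window")
        f, p = sps.welch(seg, fs=sample_rate, window="hann", nperseg=nperseg,
                         noverlap=noverlap, detrend="constant", axis=-1)
        freqs = f
        acc = p if acc is None else acc + p
    power = acc / len(segments)
    freqs, power = _regrid(freqs, power, freq_resolution)
    return PSDResult(freqs=freqs, power=power,
                     channel_labels=list(channel_labels),
                     window_len=window_len, overlap=overlap)


def welch_psd_per_channel(segments_by_channel: dict, sample_rate: float,
                          window_len: float, overlap: float,
                          freq_resolution: float | None = None) -> PSDResult:
    """Welch PSD where each channel has its own list of surviving 1D segments.

    Used after window-level rejection, which leaves per-channel gaps: each
    channel's segments are Welch-averaged independently with equal segment
    weights. Channels with no usable segment come back as all-NaN with a
    warning.
    """
    labels = list(segments_by_channel)
    nperseg = int(round(window_len * sample_rate))
    noverlap = int(round(nperseg * overlap))
    freqs = None
    rows = []
    for lab in labels:
        segs = [np.asarray(s, dtype=float) for s in segments_by_channel[lab]
                if np.asarray(s).size >= nperseg]
        if not segs:
            logger.warning("channel %s has no surviving segments", lab)
            rows.append(None)
            continue
        acc = None
        for s in segs:
            f, p = sps.welch(s, fs=sample_rate, window="hann", nperseg=nperseg,
                             noverlap=noverlap, detrend="constant")
            freqs = f
            acc = p if acc is None else acc + p
        rows.append(acc / len(segs))
    if freqs is None:
        raise ValueError("no surviving segments on any channel")
    power = np.vstack([np.full(freqs.size, np.nan) if r is None else r
                       for r in rows])
    freqs, power = _regrid(freqs, power, freq_resolution)
    return PSDResult(freqs=freqs, power=power, channel_labels=labels,
                     window_len=window_len, overlap=overlap)


def standardize_psd(psd: PSDResult, freq_range=ASSR_RANGE) -> PSDResult:
    """Z-score the PSD per channel across the bins of ``freq_range``.

    The returned result is restricted to the range; mean/SD use only the
    in-range bins of each channel.
    """
    lo, hi = freq_range
    out = psd.restrict(lo, hi)
    if out.freqs.size < 2:
        raise ValueError("standardization range contains < 2 bins")
    mean = out.power.mean(axis=1, keepdims=True)
    sd = out.power.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: Z-score undefined")
    with np.errstate(invalid="ignore"):
        z = (out.power - mean) / sd
    return replace(out, z=z)


def band_power(psd: PSDResult, bands: BandSet = DEFAULT_BANDS) -> pd.DataFrame:
    """Mean PSD per band and channel (absolute, plus z when present).

    A bin belongs to a band when its center lies in [low, high); the last
    band is closed above.
    """
    absolute = band_means(psd.freqs, psd.power, bands)  # channels x bands
    frames = {"absolute": pd.DataFrame(absolute, index=psd.channel_labels,
                                       columns=bands.names)}
    if psd.z is not None:
        frames["standardized"] = pd.DataFrame(
            band_means(psd.freqs, psd.z, bands),
            index=psd.channel_labels, columns=bands.names)
    out = pd.concat(frames, axis=1)
    out.index.name = "channel"
    return out


@dataclass
class AssrMetrics:
    """40 Hz power and SNR per channel, absolute and standardized."""

    p40: pd.Series  # μV²/Hz
    snr: pd.Series  # unitless
    p40_z: pd.Series = None
    snr_z: pd.Series = None
    noise_bands: tuple = NOISE_BANDS

    def to_frame(self) -> pd.DataFrame:
        cols = {"p40_abs": self.p40, "snr_abs": self.snr}
        if self.p40_z is not None:
            cols["p40_z"] = self.p40_z
            cols["snr_z"] = self.snr_z
        df = pd.DataFrame(cols)
        df.index.name = "channel"
        return df


def _noise_mask(freqs: np.ndarray, resolution: float) -> np.ndarray:
    """Noise bins: every bin in the 35–45 Hz strip except the 40 Hz signal bin
    (20 bins at 0.5 Hz resolution)."""
    lo, hi = NOISE_BANDS[0][0], NOISE_BANDS[1][1]
    in_strip = (freqs >= lo - resolution / 4) & (freqs <= hi + resolution / 4)
    return in_strip & (np.abs(freqs - 40.0) > resolution / 4)


def assr_snr(power_row: np.ndarray, freqs: np.ndarray,
             resolution: float) -> tuple[float, float]:
    """(P40, SNR) of one spectrum: P40 / sample SD over the 35–39 & 41–45 Hz bins."""
    i40 = int(np.argmin(np.abs(freqs - 40.0)))
    if abs(freqs[i40] - 40.0) > resolution / 4:
        raise ValueError("no 40.0 Hz bin on the frequency grid")
    p40 = float(power_row[i40])
    noise = power_row[_noise_mask(freqs, resolution)]
    sd = float(np.std(noise, ddof=1))
    if sd == 0:
        logger.warning("noise-band SD is zero: SNR undefined")
        return p40, np.nan
    return p40, p40 / sd


def assr_metrics(psd: PSDResult) -> AssrMetrics:
    """Per-channel 40 Hz power and SNR, for absolute and z spectra."""
    res = psd.resolution
    p40, snr = zip(*(assr_snr(row, psd.freqs, res) for row in psd.power))
    out = AssrMetrics(
        p40=pd.Series(p40, index=psd.channel_labels, name="p40_abs"),
        snr=pd.Series(snr, index=psd.channel_labels, name="snr_abs"))
    if psd.z is not None:
        p40z, snrz = zip(*(assr_snr(row, psd.freqs, res) for row in psd.z))
        out.p40_z = pd.Series(p40z, index=psd.channel_labels, name="p40_z")
        out.snr_z = pd.Series(snrz, index=psd.channel_labels, name="snr_z")
    return out
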