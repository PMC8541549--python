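"""The three-tier artifact-rejection cascade and the dry-signal reliability metric.

Tiers, applied in order:

1. global bad channels — mean absolute amplitude below 1 μV (flat line) or
   above 50 μV over the whole filtered recording;
2. task bad channels — the same amplitude rule within the task segment, or a
   task-mean amplitude above mean + 2·SD over all channels, or Hann-windowed
   band power above mean + 2·SD over all channels in at least 2 of the 5
   canonical bands;
3. bad units — per channel, trials (ERP), 1 s windows (ASSR, gamma only) or
   1 s windows (EOEC) whose amplitude or band power exceeds mean + 2·SD over
   that channel's own units.

"Average amplitude" is the mean absolute value throughout (the signed mean
of high-passed EEG is ~0 and could not express the flat-line rule).
Thresholds use the sample SD (n−1) and strict ">", with the candidate
included in the statistics (single pass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Recording

logger = logging.getLogger(__name__)

AMP_FLAT_UV = 1.0
AMP_MAX_UV = 50.0
SD_FACTOR = 2.0

#: task-specific Hann window lengths (s) for the channel-level power criterion
TASK_WINDOW_LEN = {"VEP": 0.5, "AEP": 0.8, "ASSR": 11.0, "EOEC": 3.0}


@dataclass(frozen=True)
class BandSet:
    """Named, ordered, non-overlapping frequency intervals in Hz."""

    bands: tuple  # ((name, low, high), ...)

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, low, high in self.bands:
            if low >= high:
                raise ValueError(f"band {name}: low >= high")
            if low < prev_high:
                raise ValueError(f"band {name} overlaps the previous band")
            prev_high = high

    @property
    def names(self) -> list:
        return [b[0] for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def select(self, names) -> "BandSet":
        keep = [b for b in self.bands if b[0] in set(names)]
        return BandSet(tuple(keep))


#: delta/theta/alpha/beta/gamma as used throughout the analysis
DEFAULT_BANDS = BandSet((("delta", 1.0, 4.0), ("theta", 4.0, 8.0),
                         ("alpha", 8.0, 14.0), ("beta", 14.0, 30.0),
                         ("gamma", 30.0, 48.0)))
#: ERP trial rejection uses the four bands below 30 Hz
ERP_BANDS = DEFAULT_BANDS.select(("delta", "theta", "alpha", "beta"))
#: ASSR window rejection looks at gamma only
GAMMA_ONLY = DEFAULT_BANDS.select(("gamma",))


@dataclass
class QCReport:
    """Rejection flags with the first-triggering criterion and durations.

    ``duration_s`` is the per-channel amount of data the report covers, so
    rejected channel-seconds aggregate across reports into the percent-
    rejected accounting.
    """

    labels: list
    duration_s: float
    channel_flags: dict = field(default_factory=dict)  # label -> criterion
    unit_flags: dict = field(default_factory=dict)  # (unit, label) -> criterion
    n_units: int = 0
    unit_duration_s: float = 0.0
    stage: str = ""

    @property
    def rejected_channels(self) -> list:
        return sorted(self.channel_flags)

    @property
    def kept_channels(self) -> list:
        return [l for l in self.labels if l not in self.channel_flags]

    def rejected_seconds(self) -> pd.Series:
        """Channel-seconds rejected per channel (full-channel flags count the
        whole duration; unit flags count their window)."""
        out = pd.Series(0.0, index=self.labels)
        for lab in self.channel_flags:
            out[lab] = self.duration_s
        for (_, lab), _crit in self.unit_flags.items():
            if lab not in self.channel_flags:
                out[lab] = min(out[lab] + self.unit_duration_s, self.duration_s)
        return out

    def percent_rejected(self) -> pd.Series:
        if self.duration_s == 0:
            return pd.Series(0.0, index=self.labels)
        return 100.0 * self.rejected_seconds() / self.duration_s

    def to_frame(self) -> pd.DataFrame:
        rej = self.rejected_seconds()
        return pd.DataFrame({
            "channel": self.labels,
            "status": ["rejected" if l in self.channel_flags else "kept"
                       for l in self.labels],
            "criterion": [self.channel_flags.get(l, "") for l in self.labels],
            "rejected_seconds": rej.to_numpy(),
            "percent_rejected": self.percent_rejected().to_numpy(),
        }).set_index("channel")


# ---------------------------------------------------------------------------
# helpers

def _mean_abs(data: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.mean(np.abs(data), axis=axis)


def _hann_band_power(data: np.ndarray, sample_rate: float, window_len: float,
                     bands: BandSet) -> np.ndarray:
    """Average Hann-windowed power per band (… x n_bands).

    Nonoverlapping windows of ``window_len`` seconds; bins assigned to a band
    when the bin center lies in [low, high), the last band closed above.
    """
    nperseg = int(round(window_len * sample_rate))
    if nperseg < 2:
        raise ValueError("window_len too short for the sample rate")
    if data.shape[-1] < nperseg:
        raise ValueError("window_len longer than the data")
    freqs, psd = sps.welch(data, fs=sample_rate, window="hann",
                           nperseg=nperseg, noverlap=0, detrend=False,
                           axis=-1)
    return band_means(freqs, psd, bands)


def band_means(freqs: np.ndarray, psd: np.ndarray, bands: BandSet) -> np.ndarray:
    """Mean PSD per band along the last axis; last band closed above."""
    out = []
    last = bands.bands[-1][0]
    for name, low, high in bands:
        if name == last:
            mask = (freqs >= low) & (freqs <= high)
        else:
            mask = (freqs >= low) & (freqs < high)
        if not mask.any():
            raise ValueError(f"band {name} contains no frequency bins")
        out.append(psd[..., mask].mean(axis=-1))
    return np.stack(out, axis=-1)


def _exceeds_2sd(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Strict mean + 2·SD exceedance along `axis` (sample SD, candidate included)."""
    mean = values.mean(axis=axis, keepdims=True)
    sd = values.std(axis=axis, ddof=1, keepdims=True)
    return values > mean + SD_FACTOR * sd


# ---------------------------------------------------------------------------
# tier 1: global channels

def flag_bad_channels_global(recording: Recording) -> QCReport:
    """Reject channels whose mean absolute amplitude is < 1 μV or > 50 μV."""
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    amp = _mean_abs(recording.data)
    report = QCReport(labels=list(recording.channel_labels),
                      duration_s=recording.duration, stage="global-channel")
    for lab, a in zip(recording.channel_labels, amp):
        if a < AMP_FLAT_UV:
            report.channel_flags[lab] = "amplitude<1uV (flat line)"
        elif a > AMP_MAX_UV:
            report.channel_flags[lab] = "amplitude>50uV"
    return report


# ---------------------------------------------------------------------------
# tier 2: task channels

def flag_bad_channels_task(task_segment: Recording, window_len: float,
                           bands: BandSet = DEFAULT_BANDS,
                           min_bands: int = 2) -> QCReport:
    """Task-level channel rejection by the three printed criteria."""
    data = task_segment.data
    labels = list(task_segment.channel_labels)
    report = QCReport(labels=labels, duration_s=task_segment.duration,
                      stage="task-channel")

    amp = _mean_abs(data)
    n_ch = len(labels)
    power = _hann_band_power(data, task_segment.sample_rate, window_len, bands)
    amp_high = (amp > amp.mean() + SD_FACTOR * amp.std(ddof=1)) \
        if n_ch > 1 else np.zeros(n_ch, bool)
    band_high = _exceeds_2sd(power, axis=0) if n_ch > 1 \
        else np.zeros_like(power, bool)

    for i, lab in enumerate(labels):
        if amp[i] < AMP_FLAT_UV:
            report.channel_flags[lab] = "amplitude<1uV (flat line)"
        elif amp[i] > AMP_MAX_UV:
            report.channel_flags[lab] = "amplitude>50uV"
        elif amp_high[i]:
            report.channel_flags[lab] = "amplitude>mean+2SD"
        elif band_high[i].sum() >= min_bands:
            report.channel_flags[lab] = (
                f"power>mean+2SD in >= {min_bands} bands")
    return report


# ---------------------------------------------------------------------------
# tier 3: units (trials or windows)

def flag_bad_units(data: np.ndarray, sample_rate: float, labels,
                   bands: BandSet = ERP_BANDS, min_bands: int = 2,
                   unit: str = "trial") -> QCReport:
    """Per-channel unit rejection over a units x channels x samples array.

    A unit is flagged for a channel when its mean absolute amplitude, or its
    Hann power in at least ``min_bands`` of ``bands``, exceeds mean + 2·SD
    over that channel's own units.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected units x channels x samples")
    n_units, n_ch, n_samp = data.shape
    if n_units < 3:
        raise ValueError("need at least 3 units for a stable SD")
    labels = list(labels)
    unit_dur = n_samp / sample_rate
    report = QCReport(labels=labels, duration_s=n_units * unit_dur,
                      n_units=n_units, unit_duration_s=unit_dur,
                      stage=f"{unit}-level")

    amp = _mean_abs(data)  # units x channels
    amp_bad = _exceeds_2sd(amp, axis=0)

    freqs, psd = sps.welch(data, fs=sample_rate, window="hann",
                           nperseg=n_samp, noverlap=0, detrend=False, axis=-1)
    power = band_means(freqs, psd, bands)  # units x channels x bands
    power_bad = _exceeds_2sd(power, axis=0).sum(axis=-1) >= min_bands

    for u in range(n_units):
        for c, lab in enumerate(labels):
            if amp_bad[u, c]:
                report.unit_flags[(u, lab)] = "amplitude>mean+2SD"
            elif power_bad[u, c]:
                report.unit_flags[(u, lab)] = (
                    f"power>mean+2SD in >= {min_bands} bands")
    return report


# ---------------------------------------------------------------------------
# dry-signal reliability

def channel_reliability(recording: Recording, p2p_threshold: float = 400.0,
                        window: float = 1.0) -> pd.Series:
    """Percent of nonoverlapping windows with peak-to-peak <= threshold."""
    nwin = int(round(window * recording.sample_rate))
    n = recording.n_samples // nwin
    if n < 1:
        raise ValueError("recording shorter than one window")
    segs = recording.data[:, : n * nwin].reshape(recording.n_channels, n, nwin)
    ptp = segs.max(axis=-1) - segs.min(axis=-1)
    pct = 100.0 * (ptp <= p2p_threshold).mean(axis=1)
    return pd.Series(pct, index=recording.channel_labels, name="percent_reliable")


# ---------------------------------------------------------------------------
# summary

def rejection_summary(reports) -> tuple[pd.Series, float]:
    """Aggregate rejected channel-seconds across reports.

    Returns (percent rejected per channel, overall percent over all
    channel-seconds). Channels enter the denominator with the duration of
    every report that covers them.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    rejected: dict[str, float] = {}
    total: dict[str, float] = {}
    for rep in reports:
        rej = rep.rejected_seconds()
        for lab in rep.labels:
            rejected[lab] = rejected.get(lab, 0.0) + rej[lab]
            total[lab] = total.get(lab, 0.0) + rep.duration_s
    labels = sorted(total, key=lambda l: list(total).index(l))
    per_channel = pd.Series(
        {l: 100.0 * rejected[l] / total[l] if total[l] else 0.0 for l in labels},
        name="percent_rejected")
    grand_total = sum(total.values())
    subject = 100.0 * sum(rejected.values()) / grand_total if grand_total else 0.0
    return per_channel, subject
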