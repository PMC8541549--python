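"""Time-domain analysis: epoching, ERP averaging, global field power.

The global field power at time t (GFPt) is the spatial standard deviation of
the instantaneous potential over the n channels — equivalently the pairwise
form sqrt(sum_ij (U_i − U_j)^2 / (2 n^2)). Between-system agreement of two
GFPt series is summarized per subject by the Spearman rank correlation (COR)
and the root mean square deviation (RMSD); component amplitudes/latencies
are read off the GFPt peaks inside component-specific search windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .recording import EventList, Recording

logger = logging.getLogger(__name__)

#: GFPt peak-search windows (s); the upper components absorb the fixed
#: presentation delay of the stimulus chain
DEFAULT_SEARCH_WINDOWS = {
    "N75": (0.09, 0.14),
    "P100": (0.13, 0.19),
    "N1": (0.25, 0.36),
    "P1": (0.36, 0.46),
}

VEP_EPOCH = (-0.1, 0.4)
AEP_EPOCH = (-0.1, 0.7)
DEFAULT_BASELINE = (-0.1, 0.0)


@dataclass
class EpochSet:
    """trials x channels x samples with a time axis relative to stimulus."""

    data: np.ndarray
    times: np.ndarray  # s, strictly increasing
    channel_labels: list
    valid: np.ndarray = None  # (trials, channels) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("expected trials x channels x samples")
        if self.times.size != self.data.shape[2]:
            raise ValueError("times length must match the sample axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis must match labels")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[:2], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape[:2]:
            raise ValueError("valid mask must be trials x channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def apply_unit_flags(self, unit_flags: dict) -> "EpochSet":
        """Invalidate (trial, channel) entries listed in a QC unit-flag map."""
        valid = self.valid.copy()
        index = {l: i for i, l in enumerate(self.channel_labels)}
        for (trial, lab) in unit_flags:
            if lab in index and 0 <= trial < self.n_trials:
                valid[trial, index[lab]] = False
        return EpochSet(self.data, self.times, list(self.channel_labels), valid)


def extract_epochs(recording: Recording, events=None, tmin: float = -0.1,
                   tmax: float = 0.4, baseline=DEFAULT_BASELINE,
                   event_label: str | None = None) -> EpochSet:
    """Cut stimulus-locked epochs with per-trial baseline correction.

    Epochs span the half-open sample interval covering [tmin, tmax) with
    round((tmax − tmin)·fs) samples; the per-channel mean over the baseline
    window (default [−0.1, 0) s) is subtracted per trial. Events too close to
    the recording edge are dropped with a warning.
    """
    if events is None:
        events = recording.events
    if isinstance(events, EventList):
        onsets = (events.select(event_label) if event_label is not None
                  else events.onsets)
    else:
        onsets = np.asarray(events, dtype=np.int64)
    sr = recording.sample_rate
    n_samp = int(round((tmax - tmin) * sr))
    if n_samp < 1:
        raise ValueError("empty epoch window")
    offset = int(round(tmin * sr))
    times = (offset + np.arange(n_samp)) / sr

    starts = onsets + offset
    keep = (starts >= 0) & (starts + n_samp <= recording.n_samples)
    if not np.all(keep):
        logger.warning("dropped %d trial(s) too close to the recording edge",
                       int((~keep).sum()))
    starts = starts[keep]
    if starts.size == 0:
        raise ValueError("no trials fit inside the recording")
    idx = starts[:, None] + np.arange(n_samp)[None, :]
    data = recording.data[:, idx].transpose(1, 0, 2)  # trials x ch x samples

    if baseline is not None:
        b0, b1 = baseline
        bmask = (times >= b0) & (times < b1)
        if not bmask.any():
            raise ValueError("baseline window outside the epoch")
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(data, times, list(recording.channel_labels))


def average_erp(epochs: EpochSet) -> pd.DataFrame:
    """Per-channel mean over valid trials (channels x samples).

    Channels with zero valid trials come back as all-NaN rows.
    """
    if not epochs.valid.any():
        raise ValueError("all trials are invalid")
    counts = epochs.valid.sum(axis=0).astype(float)  # per channel
    masked = np.where(epochs.valid[:, :, None], epochs.data, 0.0)
    with np.errstate(invalid="ignore"):
        erp = masked.sum(axis=0) / counts[:, None]
    erp[counts == 0] = np.nan
    if np.any(counts == 0):
        dead = [l for l, c in zip(epochs.channel_labels, counts) if c == 0]
        logger.warning("channels with no valid trials: %s", dead)
    return pd.DataFrame(erp, index=epochs.channel_labels, columns=epochs.times)


@dataclass
class GFPSeries:
    """Global field power over time (μV); nonnegative by construction."""

    times: np.ndarray
    gfp: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.times.shape != self.gfp.shape:
            raise ValueError("times and gfp must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "gfp_uv": self.gfp})


def gfp_timecourse(erp) -> GFPSeries:
    """Spatial SD of the instantaneous potential over channels, per time point.

    Computed with the mean-centered (population variance) form; identical to
    the pairwise double-sum with 1/(2 n^2) normalization.
    """
    if isinstance(erp, pd.DataFrame):
        times = erp.columns.to_numpy(dtype=float)
        values = erp.to_numpy()
    else:
        values = np.asarray(erp, dtype=float)
        times = np.arange(values.shape[1], dtype=float)
    values = values[~np.isnan(values).any(axis=1)]
    n = values.shape[0]
    if n < 2:
        raise ValueError("GFP needs at least 2 non-missing channels")
    gfp = values.std(axis=0, ddof=0)
    return GFPSeries(times=times, gfp=gfp, n_channels=n)


@dataclass
class GFPComparison:
    """Between-system GFPt agreement: Spearman rho (COR) and RMSD (μV)."""

    rho: float
    rmsd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": [self.rho], "rmsd_uv": [self.rmsd]})


def compare_gfp(gfp_a: GFPSeries, gfp_b: GFPSeries) -> GFPComparison:
    """Spearman correlation (average ranks on ties) and RMSD of two series."""
    if gfp_a.gfp.size != gfp_b.gfp.size:
        raise ValueError("GFP series length mismatch")
    if not np.allclose(gfp_a.times, gfp_b.times):
        raise ValueError("GFP series time axes differ")
    a, b = gfp_a.gfp, gfp_b.gfp
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant GFP series: rho undefined")
        rho = np.nan
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    return GFPComparison(rho=rho, rmsd=rmsd)


def find_gfp_peaks(gfp: GFPSeries,
                   search_windows: dict = None) -> pd.DataFrame:
    """Maximum GFPt per component search window (ties -> earliest time)."""
    if search_windows is None:
        search_windows = DEFAULT_SEARCH_WINDOWS
    rows = []
    for name, (lo, hi) in search_windows.items():
        mask = (gfp.times >= lo) & (gfp.times <= hi)
        if not mask.any():
            raise ValueError(f"empty search window for {name}")
        seg = gfp.gfp[mask]
        seg_t = gfp.times[mask]
        k = int(np.argmax(seg))
        rows.append({"component": name, "amplitude_uv": float(seg[k]),
                     "latency_s": float(seg_t[k])})
    return pd.DataFrame(rows).set_index("component")
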