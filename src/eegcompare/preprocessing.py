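"""Filtering, channel harmonization, re-referencing and blink-component removal.

The filter chain is a zero-phase (forward–backward) Butterworth bandpass
1–48 Hz followed by a zero-phase Butterworth bandstop 48–52 Hz for line
noise; "2nd order" refers to the base design before the forward–backward
pass (effective 4th-order magnitude).

The ICA decomposition itself is delegated to FastICA; this module implements
the blink-component *selection* criteria: (1) frontal-only topography,
(2) stereotyped blink deflections in the source over time, and (3) presence
over the whole session rather than within one task block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .montage import FRONTAL_CHANNELS, SHARED_CHANNELS, canonical_label
from .recording import Recording

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """A Butterworth filter to be applied forward–backward (zero net phase)."""

    kind: str  # bandpass | bandstop
    low: float
    high: float
    order: int = 2  # base order before the forward-backward pass

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sample_rate: float) -> np.ndarray:
        if self.high >= sample_rate / 2:
            raise ValueError(
                f"high cutoff {self.high} Hz >= Nyquist ({sample_rate / 2} Hz)")
        return sps.butter(self.order, [self.low, self.high], btype=self.kind,
                          fs=sample_rate, output="sos")

    def magnitude_at(self, freq: float, sample_rate: float) -> float:
        """Effective magnitude response after forward–backward application."""
        _, h = sps.sosfreqz(self.sos(sample_rate),
                            worN=[freq], fs=sample_rate)
        return float(np.abs(h[0]) ** 2)


BANDPASS_BROAD = FilterSpec("bandpass", 1.0, 48.0)
BANDSTOP_LINE = FilterSpec("bandstop", 48.0, 52.0)
BANDPASS_ERP = FilterSpec("bandpass", 1.0, 30.0)
BANDPASS_ASSR = FilterSpec("bandpass", 30.0, 48.0)


def filter_zero_phase(recording: Recording, spec: FilterSpec) -> Recording:
    """Forward–backward Butterworth filtering; shape-preserving, zero phase."""
    sos = spec.sos(recording.sample_rate)
    filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=filtered)


def harmonize_and_rereference(dry: Recording, gel: Recording
                              ) -> tuple[Recording, Recording]:
    """Re-reference the gel recording to M2 and restrict both systems to the
    shared channel set in identical order.

    The dry system is recorded against an external M2 electrode already; the
    gel recording must contain an M2 data channel (subtracted, then dropped).
    """
    gel = gel.copy()
    if "M2" in gel.channel_labels:
        gel.data = gel.data - gel.get_channel("M2")[None, :]
        gel = gel.drop(["M2"])
        gel = replace(gel, reference_label="M2")
    elif gel.reference_label != "M2":
        raise ValueError("gel recording has no M2 channel and is not "
                         "M2-referenced")
    shared = [l for l in SHARED_CHANNELS
              if l in dry.channel_labels and l in gel.channel_labels]
    if len(shared) != len(SHARED_CHANNELS):
        logger.warning("shared-channel set has %d channels (expected %d); "
                       "proceeding with the intersection",
                       len(shared), len(SHARED_CHANNELS))
    return dry.pick(shared), gel.pick(shared)


@dataclass
class ComponentDecomposition:
    """A linear decomposition data = mixing @ sources (square, un-centered)."""

    mixing: np.ndarray  # channels x components
    sources: np.ndarray  # components x samples
    channel_labels: list

    def __post_init__(self) -> None:
        if self.mixing.shape[1] != self.sources.shape[0]:
            raise ValueError("mixing/source component counts differ")
        if self.mixing.shape[0] != len(self.channel_labels):
            raise ValueError("mixing rows must match channel labels")

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.sources


def decompose(recording: Recording, seed: int = 0,
              max_iter: int = 500) -> ComponentDecomposition:
    """Square ICA decomposition of a recording via FastICA.

    Sources are computed from the *un-centered* data with the fitted unmixing
    matrix and the mixing matrix is its inverse, so ``mixing @ sources``
    reconstructs the input exactly (removing every component yields zero).
    """
    from sklearn.decomposition import FastICA

    X = recording.data  # channels x samples
    ica = FastICA(n_components=X.shape[0], whiten="unit-variance",
                  random_state=seed, max_iter=max_iter, tol=1e-4)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(X.T)
    W = ica.components_  # components x channels (acts on centered data)
    sources = W @ X
    mixing = np.linalg.pinv(W)
    return ComponentDecomposition(mixing=mixing, sources=sources,
                                  channel_labels=list(recording.channel_labels))


def _blink_peaks(source: np.ndarray, sample_rate: float) -> np.ndarray:
    """Sample indices of stereotyped large monophasic deflections."""
    s = source - np.median(source)
    mad = np.median(np.abs(s)) * 1.4826
    if mad == 0:
        return np.empty(0, dtype=int)
    z = s / mad
    sign = 1.0 if np.abs(z.max()) >= np.abs(z.min()) else -1.0
    peaks, _ = sps.find_peaks(sign * z, height=4.0,
                              distance=int(0.3 * sample_rate))
    return peaks


def identify_blink_component(decomp: ComponentDecomposition,
                             sample_rate: float,
                             frontality_threshold: float = 0.6,
                             min_peaks_per_min: float = 1.0,
                             cv_threshold: float = 0.5,
                             n_blocks: int = 3) -> int | None:
    """Select the blink component, or None if no component qualifies.

    A component passes when (1) the fraction of its mixing-vector energy on
    the frontal electrodes exceeds ``frontality_threshold``, (2) its source
    shows stereotyped large deflections at a plausible blink rate, and
    (3) those deflections are spread over the whole session (coefficient of
    variation of per-block counts below ``cv_threshold``). Among qualifying
    components the one with the highest frontality wins.
    """
    if decomp.n_components == 0:
        raise ValueError("empty decomposition")
    frontal_idx = [i for i, l in enumerate(decomp.channel_labels)
                   if canonical_label(l) in FRONTAL_CHANNELS]
    if not frontal_idx:
        return None
    n = decomp.sources.shape[1]
    duration_min = n / sample_rate / 60.0
    energy = decomp.mixing ** 2
    total = energy.sum(axis=0)
    total[total == 0] = np.inf
    frontality = energy[frontal_idx].sum(axis=0) / total

    best, best_score = None, -np.inf
    edges = np.linspace(0, n, n_blocks + 1)
    for k in range(decomp.n_components):
        if frontality[k] < frontality_threshold:
            continue  # criterion 1 is necessary
        peaks = _blink_peaks(decomp.sources[k], sample_rate)
        if duration_min > 0 and peaks.size / duration_min < min_peaks_per_min:
            continue  # criterion 2
        counts = np.histogram(peaks, bins=edges)[0].astype(float)
        if counts.mean() == 0:
            continue
        cv = counts.std(ddof=0) / counts.mean()
        if cv > cv_threshold:
            continue  # criterion 3: not tied to one block
        if frontality[k] > best_score:
            best, best_score = k, frontality[k]
    return best


def remove_components(recording: Recording, decomp: ComponentDecomposition,
                      indices) -> Recording:
    """Subtract the listed components' contribution from the recording."""
    indices = list(indices)
    for i in indices:
        if not 0 <= i < decomp.n_components:
            raise IndexError(f"component index {i} out of range")
    if list(decomp.channel_labels) != list(recording.channel_labels):
        raise ValueError("decomposition channels do not match recording")
    if not indices:
        return recording.copy()
    contribution = decomp.mixing[:, indices] @ decomp.sources[indices]
    return replace(recording, data=recording.data - contribution)


def remove_blinks(recording: Recording, seed: int = 0) -> tuple[Recording, int | None]:
    """Decompose, identify the blink component and remove it (if found)."""
    decomp = decompose(recording, seed=seed)
    idx = identify_blink_component(decomp, recording.sample_rate)
    if idx is None:
        return recording.copy(), None
    return remove_components(recording, decomp, [idx]), idx
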