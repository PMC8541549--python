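"""Scalp topographies and between-system statistics.

Topographic maps are built by biharmonic spline interpolation (Green's
function g(r) = r²(ln r − 1), g(0) = 0) of per-electrode values onto a
square grid masked to the unit head disc (default 67 × 67 → 3,409 masked
pixels).

The between-system map comparison is a paired sign-flip permutation test
with pixel-based max-statistic correction: for every sign pattern over the
n subject difference maps, the paired t-map t = mean(D)/(SD(D)/√n) is
computed, converted pixelwise to Z with the per-pixel permutation mean/SD,
and the map-wide minimum and maximum Z are recorded. The corrected
thresholds are the 2.5th percentile of the minima and the 97.5th percentile
of the maxima; the observed Z map is compared against them. All 2ⁿ sign
patterns are enumerated when n is small enough, otherwise Monte-Carlo
sampling with a seed is used (the identity pattern always included).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .montage import Montage

logger = logging.getLogger(__name__)

DEFAULT_GRID_RESOLUTION = 67  # 67x67 linspace over [-1,1]^2 -> 3409 in-head pixels
ENUMERATION_CUTOFF = 20  # full 2^n enumeration up to this many subjects


# ---------------------------------------------------------------------------
# biharmonic interpolation

def _greens(r: np.ndarray) -> np.ndarray:
    """Biharmonic Green's function g(r) = r²(ln r − 1) with g(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * (np.log(r[nz]) - 1.0)
    return out


def biharmonic_weights(positions: np.ndarray, values: np.ndarray,
                       ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Green's-function weights plus affine term of the biharmonic spline.

    The interpolant is s(p) = Σ wⱼ g(‖p − pⱼ‖) + a₀ + a₁x + a₂y with the
    usual orthogonality side conditions on w; the affine null-space term
    makes constants and planes exactly reproducible. Returns (w, a).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(positions)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    if np.any(d[~np.eye(n, dtype=bool)] == 0):
        raise ValueError("duplicate electrode positions")
    G = _greens(d)
    if ridge:
        G = G + ridge * np.eye(n)
    P = np.column_stack([np.ones(n), positions])
    A = np.block([[G, P], [P.T, np.zeros((3, 3))]])
    rhs = np.concatenate([values, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        logger.warning("singular biharmonic system; ridge-regularized solve")
        A[:n, :n] += 1e-8 * np.eye(n)
        sol = np.linalg.solve(A, rhs)
    return sol[:n], sol[n:]


def biharmonic_evaluate(weights, positions: np.ndarray,
                        points: np.ndarray) -> np.ndarray:
    w, a = weights
    d = np.linalg.norm(points[:, None, :] - positions[None, :, :], axis=-1)
    return _greens(d) @ w + a[0] + points @ a[1:]


@dataclass
class HeadGrid:
    """Square pixel grid over [−1, 1]² masked to the unit head disc."""

    resolution: int = DEFAULT_GRID_RESOLUTION

    def __post_init__(self) -> None:
        axis = np.linspace(-1.0, 1.0, self.resolution)
        gx, gy = np.meshgrid(axis, axis)
        self.xy = np.column_stack([gx.ravel(), gy.ravel()])
        self.mask = np.linalg.norm(self.xy, axis=1) <= 1.0
        self.points = self.xy[self.mask]

    @property
    def n_pixels(self) -> int:
        """Number of masked (inside-head) pixels."""
        return int(self.mask.sum())


@dataclass
class TopoMap:
    """Interpolated values on the masked pixels of a head grid."""

    grid: HeadGrid
    values: np.ndarray  # one value per masked pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.grid.n_pixels:
            raise ValueError("values must cover exactly the masked pixels")

    @property
    def n_pixels(self) -> int:
        return self.values.size

    def as_image(self) -> np.ndarray:
        """resolution x resolution array with NaN outside the head."""
        img = np.full(self.grid.mask.size, np.nan)
        img[self.grid.mask] = self.values
        return img.reshape(self.grid.resolution, self.grid.resolution)


def biharmonic_interpolate(values, positions, grid: HeadGrid | int = None
                           ) -> TopoMap:
    """Interpolate per-electrode values onto the masked head grid.

    The interpolant passes exactly through the electrode values; electrodes
    with non-finite values are dropped (no imputation).
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    finite = np.isfinite(values)
    values, positions = values[finite], positions[finite]
    if values.size < 3:
        raise ValueError("need at least 3 electrodes with finite values")
    if grid is None:
        grid = HeadGrid()
    elif isinstance(grid, int):
        grid = HeadGrid(grid)
    w = biharmonic_weights(positions, values)
    return TopoMap(grid=grid, values=biharmonic_evaluate(w, positions,
                                                         grid.points))


def make_topomap(per_electrode_values, montage: Montage,
                 standardize: bool = False,
                 grid: HeadGrid | int = None) -> TopoMap:
    """Topographic map of a per-electrode quantity; optional map-level Z-score.

    ``per_electrode_values`` may be a pandas Series (indexed by label, only
    those electrodes are used) or an array aligned with the montage.
    """
    if isinstance(per_electrode_values, pd.Series):
        labels = [l for l in per_electrode_values.index if l in montage.labels]
        values = per_electrode_values.loc[labels].to_numpy(dtype=float)
        positions = montage.get_positions(labels)
    else:
        values = np.asarray(per_electrode_values, dtype=float)
        positions = montage.positions
    tm = biharmonic_interpolate(values, positions, grid)
    if standardize:
        sd = tm.values.std(ddof=0)
        if sd == 0:
            raise ValueError("constant map: Z-score undefined")
        tm = TopoMap(grid=tm.grid, values=(tm.values - tm.values.mean()) / sd)
    return tm


# ---------------------------------------------------------------------------
# sign-flip permutation test with pixel-based correction

@dataclass
class PermutationResult:
    """Observed Z map with pixel-corrected thresholds and significance mask."""

    observed_z: np.ndarray
    lower_thr: float
    upper_thr: float
    sig_mask: np.ndarray
    n_iter: int
    min_t: np.ndarray  # per-iteration map-wide minima (Z scale)
    max_t: np.ndarray  # per-iteration map-wide maxima (Z scale)
    h0_mean: np.ndarray
    h0_sd: np.ndarray

    @property
    def fraction_significant(self) -> float:
        return float(self.sig_mask.mean())


def _sign_patterns(n: int) -> np.ndarray:
    """All 2^n sign patterns as a (2^n, n) ±1 matrix (row 0 = identity)."""
    bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
    return 1.0 - 2.0 * bits  # pattern 0 is all +1


def permutation_pixel_test(maps_a, maps_b=None, n_iter: int = 10000,
                           seed: int = 0, alpha: float = 0.05,
                           enumeration_cutoff: int = ENUMERATION_CUTOFF,
                           chunk: int = 2048) -> PermutationResult:
    """Paired two-condition permutation test over per-subject maps.

    ``maps_a``/``maps_b`` are per-subject sequences of TopoMaps (or value
    arrays on a common grid); alternatively ``maps_a`` may already be the
    per-subject difference maps with ``maps_b=None``. Swapping a subject's
    condition labels negates its difference map, so the permutation scheme
    is sign flipping of the difference maps.
    """
    def to_array(maps):
        return np.stack([m.values if isinstance(m, TopoMap) else np.asarray(m)
                         for m in maps])

    D = to_array(maps_a)
    if maps_b is not None:
        B = to_array(maps_b)
        if B.shape != D.shape:
            raise ValueError("map sets differ in shape")
        D = D - B
    n, n_pix = D.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")

    if np.allclose(D, 0):
        logger.warning("all difference maps are zero; nothing can be significant")
        z = np.zeros(n_pix)
        return PermutationResult(observed_z=z, lower_thr=0.0, upper_thr=0.0,
                                 sig_mask=np.zeros(n_pix, dtype=bool),
                                 n_iter=0, min_t=np.zeros(0), max_t=np.zeros(0),
                                 h0_mean=np.zeros(n_pix), h0_sd=np.ones(n_pix))

    if n <= enumeration_cutoff:
        signs = _sign_patterns(n)
    else:
        rng = np.random.default_rng(seed)
        signs = 1.0 - 2.0 * rng.integers(0, 2, size=(n_iter, n)).astype(float)
        signs[0] = 1.0  # keep the identity pattern in the null
    n_it = signs.shape[0]

    ssq = np.sum(D ** 2, axis=0)  # invariant under sign flips

    def t_maps(sign_block):
        m = sign_block @ D / n
        var = (ssq[None, :] - n * m ** 2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        t[~np.isfinite(t)] = 0.0
        return t

    # pass 1: per-pixel H0 mean and SD of t over all iterations
    s1 = np.zeros(n_pix)
    s2 = np.zeros(n_pix)
    for i in range(0, n_it, chunk):
        t = t_maps(signs[i:i + chunk])
        s1 += t.sum(axis=0)
        s2 += (t ** 2).sum(axis=0)
    h0_mean = s1 / n_it
    h0_sd = np.sqrt(np.maximum(s2 / n_it - h0_mean ** 2, 0.0))
    degenerate = h0_sd == 0
    if degenerate.any():
        logger.warning("%d pixel(s) with degenerate permutation SD",
                       int(degenerate.sum()))
    safe_sd = np.where(degenerate, 1.0, h0_sd)

    # pass 2: map-wide extremes of the pixelwise Z maps
    mins = np.empty(n_it)
    maxs = np.empty(n_it)
    for i in range(0, n_it, chunk):
        t = t_maps(signs[i:i + chunk])
        z = (t - h0_mean[None, :]) / safe_sd[None, :]
        mins[i:i + chunk] = z.min(axis=1)
        maxs[i:i + chunk] = z.max(axis=1)

    lower = float(np.percentile(mins, 100 * alpha / 2))
    upper = float(np.percentile(maxs, 100 * (1 - alpha / 2)))

    t_obs = t_maps(np.ones((1, n)))[0]
    z_obs = (t_obs - h0_mean) / safe_sd
    z_obs[degenerate] = 0.0
    sig = (z_obs < lower) | (z_obs > upper)
    return PermutationResult(observed_z=z_obs, lower_thr=lower,
                             upper_thr=upper, sig_mask=sig, n_iter=n_it,
                             min_t=mins, max_t=maxs,
                             h0_mean=h0_mean, h0_sd=h0_sd)


# ---------------------------------------------------------------------------
# electrode-pair correlation and paired band comparison

def electrode_pair_spearman(metric_a, metric_b) -> tuple[float, float]:
    """Spearman rho over pooled (subject, electrode) pairs.

    Inputs are aligned 2D arrays or DataFrames (subjects x electrodes);
    entries missing in either are removed pairwise.
    """
    a = np.asarray(metric_a, dtype=float).ravel()
    b = np.asarray(metric_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("metric shapes differ")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 matched pairs")
    res = stats.spearmanr(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue)


def paired_band_comparison(per_subject_a: pd.DataFrame,
                           per_subject_b: pd.DataFrame,
                           n_tests: int = None,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank per band with Bonferroni-adjusted α.

    Inputs are subjects x bands tables of paired summary values. Returns a
    per-band table with the statistic, raw p, the adjusted α and the
    significance call at that adjusted level.
    """
    if list(per_subject_a.columns) != list(per_subject_b.columns):
        raise ValueError("band columns differ")
    if len(per_subject_a) != len(per_subject_b):
        raise ValueError("subject counts differ")
    if len(per_subject_a) < 5:
        raise ValueError("need at least 5 paired subjects")
    if n_tests is None:
        n_tests = per_subject_a.shape[1]
    alpha_adj = alpha / n_tests
    rows = []
    for band in per_subject_a.columns:
        d = per_subject_a[band].to_numpy() - per_subject_b[band].to_numpy()
        if np.allclose(d, 0):
            raise ValueError(f"band {band}: all paired differences are zero")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(d, alternative="two-sided")
        rows.append({"band": band, "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue), "alpha_adjusted": alpha_adj,
                     "significant": bool(res.pvalue < alpha_adj)})
    return pd.DataFrame(rows).set_index("band")
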