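"""Simulation experiments that validate the statistical machinery.

Two studies, both on down-scaled cohorts:

* family-wise error calibration — null cohorts (both conditions drawn from
  one distribution) pushed through the topographic permutation test; the
  fraction of cohorts with any significant pixel estimates the family-wise
  error rate, which should match the nominal α = 0.05;
* effect recovery — cohorts simulated with the generator's built-in
  condition effects (eyes-closed alpha gain, dry-system delta excess); the
  paired band comparisons should detect both at the Bonferroni-adjusted
  α = 0.01 in nearly every cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import topo as topo_mod
from .montage import shared_montage
from .pipeline import PipelineConfig, analyze_eoec_task
from .preprocessing import BANDPASS_BROAD, filter_zero_phase, \
    harmonize_and_rereference
from .synthetic import SimConfig, simulate_subject

logger = logging.getLogger(__name__)


def null_cohort_has_significant_pixel(seed: int, n_subjects: int = 15,
                                      grid_resolution: int = 20,
                                      alpha: float = 0.05) -> bool:
    """One null cohort through the pixel-corrected permutation test.

    Per subject, both condition maps are interpolated from i.i.d. standard
    normal electrode values (no true effect anywhere); returns whether any
    pixel came out significant.
    """
    montage = shared_montage()
    grid = topo_mod.HeadGrid(grid_resolution)
    rng = np.random.default_rng(seed)
    maps_a, maps_b = [], []
    for _ in range(n_subjects):
        v = rng.standard_normal((2, len(montage)))
        maps_a.append(topo_mod.make_topomap(v[0], montage, standardize=True,
                                            grid=grid))
        maps_b.append(topo_mod.make_topomap(v[1], montage, standardize=True,
                                            grid=grid))
    res = topo_mod.permutation_pixel_test(maps_a, maps_b, alpha=alpha)
    return bool(res.sig_mask.any())


def fwer_calibration(seeds, n_subjects: int = 15,
                     grid_resolution: int = 20) -> float:
    """Fraction of null cohorts with >= 1 significant pixel (the empirical
    family-wise error rate; nominal 0.05)."""
    hits = sum(null_cohort_has_significant_pixel(s, n_subjects,
                                                 grid_resolution)
               for s in seeds)
    return hits / len(list(seeds))


def _effect_sim_config(seed: int, n_subjects: int = 15) -> SimConfig:
    """Study conditions at reduced problem size for the recovery loops:
    256 Hz, 6 EOEC trials, 1 s block baseline; effects at their defaults
    (alpha EC gain 4, dry delta power x2)."""
    return SimConfig(seed=seed, n_subjects=n_subjects).reduced(
        n_eoec_trials=6, baseline_duration=1.0)


def cohort_band_tables(seed: int, n_subjects: int = 15
                       ) -> dict[str, pd.DataFrame]:
    """Per-subject mean band power tables of one simulated cohort.

    Returns subjects x bands DataFrames for dry/gel x EO/EC (absolute
    scale), computed through the standard EOEC analysis path.
    """
    sim_cfg = _effect_sim_config(seed, n_subjects)
    pcfg = PipelineConfig(reduced=True, seed=seed, n_subjects=n_subjects)
    rows: dict[str, list] = {f"{sys}_{cond}": []
                             for sys in ("dry", "gel") for cond in ("EO", "EC")}
    for subject in range(n_subjects):
        recs = {}
        for system in ("dry", "gel"):
            r, _ = simulate_subject(sim_cfg, subject, system, tasks=("EOEC",))
            recs[system] = filter_zero_phase(r["EOEC"], BANDPASS_BROAD)
        d29, g29 = harmonize_and_rereference(recs["dry"], recs["gel"])
        for system, rec in (("dry", d29), ("gel", g29)):
            se = analyze_eoec_task(rec, pcfg, sim_cfg)
            for cond in ("EO", "EC"):
                rows[f"{system}_{cond}"].append(
                    se.band_abs[cond].mean(axis=0, skipna=True)
                    .rename(subject))
    return {k: pd.DataFrame(v) for k, v in rows.items()}


def effect_recovery(seed: int, n_subjects: int = 15,
                    alpha_adjusted: float = 0.01) -> dict[str, bool]:
    """Detection flags of one cohort: eyes-closed alpha gain and dry delta
    excess, each at the Bonferroni-adjusted level."""
    tabs = cohort_band_tables(seed, n_subjects)
    alpha_d = tabs["dry_EC"]["alpha"] - tabs["dry_EO"]["alpha"]
    alpha_g = tabs["gel_EC"]["alpha"] - tabs["gel_EO"]["alpha"]
    alpha_diff = pd.concat([alpha_d, alpha_g], axis=1).mean(axis=1)
    res_alpha = stats.wilcoxon(alpha_diff, alternative="two-sided")
    alpha_detected = bool(res_alpha.pvalue < alpha_adjusted
                          and alpha_diff.median() > 0)

    comp = topo_mod.paired_band_comparison(tabs["dry_EO"], tabs["gel_EO"],
                                           n_tests=5)
    delta_detected = bool(
        comp.loc["delta", "significant"]
        and (tabs["dry_EO"]["delta"] - tabs["gel_EO"]["delta"]).median() > 0)
    return {"alpha_ec_gt_eo": alpha_detected, "delta_dry_gt_gel": delta_detected}


def effect_recovery_rates(seeds, n_subjects: int = 15) -> dict[str, float]:
    """Detection rates over many seeded cohorts."""
    seeds = list(seeds)
    counts = {"alpha_ec_gt_eo": 0, "delta_dry_gt_gel": 0}
    for s in seeds:
        flags = effect_recovery(s, n_subjects)
        for k in counts:
            counts[k] += flags[k]
        logger.debug("cohort %d: %s", s, flags)
    return {k: v / len(seeds) for k, v in counts.items()}
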