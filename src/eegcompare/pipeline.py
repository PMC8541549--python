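"""End-to-end orchestration of the dual-system validation analysis.

Stage order per subject/system session: load or simulate → 1–48 Hz bandpass
+ 48–52 Hz bandstop → global bad channels → blink-component removal (ICA)
→ re-reference/harmonize to the shared 29 channels → per-task extraction
with 5 s padding → task-level bad channels → task analyses:

* CHECK  → VEP epochs, trial rejection, ERP, GFPt, COR/RMSD, peak table
* ASSR   → AEP (as above) and 40 Hz PSD, P40, SNR (absolute + standardized)
* EOEC   → per-condition band power (absolute + standardized)

followed by the group-level spatial statistics (standardized component and
alpha topographies, sign-flip permutation tests with pixel-based
correction), the paired Wilcoxon/Bonferroni band comparisons, the
electrode-pair Spearman correlations, and the percent-rejected QC summary.
Every stage logs counts; all outputs are delimited tables plus a manifest
with the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import io as eio
from . import qc as qc_mod
from . import spectral as spec_mod
from . import topo as topo_mod
from .montage import ASSR_EXCLUDED_CHANNELS, REFERENCE_LABEL, shared_montage
from .preprocessing import (BANDPASS_ASSR, BANDPASS_BROAD, BANDPASS_ERP,
                            BANDSTOP_LINE, filter_zero_phase,
                            harmonize_and_rereference, remove_blinks)
from .recording import Recording
from .synthetic import SimConfig, simulate_subject

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every printed constant is a default."""

    simulate: bool = True
    input_dir: str | None = None
    out_dir: str = "results/pipeline"
    seed: int = 0
    n_subjects: int = 15
    tasks: tuple = ("CHECK", "ASSR", "EOEC")
    reduced: bool = False  # down-scaled simulation + smaller grid
    ica: bool = True
    sim_overrides: dict = field(default_factory=dict)

    # epoching
    vep_epoch: tuple = erp_mod.VEP_EPOCH
    aep_epoch: tuple = erp_mod.AEP_EPOCH
    baseline: tuple = erp_mod.DEFAULT_BASELINE
    search_windows: dict = field(
        default_factory=lambda: dict(erp_mod.DEFAULT_SEARCH_WINDOWS))
    task_pad_s: float = 5.0

    # spectral
    assr_psd_window_s: float = 4.0
    assr_psd_overlap: float = 0.75
    assr_freq_resolution: float = 0.5  # explicit analysis grid (Hz)
    assr_trial_s: float = 12.0
    eoec_psd_window_s: float = 1.0
    eoec_psd_overlap: float = 0.5
    assr_excluded_channels: tuple = ASSR_EXCLUDED_CHANNELS

    # spatial statistics
    grid_resolution: int = topo_mod.DEFAULT_GRID_RESOLUTION
    n_iter: int = 10000
    alpha: float = 0.05
    enumeration_cutoff: int = topo_mod.ENUMERATION_CUTOFF

    def sim_config(self) -> SimConfig:
        cfg = SimConfig(n_subjects=self.n_subjects, seed=self.seed)
        if self.reduced:
            cfg = cfg.reduced()
        if self.sim_overrides:
            cfg = dataclasses.replace(cfg, **self.sim_overrides)
        return cfg

    def grid(self) -> topo_mod.HeadGrid:
        res = 21 if self.reduced and self.grid_resolution == \
            topo_mod.DEFAULT_GRID_RESOLUTION else self.grid_resolution
        return topo_mod.HeadGrid(res)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("input_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("vep_epoch", "aep_epoch", "baseline", "tasks",
                    "assr_excluded_channels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        import yaml
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       default_flow_style=None))
        return path


# ---------------------------------------------------------------------------
# per-session preprocessing

def preprocess_session(rec: Recording, ica: bool = True,
                       seed: int = 0) -> tuple[Recording, list]:
    """Broadband + line filters, global bad channels, blink removal."""
    reports = []
    out = filter_zero_phase(rec, BANDPASS_BROAD)
    out = filter_zero_phase(out, BANDSTOP_LINE)
    rep = qc_mod.flag_bad_channels_global(out)
    if rec.system == "gel" and REFERENCE_LABEL in rep.labels:
        # M2 is the reference, not an analysis channel: it is near-silent by
        # construction and must neither be dropped nor counted as rejected
        rep.labels = [l for l in rep.labels if l != REFERENCE_LABEL]
        rep.channel_flags.pop(REFERENCE_LABEL, None)
    reports.append(rep)
    drop = [l for l in rep.rejected_channels
            if not (rec.system == "gel" and l == REFERENCE_LABEL)]
    if drop:
        logger.info("s%02d %s %s: dropping global bad channels %s",
                    rec.subject_id, rec.system, rec.task, drop)
        out = out.drop(drop)
    if ica and out.n_channels >= 4:
        out, blink_idx = remove_blinks(out, seed=seed)
        logger.info("s%02d %s %s: blink component %s",
                    rec.subject_id, rec.system, rec.task,
                    "none" if blink_idx is None else blink_idx)
    return out, reports


def task_segment(rec: Recording, pad_s: float = 5.0) -> Recording:
    """The event-spanning portion of a recording plus pre/post padding."""
    if len(rec.events) == 0:
        return rec.copy()
    pad = int(round(pad_s * rec.sample_rate))
    start = int(rec.events.onsets[0]) - pad
    stop = int(rec.events.onsets[-1]) + pad
    return rec.crop(max(start, 0), min(stop + pad, rec.n_samples))


# ---------------------------------------------------------------------------
# windowed-rejection bookkeeping shared by ASSR / EOEC

def _window_qc_segments(trials: np.ndarray, sample_rate: float, labels,
                        bands, min_bands: int, qc_window_s: float,
                        min_segment_s: float):
    """1 s-window rejection, then per-channel contiguous surviving runs.

    Returns (segments_by_channel, QCReport). Each trial is split into
    nonoverlapping windows of ``qc_window_s``; flagged windows break a
    channel's trial into runs, and runs of at least ``min_segment_s`` become
    PSD segments.
    """
    n_trials, n_ch, n_samp = trials.shape
    win = int(round(qc_window_s * sample_rate))
    n_win = n_samp // win
    windows = trials[:, :, : n_win * win].reshape(n_trials, n_ch, n_win, win)
    units = windows.transpose(0, 2, 1, 3).reshape(n_trials * n_win, n_ch, win)
    report = qc_mod.flag_bad_units(units, sample_rate, labels, bands=bands,
                                   min_bands=min_bands, unit="window")
    bad = np.zeros((n_trials * n_win, n_ch), dtype=bool)
    index = {l: i for i, l in enumerate(labels)}
    for (u, lab) in report.unit_flags:
        bad[u, index[lab]] = True
    bad = bad.reshape(n_trials, n_win, n_ch)

    min_seg = int(round(min_segment_s * sample_rate))
    segments = {lab: [] for lab in labels}
    for c, lab in enumerate(labels):
        for tr in range(n_trials):
            good = ~bad[tr, :, c]
            start = None
            for w in range(n_win + 1):
                if w < n_win and good[w]:
                    start = w if start is None else start
                elif start is not None:
                    seg = trials[tr, c, start * win: w * win]
                    if seg.size >= min_seg:
                        segments[lab].append(seg)
                    start = None
    return segments, report


def _fixed_epochs(rec: Recording, onsets, start_s: float, stop_s: float
                  ) -> np.ndarray:
    """trials x channels x samples slices [onset+start, onset+stop)."""
    sr = rec.sample_rate
    a = int(round(start_s * sr))
    b = int(round(stop_s * sr))
    starts = np.asarray(onsets) + a
    keep = (starts >= 0) & (starts + (b - a) <= rec.n_samples)
    if not np.all(keep):
        logger.warning("dropped %d trial(s) at the recording edge",
                       int((~keep).sum()))
    idx = starts[keep][:, None] + np.arange(b - a)[None, :]
    return rec.data[:, idx].transpose(1, 0, 2)


# ---------------------------------------------------------------------------
# per-subject task analyses

@dataclass
class SubjectTimeDomain:
    gfp: erp_mod.GFPSeries
    erp: pd.DataFrame  # channels x times
    n_trials_kept: int
    reports: list


def analyze_erp_task(rec: Recording, epoch: tuple, baseline: tuple,
                     window_len: float) -> SubjectTimeDomain:
    """Tier-2/3 QC plus ERP + GFPt of one task recording (one system)."""
    seg = task_segment(rec)
    rep2 = qc_mod.flag_bad_channels_task(seg, window_len)
    seg = seg.drop(rep2.rejected_channels) if rep2.rejected_channels else seg
    erp_rec = filter_zero_phase(seg, BANDPASS_ERP)
    epochs = erp_mod.extract_epochs(erp_rec, tmin=epoch[0], tmax=epoch[1],
                                    baseline=baseline)
    rep3 = qc_mod.flag_bad_units(epochs.data, erp_rec.sample_rate,
                                 epochs.channel_labels)
    epochs = epochs.apply_unit_flags(rep3.unit_flags)
    avg = erp_mod.average_erp(epochs)
    gfp = erp_mod.gfp_timecourse(avg)
    return SubjectTimeDomain(gfp=gfp, erp=avg,
                             n_trials_kept=int(epochs.valid.all(axis=1).sum()),
                             reports=[rep2, rep3])


@dataclass
class SubjectAssr:
    psd: spec_mod.PSDResult  # standardized twin included
    metrics: spec_mod.AssrMetrics
    reports: list


def analyze_assr_task(rec: Recording, cfg: PipelineConfig,
                      trial_s: float | None = None) -> SubjectAssr:
    """40 Hz-ASSR spectral analysis of one (harmonized) ASSR recording."""
    seg = task_segment(rec, cfg.task_pad_s)
    window_len = min(qc_mod.TASK_WINDOW_LEN["ASSR"],
                     (trial_s or cfg.assr_trial_s) - 1.0)
    rep2 = qc_mod.flag_bad_channels_task(seg, window_len)
    seg = seg.drop(rep2.rejected_channels) if rep2.rejected_channels else seg
    seg = seg.drop([l for l in cfg.assr_excluded_channels
                    if l in seg.channel_labels])
    narrow = filter_zero_phase(seg, BANDPASS_ASSR)
    onsets = narrow.events.onsets
    if onsets.size == 0:
        raise ValueError("ASSR recording has no trial events")
    if trial_s is None:
        trial_s = cfg.assr_trial_s
    # drop the first second of each trial (eliminates the AEP)
    trials = _fixed_epochs(narrow, onsets, 1.0, np.floor(trial_s))
    segments, rep3 = _window_qc_segments(
        trials, narrow.sample_rate, narrow.channel_labels,
        bands=qc_mod.GAMMA_ONLY, min_bands=1, qc_window_s=1.0,
        min_segment_s=cfg.assr_psd_window_s)
    psd = spec_mod.welch_psd_per_channel(
        segments, narrow.sample_rate, cfg.assr_psd_window_s,
        cfg.assr_psd_overlap, freq_resolution=cfg.assr_freq_resolution)
    psd = spec_mod.standardize_psd(psd, spec_mod.ASSR_RANGE)
    metrics = spec_mod.assr_metrics(psd)
    return SubjectAssr(psd=psd, metrics=metrics, reports=[rep2, rep3])


@dataclass
class SubjectEoec:
    band_abs: dict  # condition -> channels x bands DataFrame
    band_z: dict
    reports: list


def analyze_eoec_task(rec: Recording, cfg: PipelineConfig,
                      sim_cfg: SimConfig) -> SubjectEoec:
    """Per-condition (EO middle 3 s / EC 3 s) band power of one recording."""
    seg = task_segment(rec, cfg.task_pad_s)
    rep2 = qc_mod.flag_bad_channels_task(seg, qc_mod.TASK_WINDOW_LEN["EOEC"])
    seg = seg.drop(rep2.rejected_channels) if rep2.rejected_channels else seg
    eo_dur, ec_dur = sim_cfg.eo_duration, sim_cfg.ec_duration
    mid_off = (eo_dur - ec_dur) / 2.0
    windows = {"EO": (mid_off, mid_off + ec_dur), "EC": (0.0, ec_dur)}
    band_abs, band_z, reports = {}, {}, [rep2]
    for cond, (a, b) in windows.items():
        onsets = seg.events.select(cond)
        if onsets.size == 0:
            raise ValueError(f"no {cond} events in the EOEC recording")
        trials = _fixed_epochs(seg, onsets, a, b)
        segments, rep3 = _window_qc_segments(
            trials, seg.sample_rate, seg.channel_labels,
            bands=qc_mod.DEFAULT_BANDS, min_bands=2, qc_window_s=1.0,
            min_segment_s=cfg.eoec_psd_window_s)
        psd = spec_mod.welch_psd_per_channel(
            segments, seg.sample_rate, cfg.eoec_psd_window_s,
            cfg.eoec_psd_overlap)
        psd = spec_mod.standardize_psd(psd, spec_mod.EOEC_RANGE)
        bp = spec_mod.band_power(psd)
        band_abs[cond] = bp["absolute"]
        band_z[cond] = bp["standardized"]
        reports.append(rep3)
    return SubjectEoec(band_abs=band_abs, band_z=band_z, reports=reports)


# ---------------------------------------------------------------------------
# the full run

@dataclass
class ReportBundle:
    """Everything run_pipeline computed, ready for tables and the report."""

    config: PipelineConfig
    gfp_comparison: pd.DataFrame = None  # per subject x task (rho, rmsd)
    peak_tables: dict = field(default_factory=dict)  # system -> DataFrame
    peak_subject_tables: dict = field(default_factory=dict)
    assr_summary: pd.DataFrame = None  # per subject/system p40/snr
    assr_spearman: dict = field(default_factory=dict)
    eoec_subject_bands: dict = field(default_factory=dict)
    eoec_wilcoxon: dict = field(default_factory=dict)
    eoec_spearman: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)  # contrast -> result
    qc_per_channel: pd.DataFrame = None
    qc_per_subject: pd.DataFrame = None
    manifest: dict = field(default_factory=dict)
    tasks_run: tuple = ()


def _load_or_simulate(cfg: PipelineConfig, subject: int, system: str,
                      sim_cfg: SimConfig) -> dict:
    if cfg.simulate:
        recs, _ = simulate_subject(sim_cfg, subject, system, tasks=cfg.tasks)
        return recs
    base = Path(cfg.input_dir)
    recs = {}
    for task in cfg.tasks:
        stem = f"sub{subject:02d}_{system}_{task}"
        for ext in (".edf", ".tsv"):
            p = base / (stem + ext)
            if p.exists():
                mp = base / f"montage_{system}.tsv"
                recs[task] = eio.load_session(
                    p, montage_path=mp if mp.exists() else None)
                break
        else:
            raise FileNotFoundError(f"no session file for {stem}")
    return recs


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the complete analysis; returns the result bundle and writes
    delimited tables plus a manifest under ``config.out_dir``."""
    cfg = config
    sim_cfg = cfg.sim_config()
    grid = cfg.grid()
    montage29 = shared_montage()
    bundle = ReportBundle(config=cfg, tasks_run=tuple(cfg.tasks))

    per_subject_td: dict = {}  # (task, system, subject) -> SubjectTimeDomain
    assr_rows = []
    assr_channel_metrics: dict = {}
    eoec_results: dict = {}
    qc_reports: dict = {}

    for subject in range(cfg.n_subjects):
        session = {}
        for system in ("dry", "gel"):
            raw = _load_or_simulate(cfg, subject, system, sim_cfg)
            clean, reports = {}, []
            for task, rec in raw.items():
                c, reps = preprocess_session(rec, ica=cfg.ica, seed=cfg.seed)
                clean[task] = c
                reports.extend(reps)
            session[system] = clean
            qc_reports[(subject, system)] = reports
        for task in cfg.tasks:
            dry29, gel29 = harmonize_and_rereference(session["dry"][task],
                                                     session["gel"][task])
            for system, rec in (("dry", dry29), ("gel", gel29)):
                if task == "CHECK":
                    td = analyze_erp_task(rec, cfg.vep_epoch, cfg.baseline,
                                          qc_mod.TASK_WINDOW_LEN["VEP"])
                    per_subject_td[("VEP", system, subject)] = td
                    qc_reports[(subject, system)].extend(td.reports)
                elif task == "ASSR":
                    td = analyze_erp_task(rec, cfg.aep_epoch, cfg.baseline,
                                          qc_mod.TASK_WINDOW_LEN["AEP"])
                    per_subject_td[("AEP", system, subject)] = td
                    sa = analyze_assr_task(
                        rec, cfg,
                        trial_s=sim_cfg.assr_trial_duration
                        if cfg.simulate else None)
                    m = sa.metrics
                    assr_rows.append({
                        "subject": subject, "system": system,
                        "p40_abs": m.p40.mean(skipna=True),
                        "snr_abs": m.snr.mean(skipna=True),
                        "p40_z": m.p40_z.mean(skipna=True),
                        "snr_z": m.snr_z.mean(skipna=True)})
                    assr_channel_metrics[(subject, system)] = m
                    qc_reports[(subject, system)].extend(
                        td.reports + sa.reports)
                elif task == "EOEC":
                    se = analyze_eoec_task(rec, cfg, sim_cfg)
                    eoec_results[(subject, system)] = se
                    qc_reports[(subject, system)].extend(se.reports)
        logger.info("subject %02d done", subject)

    # ----- time domain: COR/RMSD per subject, group GFP peaks ---------------
    comp_rows = []
    for task_name in ("VEP", "AEP"):
        for subject in range(cfg.n_subjects):
            kd = ("%s" % task_name, "dry", subject)
            kg = ("%s" % task_name, "gel", subject)
            if kd in per_subject_td and kg in per_subject_td:
                c = erp_mod.compare_gfp(per_subject_td[kd].gfp,
                                        per_subject_td[kg].gfp)
                comp_rows.append({"task": task_name, "subject": subject,
                                  "rho": c.rho, "rmsd_uv": c.rmsd})
    if comp_rows:
        bundle.gfp_comparison = pd.DataFrame(comp_rows)

    windows_by_task = {
        "VEP": {k: v for k, v in cfg.search_windows.items()
                if k in ("N75", "P100")},
        "AEP": {k: v for k, v in cfg.search_windows.items()
                if k in ("N1", "P1")},
    }
    group_gfp: dict = {}
    for task_name, windows in windows_by_task.items():
        for system in ("dry", "gel"):
            tds = [per_subject_td[k] for k in per_subject_td
                   if k[0] == task_name and k[1] == system]
            if not tds:
                continue
            mean_gfp = erp_mod.GFPSeries(
                times=tds[0].gfp.times,
                gfp=np.mean([t.gfp.gfp for t in tds], axis=0),
                n_channels=tds[0].gfp.n_channels)
            group_gfp[(task_name, system)] = mean_gfp
            bundle.peak_tables[(task_name, system)] = \
                erp_mod.find_gfp_peaks(mean_gfp, windows)
            subj_peaks = pd.concat(
                [erp_mod.find_gfp_peaks(t.gfp, windows).assign(subject=i)
                 for i, t in enumerate(tds)])
            bundle.peak_subject_tables[(task_name, system)] = subj_peaks

    # ----- ASSR summaries ---------------------------------------------------
    if assr_rows:
        bundle.assr_summary = pd.DataFrame(assr_rows)
        for metric in ("p40_abs", "snr_abs", "p40_z", "snr_z"):
            dry_m, gel_m = [], []
            for subject in range(cfg.n_subjects):
                md = assr_channel_metrics.get((subject, "dry"))
                mg = assr_channel_metrics.get((subject, "gel"))
                if md is None or mg is None:
                    continue
                attr = {"p40_abs": "p40", "snr_abs": "snr",
                        "p40_z": "p40_z", "snr_z": "snr_z"}[metric]
                sd, sg = getattr(md, attr), getattr(mg, attr)
                common = sd.index.intersection(sg.index)
                dry_m.append(sd[common])
                gel_m.append(sg[common])
            if dry_m:
                a = pd.concat(dry_m).to_numpy()
                b = pd.concat(gel_m).to_numpy()
                rho, p = topo_mod.electrode_pair_spearman(a, b)
                bundle.assr_spearman[metric] = {"rho": rho, "p": p}

    # ----- EOEC band statistics --------------------------------------------
    if eoec_results:
        for cond in ("EO", "EC"):
            for kind in ("absolute", "standardized"):
                tabs = {}
                for system in ("dry", "gel"):
                    rows = []
                    for subject in range(cfg.n_subjects):
                        se = eoec_results.get((subject, system))
                        if se is None:
                            continue
                        src = se.band_abs if kind == "absolute" else se.band_z
                        rows.append(src[cond].mean(axis=0, skipna=True)
                                    .rename(subject))
                    tabs[system] = pd.DataFrame(rows)
                bundle.eoec_subject_bands[(cond, kind)] = tabs
                if min(len(tabs["dry"]), len(tabs["gel"])) >= 5:
                    bundle.eoec_wilcoxon[(cond, kind)] = \
                        topo_mod.paired_band_comparison(
                            tabs["dry"], tabs["gel"], n_tests=5,
                            alpha=cfg.alpha)
                else:
                    logger.warning("fewer than 5 paired subjects: skipping "
                                   "the %s/%s Wilcoxon comparison", cond, kind)
                # electrode-pair Spearman per band
                for band in tabs["dry"].columns:
                    a_rows, b_rows = [], []
                    for subject in range(cfg.n_subjects):
                        sd = eoec_results.get((subject, "dry"))
                        sg = eoec_results.get((subject, "gel"))
                        if sd is None or sg is None:
                            continue
                        srcd = sd.band_abs if kind == "absolute" else sd.band_z
                        srcg = sg.band_abs if kind == "absolute" else sg.band_z
                        common = srcd[cond].index.intersection(
                            srcg[cond].index)
                        a_rows.append(srcd[cond].loc[common, band])
                        b_rows.append(srcg[cond].loc[common, band])
                    rho, p = topo_mod.electrode_pair_spearman(
                        pd.concat(a_rows).to_numpy(),
                        pd.concat(b_rows).to_numpy())
                    bundle.eoec_spearman[(cond, kind, band)] = \
                        {"rho": rho, "p": p}

    # ----- spatial domain ---------------------------------------------------
    def subject_component_map(td: SubjectTimeDomain, peak_time: float):
        values = pd.Series(
            td.erp.loc[:, td.erp.columns[np.argmin(
                np.abs(td.erp.columns.to_numpy(dtype=float) - peak_time))]],
            index=td.erp.index)
        values = values.dropna()
        return topo_mod.make_topomap(values, montage29, standardize=True,
                                     grid=grid)

    for task_name, comps in (("VEP", ("N75", "P100")), ("AEP", ("N1", "P1"))):
        for comp in comps:
            maps = {"dry": [], "gel": []}
            ok = True
            for system in ("dry", "gel"):
                key = (task_name, system)
                if key not in bundle.peak_tables:
                    ok = False
                    break
                peak_time = float(
                    bundle.peak_tables[key].loc[comp, "latency_s"])
                for subject in range(cfg.n_subjects):
                    td = per_subject_td.get((task_name, system, subject))
                    if td is None:
                        ok = False
                        break
                    maps[system].append(subject_component_map(td, peak_time))
            if ok:
                bundle.permutation[comp] = topo_mod.permutation_pixel_test(
                    maps["dry"], maps["gel"], n_iter=cfg.n_iter,
                    seed=cfg.seed, alpha=cfg.alpha,
                    enumeration_cutoff=cfg.enumeration_cutoff)

    if eoec_results:
        maps = {"dry": [], "gel": []}
        ok = True
        for system in ("dry", "gel"):
            for subject in range(cfg.n_subjects):
                se = eoec_results.get((subject, system))
                if se is None:
                    ok = False
                    break
                alpha_power = pd.concat(
                    [se.band_z["EO"]["alpha"], se.band_z["EC"]["alpha"]],
                    axis=1).mean(axis=1, skipna=True).dropna()
                maps[system].append(topo_mod.make_topomap(
                    alpha_power, montage29, standardize=True, grid=grid))
        if ok:
            bundle.permutation["alpha"] = topo_mod.permutation_pixel_test(
                maps["dry"], maps["gel"], n_iter=cfg.n_iter, seed=cfg.seed,
                alpha=cfg.alpha, enumeration_cutoff=cfg.enumeration_cutoff)

    # ----- QC summary -------------------------------------------------------
    chan_rows, subj_rows = [], []
    for (subject, system), reports in sorted(qc_reports.items()):
        per_channel, subject_pct = qc_mod.rejection_summary(reports)
        subj_rows.append({"subject": subject, "system": system,
                          "percent_rejected": subject_pct})
        for lab, pct in per_channel.items():
            chan_rows.append({"subject": subject, "system": system,
                              "channel": lab, "percent_rejected": pct})
    bundle.qc_per_subject = pd.DataFrame(subj_rows)
    bundle.qc_per_channel = (pd.DataFrame(chan_rows)
                             .groupby(["system", "channel"])
                             ["percent_rejected"].mean().reset_index())

    bundle.manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                       "n_subjects": cfg.n_subjects,
                       "tasks": list(cfg.tasks),
                       "grid_pixels": grid.n_pixels}
    _write_bundle(bundle)
    return bundle


def _write_bundle(bundle: ReportBundle) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.gfp_comparison is not None:
        eio.export_table(bundle.gfp_comparison, out / "gfp_comparison.tsv")
    for (task, system), tab in bundle.peak_tables.items():
        eio.export_table(tab, out / f"gfp_peaks_{task}_{system}.tsv")
    if bundle.assr_summary is not None:
        eio.export_table(bundle.assr_summary, out / "assr_summary.tsv")
    for (cond, kind), tab in bundle.eoec_wilcoxon.items():
        eio.export_table(tab, out / f"eoec_wilcoxon_{cond}_{kind}.tsv")
    if bundle.qc_per_subject is not None:
        eio.export_table(bundle.qc_per_subject, out / "qc_per_subject.tsv")
        eio.export_table(bundle.qc_per_channel, out / "qc_per_channel.tsv")
    for comp, res in bundle.permutation.items():
        df = pd.DataFrame({"observed_z": res.observed_z,
                           "significant": res.sig_mask})
        eio.export_table(df, out / f"permutation_{comp}.tsv")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1,
                                                  sort_keys=True))
    (out / "report.txt").write_text(generate_report(bundle))


def generate_report(bundle: ReportBundle) -> str:
    """One human-readable summary of every quantity the pipeline computed."""
    lines = ["dual-system EEG validation report",
             "=" * 34,
             f"seed={bundle.manifest.get('seed')} "
             f"config={bundle.manifest.get('config_hash')} "
             f"subjects={bundle.manifest.get('n_subjects')}", ""]
    if bundle.gfp_comparison is not None:
        lines.append("GFPt agreement (per-subject median ± SD):")
        for task, g in bundle.gfp_comparison.groupby("task"):
            lines.append(
                f"  {task}: rho = {g['rho'].median():.2f} ± {g['rho'].std():.2f}; "
                f"RMSD = {g['rmsd_uv'].median():.2f} ± {g['rmsd_uv'].std():.2f} uV")
    else:
        lines.append("time-domain comparison: not run")
    lines.append("")
    if bundle.peak_subject_tables:
        lines.append("GFPt component peaks (subject mean ± SD):")
        for (task, system), tab in sorted(bundle.peak_subject_tables.items()):
            for comp, g in tab.groupby("component"):
                lines.append(
                    f"  {system:3s} {comp:4s}: "
                    f"{g['amplitude_uv'].mean():5.2f} ± {g['amplitude_uv'].std():4.2f} uV "
                    f"at {g['latency_s'].mean():.3f} ± {g['latency_s'].std():.3f} s")
    lines.append("")
    if bundle.assr_summary is not None:
        lines.append("40 Hz-ASSR (subject mean ± SD over channels):")
        for system, g in bundle.assr_summary.groupby("system"):
            lines.append(
                f"  {system:3s}: P40 = {g['p40_abs'].mean():.3f} ± "
                f"{g['p40_abs'].std():.3f} uV^2/Hz; "
                f"SNR = {g['snr_abs'].mean():.2f} ± {g['snr_abs'].std():.2f}; "
                f"SNR(z) = {g['snr_z'].mean():.2f} ± {g['snr_z'].std():.2f}")
        for metric, d in bundle.assr_spearman.items():
            lines.append(f"  electrode-pair Spearman {metric}: "
                         f"rho = {d['rho']:.2f} (p = {d['p']:.2g})")
    else:
        lines.append("ASSR: not run")
    lines.append("")
    if bundle.eoec_wilcoxon:
        lines.append("EOEC band comparisons (Wilcoxon, Bonferroni alpha):")
        for (cond, kind), tab in sorted(bundle.eoec_wilcoxon.items()):
            for band, row in tab.iterrows():
                flag = "*" if row["significant"] else " "
                lines.append(
                    f"  {cond} {kind:12s} {band:6s}: p = {row['p_raw']:.4f} "
                    f"(alpha_adj = {row['alpha_adjusted']:.3f}) {flag}")
    elif bundle.eoec_subject_bands:
        lines.append("EOEC band comparisons: skipped "
                     "(fewer than 5 paired subjects)")
    else:
        lines.append("EOEC: not run")
    lines.append("")
    if bundle.permutation:
        lines.append("permutation topography tests (pixel-corrected):")
        for comp, res in bundle.permutation.items():
            lines.append(
                f"  {comp:5s}: {100 * res.fraction_significant:.1f}% of "
                f"{res.observed_z.size} pixels significant "
                f"(thresholds [{res.lower_thr:.2f}, {res.upper_thr:.2f}], "
                f"{res.n_iter} iterations)")
    lines.append("")
    if bundle.qc_per_subject is not None and len(bundle.qc_per_subject):
        lines.append("percent of data rejected (mean over subjects):")
        for system, g in bundle.qc_per_subject.groupby("system"):
            lines.append(f"  {system:3s}: "
                         f"{g['percent_rejected'].mean():.1f}%")
    return "\n".join(lines) + "\n"
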