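"""End-to-end orchestration of the synthetic experiment and its analysis.

A run simulates a multi-stage light-dark protocol (e.g. LD12/12 ->
LD11/11 -> DD -> LD10.5/10.5) for several subjects, then applies the full
analysis chain per stage: preprocess -> score -> architecture -> state
spectra -> wake band-power rhythms (cosinor) -> activity periodogram ->
Process-S fits -> (optionally) comodulograms, with condition comparisons
against the first (baseline) stage.  Every random draw receives a seed
derived deterministically from the run seed, the config is serialized
verbatim into the output directory, and a manifest records parameters,
outputs and their content hashes, so a repeated run is byte-identical.

Problem sizes are configurable; the defaults are desk-scale (a few subjects,
two zeitgeber cycles of EEG per stage) rather than the weeks-long protocol
the generators can also produce.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as cio
from .core import Hypnogram, LightSchedule, ParameterError
from .homeostasis import (
    buildup_fit,
    compare_fits_ftest,
    nrem_decay_points,
    swa_decay_fit,
    transition_locked_swa,
)
from .pac import cluster_compare, comodulogram
from .rhythm import chi2_periodogram, cosinor_fit, group_cosinor
from .scoring import architecture_stats, compute_epoch_features, score_epochs
from .spectral import (
    BAND_EDGES,
    band_power_series,
    compare_spectra,
    erode_state_mask,
    filterbank_hilbert,
    median_band_power,
    state_spectra,
)
from .synthetic import (
    SimParams,
    make_schedule,
    simulate_activity,
    simulate_eeg_emg,
    simulate_hypnogram,
)

__all__ = ["StageConfig", "RunConfig", "run", "load_config", "save_config"]


@dataclass
class StageConfig:
    """One light-dark stage of the protocol."""

    name: str
    period_h: Optional[float]  #: None = constant darkness
    photofraction: float = 0.5
    n_days: int = 7  #: astronomic days of the stage (drives activity length)
    eeg_cycles: int = 2  #: zeitgeber cycles of EEG simulated and analyzed
    eeg_hours: Optional[float] = None  #: explicit EEG duration override
    circadian_depth: Optional[float] = None  #: override theta/gamma modulation
    swa0: Optional[float] = None  #: override the decay amplitude SWA0
    activity_amplitude: float = 1.0


@dataclass
class RunConfig:
    stages: List[StageConfig] = field(
        default_factory=lambda: [
            StageConfig(name="LD12", period_h=24.0),
            StageConfig(name="LD10.5", period_h=21.0, circadian_depth=0.0),
        ]
    )
    n_subjects: int = 3
    seed: int = 0
    out_dir: str = "out"
    do_scoring: bool = True
    do_spectra: bool = True
    do_rhythm: bool = True
    do_homeostasis: bool = True
    do_pac: bool = False  #: comodulograms are the most expensive stage
    thresh_p: float = 0.01
    cluster_p: float = 0.05
    alpha_periodogram: float = 0.01
    n_perm: int = 500
    pac_phase_centers: List[float] = field(default_factory=lambda: [6.0, 8.0, 10.0])
    pac_amp_centers: List[float] = field(default_factory=lambda: [30.0, 38.0, 46.0])
    pac_max_bins: int = 20
    params: SimParams = field(default_factory=SimParams)
    save_signals: bool = False  #: write raw EEG/EMG CSVs (large)

    def validate(self) -> None:
        if not self.stages:
            raise ParameterError("config needs at least one stage")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ParameterError("stage names must be unique")


def _derive_seed(base: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_params(cfg: RunConfig, stage: StageConfig) -> SimParams:
    p = dataclasses.replace(cfg.params)
    p.transitions = {k: np.asarray(v, float).copy() for k, v in p.transitions.items()}
    p.band_amp = {s: dict(b) for s, b in p.band_amp.items()}
    p.circadian_mod = dict(p.circadian_mod)
    if stage.circadian_depth is not None:
        p.circadian_mod = {
            band: (stage.circadian_depth, acro)
            for band, (_, acro) in p.circadian_mod.items()
        }
    if stage.swa0 is not None:
        p.swa_decay = (stage.swa0, p.swa_decay[1], p.swa_decay[2])
    return p


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default, allow_nan=True)
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_config(cfg: RunConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["params"]["transitions"] = {
        k: np.asarray(v).tolist() for k, v in d["params"]["transitions"].items()
    }
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        _dump_json(d, path)


def load_config(path) -> RunConfig:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        d = yaml.safe_load(path.read_text())
    else:
        d = json.loads(path.read_text())
    params = d.pop("params", None)
    stages = [StageConfig(**s) for s in d.pop("stages")]
    cfg = RunConfig(stages=stages, **d)
    if params is not None:
        params["transitions"] = {
            k: np.asarray(v, float) for k, v in params["transitions"].items()
        }
        params["circadian_mod"] = {
            k: tuple(v) for k, v in params["circadian_mod"].items()
        }
        params["swa_decay"] = tuple(params["swa_decay"])
        params["buildup"] = tuple(params["buildup"])
        cfg.params = SimParams(**params)
    return cfg


def run(cfg: RunConfig) -> Dict:
    """Execute the configured experiment; returns the manifest dictionary.

    Outputs land under ``cfg.out_dir/<stage>/``; the manifest
    (``manifest.json``) records every stage's parameters, written files with
    SHA-256 hashes, and headline statistics.  Any stage failure aborts with a
    stage-attributed error; files already written are left in place.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.json")

    manifest: Dict = {"seed": cfg.seed, "stages": {}, "comparisons": {}}
    files: Dict[str, str] = {}

    def record(path: Path) -> str:
        rel = str(path.relative_to(out))
        files[rel] = _sha256(path)
        return rel

    # per-subject baseline medians for the median_ld12 normalization
    baseline_medians: Dict[int, Dict[str, float]] = {}
    # per stage: per-subject artifacts needed for cross-stage comparisons
    spectra_by_stage: Dict[str, Dict[str, list]] = {}
    theta_fits_by_stage: Dict[str, list] = {}
    decay_data_by_stage: Dict[str, tuple] = {}
    comods_by_stage: Dict[str, list] = {}

    for si, stage in enumerate(cfg.stages):
        sdir = out / stage.name
        sdir.mkdir(exist_ok=True)
        params = _stage_params(cfg, stage)
        schedule = make_schedule(stage.period_h, stage.photofraction, stage.n_days)
        period = 24.0 if schedule.is_dd else schedule.period_h
        eeg_hours = (
            stage.eeg_hours if stage.eeg_hours is not None
            else stage.eeg_cycles * period
        )
        stage_info: Dict = {
            "period_h": stage.period_h,
            "n_days": stage.n_days,
            "eeg_hours": eeg_hours,
            "subjects": {},
        }

        spectra_by_stage[stage.name] = {"W": [], "N": [], "R": []}
        theta_fits_by_stage[stage.name] = []
        comods_by_stage[stage.name] = []
        decay_t_all: List[np.ndarray] = []
        decay_v_all: List[np.ndarray] = []
        buildup_curves: List[np.ndarray] = []
        buildup_t: Optional[np.ndarray] = None

        for subj in range(cfg.n_subjects):
            sub_info: Dict = {}
            # --- simulate ---
            act = simulate_activity(
                schedule,
                entrained_period_h=period,
                amplitude=stage.activity_amplitude,
                seed=_derive_seed(cfg.seed, si, subj, 0),
            )
            cio.write_activity_csv(act, sdir / f"activity_s{subj}.csv")
            record(sdir / f"activity_s{subj}.csv")

            hyp = simulate_hypnogram(
                schedule,
                params,
                seed=_derive_seed(cfg.seed, si, subj, 1),
                duration_h=eeg_hours,
            )
            cio.write_hypnogram_csv(hyp, sdir / f"hypnogram_true_s{subj}.csv")
            record(sdir / f"hypnogram_true_s{subj}.csv")
            rec = simulate_eeg_emg(
                hyp, schedule, params, seed=_derive_seed(cfg.seed, si, subj, 2)
            )
            if cfg.save_signals:
                cio.write_recording(rec, sdir / f"recording_s{subj}.csv", "csv")
                record(sdir / f"recording_s{subj}.csv")
            pre = cio.preprocess(rec)
            del rec

            # --- scoring ---
            if cfg.do_scoring:
                feats = compute_epoch_features(pre)
                scored = score_epochs(feats)
                cio.write_hypnogram_csv(scored, sdir / f"hypnogram_scored_s{subj}.csv")
                record(sdir / f"hypnogram_scored_s{subj}.csv")
                n = min(len(scored), len(hyp))
                sub_info["scoring_agreement"] = float(
                    np.mean(scored.states[:n] == hyp.states[:n])
                )
                arch = architecture_stats(hyp, schedule)
                arch.to_tidy().to_csv(
                    sdir / f"architecture_s{subj}.csv", index=False
                )
                record(sdir / f"architecture_s{subj}.csv")

            # --- state spectra ---
            if cfg.do_spectra:
                spectra = state_spectra(pre, hyp, last_n_days=2)
                for s in "WNR":
                    spectra_by_stage[stage.name][s].append(spectra[s])

            # --- band-power rhythms + homeostasis need the filter bank ---
            sample_codes = hyp.sample_states(pre.fs)[: pre.n_samples]
            t_h_samples = pre.t0_h + np.arange(pre.n_samples) / pre.fs / 3600.0
            photo_mask = schedule.is_photophase(t_h_samples)

            if cfg.do_rhythm:
                fb = filterbank_hilbert(
                    pre, bands=[BAND_EDGES["theta"]], keep_phase=False
                )
                if si == 0:
                    baseline_medians.setdefault(subj, {})["theta"] = (
                        median_band_power(fb, BAND_EDGES["theta"])
                    )
                theta_series = band_power_series(
                    fb,
                    BAND_EDGES["theta"],
                    state_mask=erode_state_mask(sample_codes == 0),
                    bin_s=600.0,
                    norm="median_ld12",
                    norm_value=baseline_medians.get(subj, {}).get("theta", 1.0),
                )
                del fb
                t_b, v_b = theta_series.dropna()
                if t_b.size >= 8:
                    fit = cosinor_fit(t_b, v_b, period)
                    theta_fits_by_stage[stage.name].append(fit)
                    sub_info["theta_cosinor"] = {
                        "amplitude": fit.amplitude,
                        "acrophase_deg": fit.acrophase_deg,
                        "p_zero_amplitude": fit.p_zero_amplitude,
                    }
                pg = chi2_periodogram(
                    act.distance, bin_h=1.0 / 60.0, alpha=cfg.alpha_periodogram
                )
                sub_info["activity_periodogram"] = {
                    "peak_period_h": pg.peak_period_h,
                    "significant": pg.peak_significant,
                }

            if cfg.do_homeostasis:
                fb_swa = filterbank_hilbert(pre, bands=[(1.0, 3.0)], keep_phase=False)
                nrem_mask = erode_state_mask(sample_codes == 1)
                # the photophase-median normalization needs photophase NREM
                # samples; a short scotophase-only recording falls back to raw
                have_photo_nrem = bool(
                    np.any(photo_mask & nrem_mask & fb_swa.valid_mask())
                )
                swa_series = band_power_series(
                    fb_swa,
                    (1.0, 3.0),
                    state_mask=nrem_mask,
                    bin_s=600.0,
                    norm="median_photophase" if have_photo_nrem else "none",
                    photophase_mask=photo_mask if have_photo_nrem else None,
                )
                t_sleep, vals = nrem_decay_points(swa_series, hyp)
                decay_t_all.append(t_sleep)
                decay_v_all.append(vals)
                try:
                    t_c, curve, n_tr = transition_locked_swa(
                        fb_swa.power[0].astype(float),
                        hyp,
                        pre.fs,
                        valid=fb_swa.valid_mask(),
                    )
                    buildup_curves.append(curve)
                    buildup_t = t_c
                    sub_info["n_buildup_transitions"] = n_tr
                except Exception as e:  # noqa: BLE001 - recorded, not fatal
                    sub_info["buildup_skipped"] = str(e)
                del fb_swa

            if cfg.do_pac:
                coms = comodulogram(
                    pre,
                    hyp,
                    schedule,
                    state="W",
                    phase_centers=cfg.pac_phase_centers,
                    amp_centers=cfg.pac_amp_centers,
                    seed=_derive_seed(cfg.seed, si, subj, 3),
                    last_n_cycles=2,
                    max_bins_per_phase=cfg.pac_max_bins,
                )
                comods_by_stage[stage.name].append(coms["scotophase"])
                com = coms["scotophase"]
                pd.DataFrame(
                    com.pacz,
                    index=pd.Index(com.phase_centers, name="phase_f"),
                    columns=pd.Index(com.amp_centers, name="amp_f"),
                ).to_csv(sdir / f"comodulogram_scoto_s{subj}.csv")
                record(sdir / f"comodulogram_scoto_s{subj}.csv")
                pz = com.pacz
                sub_info["pac_max_pacz"] = float(np.nanmax(pz)) if np.isfinite(pz).any() else None

            stage_info["subjects"][str(subj)] = sub_info
            del pre

        # --- stage-level aggregates ---
        if cfg.do_rhythm and len(theta_fits_by_stage[stage.name]) >= 3:
            g = group_cosinor(theta_fits_by_stage[stage.name])
            stage_info["theta_group_cosinor"] = {
                "amplitude": g.amplitude,
                "acrophase_deg": g.acrophase_deg,
                "p_zero_amplitude": g.p_zero_amplitude,
                "n": g.n,
            }
        if cfg.do_homeostasis and decay_t_all:
            t_cat = np.concatenate(decay_t_all)
            v_cat = np.concatenate(decay_v_all)
            decay_data_by_stage[stage.name] = (t_cat, v_cat)
            if v_cat.size >= 10:
                dfit = swa_decay_fit(t_cat, v_cat)
                stage_info["swa_decay_fit"] = {
                    "swa0": dfit.swa0,
                    "tau_h": dfit.tau_h,
                    "swa_inf": dfit.swa_inf,
                    "p_model": dfit.p_model,
                    "identifiable": dfit.identifiable,
                }
        if cfg.do_homeostasis and buildup_curves:
            mean_curve = np.nanmean(np.vstack(buildup_curves), axis=0)
            bfit = buildup_fit(buildup_t, mean_curve)
            stage_info["swa_buildup_fit"] = {
                "min": bfit.min,
                "max": bfit.max,
                "t50_s": float(10.0 ** bfit.log_t50),
                "slope": bfit.slope,
                "fraction_at_50s": bfit.fraction_of_range(50.0),
            }
        _dump_json(stage_info, sdir / "stage_summary.json")
        record(sdir / "stage_summary.json")
        manifest["stages"][stage.name] = stage_info

    # --- cross-stage comparisons against the baseline stage ---
    base = cfg.stages[0].name
    for sj, stage in enumerate(cfg.stages[1:], start=1):
        comp: Dict = {}
        if cfg.do_spectra:
            for s in ("W", "N"):
                a = [sp for sp in spectra_by_stage[base][s] if not sp.missing]
                b = [sp for sp in spectra_by_stage[stage.name][s] if not sp.missing]
                if len(a) == len(b) and len(a) >= 3:
                    res = compare_spectra(
                        a, b, thresh_p=cfg.thresh_p, n_perm=cfg.n_perm,
                        seed=_derive_seed(cfg.seed, 97, sj),
                    )
                    comp[f"spectra_{s}_clusters"] = [
                        {"mass": c.mass, "p": c.p}
                        for c in res.significant(cfg.cluster_p)
                    ]
        if cfg.do_homeostasis and base in decay_data_by_stage and (
            stage.name in decay_data_by_stage
        ):
            ft = compare_fits_ftest(
                decay_data_by_stage[base],
                decay_data_by_stage[stage.name],
                model="decay",
            )
            comp["decay_ftest"] = {
                "F": ft.f, "df_num": ft.df_num, "df_den": ft.df_den, "p": ft.p,
            }
        if cfg.do_pac and comods_by_stage[base] and comods_by_stage[stage.name]:
            res = cluster_compare(
                comods_by_stage[base],
                comods_by_stage[stage.name],
                n_perm=cfg.n_perm,
                thresh_p=cfg.thresh_p,
                cluster_p=cfg.cluster_p,
                seed=_derive_seed(cfg.seed, 98, sj),
            )
            comp["pac_clusters"] = [
                {"mass": c.mass, "p": c.p} for c in res.significant(cfg.cluster_p)
            ]
        manifest["comparisons"][f"{base}_vs_{stage.name}"] = comp

    manifest["files"] = dict(sorted(files.items()))
    _dump_json(manifest, out / "manifest.json")
    return manifest
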