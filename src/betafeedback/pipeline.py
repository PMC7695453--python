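"""Study orchestration: generate -> calibrate -> feedback -> analyze -> model.

``run_study`` simulates a cohort of STN hemispheres (default 21, the unit of
analysis), runs the online loop and the offline analysis on every session,
assembles the tidy trial table, and fits the statistics layer: paired
hemisphere-level comparisons, the mixed-model registry, and the beta-matched
subgroup control.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import detect_rt, emg_amplitude, filter_trials, tremor_power
from .calibration import calibrate_threshold
from .core import (ALPHA_BAND, GAMMA_BAND, THETA_BAND, BetaBandSpec, Recording,
                   events_of_kind, shift_band)
from .neurofeedback import simulate_ball, stream_powers
from .oscillations import (TFMap, band_power, beta_envelope, burst_metrics, coherence,
                           morlet_tf, normalize_percent_change, preprocess, psi,
                           rest_profile)
from .stats import (DAY_MODEL_REGISTRY, MODEL_REGISTRY, GlmeSpec, correlate,
                    fit_glme, match_beta_trials, paired_compare)
from .synth import SessionConfig, default_config, generate_session

__all__ = ["RunConfig", "StudyResult", "run_study", "analyze_session"]

FEEDBACK_ANALYSIS_S = 4.0  # first 4 s of the feedback phase
PRECUE_ANALYSIS_S = 2.0  # 2 s carry-over window before the Go cue


@dataclass
class RunConfig:
    """Configuration of a full synthetic study."""

    out_dir: str | None = None
    session: SessionConfig = field(default_factory=default_config)
    n_hemispheres: int = 21
    n_days: int = 1
    tremor_fraction: float = 0.43  # ~9 of 21 hemispheres show contralateral tremor
    seed: int = 0
    make_figures: bool = True

    def validate(self) -> "RunConfig":
        self.session.validate()
        if self.n_hemispheres < 1:
            raise ValueError("need at least one hemisphere")
        if self.n_days not in (1, 2):
            raise ValueError("n_days must be 1 or 2")
        return self


@dataclass
class StudyResult:
    trials: pd.DataFrame
    paired_tests: pd.DataFrame
    glme: pd.DataFrame
    correlations: pd.DataFrame
    spectra: pd.DataFrame  # group-mean normalized spectra per condition
    run_log: dict


# ---------------------------------------------------------------------------
# per-session analysis

def _tf_pair(lfp: np.ndarray, eeg: np.ndarray, rate: float, t0: float) -> tuple[TFMap, TFMap]:
    from .oscillations import TF_CYCLES, TF_FREQS, cwt_morlet

    out = cwt_morlet(np.stack([lfp, eeg]), rate, TF_FREQS, TF_CYCLES)
    mk = lambda c: TFMap(coef=c, freqs=TF_FREQS.copy(), rate=rate, t0=t0)
    return mk(out[0]), mk(out[1])


def analyze_session(
    rec: Recording,
    events: pd.DataFrame,
    band: BetaBandSpec,
    hemisphere: str = "H0",
    day: int = 1,
    eeg_channel: str = "EEG",
) -> pd.DataFrame:
    """Run the online loop and the offline analysis over one session.

    Returns one row per trial with ball state, normalized band powers (first
    4 s of feedback and the 2 s pre-cue window), burst metrics against the
    session's rest-calibrated thresholds, STN-cortex connectivity, reaction
    time, tremor and EMG measures.
    """
    rate = rec.rate
    rest = events_of_kind(events, "rest")
    if not len(rest):
        raise ValueError("events contain no rest period")
    r0, r1 = float(rest.loc[0, "onset_s"]), float(rest.loc[0, "onset_s"] + rest.loc[0, "duration_s"])

    for ch in (band.channel, eeg_channel, "FORCE", "EMG", "ACC_X", "ACC_Y", "ACC_Z"):
        if ch not in rec.labels:
            raise ValueError(f"recording lacks required channel {ch!r}")

    lfp_raw = rec.channel(band.channel)
    filt = preprocess(rec.pick([band.channel, eeg_channel]))
    lfp = filt.data[0]
    eeg = filt.data[1]
    accel = np.vstack([rec.channel(f"ACC_{ax}") for ax in "XYZ"])
    force = rec.channel("FORCE")
    emg = rec.channel("EMG")

    # --- session calibration -------------------------------------------------
    rest_powers = stream_powers(lfp_raw, band, rate, r0, r1 - r0, mode="calibration")
    thr_online = calibrate_threshold(rest_powers)

    pad = 1.0
    rest_env = beta_envelope(lfp[int(r0 * rate): int(r1 * rate)], rate, band.band, t0=r0)
    thr_env = float(np.percentile(
        np.real(rest_env.coef[0, int(pad * rate): -int(pad * rate)]), 75.0))
    rest_env_eeg = beta_envelope(eeg[int(r0 * rate): int(r1 * rate)], rate, band.band, t0=r0)
    thr_env_eeg = float(np.percentile(
        np.real(rest_env_eeg.coef[0, int(pad * rate): -int(pad * rate)]), 75.0))

    rest_tf_lfp, rest_tf_eeg = _tf_pair(
        lfp[int(r0 * rate): int(r1 * rate)], eeg[int(r0 * rate): int(r1 * rate)], rate, r0)
    trim = (r0 + 1.5, r1 - 1.5)
    baseline_lfp = rest_profile(rest_tf_lfp, [trim])
    baseline_eeg = rest_profile(rest_tf_eeg, [trim])
    tremor_ref = tremor_power(accel, rate, window=(r0 + 0.5, r1 - 0.5))

    bands = {
        "beta": band.band,
        "alpha": ALPHA_BAND,
        "theta": THETA_BAND,
        "gamma": GAMMA_BAND,
        "beta_m8": shift_band(band.band, -8.0),
        "beta_p8": shift_band(band.band, +8.0),
    }

    fb_events = events_of_kind(events, "feedback")
    go_events = events_of_kind(events, "go_cue").set_index("trial_id")
    rows = []
    spectra = []
    for _, ev in fb_events.iterrows():
        tid = int(ev["trial_id"])
        t_fb = float(ev["onset_s"])
        fb_dur = float(ev["duration_s"])
        t_go = float(go_events.loc[tid, "onset_s"])
        fb_win = (t_fb, t_fb + min(FEEDBACK_ANALYSIS_S, fb_dur))
        pre_win = (t_go - PRECUE_ANALYSIS_S, t_go)

        # online loop
        powers = stream_powers(lfp_raw, band, rate, t_fb, fb_dur)
        trace = simulate_ball(powers, thr_online, fb_dur)

        # offline TF on a padded context covering feedback + pre-cue windows
        ctx0 = t_fb - 3.4
        ctx1 = t_go + 0.3
        i0, i1 = int(round(ctx0 * rate)), int(round(ctx1 * rate))
        tf_lfp, tf_eeg = _tf_pair(lfp[i0:i1], eeg[i0:i1], rate, ctx0)
        norm_lfp = normalize_percent_change(tf_lfp, baseline=baseline_lfp)
        norm_eeg = normalize_percent_change(tf_eeg, baseline=baseline_eeg)

        row = dict(hemisphere=hemisphere, day=day, condition=ev["condition"],
                   torn=1 if ev["condition"] == "Training" else 0, trial_id=tid,
                   final_y=trace.final_y, n_crossings=int(trace.crossings.sum()),
                   threshold_online=thr_online, threshold_env=thr_env)
        for name, b in bands.items():
            row[f"{name}_fb_pct"] = band_power(norm_lfp, tf_lfp, b, fb_win)
        row["beta_pre_pct"] = band_power(norm_lfp, tf_lfp, bands["beta"], pre_win)
        row["gamma_pre_pct"] = band_power(norm_lfp, tf_lfp, bands["gamma"], pre_win)
        row["beta_eeg_fb_pct"] = band_power(norm_eeg, tf_eeg, bands["beta"], fb_win)
        raw_lfp = tf_lfp.power()
        raw_eeg = tf_eeg.power()
        for name in ("beta", "gamma", "alpha", "theta"):
            row[f"{name}_pre_db"] = band_power(raw_lfp, tf_lfp, bands[name], pre_win, db=True)
        row["beta_eeg_pre_db"] = band_power(raw_eeg, tf_eeg, bands["beta"], pre_win, db=True)
        row["alpha_eeg_pre_db"] = band_power(raw_eeg, tf_eeg, bands["alpha"], pre_win, db=True)

        # burst characteristics (LFP and EEG) against the rest 75th percentile
        env = beta_envelope(lfp[i0:i1], rate, band.band, t0=ctx0)
        env_eeg = beta_envelope(eeg[i0:i1], rate, band.band, t0=ctx0)
        for suffix, win, span in (("fb", fb_win, fb_win[1] - fb_win[0]),
                                  ("pre", pre_win, PRECUE_ANALYSIS_S)):
            bm = burst_metrics(env, thr_env, window=win)
            row[f"acc_{suffix}_pct"] = bm.accumulated_pct
            row[f"dur1_{suffix}"] = bm.accumulated_pct / 100.0 * span
            row[f"dur2_{suffix}"] = bm.mean_duration_ms / 1e3 if np.isfinite(bm.mean_duration_ms) else np.nan
            row[f"num_{suffix}"] = bm.rate
        bm_eeg = burst_metrics(env_eeg, thr_env_eeg, window=fb_win)
        row["acc_fb_eeg_pct"] = bm_eeg.accumulated_pct
        row["dur2_fb_eeg"] = bm_eeg.mean_duration_ms / 1e3 if np.isfinite(bm_eeg.mean_duration_ms) else np.nan
        row["num_fb_eeg"] = bm_eeg.rate

        # connectivity over the 4 s feedback window
        for name in ("beta", "beta_m8", "beta_p8"):
            row[f"psi_{name}"] = psi(tf_lfp, tf_eeg, bands[name], fb_win)
            row[f"coh_{name}"] = coherence(tf_lfp, tf_eeg, bands[name], fb_win)

        # behavior
        row["rt"] = detect_rt(force, rate, t_go)
        row["tremor_pct"] = tremor_power(accel, rate, window=fb_win, rest_reference=tremor_ref)
        row["emg_amp"] = emg_amplitude(emg, rate, window=(t_fb, t_fb + fb_dur))
        rows.append(row)

        spec_cols = tf_lfp._window_slice(fb_win)
        spectra.append(dict(hemisphere=hemisphere, day=day, condition=ev["condition"],
                            trial_id=tid,
                            spectrum=norm_lfp[:, spec_cols].mean(axis=1)))

    table = filter_trials(pd.DataFrame(rows))
    table.attrs["spectra"] = spectra
    return table


# ---------------------------------------------------------------------------
# cohort study

#: hemisphere-level paired comparisons: (column, family, n_comparisons, subset)
PAIRED_MEASURES = [
    ("final_y", "performance", 2), ("emg_amp", "performance", 2),
    ("beta_fb_pct", "lfp", 4), ("acc_fb_pct", "lfp", 4),
    ("dur2_fb", "lfp", 4), ("num_fb", "lfp", 4),
    ("beta_eeg_fb_pct", "eeg", 4), ("acc_fb_eeg_pct", "eeg", 4),
    ("dur2_fb_eeg", "eeg", 4), ("num_fb_eeg", "eeg", 4),
    ("psi_beta", "connectivity", 2), ("coh_beta", "connectivity", 2),
    ("gamma_fb_pct", "other_bands", 3), ("beta_m8_fb_pct", "other_bands", 3),
    ("beta_p8_fb_pct", "other_bands", 3),
    ("rt", "behavior", 3), ("tremor_pct", "behavior", 3), ("theta_fb_pct", "behavior", 3),
]


def _hemisphere_condition_means(trials: pd.DataFrame, column: str) -> pd.DataFrame:
    valid = trials[trials["valid"]] if column == "rt" else trials
    agg = valid.pivot_table(index="hemisphere", columns="condition", values=column,
                            aggfunc="mean")
    return agg.dropna()


def paired_condition_tests(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for column, family, n_comp in PAIRED_MEASURES:
        if column not in trials.columns:
            continue
        agg = _hemisphere_condition_means(trials, column)
        if len(agg) < 5 or agg.shape[1] < 2:
            continue
        res = paired_compare(agg["Training"], agg["NoTraining"], n_comparisons=n_comp)
        rows.append(dict(measure=column, family=family, test=res.test,
                         statistic=res.statistic, p_raw=res.p_raw,
                         p_corrected=res.p_corrected, n_hemispheres=res.n,
                         mean_training=float(agg["Training"].mean()),
                         mean_no_training=float(agg["NoTraining"].mean())))
    return pd.DataFrame(rows)


def matched_subgroup_tests(trials: pd.DataFrame, fraction: float = 0.75) -> pd.DataFrame:
    """Re-test RT / gamma / tremor on beta-matched trial subgroups."""
    rows = []
    out = {}
    for hemi, sub in trials[trials["valid"]].groupby("hemisphere"):
        tr = sub[sub["condition"] == "Training"].reset_index()
        nt = sub[sub["condition"] == "NoTraining"].reset_index()
        if len(tr) < 4 or len(nt) < 4:
            continue
        try:
            ia, ib = match_beta_trials(tr["beta_fb_pct"], nt["beta_fb_pct"], fraction)
        except ValueError:
            continue
        for col in ("rt", "gamma_fb_pct", "tremor_pct"):
            out.setdefault(col, []).append(
                (tr.loc[ia, col].mean(), nt.loc[ib, col].mean()))
    for col, pairs in out.items():
        arr = np.array(pairs, dtype=float)
        arr = arr[np.all(np.isfinite(arr), axis=1)]
        if len(arr) < 5:
            continue
        res = paired_compare(arr[:, 0], arr[:, 1])
        rows.append(dict(measure=f"{col}_beta_matched", family="beta_matched",
                         test=res.test, statistic=res.statistic, p_raw=res.p_raw,
                         p_corrected=res.p_corrected, n_hemispheres=res.n,
                         mean_training=float(arr[:, 0].mean()),
                         mean_no_training=float(arr[:, 1].mean())))
    return pd.DataFrame(rows)


def fit_model_registry(trials: pd.DataFrame,
                       registry: dict[str, GlmeSpec] | None = None) -> pd.DataFrame:
    """Fit every registered mixed model on the valid trials."""
    registry = MODEL_REGISTRY if registry is None else registry
    valid = trials[trials["valid"]]
    rows = []
    for name, spec in registry.items():
        try:
            res = fit_glme(valid, spec)
        except ValueError as err:
            rows.append(dict(model=name, formula=spec.formula, term="error",
                             estimate=np.nan, se=np.nan, p=np.nan,
                             aic=np.nan, r2=np.nan, note=str(err)))
            continue
        for _, c in res.coefficients.iterrows():
            rows.append(dict(model=name, formula=spec.formula, term=c["term"],
                             estimate=c["estimate"], se=c["se"], p=c["p"],
                             aic=res.aic, r2=res.r2, note=""))
    return pd.DataFrame(rows)


def _day_difference_table(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (hemi, day), sub in trials.groupby(["hemisphere", "day"]):
        t = sub[sub["condition"] == "Training"]
        n = sub[sub["condition"] == "NoTraining"]
        if not len(t) or not len(n):
            continue
        rows.append(dict(hemisphere=hemi, day=day,
                         final_y_diff=t["final_y"].mean() - n["final_y"].mean(),
                         beta_fb_pct_diff=t["beta_fb_pct"].mean() - n["beta_fb_pct"].mean(),
                         dur1_fb_diff=t["dur1_fb"].mean() - n["dur1_fb"].mean()))
    return pd.DataFrame(rows)


def study_correlations(trials: pd.DataFrame) -> pd.DataFrame:
    """Across-hemisphere correlations (tremor vs STN theta power)."""
    rows = []
    hemi = trials.groupby("hemisphere").agg(
        tremor=("tremor_pct", "mean"), theta=("theta_pre_db", "mean"))
    if len(hemi) >= 3 and hemi["tremor"].std() > 0 and hemi["theta"].std() > 0:
        r, p = correlate(hemi["tremor"], hemi["theta"])
        rows.append(dict(pair="tremor_pct~theta_pre_db", r=r, p=p, n=len(hemi)))
    return pd.DataFrame(rows)


def _hemisphere_seed(seed: int, hemi: int, day: int) -> int:
    ss = np.random.SeedSequence([seed, hemi, day])
    return int(ss.generate_state(1)[0] % (2**31))


def run_study(config: RunConfig) -> StudyResult:
    """Simulate and analyze a full cohort; optionally write the report bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    all_trials = []
    all_spectra = []
    for h in range(config.n_hemispheres):
        center = float(rng.integers(16, 25))
        tremulous = rng.random() < config.tremor_fraction
        rt_shift = float(rng.normal(0.0, 0.03))
        for day in range(1, config.n_days + 1):
            sess = dataclasses.replace(
                config.session,
                beta_center=center,
                tremor_coeff_theta=config.session.tremor_coeff_theta * (1.0 if tremulous else 0.15),
                rt_base=config.session.rt_base + rt_shift,
                seed=_hemisphere_seed(config.seed, h, day),
            )
            rec, events, _ = generate_session(sess)
            if not len(events_of_kind(events, "feedback")):
                continue
            band = BetaBandSpec(channel="LFP", center_f=center)
            table = analyze_session(rec, events, band, hemisphere=f"H{h}", day=day)
            table["tremulous"] = tremulous
            all_trials.append(table)
            all_spectra.extend(table.attrs["spectra"])

    if not all_trials:
        trials = pd.DataFrame()
        empty = pd.DataFrame()
        log = _run_log(config, trials)
        _write_outputs(config, trials, empty, empty, empty, pd.DataFrame(), log)
        return StudyResult(trials, empty, empty, empty, pd.DataFrame(), log)

    trials = pd.concat(all_trials, ignore_index=True)

    tests = paired_condition_tests(trials)
    matched = matched_subgroup_tests(trials)
    if len(matched):
        tests = pd.concat([tests, matched], ignore_index=True)

    glme_tables = [fit_model_registry(trials)]
    if config.n_days == 2:
        diffs = _day_difference_table(trials)
        day_registry = {k: v for k, v in DAY_MODEL_REGISTRY.items() if k != "day_tremor"}
        glme_tables.append(fit_model_registry(diffs.assign(valid=True), day_registry))
        glme_tables.append(fit_model_registry(
            trials[trials["tremulous"]] if trials["tremulous"].any() else trials,
            {"day_tremor": DAY_MODEL_REGISTRY["day_tremor"]}))
    glme = pd.concat(glme_tables, ignore_index=True)

    corrs = study_correlations(trials[trials["tremulous"]] if trials["tremulous"].any() else trials)

    spec_df = pd.DataFrame([
        dict(condition=s["condition"], hemisphere=s["hemisphere"],
             **{f"f{int(f)}": v for f, v in zip(range(1, 96), s["spectrum"])})
        for s in all_spectra
    ])
    spectra = spec_df.groupby("condition").mean(numeric_only=True).reset_index()

    log = _run_log(config, trials)
    _write_outputs(config, trials, tests, glme, corrs, spectra, log)
    return StudyResult(trials, tests, glme, corrs, spectra, log)


def _run_log(config: RunConfig, trials: pd.DataFrame) -> dict:
    import matplotlib
    import mne
    import scipy
    import statsmodels

    cfg = dataclasses.asdict(config)
    cfg_json = json.dumps(cfg, default=str, sort_keys=True)
    return {
        "package_version": __version__,
        "seed": config.seed,
        "n_trials": int(len(trials)),
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "statsmodels": statsmodels.__version__,
            "mne": mne.__version__, "matplotlib": matplotlib.__version__,
        },
    }


def _write_outputs(config, trials, tests, glme, corrs, spectra, log) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials.drop(columns=[], errors="ignore").to_csv(out / "trials.tsv", sep="\t", index=False)
    tests.to_csv(out / "paired_tests.tsv", sep="\t", index=False)
    glme.to_csv(out / "glme.tsv", sep="\t", index=False)
    corrs.to_csv(out / "correlations.tsv", sep="\t", index=False)
    spectra.to_csv(out / "spectra.tsv", sep="\t", index=False)
    (out / "runlog.json").write_text(json.dumps(log, indent=2, default=str))
    if config.make_figures and len(trials):
        _make_figures(out, trials, spectra)


def _make_figures(out: Path, trials: pd.DataFrame, spectra: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    if len(spectra):
        fig, ax = plt.subplots(figsize=(6, 4))
        freqs = np.arange(1, 96)
        for _, row in spectra.iterrows():
            ax.plot(freqs, [row[f"f{f}"] for f in freqs], label=row["condition"])
        ax.set(xlabel="frequency (Hz)", ylabel="power change vs rest (%)",
               title="Normalized LFP spectra, feedback phase")
        ax.legend()
        fig.savefig(figdir / "spectra.png", dpi=120)
        plt.close(fig)

    measures = [("beta_fb_pct", "normalized beta power (%)"),
                ("acc_fb_pct", "accumulated burst time (%)"),
                ("dur2_fb", "mean burst duration (s)"),
                ("num_fb", "bursts / s"),
                ("rt", "reaction time (s)"),
                ("tremor_pct", "tremor power change (%)")]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, (col, label) in zip(axes.ravel(), measures):
        agg = _hemisphere_condition_means(trials, col)
        if not len(agg):
            continue
        for cond in ("Training", "NoTraining"):
            if cond in agg:
                x = {"Training": 0, "NoTraining": 1}[cond]
                jitter = np.linspace(-0.05, 0.05, len(agg))
                ax.scatter(np.full(len(agg), x) + jitter, agg[cond], alpha=0.6, s=14)
                ax.errorbar([x], [agg[cond].mean()],
                            yerr=[agg[cond].sem()], fmt="ko", capsize=4)
        ax.set_xticks([0, 1], ["Training", "No Training"])
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(figdir / "condition_summary.png", dpi=120)
    plt.close(fig)
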