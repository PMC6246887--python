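"""End-to-end orchestration of the boundary analysis with provenance.

``run_pipeline`` executes the full chain on a set of inputs — observer
annotations, per-participant ROI time courses, optional multi-voxel
patterns and media — and writes tabular/JSON outputs plus summary figures.
``run_demo`` first generates a complete synthetic dataset with known ground
truth and then runs the same pipeline, which is the packaged, seconds-scale
demonstration. Every output carries the configuration hash; all randomness
flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations as ann
from . import datadriven, events_hmm, features, lmm, permutation, synth
from .glm import (HrfSpec, build_design, cosine_basis, estimate_amplitude,
                  fir_timecourse, single_trial_betas)
from .roi import RoiTimeCourse, zscore_and_average

__all__ = ["PipelineConfig", "run_pipeline", "run_demo"]


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with the standard defaults:
    0.9 s reaction-time correction, 10 s run-end margin, 6 s single-trial
    exclusion gap, 256 s high-pass cutoff, 1 TR boundary-match window,
    2 TR pattern-shift match window, FIR window [-2, 12] s, 1000
    permutations."""

    tr: float = 2.0
    rt: float = 0.9
    run_end_margin: float = 10.0
    min_boundary_gap: float = 6.0
    n_perm: int = 1000
    match_window_tr: float = 1.0
    ag_match_window_tr: int = 2
    fir_range: tuple[float, float] = (-2.0, 12.0)
    highpass_cutoff: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tr", "run_end_margin", "min_boundary_gap", "n_perm",
                     "match_window_tr", "ag_match_window_tr",
                     "highpass_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PipelineConfig.{name} must be positive")
        if self.rt < 0:
            raise ValueError("rt must be nonnegative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fir_range"] = list(self.fir_range)
        return d

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _highpass_zscore(tc: RoiTimeCourse, cutoff: float) -> RoiTimeCourse:
    basis = cosine_basis(tc.n_tr, tc.tr, cutoff)
    q, _ = np.linalg.qr(basis)
    resid = tc.values - q @ (q.T @ tc.values)
    sd = resid.std()
    return RoiTimeCourse(values=resid / (sd if sd > 0 else 1.0), tr=tc.tr,
                         run_id=tc.run_id, participant_id=tc.participant_id,
                         zscored=True)


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _fig(path: Path, plot_fn) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    plot_fn(ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, inputs: dict, out_dir,
                 make_figures: bool = True) -> dict:
    """Run every stage the supplied inputs allow; return the report dict.

    ``inputs`` must contain ``annotations`` (press log DataFrame),
    ``run_duration`` and ``tcs`` (list of RoiTimeCourse); optionally
    ``patterns`` (voxel x TR array for the pattern-shift stage), ``media``
    (dict with frames/frame_times/audio/audio_rate) and ``shot_table``.
    Missing optional inputs skip their stage gracefully. Any stage failure
    aborts with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "config_hash": config.hash,
                    "stages": {}}
    stage = "setup"
    try:
        # --- consensus boundaries -------------------------------------
        stage = "annotations"
        boundaries = ann.consensus_boundaries(
            inputs["annotations"], tr=config.tr,
            run_duration=inputs["run_duration"], rt=config.rt,
            margin=config.run_end_margin)
        if boundaries.empty:
            raise ValueError("no consensus boundaries survived thresholding")
        boundaries = boundaries.reset_index(drop=True)
        boundaries["boundary_id"] = [f"b{i:03d}" for i in boundaries.index]
        _write_tsv(boundaries, out / "boundaries.tsv", config.hash)
        report["stages"]["annotations"] = {
            "n_boundaries": int(len(boundaries)),
            "threshold": int(boundaries.attrs.get("threshold", 0)),
            "mirrors": "consensus boundary construction"}

        # --- group time course + pooled amplitude test ----------------
        stage = "bold_glm"
        tcs = inputs["tcs"]
        group_tc = zscore_and_average(tcs)
        amp = permutation.amplitude_null(
            group_tc, boundaries["time_s"].to_numpy(), tr=config.tr,
            n_perm=config.n_perm, seed=config.seed + 11,
            highpass_cutoff=config.highpass_cutoff)
        (out / "amplitude_test.json").write_text(json.dumps(
            {"config_hash": config.hash, "observed_beta": amp.observed,
             "p_two_tailed": amp.p, "n_perm": amp.n_perm,
             "null_mean": float(amp.null_samples.mean()),
             "null_sd": float(amp.null_samples.std(ddof=1))}, indent=1))
        report["stages"]["amplitude_test"] = {
            "observed_beta": amp.observed, "p": amp.p,
            "mirrors": "pooled boundary response vs duration-shuffled null"}

        # --- single-trial betas + FIR ---------------------------------
        stage = "single_trial"
        betas = single_trial_betas(tcs, boundaries, tr=config.tr,
                                   min_gap=config.min_boundary_gap,
                                   highpass_cutoff=config.highpass_cutoff)
        _write_tsv(betas, out / "betas.tsv", config.hash)
        fir = fir_timecourse(tcs, boundaries, tr=config.tr,
                             window=config.fir_range)
        _write_tsv(fir, out / "fir.tsv", config.hash)
        report["stages"]["single_trial"] = {
            "n_rows": int(len(betas)),
            "n_boundaries_retained": int(betas["boundary_id"].nunique()),
            "mirrors": "single-trial amplitudes and FIR salience curves"}
        if make_figures:
            def _plot_fir(ax):
                for cond, grp in fir.groupby("salience_bin"):
                    ax.errorbar(grp["time_s"], grp["mean"], yerr=grp["sem"],
                                label=cond)
                ax.axvline(0, color="k", lw=0.8)
                ax.set_xlabel("time from boundary (s)")
                ax.set_ylabel("FIR response (a.u.)")
                ax.legend(title="salience")
            _fig(out / "fir_curves.png", _plot_fir)

        # --- mixed models ---------------------------------------------
        stage = "mixed_models"
        table = betas.copy()
        table["salience_score"] = lmm.salience_score(table["salience_bin"])
        table["n_observers"] = table["n_observers"].astype(float)
        res_sal = lmm.fit_lmm(table, lmm.LmmSpec(effect="salience_score"))
        res_nobs = lmm.fit_lmm(table, lmm.LmmSpec(effect="n_observers"))
        lmm_out = {}
        for name, r in (("salience", res_sal), ("n_observers", res_nobs)):
            lmm_out[name] = {"estimate": r.estimate, "F": r.F,
                             "df_den": r.df_den, "p": r.p,
                             "r2_marginal": r.r2_marginal,
                             "singular": r.singular}
        (out / "lmm.json").write_text(json.dumps(
            {"config_hash": config.hash, **lmm_out}, indent=1))
        report["stages"]["mixed_models"] = {
            **lmm_out, "mirrors": "salience / observer-count modulation"}

        # --- perceptual covariates (optional) -------------------------
        stage = "perceptual_features"
        media = inputs.get("media")
        if media is not None:
            cov = features.boundary_covariates(
                boundaries, frames=media["frames"],
                frame_times=media["frame_times"], audio=media["audio"],
                audio_rate=media["audio_rate"],
                extractor=features.ToyPyramidExtractor(),
                shot_table=inputs.get("shot_table"), tr=config.tr)
            _write_tsv(cov.drop(columns=["member_times", "member_obs"],
                                errors="ignore"),
                       out / "covariates.tsv", config.hash)
            merged = table.merge(
                cov[["boundary_id"] + [c for c in cov.columns
                                       if c not in boundaries.columns]],
                on="boundary_id", how="left")
            cov_names = [c for c in ("visDist", "visCorr", "visHistDist",
                                     "lumDist", "psdCorr", "psdDist",
                                     "absVolDiff", "isLocTemp", "isLoc",
                                     "isTemp")
                         if c in merged.columns]
            cov_res = lmm.covariate_models(
                merged, lmm.LmmSpec(effect="salience_score"),
                covariates=cov_names)
            report["stages"]["covariate_models"] = {
                name: {"F": r.F, "p": r.p} for name, r in cov_res.items()}
            report["stages"]["covariate_models"]["mirrors"] = \
                "salience effect adjusted for each perceptual covariate"
        else:
            report["stages"]["covariate_models"] = {"skipped": True}

        # --- pattern shifts (optional) --------------------------------
        stage = "pattern_hmm"
        patterns = inputs.get("patterns")
        if patterns is not None:
            k = len(boundaries) + 1
            fit = events_hmm.fit_event_hmm(patterns, k_events=k)
            shifts = events_hmm.classify_shifts(
                fit.shift_times, boundaries["time_s"].to_numpy(),
                tr=config.tr, window_tr=config.ag_match_window_tr)
            _write_tsv(shifts, out / "pattern_shifts.tsv", config.hash)
            peri = events_hmm.peri_shift_response(
                group_tc, shifts, n_perm=config.n_perm,
                seed=config.seed + 23)
            report["stages"]["pattern_hmm"] = {
                "n_shifts": int(len(shifts)),
                "n_matched": int(shifts["matched"].sum()),
                "match_amplitude": peri["match"]["amplitude"],
                "nonmatch_amplitude": peri["non-match"]["amplitude"],
                "mirrors": "pattern-shift / boundary correspondence"}
            if make_figures:
                def _plot_peri(ax):
                    for label, color in (("match", "tab:orange"),
                                         ("non-match", "tab:gray")):
                        d = peri[label]
                        ax.errorbar(peri["epoch_lags_tr"], d["curve"],
                                    yerr=d["sem"], label=label, color=color)
                    ax.axvline(0, color="k", lw=0.8)
                    ax.set_xlabel("TRs from pattern shift")
                    ax.set_ylabel("group ROI response (z)")
                    ax.legend()
                _fig(out / "peri_shift.png", _plot_peri)
        else:
            report["stages"]["pattern_hmm"] = {"skipped": True}

        # --- data-driven events ---------------------------------------
        stage = "datadriven"
        filtered = zscore_and_average(
            [_highpass_zscore(tc, config.highpass_cutoff) for tc in tcs])
        events = datadriven.greedy_event_search(filtered, k=len(boundaries),
                                                tr=config.tr)
        spec_test = datadriven.specificity_test(
            events, boundaries["time_s"].to_numpy(), tr=config.tr,
            window_tr=config.match_window_tr, n_perm=config.n_perm,
            seed=config.seed + 31)
        dd = pd.DataFrame({"event_tr": events.event_trs,
                           "event_time_s": events.event_times_s,
                           "beta": events.betas,
                           "rss": events.rss_trace})
        _write_tsv(dd, out / "datadriven_events.tsv", config.hash)
        report["stages"]["datadriven"] = {
            "n_events": int(len(events.event_trs)),
            "n_matched": spec_test["n_matched"],
            "fraction_matched": spec_test["fraction"],
            "p": spec_test["permutation"].p,
            "stopped_early": events.stopped_early,
            "mirrors": "data-driven event specificity"}
        if make_figures:
            def _plot_dd(ax):
                ax.plot(np.arange(filtered.n_tr) * config.tr,
                        filtered.values, lw=0.8, label="group ROI")
                for t in events.event_times_s:
                    near = np.min(np.abs(
                        boundaries["time_s"].to_numpy() - t)) \
                        <= config.match_window_tr * config.tr
                    ax.axvline(t, color="tab:orange" if near else "0.6",
                               lw=1.0)
                ax.set_xlabel("time (s)")
                ax.set_ylabel("signal (z)")
                ax.legend()
            _fig(out / "datadriven_match.png", _plot_dd)

        stage = "report"
        (out / "report.json").write_text(
            json.dumps(report, indent=1, default=float))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def run_demo(config: PipelineConfig | None = None, out_dir="filmseg_demo",
             n_participants: int = 20, run_length: float = 480.0,
             make_figures: bool = True) -> dict:
    """Generate a synthetic dataset from the config seed and run everything."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    n_b = 12
    times = np.sort(rng.uniform(30.0, run_length - 40.0, n_b))
    while np.min(np.diff(times)) < 14.0:  # well-separated true boundaries
        times = np.sort(rng.uniform(30.0, run_length - 40.0, n_b))
    salience = np.linspace(0.35, 1.0, n_b)
    rng.shuffle(salience)
    gt = synth.GroundTruth(boundary_times=times, salience_prob=salience,
                           amplitudes=0.3 + 1.8 * salience,
                           run_length=run_length, tr=config.tr,
                           n_participants=n_participants,
                           n_observers=16, seed=config.seed)
    annotations = synth.simulate_observers(gt, rt_mean=config.rt,
                                           rt_jitter=0.25)
    tcs, _ = synth.simulate_bold(gt, noise_sd=1.0, ar1=0.3, drift_amp=0.3)
    boundary_trs = np.unique(np.round(gt.boundary_times / config.tr)
                             .astype(int))
    patterns = synth.simulate_patterns(40, boundary_trs, gt.n_tr,
                                       noise_sd=0.3,
                                       rng=np.random.default_rng(
                                           config.seed + 5))
    cuts = [float(t) for t in gt.boundary_times]
    frames, frame_times, audio, audio_rate = synth.simulate_media(
        run_length, cuts, frame_rate=2.0, audio_rate=4000,
        frame_shape=(24, 32), rng=np.random.default_rng(config.seed + 7))
    shot_rng = np.random.default_rng(config.seed + 9)
    loc_change = shot_rng.random(len(cuts)) < 0.6
    location = np.concatenate([[0], np.cumsum(loc_change)])
    shot_table = pd.DataFrame({
        "onset_s": [0.0] + cuts,
        "location_id": location,
        "temporal_progression": np.concatenate(
            [[0], (shot_rng.random(len(cuts)) < 0.5).astype(int)])})
    inputs = {"annotations": annotations, "run_duration": run_length,
              "tcs": tcs, "patterns": patterns,
              "media": {"frames": frames, "frame_times": frame_times,
                        "audio": audio, "audio_rate": audio_rate},
              "shot_table": shot_table,
              "ground_truth": gt}
    report = run_pipeline(config, inputs, out_dir, make_figures=make_figures)
    report["ground_truth_boundaries"] = [float(t) for t in gt.boundary_times]
    return report
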