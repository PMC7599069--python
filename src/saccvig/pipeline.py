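"""End-to-end orchestration: simulate → detect → measure → test.

``run_pipeline`` drives all analysis stages from a single configuration
and writes a result bundle of plain-text tables plus a manifest (config
hash, seed, stage timings, exclusion log) from which every number is
recomputable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import fixation as fx
from . import pupil as pp
from . import stats as st
from . import synth, traces, vigour
from .config import CONDITION_FACTORS, CONDITIONS, SimulationConfig
from .gaze_io import GazeRecording, read_recording, write_recording
from .saccades import (
    DetectionThresholds,
    apply_participant_exclusion,
    detect_session,
    saccade_table,
)

__all__ = ["load_config", "run_pipeline", "PipelineError", "ConfigError"]

ALL_STAGES = ("detect", "vigour", "traces", "pupil", "fixation", "stats")

#: per-participant condition contrasts used for the time-course tests
CONTRASTS = {"contingent": ("Performance", "Random"), "guaranteed": ("10p", "0p")}


class PipelineError(RuntimeError):
    """An analysis stage failed."""


class ConfigError(ValueError):
    """The configuration or input layout is unusable."""


def load_config(path) -> SimulationConfig:
    """Read a YAML or JSON simulation/analysis config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must hold a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return SimulationConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate_dataset(config: SimulationConfig, out_dir: Path, rng: np.random.Generator):
    """Simulate and write every participant-session; returns recordings."""
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            fh,
            sort_keys=True,
        )
    recordings = []
    truths = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        for label in config.session_labels[: config.sessions_per_participant]:
            rec, truth = synth.simulate_session(config, pid, label, rng)
            write_recording(
                rec,
                out_dir / f"{pid}_{label}_samples.tsv",
                out_dir / f"{pid}_{label}_events.tsv",
            )
            recordings.append(rec)
            truths.append(truth)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, default=float)
    return recordings


def _load_dataset(input_dir: Path) -> list[GazeRecording]:
    files = sorted(input_dir.glob("*_samples.tsv"))
    if not files:
        raise ConfigError(f"no *_samples.tsv recordings found in {input_dir}")
    recs = []
    for sp in files:
        ep = sp.with_name(sp.name.replace("_samples.tsv", "_events.tsv"))
        if not ep.exists():
            raise ConfigError(f"missing events file for {sp.name}")
        recs.append(read_recording(sp, ep))
    return recs


def _session_traces(saccades, min_valid: int = 3):
    """Per-condition kinematic profile means, autocorrelation and covariance."""
    vel, acc, auto, cov = {}, {}, {}, {}
    for cond in CONDITIONS:
        group = [s for s in saccades if s.valid and s.condition == cond]
        if len(group) < min_valid:
            continue
        vs, accs, poss = [], [], []
        for s in group:
            p, v, a = traces.kinematic_profiles(s.trajectory)
            poss.append(p.values)
            vs.append(v.values)
            accs.append(a.values)
        vel[cond] = np.mean(vs, axis=0)
        acc[cond] = np.mean(accs, axis=0)
        stack = np.vstack(poss)
        auto[cond] = traces.autocorrelation_matrix(stack, condition=cond).z
        cov[cond] = traces.covariance_matrix(stack)
    return vel, acc, auto, cov


def run_pipeline(
    config: SimulationConfig,
    input_dir: str | Path = "simulate",
    output_dir: str | Path = "results",
    seed: int | None = None,
    n_perm: int = 1000,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the requested stages and write the result bundle.

    ``input_dir="simulate"`` generates a dataset from ``config`` first;
    otherwise recordings are read from the directory.  Returns the run
    manifest (also written to ``manifest.json``).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": int(seed if seed is not None else config.rng_seed),
        "n_perm": n_perm,
        "stages": list(stages),
        "timings_s": {},
        "exclusions": {"trials": [], "participants": []},
    }
    t0 = time.perf_counter()
    try:
        if str(input_dir) == "simulate":
            recordings = _simulate_dataset(config, out / "simulated", rng)
        else:
            recordings = _load_dataset(Path(input_dir))
    except ConfigError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    manifest["timings_s"]["input"] = round(time.perf_counter() - t0, 3)
    manifest["n_sessions"] = len(recordings)

    if not stages:  # simulate-only run
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
        return manifest

    th = DetectionThresholds()

    # ---- detect -----------------------------------------------------------
    t0 = time.perf_counter()
    per_session: dict[tuple[str, str], list] = {}
    tables = []
    for rec in recordings:
        sacc = detect_session(rec, th)
        per_session[(rec.participant_id, rec.session_label)] = sacc
        tab = saccade_table(sacc)
        tab.insert(0, "participant_id", rec.participant_id)
        tab.insert(1, "session_label", rec.session_label)
        tables.append(tab)
        for s in sacc:
            if not s.valid:
                manifest["exclusions"]["trials"].append(
                    {
                        "participant_id": rec.participant_id,
                        "session_label": rec.session_label,
                        "trial_index": s.trial_index,
                        "reason": s.rejection_reason,
                    }
                )
    all_sacc = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    if "detect" in stages:
        all_sacc.to_csv(out / "saccades.csv", index=False)
    manifest["timings_s"]["detect"] = round(time.perf_counter() - t0, 3)

    # participant exclusion: < 10 valid trials in any condition of any session
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for (pid, label), sacc in per_session.items():
        c = {cond: sum(1 for s in sacc if s.valid and s.condition == cond) for cond in CONDITIONS}
        counts.setdefault(pid, {})[label] = c
    kept = {
        pid
        for pid, sess in counts.items()
        if apply_participant_exclusion(sess, th.min_valid_trials)
    }
    for pid, sess in counts.items():
        if pid not in kept:
            manifest["exclusions"]["participants"].append(
                {"participant_id": pid, "counts": sess}
            )
    if not kept:
        raise PipelineError("detect: no participant retained after exclusions")

    session_labels = sorted({label for _, label in per_session})
    multi_session = len(session_labels) > 1
    within = ["contingency", "motivation"] + (["session_label"] if multi_session else [])

    # ---- vigour -----------------------------------------------------------
    t0 = time.perf_counter()
    trial_tabs = []
    for (pid, label), sacc in per_session.items():
        if pid not in kept:
            continue
        trial_tabs.append(vigour.session_residual_table(sacc, pid, label))
    trials = pd.concat(trial_tabs, ignore_index=True)
    ep_var = (
        trials.groupby(["participant_id", "session_label", "condition"])
        .apply(
            lambda g: vigour.endpoint_variability(g[["endpoint_x", "endpoint_y"]].to_numpy()),
            include_groups=False,
        )
        .rename("endpoint_variability")
        .reset_index()
    )
    measures = ["velocity_residual", "amplitude_deg", "latency_ms", "peak_velocity"]
    cells = vigour.condition_means(trials, measures)
    factors = ep_var["condition"].map(CONDITION_FACTORS)
    ep_var["contingency"] = factors.str[0]
    ep_var["motivation"] = factors.str[1]
    cells = cells.merge(
        ep_var.drop(columns=["condition"]),
        on=["participant_id", "session_label", "contingency", "motivation"],
    )
    if "vigour" in stages:
        trials.to_csv(out / "trials.csv", index=False)
        cells.to_csv(out / "cell_means.csv", index=False)
    manifest["timings_s"]["vigour"] = round(time.perf_counter() - t0, 3)

    # ---- stats on scalar measures ----------------------------------------
    if "stats" in stages:
        t0 = time.perf_counter()
        anova_rows = []
        for measure in measures + ["endpoint_variability"]:
            res = st.rm_anova(cells, dv=measure, within=within)
            res.insert(0, "measure", measure)
            anova_rows.append(res)
        anova = pd.concat(anova_rows, ignore_index=True)
        anova.to_csv(out / "anova.csv", index=False)
        manifest["timings_s"]["stats"] = round(time.perf_counter() - t0, 3)
        manifest["anova_df_den"] = int(anova["df_den"].iloc[0])

    # ---- traces ----------------------------------------------------------
    if "traces" in stages:
        t0 = time.perf_counter()
        by = {}
        for (pid, label), sacc in per_session.items():
            if pid not in kept:
                continue
            by[(pid, label)] = _session_traces(sacc)
        cluster_report = {}
        for label in session_labels:
            for cname, (hi, lo) in CONTRASTS.items():
                diffs = {"velocity": [], "acceleration": [], "autocorr": [], "covariance": []}
                for (pid, lab), (vel, acc, auto, cov) in by.items():
                    if lab != label or hi not in vel or lo not in vel:
                        continue
                    diffs["velocity"].append(vel[hi] - vel[lo])
                    diffs["acceleration"].append(acc[hi] - acc[lo])
                    dz = auto[hi] - auto[lo]
                    np.fill_diagonal(dz, np.nan)
                    diffs["autocorr"].append(dz)
                    diffs["covariance"].append(cov[hi] - cov[lo])
                if len(diffs["velocity"]) >= 6:
                    for kind, stack in diffs.items():
                        res = st.cluster_permutation(np.stack(stack), n_perm=n_perm, rng=rng)
                        cluster_report[f"{kind}_{cname}_{label}"] = _cluster_json(res)
                    pd.DataFrame(np.mean(diffs["autocorr"], axis=0)).to_csv(
                        out / f"autocorr_diff_{cname}_{label}.csv", index=False
                    )
        with open(out / "clusters.json", "w") as fh:
            json.dump(cluster_report, fh, indent=1)
        manifest["timings_s"]["traces"] = round(time.perf_counter() - t0, 3)

    # ---- pupil -----------------------------------------------------------
    if "pupil" in stages:
        t0 = time.perf_counter()
        rows = []
        for rec in recordings:
            if rec.participant_id not in kept:
                continue
            cleaned = pp.clean_pupil(np.where(rec.valid, rec.pupil, np.nan))
            for ev in rec.events:
                i_cue = rec.index_at(ev.cue_onset)
                try:
                    tr = pp.trial_trace(cleaned, i_cue)
                except ValueError:
                    continue
                if np.isnan(tr.values).all():
                    continue
                rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "session_label": rec.session_label,
                        "condition": ev.condition,
                        "window_mean": pp.window_mean(tr),
                        **{f"bin{k}": v for k, v in enumerate(tr.values)},
                    }
                )
        pupil_df = pd.DataFrame(rows)
        if len(pupil_df):
            mean_traces = (
                pupil_df.groupby(["session_label", "condition"])[
                    [c for c in pupil_df.columns if c.startswith("bin")]
                ]
                .mean()
                .reset_index()
            )
            mean_traces.to_csv(out / "pupil_traces.csv", index=False)
            pup_cells = vigour.condition_means(pupil_df, ["window_mean"])
            pup_cells.to_csv(out / "pupil_cells.csv", index=False)
            if "stats" in stages:
                try:
                    st.rm_anova(pup_cells, dv="window_mean", within=within).to_csv(
                        out / "pupil_anova.csv", index=False
                    )
                except ValueError:
                    pass  # some participant lost a full pupil cell
            # hypothesis-free cluster test across the whole time-course
            bins = [c for c in pupil_df.columns if c.startswith("bin")]
            per_cell = pupil_df.groupby(
                ["participant_id", "session_label", "condition"]
            )[bins].mean()
            pupil_clusters = {}
            for label in session_labels:
                for cname, (hi, lo) in CONTRASTS.items():
                    diffs = []
                    for pid in sorted(kept):
                        try:
                            d = (
                                per_cell.loc[(pid, label, hi)]
                                - per_cell.loc[(pid, label, lo)]
                            ).to_numpy()
                        except KeyError:
                            continue
                        if np.isfinite(d).all():
                            diffs.append(d)
                    if len(diffs) >= 6:
                        res = st.cluster_permutation(np.vstack(diffs), n_perm=n_perm, rng=rng)
                        pupil_clusters[f"pupil_{cname}_{label}"] = _cluster_json(res)
            with open(out / "pupil_clusters.json", "w") as fh:
                json.dump(pupil_clusters, fh, indent=1)
        manifest["timings_s"]["pupil"] = round(time.perf_counter() - t0, 3)

    # ---- fixation --------------------------------------------------------
    if "fixation" in stages:
        t0 = time.perf_counter()
        rows = []
        for rec in recordings:
            if rec.participant_id not in kept:
                continue
            for ev in rec.events:
                i0 = rec.index_at(ev.cue_onset)
                i1 = i0 + 1400
                if i1 > len(rec.t):
                    continue
                win = fx.clean_fixation(rec.x[i0:i1], rec.y[i0:i1], rec.valid[i0:i1])
                if not win.kept:
                    continue
                ms = fx.detect_microsaccades(win)
                row = {
                    "participant_id": rec.participant_id,
                    "session_label": rec.session_label,
                    "condition": ev.condition,
                    "n_microsaccades": len(ms),
                    "drift_speed": fx.drift_speed(win, ms),
                }
                for wname in fx.SPECTRUM_WINDOWS:
                    try:
                        freqs, amp = fx.fixation_spectrum(win.x, wname)
                        for f, a in zip(freqs, amp):
                            row[f"{wname}_{f:.0f}Hz"] = a
                    except ValueError:
                        pass
                rows.append(row)
        fix_df = pd.DataFrame(rows)
        if len(fix_df):
            fix_df.to_csv(
                out / "fixation_trials.csv",
                index=False,
                columns=[c for c in fix_df.columns if "Hz" not in c],
            )
            spec_cols = [c for c in fix_df.columns if c.endswith("Hz")]
            if spec_cols:
                spectra = (
                    fix_df.groupby(["session_label", "condition"])[spec_cols]
                    .mean()
                    .reset_index()
                )
                spectra.to_csv(out / "fixation_spectra.csv", index=False)
        manifest["timings_s"]["fixation"] = round(time.perf_counter() - t0, 3)

    manifest["n_participants_kept"] = len(kept)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest


def _cluster_json(res: st.ClusterTestResult) -> dict:
    return {
        "n_permutations": res.n_permutations,
        "threshold": res.threshold,
        "clusters": [
            {"size": int(len(c.indices)), "mass": c.mass, "p": c.p, "sign": c.sign}
            for c in res.clusters
        ],
    }
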