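"""End-to-end orchestration: simulate -> cardiac -> spectral/EMG -> stats -> circular.

A *study* is a set of subjects, each contributing one motor-imagery session
(and optionally a shorter motor-execution session used for the ECG sanity
contrasts).  Every stage consumes the outputs of the previous one exactly as
it would for recorded data; nothing downstream ever touches the simulation
ground truth.  A single master seed fans out to named substreams
(simulation, permutations, control runs, Monte-Carlo) so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardiac, circular, emg, spectral, stats
from .simulate import SimulationConfig, Session, simulate_session

logger = logging.getLogger("cardiomotor")

REGIONS = ("M1", "S1")


@dataclass
class RunConfig:
    """Study-level analysis parameters (defaults follow the analysis plan)."""

    n_subjects: int = 6
    window: tuple[float, float] = spectral.ANALYSIS_WINDOWS["primary"]
    n_perm: int = 500
    q: float = 0.05
    n_control_runs: int = 10
    percentiles: tuple[int, ...] = (50, 75, 90)
    mc_perm: int = 1000
    seed: int = 0
    include_me: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_perm", "n_control_runs", "mc_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if not -1.0 <= self.window[0] < self.window[1] <= 4.0:
            raise ValueError("analysis window must lie inside the epoch")


@dataclass
class SubjectData:
    """All per-subject intermediates the group stages need."""

    events: pd.DataFrame                    # enriched cue table (phase, theta)
    cardiac_events: cardiac.CardiacEvents
    band_power: spectral.BandPowerSet
    ipsi: np.ndarray                        # (trials, regions, bands, samples)
    contra: np.ndarray
    emg_env: emg.EmgEnvelopeSet
    ecg_epochs: spectral.EpochSet
    mean_ibi: float


def process_subject(session: Session,
                    run: RunConfig) -> SubjectData:
    """Single-session processing chain on one subject's recording."""
    fs = session.sampling_rate
    events = cardiac.delineate(session.ecg, fs)
    cues = cardiac.enrich_events(session.events, events)
    labelled = cues[cues["phase"].isin(["systole", "diastole"])].reset_index(drop=True)

    cleaned = cardiac.regress_cardiac_artifact(session.neural, session.ecg)
    neural_epochs = spectral.epoch(cleaned, fs, labelled["onset_s"].to_numpy(),
                                   channels=session.neural_channels,
                                   events=labelled)
    bp = spectral.compute_band_power(neural_epochs)
    ipsi, contra = spectral.lateralize(bp, bp.events["side"].to_numpy())

    env = emg.preprocess_emg(session.emg, fs)
    env_epochs = spectral.epoch(env, fs, labelled["onset_s"].to_numpy(),
                                channels=session.emg_channels, events=labelled)
    ipsi_env, contra_env = emg.split_ipsi_contra(
        env_epochs.data, env_epochs.events["side"].to_numpy())
    env_set = emg.EmgEnvelopeSet(
        envelopes=np.stack([ipsi_env, contra_env], axis=1),
        sampling_rate=fs, t0_offset=env_epochs.t0_offset,
        smoothing_window=0.1, events=env_epochs.events)

    ecg_epochs = spectral.epoch(session.ecg, fs,
                                labelled["onset_s"].to_numpy(),
                                channels=("ECG",), events=labelled)
    return SubjectData(events=labelled, cardiac_events=events,
                       band_power=bp, ipsi=ipsi, contra=contra,
                       emg_env=env_set, ecg_epochs=ecg_epochs,
                       mean_ibi=float(events.ibis.mean()))


def simulate_study(run: RunConfig) -> tuple[list[Session], list[Session]]:
    """One MI session per subject (plus an optional ME session)."""
    ss = np.random.SeedSequence(run.seed)
    sim_seeds = ss.spawn(2 * run.n_subjects + 1)
    subj_rng = np.random.default_rng(sim_seeds[-1])
    mi_sessions, me_sessions = [], []
    for s in range(run.n_subjects):
        ibi = float(np.clip(subj_rng.normal(run.sim.ibi_mean, 0.03), 0.7, 1.1))
        base = dataclasses.replace(
            run.sim, ibi_mean=ibi,
            seed=int(sim_seeds[2 * s].generate_state(1)[0] % (2 ** 31)))
        mi_sessions.append(simulate_session(base, task="MI")[0])
        if run.include_me:
            me_cfg = dataclasses.replace(
                base, n_trials_left=25, n_trials_right=25,
                seed=int(sim_seeds[2 * s + 1].generate_state(1)[0] % (2 ** 31)))
            me_sessions.append(simulate_session(me_cfg, task="ME")[0])
    return mi_sessions, me_sessions


def _subject_traces(subjects: list[SubjectData], region: int, band: int,
                    mask: np.ndarray, phase: str | None,
                    trial_sets: list[np.ndarray] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject mean ipsi/contra traces over a trial subset and time mask."""
    a, b = [], []
    for s, sub in enumerate(subjects):
        idx = np.arange(sub.ipsi.shape[0])
        if phase is not None:
            idx = idx[sub.band_power.events["phase"].to_numpy()[idx] == phase]
        if trial_sets is not None:
            idx = trial_sets[s]
        a.append(sub.ipsi[idx, region, band][:, mask].mean(axis=0))
        b.append(sub.contra[idx, region, band][:, mask].mean(axis=0))
    return np.asarray(a), np.asarray(b)


def _laterality_tests(subjects, run, mask, times, rng,
                      trial_sets_by_phase=None) -> dict:
    """Ipsi-vs-contra timewise tests for every region x band x phase subset."""
    out = {}
    for phase in (None, "systole", "diastole"):
        key = phase or "all"
        out[key] = {}
        for r, region in enumerate(REGIONS):
            for bnd, band in enumerate(("alpha", "beta")):
                trial_sets = None
                if trial_sets_by_phase is not None:
                    trial_sets = trial_sets_by_phase[key]
                a, b = _subject_traces(subjects, r, bnd, mask, phase,
                                       trial_sets)
                res = stats.timewise_perm_test(
                    a, b, times=times, n_perm=run.n_perm, q=run.q, rng=rng)
                out[key][f"{region}_{band}"] = res
    return out


def run_pipeline(run: RunConfig,
                 mi_sessions: list[Session] | None = None,
                 me_sessions: list[Session] | None = None) -> dict:
    """Execute the full study analysis; returns the report bundle.

    When no sessions are given, a synthetic study is simulated from
    ``run.sim`` under the master seed.  The report contains every statistic
    with its window, seed and parameters; ``run.out_dir`` additionally
    persists it as JSON plus per-test TSVs.
    """
    ss = np.random.SeedSequence(run.seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(("perm", "control", "mc"), ss.spawn(4)[1:])}
    if mi_sessions is None:
        logger.info("simulating study: %d subjects", run.n_subjects)
        mi_sessions, me_sessions = simulate_study(run)

    subjects = [process_subject(s, run) for s in mi_sessions]
    me_subjects = ([process_subject(s, run) for s in me_sessions]
                   if me_sessions else [])

    bp0 = subjects[0].band_power
    times = bp0.times
    mask = bp0.window_mask(run.window)
    wtimes = times[mask]

    report: dict = {"config": {"n_subjects": run.n_subjects,
                               "window_s": list(run.window),
                               "n_perm": run.n_perm, "q": run.q,
                               "n_control_runs": run.n_control_runs,
                               "percentiles": list(run.percentiles),
                               "mc_perm": run.mc_perm, "seed": run.seed}}

    # --- ECG sanity contrasts -------------------------------------------
    ecg_mask = (subjects[0].ecg_epochs.times >= -0.5) \
        & (subjects[0].ecg_epochs.times < 2.0)
    ecg_by_side = {side: np.asarray(
        [sub.ecg_epochs.data[sub.ecg_epochs.events["side"] == side, 0][:, ecg_mask]
         .mean(axis=0) for sub in subjects]) for side in ("left", "right")}
    ecg_test = stats.timewise_perm_test(
        ecg_by_side["left"], ecg_by_side["right"],
        times=subjects[0].ecg_epochs.times[ecg_mask],
        n_perm=run.n_perm, q=run.q, rng=streams["perm"])
    report["ecg_waveform_left_vs_right"] = ecg_test.summary()
    if me_subjects and len(me_subjects) == len(subjects) and len(subjects) >= 5:
        ibi_mi = np.asarray([[s.mean_ibi] for s in subjects])
        ibi_me = np.asarray([[s.mean_ibi] for s in me_subjects])
        report["ibi_mi_vs_me"] = stats.timewise_perm_test(
            ibi_mi, ibi_me, n_perm=run.n_perm, q=run.q,
            rng=streams["perm"]).summary()

    # --- EMG contrasts ---------------------------------------------------
    emg_mask = (subjects[0].emg_env.times >= run.window[0]) \
        & (subjects[0].emg_env.times < run.window[1])
    emg_times = subjects[0].emg_env.times[emg_mask]
    emg_ipsi = np.asarray([s.emg_env.ipsi[:, emg_mask].mean(axis=0)
                           for s in subjects])
    emg_contra = np.asarray([s.emg_env.contra[:, emg_mask].mean(axis=0)
                             for s in subjects])
    report["emg_ipsi_vs_contra"] = stats.timewise_perm_test(
        emg_ipsi, emg_contra, times=emg_times, n_perm=run.n_perm, q=run.q,
        rng=streams["perm"]).summary()
    by_phase = {}
    for ph in ("diastole", "systole"):
        by_phase[ph] = np.asarray(
            [s.emg_env.ipsi[s.emg_env.events["phase"] == ph][:, emg_mask]
             .mean(axis=0) for s in subjects])
    report["emg_ipsi_diastole_vs_systole"] = stats.timewise_perm_test(
        by_phase["diastole"], by_phase["systole"], times=emg_times,
        n_perm=run.n_perm, q=run.q, rng=streams["perm"]).summary()

    # --- neural laterality: all / systole / diastole subsets ------------
    laterality = _laterality_tests(subjects, run, mask, wtimes,
                                   streams["perm"])
    report["laterality"] = {
        subset: {contrast: res.summary() | {"runs_s": res.significant_runs()}
                 for contrast, res in tests.items()}
        for subset, tests in laterality.items()}

    # --- balanced control runs ------------------------------------------
    control = []
    for _ in range(run.n_control_runs):
        trial_sets_by_phase = {"all": [], "systole": [], "diastole": []}
        for sub in subjects:
            phases = sub.band_power.events["phase"].to_numpy()
            sys_idx = np.nonzero(phases == "systole")[0]
            dia_idx = np.nonzero(phases == "diastole")[0]
            n_target = min(sys_idx.size, dia_idx.size)
            sys_sel = stats.balanced_control_runs(sys_idx, n_target, 1,
                                                  streams["control"])[0]
            dia_sel = stats.balanced_control_runs(dia_idx, n_target, 1,
                                                  streams["control"])[0]
            trial_sets_by_phase["systole"].append(sys_sel)
            trial_sets_by_phase["diastole"].append(dia_sel)
            trial_sets_by_phase["all"].append(
                np.concatenate([sys_sel, dia_sel]))
        tests = _laterality_tests(subjects, run, mask, wtimes,
                                  streams["perm"], trial_sets_by_phase)
        control.append({subset: {c: r.summary() for c, r in t.items()}
                        for subset, t in tests.items()})
    report["control_runs"] = control

    # --- suppression-index circular analysis ----------------------------
    circ_report = {}
    for r, region in enumerate(REGIONS):
        for bnd, band in enumerate(("alpha", "beta")):
            res_all = laterality["all"][f"{region}_{band}"]
            runs = res_all.significant_runs()
            if runs:
                window = max(runs, key=lambda w: w[1] - w[0])
                fallback = False
            else:
                window = run.window
                fallback = True
                logger.info("no significant interval for %s %s: "
                            "falling back to full analysis window",
                            region, band)
            entry = {"window_s": list(window), "window_is_fallback": fallback}
            for pct in run.percentiles:
                dirs, rbars, counts = [], [], []
                for sub in subjects:
                    idx_full = suppression_index_for(sub, r, bnd, window)
                    sel = circular.select_trials(idx_full, pct)
                    theta = sub.band_power.events["theta_rad"].to_numpy()[sel]
                    theta = theta[np.isfinite(theta)]
                    if theta.size < 3:
                        logger.info("subject dropped from circular analysis "
                                    "(%d above-threshold trials)", theta.size)
                        continue
                    sr = circular.rayleigh_test(theta)
                    dirs.append(sr.mean_direction)
                    rbars.append(sr.r_bar)
                    counts.append(theta.size)
                if len(dirs) < 3:
                    entry[f"p{pct}"] = None
                    continue
                grp = circular.group_rayleigh(np.asarray(dirs),
                                              np.asarray(rbars))
                null = circular.monte_carlo_null(np.asarray(counts),
                                                 run.mc_perm, streams["mc"])
                grp.monte_carlo_p = circular.monte_carlo_p(grp.z, null)
                grp.n_mc_perm = run.mc_perm
                entry[f"p{pct}"] = grp.to_dict() | {
                    "subject_directions": list(grp.subject_directions),
                    "n_selected_per_subject": counts}
            circ_report[f"{region}_{band}"] = entry
    report["circular"] = circ_report

    # --- systole overlap summary (diastole-cued laterality window) ------
    overlap = {}
    for r, region in enumerate(REGIONS):
        for bnd, band in enumerate(("alpha", "beta")):
            res = laterality["diastole"][f"{region}_{band}"]
            runs = res.significant_runs()
            if not runs:
                overlap[f"{region}_{band}"] = None
                continue
            window = max(runs, key=lambda w: w[1] - w[0])
            per_subject = []
            for sub in subjects:
                ev = sub.band_power.events
                dia_cues = ev.loc[ev["phase"] == "diastole",
                                  "onset_s"].to_numpy()
                val = circular.systole_overlap_summary(
                    window, sub.cardiac_events.r_times,
                    sub.cardiac_events.t_offsets, dia_cues)
                if np.isfinite(val):
                    per_subject.append(val)
            overlap[f"{region}_{band}"] = {
                "window_s": list(window),
                "mean_overlap_s": float(np.mean(per_subject)),
                "per_subject_s": per_subject}
    report["systole_overlap"] = overlap

    if run.out_dir is not None:
        _write_report(report, laterality, run)
    return report


def suppression_index_for(sub: SubjectData, region: int, band: int,
                          window: tuple[float, float]) -> np.ndarray:
    """Trial-wise suppression index of one subject for a region and band."""
    times = sub.band_power.times
    return circular.suppression_index(sub.ipsi[:, region, band],
                                      sub.contra[:, region, band],
                                      times, window)


def _write_report(report: dict, laterality: dict, run: RunConfig) -> None:
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    class _Encoder(json.JSONEncoder):
        def default(self, obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return super().default(obj)

    (out / "report.json").write_text(json.dumps(report, cls=_Encoder,
                                                indent=1))
    for subset, tests in laterality.items():
        for contrast, res in tests.items():
            res.to_tsv(out / f"laterality_{subset}_{contrast}.tsv")
    logger.info("report written to %s", out)
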