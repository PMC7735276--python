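"""End-to-end orchestration: dataset generation, calibration, reconstruction,
kinematics, morphometrics and statistics, with CSV contracts and a run log.

The on-disk dataset layout written by :func:`generate_dataset` and read by
:func:`run_pipeline`::

    <dir>/calibration.csv            checkerboard correspondences (all views)
    <dir>/morphology.csv             one row per toad
    <dir>/trials.csv                 trial_id -> animal_id index
    <dir>/trials/<trial>_landmarks.csv
    <dir>/trials/<trial>_brightness.csv
    <dir>/trials/<trial>_truth.csv   ground-truth sidecar (synthetic data)
    <dir>/raceway_events.csv         optional

Every stage writes its outputs before the next begins; a stage failure
raises :class:`PipelineError` carrying the stage name and offending trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .errors import ToadhopError
from .kinematics import (
    EPSILON_CM,
    align_trajectory,
    detect_takeoff_landing,
    extract_kinematics,
    select_best_jump,
)
from .morphometrics import LINEAR_TRAITS, records_to_frame, shape_residuals
from .raceway import RacewayTrial, jump_vs_raceway, summarize_raceway
from .stats import nested_anova
from .stereo import calibrate_rig, estimate_sync_offset, reconstruct_trajectory
from .synthetic import (
    CohortSpec,
    default_rig,
    generate_checkerboard_views,
    render_stereo,
    simulate_cohort,
    simulate_jump,
    simulate_raceway_trial,
)

logger = logging.getLogger("toadhop")

KINEMATIC_VARS = ("mean_velocity", "max_velocity", "distance", "height",
                  "angle_takeoff", "angle_landing")


class PipelineError(ToadhopError):
    """A pipeline stage failed; carries the stage and offending trial."""

    def __init__(self, stage: str, trial_id: str | None, cause: Exception):
        super().__init__(
            f"stage {stage!r} failed"
            + (f" for trial {trial_id!r}" if trial_id else "")
            + f": {cause}"
        )
        self.stage = stage
        self.trial_id = trial_id


@dataclass
class PipelineConfig:
    """Run parameters; defaults mirror the recording protocol."""

    data_dir: Path
    out_dir: Path
    fps: float = 240.0
    qc_threshold: float = 0.01
    epsilon: float = EPSILON_CM
    smooth: bool = False
    residual_grouping: str = "by-generation"
    stay_threshold: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)


@dataclass
class PipelineResult:
    kinematics: pd.DataFrame
    residuals: pd.DataFrame
    stats: pd.DataFrame
    qc: pd.DataFrame
    raceway: pd.DataFrame | None
    out_dir: Path


# --------------------------------------------------------------------------
# synthetic dataset generation
# --------------------------------------------------------------------------

def generate_dataset(
    out_dir,
    cohorts: list[CohortSpec],
    seed: int = 0,
    n_per_cohort: int | None = None,
    populations: tuple[str, ...] | None = None,
    pixel_noise_sd: float = 0.0,
    sync_offset_frames: int = 0,
    n_calibration_views: int = 12,
    calibration_corruption=None,
    jumps_per_animal: int = 1,
    raceway: bool = True,
) -> Path:
    """Write a complete ground-truthed dataset for the pipeline.

    Raceway hop distances are loosely coupled to each animal's planted jump
    distance so the jump-versus-raceway correlation is positive, as in the
    field data.
    """
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rig = default_rig(pixel_noise_sd=pixel_noise_sd,
                      sync_offset_frames=sync_offset_frames)
    views = generate_checkerboard_views(rig, n_calibration_views, rng=rng,
                                        corruption=calibration_corruption)
    tio.write_table(tio.views_to_frame(views), out / "calibration.csv",
                    "correspondences")
    morph_rows, trial_rows, race_rows = [], [], []
    for spec in cohorts:
        cohort = simulate_cohort(spec, rng=rng, n=n_per_cohort,
                                 populations=populations)
        for rec, params in cohort:
            morph_rows.append(rec)
            for k in range(jumps_per_animal):
                trial_id = f"{rec.animal_id}-j{k}"
                traj, truth = simulate_jump(params, rig.fps)
                obs, traces = render_stereo(traj, rig, rng=rng)
                tio.write_table(obs, out / "trials" / f"{trial_id}_landmarks.csv",
                                "landmarks")
                bri = pd.concat([
                    pd.DataFrame({"camera": cam, "frame": np.arange(len(tr)),
                                  "brightness": tr})
                    for cam, tr in traces.items()
                ])
                tio.write_table(bri, out / "trials" / f"{trial_id}_brightness.csv",
                                "brightness")
                tio.write_table(pd.DataFrame([{
                    "trial_id": trial_id, "distance": truth.distance,
                    "height": truth.height, "flight_time": truth.flight_time,
                    "angle_takeoff": truth.angle_takeoff,
                    "angle_landing": truth.angle_landing,
                }]), out / "trials" / f"{trial_id}_truth.csv", "ground_truth")
                trial_rows.append({"trial_id": trial_id,
                                   "animal_id": rec.animal_id})
            if raceway:
                range_m = (params.takeoff_speed ** 2
                           * np.sin(2 * np.radians(params.takeoff_elevation))
                           / params.gravity) / 100.0
                hop_mean = max(0.15, 0.6 * range_m + rng.normal(0.0, 0.08))
                trial = simulate_raceway_trial(hop_mean, 0.12, 2.0, 0.05,
                                               rng=rng, animal_id=rec.animal_id)
                for t, p in trial.hops:
                    race_rows.append((rec.animal_id, "hop", t, f"{p:.6f}"))
                for t in trial.refusals:
                    race_rows.append((rec.animal_id, "refusal", t, ""))
    morph = records_to_frame(morph_rows)
    tio.write_table(morph, out / "morphology.csv", "morphology")
    pd.DataFrame(trial_rows).to_csv(out / "trials.csv", index=False)
    if raceway:
        tio.write_table(
            pd.DataFrame(race_rows,
                         columns=["animal_id", "event", "timestamp", "position"]),
            out / "raceway_events.csv", "raceway_events")
    return out


# --------------------------------------------------------------------------
# full pipeline over a dataset directory
# --------------------------------------------------------------------------

def _stage(name: str, trial_id: str | None = None):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s%s", name, f" [{trial_id}]" if trial_id else "")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, trial_id, exc) from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """calibrate -> sync -> reconstruct -> align -> kinematics -> best-jump
    -> residuals -> stats, writing each stage's tables under ``out_dir``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        logger.info("toadhop pipeline; seed=%s; config=%s", config.seed, config)

        with _stage("calibrate"):
            corr = tio.read_table(config.data_dir / "calibration.csv",
                                  "correspondences")
            views = tio.frame_to_views(corr)
            left, right, reports = calibrate_rig(views, config.qc_threshold)
            qc = pd.DataFrame([{
                "view_id": r.view_id, "inaccuracy": r.inaccuracy,
                "threshold": r.threshold, "accepted": r.accepted,
                "reason": r.reason or "",
            } for r in reports])
            tio.write_table(qc, out / "qc_report.csv", "qc")
            for r in reports:
                if not r.accepted:
                    logger.warning("QC rejected view %s (inaccuracy %.4f)",
                                   r.view_id, r.inaccuracy)

        trials = pd.read_csv(config.data_dir / "trials.csv")
        jumps = []
        for row in trials.itertuples():
            with _stage("reconstruct", row.trial_id):
                lm = tio.read_table(
                    config.data_dir / "trials" / f"{row.trial_id}_landmarks.csv",
                    "landmarks")
                bri = tio.read_table(
                    config.data_dir / "trials" / f"{row.trial_id}_brightness.csv",
                    "brightness")
                off = estimate_sync_offset(
                    bri.loc[bri.camera == "left"].sort_values("frame")["brightness"],
                    bri.loc[bri.camera == "right"].sort_values("frame")["brightness"])
                raw = reconstruct_trajectory(lm, left, right, off, config.fps)
            with _stage("kinematics", row.trial_id):
                aligned = align_trajectory(raw)
                tio.write_table(tio.trajectory_to_frame(aligned),
                                out / "trajectories" / f"{row.trial_id}.csv",
                                "trajectory")
                t0, t1 = detect_takeoff_landing(aligned, config.epsilon)
                jumps.append(extract_kinematics(
                    aligned, t0, t1, smooth=config.smooth,
                    trial_id=row.trial_id, animal_id=row.animal_id))

        with _stage("best-jump"):
            best_ids = set()
            for animal, group in pd.Series(
                    range(len(jumps)),
                    index=[j.animal_id for j in jumps]).groupby(level=0):
                best = select_best_jump([jumps[i] for i in group])
                best_ids.add(best.trial_id)
            kin = tio.kinematics_to_frame(jumps, best_ids)
            tio.write_table(kin, out / "kinematics.csv", "kinematics")

        with _stage("residuals"):
            morph = tio.read_table(config.data_dir / "morphology.csv", "morphology")
            label_col = {"pooled": None, "by-generation": "generation",
                         "by-class": "class"}[config.residual_grouping]
            labels = (morph.set_index("animal_id")[label_col]
                      if label_col else
                      pd.Series("all", index=morph["animal_id"]))
            res_rows = []
            for trait in LINEAR_TRAITS:
                sr = shape_residuals(morph, trait, config.residual_grouping)
                for aid, val in sr.residuals.items():
                    grp = labels[aid]
                    slope, intercept = sr.fits[grp]
                    res_rows.append((aid, trait, grp, val, slope, intercept))
            residuals = pd.DataFrame(
                res_rows, columns=tio.SCHEMAS["residuals"][0])
            tio.write_table(residuals, out / "residuals.csv", "residuals")

        with _stage("stats"):
            best = kin[kin["best"]].merge(
                morph[["animal_id", "invasion_category", "population"]],
                on="animal_id")
            stats_rows = []
            for var in KINEMATIC_VARS:
                try:
                    for res in nested_anova(best[var], best["invasion_category"],
                                            best["population"]):
                        stats_rows.append(("nested_anova", var, res.term,
                                           res.df_num, res.df_den, res.F, res.p))
                except ToadhopError as exc:
                    logger.warning("nested ANOVA skipped for %s: %s", var, exc)
            wide = residuals.pivot(index="animal_id", columns="trait",
                                   values="residual").reset_index()
            wide = wide.merge(
                morph[["animal_id", "invasion_category", "population"]],
                on="animal_id")
            for trait in LINEAR_TRAITS:
                try:
                    for res in nested_anova(wide[trait],
                                            wide["invasion_category"],
                                            wide["population"]):
                        stats_rows.append(("nested_anova", f"resid_{trait}",
                                           res.term, res.df_num, res.df_den,
                                           res.F, res.p))
                except ToadhopError as exc:
                    logger.warning("nested ANOVA skipped for %s: %s", trait, exc)
            stats_df = pd.DataFrame(stats_rows, columns=tio.SCHEMAS["stats"][0])

        race_summary = None
        race_path = config.data_dir / "raceway_events.csv"
        if race_path.exists():
            with _stage("raceway"):
                events = tio.read_table(race_path, "raceway_events")
                summaries = []
                for aid, sub in events.groupby("animal_id"):
                    hops = sub[sub["event"] == "hop"]
                    trial = RacewayTrial(
                        animal_id=str(aid),
                        hops=np.column_stack([
                            hops["timestamp"].to_numpy(dtype=float),
                            hops["position"].astype(float).to_numpy()]),
                        refusals=sub.loc[sub["event"] == "refusal",
                                         "timestamp"].to_numpy(dtype=float),
                        terminated_early=(sub["event"] == "refusal").sum() >= 10,
                    )
                    s = summarize_raceway(trial)
                    summaries.append({
                        "animal_id": s.animal_id, "n_hops": s.n_hops,
                        "total_time_s": s.total_time_s,
                        "mean_hop_distance_m": s.mean_hop_distance_m,
                        "mean_speed_m_s": s.mean_speed_m_s,
                        "finished": s.finished,
                        "terminated_early": s.terminated_early,
                    })
                race_summary = pd.DataFrame(summaries)
                tio.write_table(race_summary, out / "raceway_summary.csv",
                                "raceway_summary")
                joined = race_summary.merge(
                    kin[kin["best"]][["animal_id", "distance", "height"]],
                    on="animal_id").rename(columns={
                        "mean_hop_distance_m": "raceway_mean_hop_m",
                        "distance": "jump_distance_cm",
                        "height": "jump_height_cm"})
                try:
                    r_d, r_h = jump_vs_raceway(joined)
                    stats_rows.append(("pearson", "raceway_hop_vs_jump_distance",
                                       "r", r_d.n, 0, r_d.r, r_d.p))
                    stats_rows.append(("pearson", "raceway_hop_vs_jump_height",
                                       "r", r_h.n, 0, r_h.r, r_h.p))
                    stats_df = pd.DataFrame(stats_rows,
                                            columns=tio.SCHEMAS["stats"][0])
                except ToadhopError as exc:
                    logger.warning("jump-vs-raceway skipped: %s", exc)

        tio.write_table(stats_df, out / "stats.csv", "stats")
        logger.info("pipeline complete: %d jumps, %d QC rejections",
                    len(jumps), int((~qc["accepted"]).sum()))
        return PipelineResult(kinematics=kin, residuals=residuals,
                              stats=stats_df, qc=qc, raceway=race_summary,
                              out_dir=out)
    finally:
        logger.removeHandler(handler)
        handler.close()


# --------------------------------------------------------------------------
# in-memory cohort pipeline (no file I/O)
# --------------------------------------------------------------------------

def cohort_pipeline(
    spec: CohortSpec,
    seed: int = 0,
    n: int | None = None,
    pixel_noise_sd: float = 0.0,
    epsilon: float = EPSILON_CM,
) -> pd.DataFrame:
    """Simulate a cohort and push every hop through the full chain.

    Each animal's hop is rendered through the (default, calibrated-from-
    checkerboards) stereo rig, synchronized, triangulated, aligned and
    reduced to its six kinematic variables. Returns one row per animal with
    the extracted variables plus the planted ground truth (columns prefixed
    ``true_``).
    """
    rng = np.random.default_rng(seed)
    rig = default_rig(pixel_noise_sd=pixel_noise_sd)
    views = generate_checkerboard_views(rig, 12, rng=rng)
    left, right, _ = calibrate_rig(views)
    rows = []
    for rec, params in simulate_cohort(spec, rng=rng, n=n):
        traj, truth = simulate_jump(params, rig.fps)
        obs, traces = render_stereo(traj, rig, rng=rng)
        off = estimate_sync_offset(traces["left"], traces["right"])
        raw = reconstruct_trajectory(obs, left, right, off, rig.fps)
        aligned = align_trajectory(raw)
        t0, t1 = detect_takeoff_landing(aligned, epsilon)
        k = extract_kinematics(aligned, t0, t1, animal_id=rec.animal_id)
        rows.append({
            "animal_id": rec.animal_id,
            "mean_velocity": k.mean_velocity, "max_velocity": k.max_velocity,
            "distance": k.distance, "height": k.height,
            "angle_takeoff": k.angle_takeoff, "angle_landing": k.angle_landing,
            "true_distance": truth.distance, "true_height": truth.height,
            "true_angle_takeoff": truth.angle_takeoff,
            "true_angle_landing": truth.angle_landing,
        })
    return pd.DataFrame(rows)
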