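"""End-to-end orchestration: simulate a synthetic study, analyze it back to
per-trial and per-animal tables, and run the statistics layer.

Everything is deterministic under a fixed configuration: per-trial seeds are
derived arithmetically from the run seed, tables are written with fixed
float formatting and sorted rows, and the manifest records every generator
parameter so round-trip tests can compare recovered metrics against truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, grf, io, spatiotemporal, stats, synth, video
from .config import RunConfig
from .exceptions import FormatError, InsufficientDataError, RatGaitError

log = logging.getLogger("ratgait")

GROUP_PREFIX = {"naive": "N", "sham": "S", "operated": "O"}
OPERATED_LIMB = "RH"
CONTRALATERAL_LIMB = "LH"
GAIT_METRICS_TESTED = ("symmetry", "stance_time_balance_pct")
GRF_FEATURES_TESTED = ("peak_vertical", "vertical_impulse",
                       "peak_propulsive", "propulsive_impulse")


def _derive_seed(base: int, *indices: int) -> int:
    """Stable sub-seed from the run seed and a path of indices."""
    h = hashlib.sha256(("/".join(map(str, (base, *indices)))).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)


def _animals(cfg: RunConfig) -> list[tuple[str, str]]:
    out = []
    for group in synth.GROUPS:
        for i in range(cfg.n_per_group.get(group, 0)):
            out.append((f"{GROUP_PREFIX[group]}{i + 1:02d}", group))
    return out


def _day_ramp(cfg: RunConfig, day: int) -> float:
    """Progressive-asymmetry ramp: deficits grow linearly across the
    follow-up days (0.5x at the first timepoint to 1.5x at the last)."""
    days = sorted(cfg.days)
    if len(days) == 1:
        return 1.0
    frac = (day - days[0]) / (days[-1] - days[0])
    return 0.5 + frac


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate_study(cfg: RunConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic study to ``outdir``; return the manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    animals = _animals(cfg)
    rng = np.random.default_rng(_derive_seed(cfg.seed, 0))

    deficits = {a: (float(rng.normal(1.0, 0.25)) if g == "operated" else 0.0)
                for a, g in animals}
    body_weights = {a: float(rng.uniform(2.0, 2.5)) for a, _ in animals}

    truth: dict = {"deficits": deficits, "body_weight_N": body_weights,
                   "gait_trials": {}, "grf_trials": {}, "videos": {},
                   "vonfrey": {}, "incapacitance": {}}
    footfall_frames, gait_rows = [], []
    vf_rows, inc_rows = [], []
    grf_dir = outdir / "grf"
    counter = 0

    for animal, group in animals:
        d = deficits[animal]
        for day in cfg.days:
            ramp = _day_ramp(cfg, day)
            true_symmetry = min(max(0.5 + 0.02 * d * ramp, 0.05), 0.95)
            true_duty_right = min(max(0.6 - 0.02 * d * ramp, 0.05), 0.95)
            for k in range(cfg.gait_trials_per_session):
                counter += 1
                seed = _derive_seed(cfg.seed, 1, counter)
                trial_rng = np.random.default_rng(seed)
                params = synth.GaitParams(
                    velocity_cm_s=float(np.clip(
                        trial_rng.normal(40.0, 5.0), 25.0, 55.0)),
                    stride_frequency_hz=float(np.clip(
                        trial_rng.normal(2.65, 0.2), 2.0, 3.5)),
                    duty_left=0.6,
                    duty_right=true_duty_right,
                    symmetry=true_symmetry,
                    step_width_cm=float(np.clip(
                        trial_rng.normal(3.6, 0.3), 2.5, 5.0)),
                    n_cycles=cfg.n_cycles,
                    timing_noise_sd_s=cfg.timing_noise_sd_s,
                    seed=seed)
                trial_id = f"{animal}_d{day:02d}_g{k}"
                footfall_frames.append(
                    synth.gen_footfall_sequence(params, trial_id=trial_id))
                gait_rows.append((trial_id, animal, group, day))
                truth["gait_trials"][trial_id] = {
                    "symmetry": params.symmetry,
                    "duty_left": params.duty_left,
                    "duty_right": params.duty_right,
                    "velocity_cm_s": params.velocity_cm_s,
                    "stride_frequency_hz": params.stride_frequency_hz,
                    "step_width_cm": params.step_width_cm,
                    "seed": seed}
                if cfg.simulate_video and k == 0:
                    counter += 1
                    vseed = _derive_seed(cfg.seed, 2, counter)
                    stack, v_truth = synth.gen_video(
                        velocity_cm_s=params.velocity_cm_s,
                        frame_rate_hz=cfg.frame_rate_hz,
                        n_frames=cfg.video_frames,
                        calibration_cm_per_px=cfg.calibration_cm_per_px,
                        noise_sd=cfg.video_noise_sd, seed=vseed)
                    io.write_frames(
                        stack.frames, stack.background,
                        {"trial_id": trial_id, "animal": animal, "day": day,
                         "frame_rate_hz": cfg.frame_rate_hz,
                         "calibration_cm_per_px": cfg.calibration_cm_per_px},
                        outdir / "video" / trial_id)
                    truth["videos"][trial_id] = {"velocity_cm_s": v_truth,
                                                 "seed": vseed}

            day_index = sorted(cfg.days).index(day)
            for k in range(cfg.grf_trials_per_session):
                counter += 1
                seed = _derive_seed(cfg.seed, 3, counter)
                trial_rng = np.random.default_rng(seed)
                # alternate plate contacts so both limbs are sampled
                limb = OPERATED_LIMB if (day_index * cfg.
                                         grf_trials_per_session + k) % 2 \
                    == 0 else CONTRALATERAL_LIMB
                injured = limb == OPERATED_LIMB
                shape = synth.GRFShapeParams(
                    peak_vertical=max(
                        0.6 - (0.06 * d * ramp if injured else 0.0), 0.1),
                    peak_braking=0.1,
                    peak_propulsive=max(
                        0.1 - (0.03 * d * ramp if injured else 0.0), 0.02),
                    peak_ml_first=0.05, peak_ml_second=0.05,
                    stance_time_s=float(np.clip(
                        trial_rng.normal(0.37, 0.05), 0.2, 0.6)),
                    body_weight_N=body_weights[animal],
                    sample_rate_hz=cfg.sample_rate_hz,
                    noise_sd_N=cfg.grf_noise_sd_N, seed=seed)
                recording, feats = synth.gen_grf_curve(shape, limb=limb)
                trial_id = f"{animal}_d{day:02d}_f{k}"
                io.write_grf(recording.data,
                             {"trial_id": trial_id, "animal": animal,
                              "group": group, "day": day, "limb": limb,
                              "body_weight_N": shape.body_weight_N,
                              "sample_rate_hz": shape.sample_rate_hz},
                             grf_dir / f"{trial_id}.tsv")
                truth["grf_trials"][trial_id] = {
                    "limb": limb, "seed": seed,
                    "stance_time_s": shape.stance_time_s,
                    **feats.to_dict()}

            for limb in (CONTRALATERAL_LIMB, OPERATED_LIMB):
                counter += 1
                seed = _derive_seed(cfg.seed, 4, counter)
                injured = limb == OPERATED_LIMB
                thr = max(12.0 - (6.0 * d * ramp if injured else 0.0), 0.6)
                observer = synth.PsychometricObserver(
                    true_threshold_g=thr, slope=8.0, seed=seed)
                session = synth.gen_vonfrey_responses(
                    observer, cfg.filament_set_g)
                for i, (f, r) in enumerate(zip(session.filaments_applied,
                                               session.responses)):
                    vf_rows.append((animal, group, day, limb, i, f, int(r)))
                truth["vonfrey"][f"{animal}_d{day:02d}_{limb}"] = {
                    "true_threshold_g": thr, "seed": seed}

            counter += 1
            seed = _derive_seed(cfg.seed, 5, counter)
            inc_rng = np.random.default_rng(seed)
            mass_g = body_weights[animal] / 9.81 * 1000.0
            right_pct = 50.0 - 1.5 * d * ramp
            for k in range(cfg.incapacitance_trials):
                total = float(np.clip(inc_rng.normal(0.8, 0.05), 0.5, 1.0)) \
                    * mass_g
                pct = float(np.clip(inc_rng.normal(right_pct, 2.0), 5, 95))
                inc_rows.append((animal, group, day, k,
                                 total * (1 - pct / 100), total * pct / 100))
            truth["incapacitance"][f"{animal}_d{day:02d}"] = {
                "right_pct": right_pct, "seed": seed}

    io.write_footfalls(pd.concat(footfall_frames, ignore_index=True),
                       outdir / "footfalls.tsv")
    io.write_table(pd.DataFrame(gait_rows, columns=[
        "trial_id", "animal", "group", "day"]), outdir / "gait_trials.tsv")
    io.write_table(pd.DataFrame(vf_rows, columns=[
        "animal", "group", "day", "limb", "trial_index", "filament_g",
        "response"]), outdir / "vonfrey.tsv")
    io.write_table(pd.DataFrame(inc_rows, columns=[
        "animal", "group", "day", "trial", "left_g", "right_g"]),
        outdir / "incapacitance.tsv")

    # endpoint deficits are tied to the per-animal deficits that drove the
    # behavioral generators, so the correlation stage has coherent truth
    endpoints = _endpoints_from_deficits(cfg, deficits, animals)
    io.write_table(endpoints, outdir / "endpoints.tsv")

    manifest = {"config": cfg.to_dict(), "truth": truth,
                "format_version": 1}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    log.info("simulated study with %d animals into %s", len(animals), outdir)
    return manifest


def _endpoints_from_deficits(cfg: RunConfig, deficits: dict,
                             animals: list[tuple[str, str]]) -> pd.DataFrame:
    """Endpoint table driven by the same per-animal deficits as behavior."""
    rng = np.random.default_rng(_derive_seed(cfg.seed, 7))
    rows = []
    for animal, group in animals:
        d = deficits[animal]
        rows.append((animal, group, "injected_deficit", d))
        for name, (b0, b1, sd) in synth.DEFAULT_LESION_MODELS.items():
            rows.append((animal, group, name,
                         max(b0 + b1 * d + rng.normal(0, sd), 0.0)))
        grade = float(np.clip(round(0.5 + 3.5 * d + rng.normal(0, 0.7)),
                              0, 6))
        rows.append((animal, group, "oarsi_grade", grade))
        il6 = 10.0 ** (1.3 + 0.4 * d + rng.normal(0, 0.2))
        rows.append((animal, group, "serum_il6_pg_ml", il6))
    return pd.DataFrame(rows, columns=["animal", "group", "measure",
                                       "value"])


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def analyze_study(dataset: str | Path, cfg: RunConfig,
                  outdir: str | Path) -> list[str]:
    """Run every analysis module over a dataset directory.

    Writes per-trial and per-animal metric tables plus an exclusion log
    with machine-readable reason codes.  Returns a list of per-file error
    messages (empty on success); input errors do not abort the remaining
    files.
    """
    cfg.validate()
    dataset = Path(dataset)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    errors: list[str] = []

    if not (dataset / "footfalls.tsv").exists() \
            and not (dataset / "grf").exists():
        raise FormatError(f"no dataset found in {dataset} "
                          "(missing footfalls.tsv and grf/)")

    _analyze_gait(dataset, cfg, outdir, errors)
    _analyze_grf(dataset, cfg, outdir, errors)
    _analyze_video(dataset, cfg, outdir, errors)
    _analyze_assays(dataset, cfg, outdir, errors)

    endpoints = dataset / "endpoints.tsv"
    if endpoints.exists():
        io.write_table(io.read_table(endpoints), outdir / "endpoints.tsv")

    if errors:
        io.write_table(pd.DataFrame({"error": errors}),
                       outdir / "errors.tsv")
        for message in errors:
            log.error("%s", message)
    return errors


def _analyze_gait(dataset: Path, cfg: RunConfig, outdir: Path,
                  errors: list[str]) -> None:
    path = dataset / "footfalls.tsv"
    if not path.exists():
        return
    try:
        events = io.read_footfalls(path)
        meta = io.read_table(dataset / "gait_trials.tsv")
    except FormatError as exc:
        errors.append(str(exc))
        return
    meta = meta.set_index("trial_id")
    metric_rows, exclusion_rows = [], []
    for trial_id, trial in events.groupby("trial_id", sort=True):
        try:
            metrics = spatiotemporal.trial_metrics(trial)
            velocities = spatiotemporal.cycle_velocities(trial)
        except (FormatError, InsufficientDataError) as exc:
            errors.append(f"{path}:{trial_id}: {exc}")
            continue
        validation = spatiotemporal.validate_trial(
            velocities, metrics.n_cycles, min_cycles=cfg.min_cycles,
            max_cycles=cfg.max_cycles, max_drift=cfg.max_velocity_drift)
        info = meta.loc[trial_id] if trial_id in meta.index else None
        metric_rows.append({
            "trial_id": trial_id,
            "animal": info["animal"] if info is not None else "",
            "group": info["group"] if info is not None else "",
            "day": int(info["day"]) if info is not None else -1,
            "accepted": validation.accepted,
            **metrics.to_dict()})
        for reason in validation.reasons:
            exclusion_rows.append({"trial_id": trial_id, "reason": reason})
    if not metric_rows:
        return
    per_trial = pd.DataFrame(metric_rows).sort_values("trial_id")
    io.write_table(per_trial, outdir / "gait_metrics.tsv")
    io.write_table(
        pd.DataFrame(exclusion_rows,
                     columns=["trial_id", "reason"]).sort_values(
            ["trial_id", "reason"]) if exclusion_rows
        else pd.DataFrame(columns=["trial_id", "reason"]),
        outdir / "exclusions.tsv")

    accepted = per_trial[per_trial["accepted"]
                         & (per_trial["animal"] != "")]
    if len(accepted):
        fields = list(spatiotemporal.SpatiotemporalMetrics.FIELDS)
        by_animal = accepted.groupby(
            ["animal", "group", "day"], sort=True)[fields].mean()
        io.write_table(by_animal.reset_index(),
                       outdir / "gait_by_animal.tsv")


def _analyze_grf(dataset: Path, cfg: RunConfig, outdir: Path,
                 errors: list[str]) -> None:
    grf_dir = dataset / "grf"
    if not grf_dir.exists():
        return
    rows = []
    for path in sorted(grf_dir.glob("*.tsv")):
        try:
            data, meta = io.read_grf(path)
            recording = grf.GRFRecording(
                data=data, body_weight_N=meta["body_weight_N"],
                sample_rate_hz=meta["sample_rate_hz"],
                limb=meta.get("limb", ""), meta=meta)
            analysis = grf.analyze_recording(
                recording, cutoff_hz=cfg.filter_cutoff_hz,
                order=cfg.filter_order,
                threshold_frac=cfg.stance_threshold_frac,
                n_points=cfg.grid_points)
        except RatGaitError as exc:
            errors.append(f"{path}: {exc}")
            continue
        rows.append({
            "trial_id": meta.get("trial_id", path.stem),
            "animal": meta.get("animal", ""),
            "group": meta.get("group", ""),
            "day": meta.get("day", -1),
            "limb": meta.get("limb", ""),
            "stance_time_s": analysis.window.duration_s,
            **analysis.features.to_dict(),
            "flags": ";".join(analysis.features.flags)})
    if rows:
        io.write_table(pd.DataFrame(rows).sort_values("trial_id"),
                       outdir / "grf_features.tsv")


def _analyze_video(dataset: Path, cfg: RunConfig, outdir: Path,
                   errors: list[str]) -> None:
    video_dir = dataset / "video"
    if not video_dir.exists():
        return
    rows = []
    for trial_dir in sorted(p for p in video_dir.iterdir() if p.is_dir()):
        try:
            frames, background, meta = io.read_frames(trial_dir)
            stack = video.FrameStack(
                frames=frames, background=background,
                frame_rate_hz=meta.get("frame_rate_hz", cfg.frame_rate_hz),
                calibration_cm_per_px=meta.get("calibration_cm_per_px",
                                               cfg.calibration_cm_per_px))
            track = video.track_velocity(stack)
        except RatGaitError as exc:
            errors.append(f"{trial_dir}: {exc}")
            continue
        heading = track.heading or (np.nan, np.nan)
        rows.append({"trial_id": meta.get("trial_id", trial_dir.name),
                     "animal": meta.get("animal", ""),
                     "day": meta.get("day", -1),
                     "velocity_cm_s": track.mean_velocity_cm_s,
                     "heading_x": heading[0], "heading_y": heading[1],
                     "flags": ";".join(track.flags)})
    if rows:
        io.write_table(pd.DataFrame(rows).sort_values("trial_id"),
                       outdir / "video_velocity.tsv")


def _analyze_assays(dataset: Path, cfg: RunConfig, outdir: Path,
                    errors: list[str]) -> None:
    vf_path = dataset / "vonfrey.tsv"
    if vf_path.exists():
        try:
            vf = io.read_table(vf_path)
            rows = []
            for (animal, group, day, limb), sub in vf.groupby(
                    ["animal", "group", "day", "limb"], sort=True):
                sub = sub.sort_values("trial_index")
                session = assays.VonFreySession(
                    filament_set_g=tuple(cfg.filament_set_g),
                    filaments_applied=tuple(sub["filament_g"]),
                    responses=tuple(bool(r) for r in sub["response"]),
                    limb=limb, animal=animal, day=int(day))
                rows.append({"animal": animal, "group": group,
                             "day": int(day), "limb": limb,
                             "threshold_g": assays.updown_threshold(session),
                             "n_trials": len(sub)})
            io.write_table(pd.DataFrame(rows).sort_values(
                ["animal", "day", "limb"]), outdir / "thresholds.tsv")
        except RatGaitError as exc:
            errors.append(f"{vf_path}: {exc}")

    inc_path = dataset / "incapacitance.tsv"
    if inc_path.exists():
        try:
            inc = io.read_table(inc_path)
            rows = []
            for (animal, group, day), sub in inc.groupby(
                    ["animal", "group", "day"], sort=True):
                reading = assays.IncapacitanceReading(
                    left_g=tuple(sub["left_g"]),
                    right_g=tuple(sub["right_g"]),
                    animal=animal, day=int(day))
                rows.append({"animal": animal, "group": group,
                             "day": int(day),
                             "weight_distribution_pct":
                                 assays.weight_distribution(reading),
                             "n_trials": len(sub)})
            io.write_table(pd.DataFrame(rows).sort_values(
                ["animal", "day"]), outdir / "weight_distribution.tsv")
        except RatGaitError as exc:
            errors.append(f"{inc_path}: {exc}")


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------


def run_stats(results: str | Path, cfg: RunConfig,
              outdir: str | Path) -> dict:
    """Group-comparison tables and the endpoint correlation report."""
    cfg.validate()
    results = Path(results)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict = {}

    gait = _maybe_read(results / "gait_by_animal.tsv")
    weight = _maybe_read(results / "weight_distribution.tsv")
    thresholds = _maybe_read(results / "thresholds.tsv")
    grf_features = _maybe_read(results / "grf_features.tsv")
    endpoints = _maybe_read(results / "endpoints.tsv")

    onesample_rows = []
    tidy_frames = []
    if gait is not None:
        for metric in GAIT_METRICS_TESTED:
            sub = gait[["animal", "group", "day", metric]].rename(
                columns={metric: "value"})
            sub.insert(3, "metric", metric)
            tidy_frames.append(sub)
        vel = gait[["animal", "group", "day", "velocity_cm_s"]].rename(
            columns={"velocity_cm_s": "value"})
        vel.insert(3, "metric", "velocity_cm_s")
        tidy_frames.append(vel)
    if weight is not None:
        sub = weight[["animal", "group", "day",
                      "weight_distribution_pct"]].rename(
            columns={"weight_distribution_pct": "value"})
        sub.insert(3, "metric", "weight_distribution_pct")
        tidy_frames.append(sub)
    tidy = pd.concat(tidy_frames, ignore_index=True) if tidy_frames else None

    if tidy is not None:
        for metric, constant in stats.NULL_CONSTANTS.items():
            sub = tidy[tidy["metric"] == metric]
            for (group, day), cell in sub.groupby(["group", "day"],
                                                  sort=True):
                means = stats.collapse_to_animal_means(cell)
                if len(means) < 2:
                    continue
                res = stats.one_sample_repeated_t(means, constant)
                onesample_rows.append({
                    "metric": metric, "group": group, "day": int(day),
                    "null_constant": constant, "n": res.n,
                    "mean": res.mean, "t": res.t, "p": res.p,
                    "degenerate": res.degenerate})
        io.write_table(pd.DataFrame(onesample_rows),
                       outdir / "onesample_tests.tsv")
        written["onesample"] = len(onesample_rows)

        anova_rows, tukey_rows = [], []
        for metric, sub in tidy.groupby("metric", sort=True):
            if sub["group"].nunique() < 2 or sub["day"].nunique() < 2:
                continue
            table = stats.factorial_anova(sub, "value", ["group", "day"])
            table.insert(0, "metric", metric)
            anova_rows.append(table)
            group_p = table.loc[table["term"] == "group", "p"]
            if len(group_p) and float(group_p.iloc[0]) < cfg.alpha:
                means = sub.groupby(["group", "animal"])["value"].mean()
                labels = sorted(means.index.get_level_values(0).unique())
                pairs = stats.tukey_hsd(
                    *[means[g].to_numpy() for g in labels], labels=labels)
                pairs.insert(0, "metric", metric)
                tukey_rows.append(pairs)
        if anova_rows:
            io.write_table(pd.concat(anova_rows, ignore_index=True),
                           outdir / "anova.tsv")
        if tukey_rows:
            io.write_table(pd.concat(tukey_rows, ignore_index=True),
                           outdir / "tukey.tsv")

    per_trial = _maybe_read(results / "gait_metrics.tsv")
    if per_trial is not None:
        accepted = per_trial[per_trial["accepted"]
                             & (per_trial["group"] != "")]
        ancova_rows = []
        for metric in ("stride_length_cm", "step_width_cm"):
            sub = accepted.rename(columns={metric: "value",
                                           "velocity_cm_s": "velocity"})
            if sub["group"].nunique() < 2 or sub["day"].nunique() < 2:
                continue
            res = stats.ancova_velocity(sub)
            table = res.anova.copy()
            table.insert(0, "metric", metric)
            table["velocity_slope"] = res.velocity_slope
            ancova_rows.append(table)
        if ancova_rows:
            io.write_table(pd.concat(ancova_rows, ignore_index=True),
                           outdir / "ancova.tsv")

    if grf_features is not None:
        anova_rows = []
        operated = grf_features[grf_features["limb"] == OPERATED_LIMB]
        for feature in GRF_FEATURES_TESTED:
            sub = operated.rename(columns={feature: "value"})
            if sub["group"].nunique() < 2 or sub["day"].nunique() < 2:
                continue
            table = stats.factorial_anova(sub, "value", ["group", "day"])
            table.insert(0, "metric", f"grf_{feature}")
            anova_rows.append(table)
        if anova_rows:
            io.write_table(pd.concat(anova_rows, ignore_index=True),
                           outdir / "grf_anova.tsv")

    if thresholds is not None:
        paired = stats.paired_limb_tests(
            thresholds[thresholds["group"] == "operated"],
            value="threshold_g")
        if len(paired):
            paired.insert(0, "metric", "paw_withdrawal_threshold_g")
            io.write_table(paired, outdir / "paired_tests.tsv")

    if endpoints is None:
        log.warning("no endpoints table: correlation step skipped")
        written["correlations"] = 0
    else:
        _endpoint_stats(cfg, endpoints, gait, thresholds, grf_features,
                        weight, outdir)
        written["correlations"] = 1

    summary = {"tables": sorted(p.name for p in outdir.glob("*.tsv"))}
    (outdir / "stats_summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1) + "\n")
    return written


def _endpoint_stats(cfg: RunConfig, endpoints: pd.DataFrame,
                    gait, thresholds, grf_features, weight,
                    outdir: Path) -> None:
    wide = endpoints.pivot_table(index=["animal", "group"],
                                 columns="measure",
                                 values="value").reset_index()
    test_rows = []
    if "oarsi_grade" in wide.columns and wide["group"].nunique() >= 2:
        groups = [g["oarsi_grade"].dropna().to_numpy()
                  for _, g in wide.groupby("group", sort=True)]
        h, p = stats.kruskal_wallis(*groups)
        test_rows.append({"measure": "oarsi_grade",
                          "test": "kruskal_wallis", "statistic": h, "p": p})
    for measure in ("lesion_size_pct", "lesion_surface_pct",
                    "lesion_depth_pct"):
        if measure not in wide.columns or wide["group"].nunique() < 2:
            continue
        sub = wide[["group", measure]].rename(columns={measure: "value"})
        table = stats.factorial_anova(sub, "value", ["group"])
        row = table[table["term"] == "group"].iloc[0]
        test_rows.append({"measure": measure, "test": "anova_group",
                          "statistic": float(row["F"]),
                          "p": float(row["p"])})
    if test_rows:
        io.write_table(pd.DataFrame(test_rows),
                       outdir / "endpoint_tests.tsv")

    # endpoint (final-day) behaviors, one value per animal
    frames = []
    if gait is not None:
        final = gait[gait["day"] == gait["day"].max()]
        frames.append(final.set_index("animal")[
            ["symmetry", "stance_time_balance_pct"]])
    if thresholds is not None:
        final = thresholds[(thresholds["day"] == thresholds["day"].max())
                           & (thresholds["limb"] == OPERATED_LIMB)]
        frames.append(final.set_index("animal")[["threshold_g"]].rename(
            columns={"threshold_g": "paw_withdrawal_threshold_g"}))
    if weight is not None:
        final = weight[weight["day"] == weight["day"].max()]
        frames.append(final.set_index("animal")[
            ["weight_distribution_pct"]])
    if grf_features is not None:
        final = grf_features[
            (grf_features["day"] == grf_features["day"].max())
            & (grf_features["limb"] == OPERATED_LIMB)]
        frames.append(final.groupby("animal")[
            list(GRF_FEATURES_TESTED)].mean())
    behaviors = pd.concat(frames, axis=1) if frames else pd.DataFrame()
    if "serum_il6_pg_ml" in wide.columns:
        il6 = wide.set_index("animal")["serum_il6_pg_ml"]
        behaviors["log10_serum_il6"] = np.log10(il6)

    lesion_cols = [c for c in ("oarsi_grade", "lesion_size_pct",
                               "lesion_surface_pct", "lesion_depth_pct")
                   if c in wide.columns]
    if len(behaviors.columns) and lesion_cols:
        merged = behaviors.join(wide.set_index("animal")[lesion_cols],
                                how="inner")
        table = stats.correlation_table(
            merged, behaviors=list(behaviors.columns),
            lesions=lesion_cols, adjust=cfg.p_adjust)
        io.write_table(table, outdir / "correlations.tsv")


def _maybe_read(path: Path) -> pd.DataFrame | None:
    return io.read_table(path) if path.exists() else None


def write_report(stats_dir: str | Path, path: str | Path,
                 alpha: float = 0.05) -> str:
    """Condense the stats tables into a plain-text report."""
    stats_dir = Path(stats_dir)
    lines = ["Study report", "============", ""]
    for name in ("onesample_tests.tsv", "anova.tsv", "grf_anova.tsv",
                 "endpoint_tests.tsv", "correlations.tsv"):
        table_path = stats_dir / name
        if not table_path.exists():
            continue
        table = io.read_table(table_path)
        lines.append(f"{name} ({len(table)} rows)")
        pcol = "p"
        if pcol in table.columns:
            hits = table[table[pcol] < alpha]
            lines.append(f"  {len(hits)} results with p < {alpha}")
            for _, row in hits.iterrows():
                label = " ".join(str(row[c]) for c in table.columns[:3])
                lines.append(f"    {label}: p = {row[pcol]:.4g}")
        lines.append("")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
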