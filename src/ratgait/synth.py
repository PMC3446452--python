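"""Synthetic study generator with known ground truth.

Every downstream stage of the package (spatiotemporal gait metrics, GRF
feature extraction, video velocity tracking, the behavioral assays, and the
statistics layer) is exercised against data produced here, where the
generating parameters are known exactly, so each analysis has a
parameter-recovery test surface.

The generators emulate the conditions of a rat knee-destabilization study:
footfall sequences with configurable duty-factor imbalance and strike-phase
offset (the asymmetries of interest are shifts of 1-3% of stride time),
parametric three-axis ground-reaction-force curves whose nine shape
descriptors have closed forms, constant-velocity blob motion on grayscale
video, psychometric von Frey responders played against the up-down
staircase, and a three-group cohort (naive n=4, sham n=6, operated n=6 at
days 9, 16, 23) with operated-limb deficits and a lesion endpoint generated
as a linear function of the injected deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import assays
from .exceptions import ParameterError
from .grf import GRFFeatures, GRFRecording
from .video import FrameStack

# ---------------------------------------------------------------------------
# footfall sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitParams:
    """Generating parameters for one footfall sequence.

    ``symmetry`` is the phase of right-hindlimb strikes within the
    left-strike cycle (0.5 = evenly alternating); ``duty_left/right`` are
    stance fractions of stride time.  Defaults are representative of a
    healthy walking rat (velocity ~38 cm/s, stride frequency ~2.65 Hz).
    """

    velocity_cm_s: float = 38.2
    stride_frequency_hz: float = 2.65
    duty_left: float = 0.6
    duty_right: float = 0.6
    symmetry: float = 0.5
    step_width_cm: float = 3.72
    n_cycles: int = 4
    timing_noise_sd_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.duty_left < 1 or not 0 < self.duty_right < 1:
            raise ParameterError("duty factors must lie in (0, 1)")
        if not 0 < self.symmetry < 1:
            raise ParameterError("symmetry must lie in (0, 1)")
        if self.n_cycles < 2:
            raise ParameterError("need at least 2 gait cycles")
        if self.velocity_cm_s <= 0 or self.stride_frequency_hz <= 0:
            raise ParameterError("velocity and stride frequency must be "
                                 "positive")
        if self.step_width_cm < 0 or self.timing_noise_sd_s < 0:
            raise ParameterError("step width and timing noise must be "
                                 "non-negative")

    @property
    def stride_time_s(self) -> float:
        return 1.0 / self.stride_frequency_hz

    @property
    def stride_length_cm(self) -> float:
        return self.velocity_cm_s / self.stride_frequency_hz


def gen_footfall_sequence(params: GaitParams,
                          trial_id: str = "trial") -> pd.DataFrame:
    """Generate a footfall-event table with known spatiotemporal truth.

    Left-hindlimb strikes fall at multiples of the stride time; right
    strikes are offset by ``symmetry`` x stride time; toe-offs follow each
    strike by ``duty`` x stride time.  Paw x positions advance by one stride
    length per stride, y positions are split symmetrically by the step
    width.  Gaussian timing noise is added per event, clipped to preserve
    the per-limb event ordering.  With zero noise every downstream
    spatiotemporal metric equals its generating parameter exactly.
    """
    T = params.stride_time_s
    L = params.stride_length_cm
    rows = []
    # one extra left strike closes the final cycle
    for k in range(params.n_cycles + 1):
        rows.append((trial_id, "LH", "strike", k * T, k * L,
                     +params.step_width_cm / 2))
        rows.append((trial_id, "LH", "off", (k + params.duty_left) * T,
                     k * L, +params.step_width_cm / 2))
    for k in range(params.n_cycles):
        t = (k + params.symmetry) * T
        rows.append((trial_id, "RH", "strike", t, t * params.velocity_cm_s,
                     -params.step_width_cm / 2))
        rows.append((trial_id, "RH", "off",
                     (k + params.symmetry + params.duty_right) * T,
                     t * params.velocity_cm_s, -params.step_width_cm / 2))
    events = pd.DataFrame(
        rows, columns=["trial_id", "limb", "event", "time_s", "x_cm", "y_cm"])

    if params.timing_noise_sd_s > 0:
        rng = np.random.default_rng(params.seed)
        for limb in ("LH", "RH"):
            idx = events.index[events["limb"] == limb]
            order = events.loc[idx, "time_s"].argsort(kind="mergesort")
            idx = idx[order]
            t = events.loc[idx, "time_s"].to_numpy()
            noise = rng.normal(0.0, params.timing_noise_sd_s, size=t.size)
            gaps = np.diff(t)
            lo = np.concatenate(([np.inf], 0.49 * gaps))
            hi = np.concatenate((0.49 * gaps, [np.inf]))
            events.loc[idx, "time_s"] = t + np.clip(noise, -lo, hi)
    return events.sort_values(["time_s", "limb"],
                              kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ground reaction force curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GRFShapeParams:
    """Parametric shape of one single-contact force recording.

    Peaks are body-weight fractions.  The vertical channel is a half-sine
    over stance; the fore-aft channel is two independently scaled sine
    lobes (braking first, propulsive second); the mediolateral channel is
    two half-sine bumps centered at 25% and 75% of stance.
    """

    peak_vertical: float = 0.6
    peak_braking: float = 0.1
    peak_propulsive: float = 0.1
    peak_ml_first: float = 0.05
    peak_ml_second: float = 0.05
    stance_time_s: float = 0.37
    body_weight_N: float = 2.45
    sample_rate_hz: float = 200.0
    noise_sd_N: float = 0.0
    pad_s: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        peaks = (self.peak_vertical, self.peak_braking, self.peak_propulsive,
                 self.peak_ml_first, self.peak_ml_second)
        if any(p < 0 for p in peaks):
            raise ParameterError("peaks must be non-negative")
        if self.stance_time_s <= 0:
            raise ParameterError("stance_time_s must be positive")
        if self.sample_rate_hz < 200:
            raise ParameterError("sample_rate_hz below the 200 Hz plate rate")
        if self.body_weight_N <= 0:
            raise ParameterError("body_weight_N must be positive")
        if self.stance_time_s * self.sample_rate_hz < 10:
            raise ParameterError("sample rate too low to resolve the stance "
                                 "(fewer than 10 samples)")


def grf_truth_features(shape: GRFShapeParams) -> GRFFeatures:
    """Closed-form dimensionless descriptors of the parametric curves.

    A half-sine of peak p integrates to 2p/pi over its full support and to
    p/pi over a half-period lobe, so the analytic impulses are
    ``vertical = 2*peak_vertical/pi``, ``braking = peak_braking/pi``,
    ``propulsive = peak_propulsive/pi``, and
    ``mediolateral = (p1 + p2)/pi``.
    """
    return GRFFeatures(
        peak_braking=shape.peak_braking,
        peak_propulsive=shape.peak_propulsive,
        braking_impulse=shape.peak_braking / math.pi,
        propulsive_impulse=shape.peak_propulsive / math.pi,
        peak_ml_first=shape.peak_ml_first,
        peak_ml_second=shape.peak_ml_second,
        ml_impulse=(shape.peak_ml_first + shape.peak_ml_second) / math.pi,
        peak_vertical=shape.peak_vertical,
        vertical_impulse=2.0 * shape.peak_vertical / math.pi)


def gen_grf_curve(shape: GRFShapeParams,
                  limb: str = "RH") -> tuple[GRFRecording, GRFFeatures]:
    """Generate a force recording plus its analytic feature truth.

    The stance starts exactly on a sample, with ``pad_s`` of zero force
    before and after, and spans ``round(stance_time * sample_rate)`` sample
    intervals.  Gaussian sensor noise (``noise_sd_N``) is added to every
    sample of all three channels.
    """
    fs = shape.sample_rate_hz
    bw = shape.body_weight_N
    n_pad = int(round(shape.pad_s * fs))
    n_stance = int(round(shape.stance_time_s * fs))
    n_total = n_stance + 2 * n_pad + 1
    t = np.arange(n_total) / fs

    tau = np.full(n_total, np.nan)
    in_stance = slice(n_pad, n_pad + n_stance + 1)
    tau[in_stance] = (t[in_stance] - t[n_pad]) / shape.stance_time_s

    fz = np.zeros(n_total)
    fx = np.zeros(n_total)
    fy = np.zeros(n_total)
    ts = tau[in_stance]
    fz[in_stance] = shape.peak_vertical * bw * np.sin(np.pi * ts)
    first = ts <= 0.5
    fx_st = np.where(first,
                     -shape.peak_braking * bw * np.sin(2 * np.pi * ts),
                     -shape.peak_propulsive * bw * np.sin(2 * np.pi * ts))
    fx[in_stance] = fx_st
    fy_st = np.where(first,
                     shape.peak_ml_first * bw * np.sin(2 * np.pi * ts),
                     shape.peak_ml_second * bw * np.sin(2 * np.pi * (ts - 0.5)))
    fy[in_stance] = fy_st

    if shape.noise_sd_N > 0:
        rng = np.random.default_rng(shape.seed)
        fx = fx + rng.normal(0, shape.noise_sd_N, n_total)
        fy = fy + rng.normal(0, shape.noise_sd_N, n_total)
        fz = fz + rng.normal(0, shape.noise_sd_N, n_total)

    data = pd.DataFrame({"time_s": t, "fx_N": fx, "fy_N": fy, "fz_N": fz})
    meta = {"stance_start_s": float(t[n_pad]),
            "stance_time_s": shape.stance_time_s,
            "n_stance_samples": n_stance,
            "synthetic": True}
    recording = GRFRecording(data=data, body_weight_N=bw, sample_rate_hz=fs,
                             limb=limb, meta=meta)
    return recording, grf_truth_features(shape)


# ---------------------------------------------------------------------------
# video
# ---------------------------------------------------------------------------


def gen_video(velocity_cm_s: float = 38.2, frame_rate_hz: float = 200.0,
              n_frames: int = 50, blob_axes_cm: tuple[float, float] = (3.0, 1.5),
              calibration_cm_per_px: float = 0.1,
              frame_shape: tuple[int, int] = (64, 256),
              background_intensity: float = 40.0,
              blob_intensity: float = 200.0,
              noise_sd: float = 0.0, seed: int = 0) -> tuple[FrameStack, float]:
    """Grayscale frames of a bright ellipse translating at constant velocity.

    The ellipse (semi-axes ``blob_axes_cm``, along x and y) starts near the
    left edge at mid-height and advances ``velocity / (calibration *
    frame_rate)`` pixels per frame along +x.  Returns the stack (with a
    separate clean background frame) and the configured truth velocity.
    Raises if the blob would leave the frame, naming the maximum feasible
    frame count.
    """
    if calibration_cm_per_px <= 0:
        raise ParameterError("calibration must be positive")
    if frame_rate_hz <= 0:
        raise ParameterError("frame rate must be positive")
    if n_frames < 1:
        raise ParameterError("need at least one frame")
    h, w = frame_shape
    ax_px = blob_axes_cm[0] / calibration_cm_per_px
    ay_px = blob_axes_cm[1] / calibration_cm_per_px
    step_px = velocity_cm_s / (calibration_cm_per_px * frame_rate_hz)
    x0 = ax_px + 2.0
    y0 = h / 2.0
    if step_px > 0:
        max_feasible = int((w - 1 - ax_px - 2.0 - x0) / step_px) + 1
        if n_frames > max_feasible:
            raise ParameterError(
                f"blob leaves the {w}-px frame after {max_feasible} frames; "
                f"requested {n_frames}")
    if ay_px + 2.0 > y0 or 2 * ax_px + 4.0 > w:
        raise ParameterError("blob does not fit inside the frame")

    background = np.full((h, w), float(background_intensity))
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w))
    for i in range(n_frames):
        cx = x0 + i * step_px
        inside = ((xx - cx) / ax_px) ** 2 + ((yy - y0) / ay_px) ** 2 <= 1.0
        frame = np.where(inside, float(blob_intensity), background)
        if noise_sd > 0:
            frame = frame + rng.normal(0, noise_sd, size=frame.shape)
        frames[i] = frame
    stack = FrameStack(frames=frames, background=background,
                       frame_rate_hz=frame_rate_hz,
                       calibration_cm_per_px=calibration_cm_per_px,
                       meta={"synthetic": True, "truth_velocity_cm_s":
                             float(velocity_cm_s)})
    return stack, float(velocity_cm_s)


# ---------------------------------------------------------------------------
# von Frey responders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricObserver:
    """Synthetic responder for the up-down staircase.

    Withdrawal probability is a logistic function of log10 force centered
    on ``true_threshold_g`` with steepness ``slope`` (``math.inf`` gives a
    deterministic step: withdraw iff force >= threshold).
    """

    true_threshold_g: float
    slope: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_threshold_g <= 0:
            raise ParameterError("true_threshold_g must be positive")
        if self.slope < 0:
            raise ParameterError("slope must be non-negative")

    def withdrawal_probability(self, force_g: float) -> float:
        x = math.log10(force_g) - math.log10(self.true_threshold_g)
        if math.isinf(self.slope):
            return 1.0 if x >= 0 else 0.0
        return 1.0 / (1.0 + math.exp(-self.slope * x))


def gen_vonfrey_responses(observer: PsychometricObserver,
                          filament_set_g: Sequence[float] =
                          assays.DEFAULT_FILAMENTS_G,
                          **protocol_kwargs) -> assays.VonFreySession:
    """Play the up-down protocol against a psychometric observer.

    Returns the ordered (filament, response) session; responses are
    Bernoulli draws from the observer's psychometric function (seeded,
    reproducible).
    """
    rng = np.random.default_rng(observer.seed)

    def respond(force_g: float) -> bool:
        p = observer.withdrawal_probability(force_g)
        if p in (0.0, 1.0):
            return bool(p)
        return bool(rng.random() < p)

    return assays.run_updown_protocol(respond, filament_set_g,
                                      **protocol_kwargs)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricEffect:
    """Normal model for one behavioral metric: baseline mean/SD plus the
    shift injected into the operated group (scaled by each animal's
    deficit)."""

    baseline: float
    sd: float
    operated_shift: float = 0.0


#: behavioral metrics emulating the study conditions: symmetric/balanced
#: baselines with operated-limb deficits in the directions seen after
#: unilateral knee destabilization.
DEFAULT_METRICS: Mapping[str, MetricEffect] = {
    "symmetry": MetricEffect(0.5, 0.01, 0.02),
    "stance_time_balance_pct": MetricEffect(0.0, 1.0, 2.0),
    "weight_distribution_pct": MetricEffect(50.0, 2.0, -1.5),
    "paw_withdrawal_threshold_g": MetricEffect(12.0, 4.0, -6.0),
    "peak_vertical": MetricEffect(0.6, 0.05, -0.06),
    "vertical_impulse": MetricEffect(0.38, 0.04, -0.05),
    "peak_propulsive": MetricEffect(0.10, 0.02, -0.03),
    "propulsive_impulse": MetricEffect(0.032, 0.007, -0.008),
}

#: endpoint lesion measures: intercept, slope on the injected deficit, and
#: noise SD (percent scales)
DEFAULT_LESION_MODELS: Mapping[str, tuple[float, float, float]] = {
    "lesion_size_pct": (2.0, 15.0, 3.0),
    "lesion_surface_pct": (3.0, 30.0, 6.0),
    "lesion_depth_pct": (5.0, 70.0, 14.0),
}

GROUPS = ("naive", "sham", "operated")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic three-group study.

    Defaults mirror the emulated study: naive n=4, sham n=6, operated n=6,
    behavioral timepoints at days 9/16/23, operated-limb deficits scaled by
    a per-animal severity ("deficit") that also drives the lesion endpoint
    linearly, so the correlation stage has known ground truth.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"naive": 4, "sham": 6, "operated": 6})
    timepoints: tuple[int, ...] = (9, 16, 23)
    metrics: Mapping[str, MetricEffect] = field(
        default_factory=lambda: dict(DEFAULT_METRICS))
    lesion_models: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LESION_MODELS))
    deficit_mean: float = 1.0
    deficit_sd: float = 0.25
    lesion_noise_scale: float = 1.0
    oarsi_base: float = 0.5
    oarsi_slope: float = 3.5
    oarsi_sd: float = 0.7
    il6_log_base: float = 1.3
    il6_log_slope: float = 0.4
    il6_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for group, n in self.n_per_group.items():
            if group not in GROUPS:
                raise ParameterError(f"unknown group {group!r}")
            if n < 2:
                raise ParameterError("need at least 2 animals per group")
        if len(self.timepoints) < 1:
            raise ParameterError("need at least one timepoint")
        for name, eff in self.metrics.items():
            if not all(np.isfinite([eff.baseline, eff.sd,
                                    eff.operated_shift])):
                raise ParameterError(f"non-finite effect for {name!r}")

    @classmethod
    def null(cls, seed: int = 0) -> "CohortSpec":
        """All group effects zero: every metric is pure noise around its
        baseline and the lesion endpoint is independent of behavior."""
        metrics = {name: MetricEffect(eff.baseline, eff.sd, 0.0)
                   for name, eff in DEFAULT_METRICS.items()}
        return cls(metrics=metrics, deficit_mean=0.0, deficit_sd=0.0,
                   oarsi_slope=0.0, il6_log_slope=0.0, seed=seed)


@dataclass(frozen=True)
class Cohort:
    """Generated cohort: tidy behavior table, endpoint table, ground truth."""

    behavior: pd.DataFrame  # animal, group, day, metric, value
    endpoints: pd.DataFrame  # animal, group, measure, value
    truth: dict


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort.

    Each animal receives a deficit severity ``d`` (0 for naive/sham,
    ``N(1, deficit_sd)`` for operated).  Behavioral values are
    ``baseline + operated_shift * d + N(0, sd)`` per animal, day, and
    metric; each lesion measure is ``b0 + b1 * d + noise`` so a downstream
    regression of lesion on deficit recovers ``b1`` (exactly when
    ``lesion_noise_scale = 0``).
    """
    rng = np.random.default_rng(spec.seed)
    animals = []
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            animals.append((f"{group[0].upper()}{i + 1:02d}", group))

    deficits = {}
    for animal, group in animals:
        deficits[animal] = float(rng.normal(spec.deficit_mean,
                                            spec.deficit_sd)) \
            if group == "operated" else 0.0

    behavior_rows = []
    for animal, group in animals:
        d = deficits[animal]
        for day in spec.timepoints:
            for name, eff in spec.metrics.items():
                value = eff.baseline + eff.operated_shift * d \
                    + rng.normal(0.0, eff.sd)
                behavior_rows.append((animal, group, day, name, value))
    behavior = pd.DataFrame(
        behavior_rows, columns=["animal", "group", "day", "metric", "value"])

    endpoint_rows = []
    for animal, group in animals:
        d = deficits[animal]
        endpoint_rows.append((animal, group, "injected_deficit", d))
        for name, (b0, b1, noise_sd) in spec.lesion_models.items():
            value = b0 + b1 * d + rng.normal(
                0.0, noise_sd * spec.lesion_noise_scale)
            endpoint_rows.append((animal, group, name, value))
        grade = np.clip(round(spec.oarsi_base + spec.oarsi_slope * d
                              + rng.normal(0.0, spec.oarsi_sd)), 0, 6)
        endpoint_rows.append((animal, group, "oarsi_grade", float(grade)))
        il6 = 10.0 ** (spec.il6_log_base + spec.il6_log_slope * d
                       + rng.normal(0.0, spec.il6_log_sd))
        endpoint_rows.append((animal, group, "serum_il6_pg_ml", il6))
    endpoints = pd.DataFrame(
        endpoint_rows, columns=["animal", "group", "measure", "value"])

    truth = {"deficits": deficits,
             "lesion_models": {k: tuple(v)
                               for k, v in spec.lesion_models.items()},
             "metrics": {k: (v.baseline, v.sd, v.operated_shift)
                         for k, v in spec.metrics.items()},
             "seed": spec.seed}
    return Cohort(behavior=behavior, endpoints=endpoints, truth=truth)
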