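"""Spatiotemporal gait metrics from timed, positioned footfall events.

The substrate is a table of hindlimb foot-strike and toe-off events (limb,
event kind, time, paw position).  From it this module computes, per trial:

* stride length — distance between successive same-limb strikes;
* step width — perpendicular left/right strike separation about the
  direction of travel;
* duty factor (percentage stance time) — stance time over stride time;
* stance-time balance — left minus right hindlimb duty factor, in
  percentage points (zero for a balanced gait);
* gait symmetry — phase of the right-hindlimb strike within the left
  hindlimb's stride (0.5 for an evenly alternating gait);
* stride frequency and per-cycle velocity.

Trials qualify for analysis when they contain two to five complete gait
cycles with less than 15% change in cycle velocity; accepted trials are
averaged to one record per animal per timepoint, the unit used by the
statistics layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError, ParameterError

MIN_CYCLES = 2
MAX_CYCLES = 5
MAX_VELOCITY_DRIFT = 0.15


@dataclass(frozen=True)
class SpatiotemporalMetrics:
    """Per-trial (or per-animal) spatiotemporal gait summary."""

    stride_length_cm: float
    step_width_cm: float
    duty_lh_pct: float
    duty_rh_pct: float
    stance_time_balance_pct: float
    symmetry: float
    stride_frequency_hz: float
    velocity_cm_s: float
    n_cycles: int

    FIELDS = ("stride_length_cm", "step_width_cm", "duty_lh_pct",
              "duty_rh_pct", "stance_time_balance_pct", "symmetry",
              "stride_frequency_hz", "velocity_cm_s", "n_cycles")

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


@dataclass(frozen=True)
class TrialValidation:
    accepted: bool
    reasons: tuple[str, ...]


def _limb_events(events: pd.DataFrame, limb: str) -> pd.DataFrame:
    # toe-off sorts before a strike at the same instant: a stance that ends
    # exactly when the next begins belongs to the preceding stride
    sub = events[events["limb"] == limb].copy()
    sub["_rank"] = (sub["event"] == "strike").astype(int)
    sub = sub.sort_values(["time_s", "_rank"],
                          kind="mergesort").drop(columns="_rank")
    sub = sub.reset_index(drop=True)
    kinds = sub["event"].to_list()
    for i in range(1, len(kinds)):
        if kinds[i] == kinds[i - 1]:
            raise FormatError(
                f"{limb}: events do not alternate strike/off at index {i}")
    return sub


def _strikes(events: pd.DataFrame, limb: str) -> pd.DataFrame:
    sub = _limb_events(events, limb)
    return sub[sub["event"] == "strike"].reset_index(drop=True)


def duty_factor(events: pd.DataFrame, limb: str) -> float:
    """Percentage stance time: stance / stride, averaged over cycles.

    For each stride (strike to next same-limb strike) containing a complete
    stance (strike to toe-off), the ratio is taken in percent and ratios are
    averaged over the available cycles.
    """
    sub = _limb_events(events, limb)
    strikes = sub[sub["event"] == "strike"]["time_s"].to_numpy()
    offs = sub[sub["event"] == "off"]["time_s"].to_numpy()
    if len(strikes) < 2:
        raise InsufficientDataError(
            f"{limb}: need at least 2 strikes for a stride, "
            f"got {len(strikes)}")
    ratios = []
    for i in range(len(strikes) - 1):
        stride = strikes[i + 1] - strikes[i]
        within = offs[(offs > strikes[i]) & (offs <= strikes[i + 1])]
        if within.size == 0:
            continue
        stance = within[0] - strikes[i]
        ratios.append(100.0 * stance / stride)
    if not ratios:
        raise InsufficientDataError(
            f"{limb}: no complete stance inside a complete stride")
    mean = float(np.mean(ratios))
    if any(r >= 100.0 - 1e-9 for r in ratios):
        warnings.warn(f"{limb}: degenerate duty factor (stance spans the "
                      "full stride)", stacklevel=2)
    return mean


def stance_time_balance(duty_lh_pct: float, duty_rh_pct: float) -> float:
    """Left minus right duty factor, percentage points (positive = more
    stance on the left)."""
    return float(duty_lh_pct - duty_rh_pct)


def gait_symmetry(events: pd.DataFrame, reference_limb: str = "LH") -> float:
    """Phase of the contralateral strike within the reference limb's stride.

    For each reference-limb stride, the first contralateral strike inside it
    contributes ``(t_contra - t_ref) / (t_ref_next - t_ref)``; values are
    averaged over cycles.  0.5 marks an evenly alternating (symmetric) gait.
    Cycles with no contralateral strike are skipped; if every cycle is
    skipped an insufficient-data error is raised.
    """
    other = {"LH": "RH", "RH": "LH"}.get(reference_limb)
    if other is None:
        raise ParameterError(f"unknown reference limb {reference_limb!r}")
    ref = _strikes(events, reference_limb)["time_s"].to_numpy()
    contra = _strikes(events, other)["time_s"].to_numpy()
    if len(ref) < 2:
        raise InsufficientDataError(
            f"{reference_limb}: need at least 2 strikes, got {len(ref)}")
    phases = []
    for i in range(len(ref) - 1):
        inside = contra[(contra >= ref[i]) & (contra < ref[i + 1])]
        if inside.size == 0:
            continue
        phases.append((inside[0] - ref[i]) / (ref[i + 1] - ref[i]))
    if not phases:
        raise InsufficientDataError(
            f"no {other} strike falls inside any {reference_limb} stride")
    return float(np.mean(phases))


def stride_length(events: pd.DataFrame, limb: str) -> float:
    """Mean Euclidean distance between successive same-limb strikes, cm."""
    strikes = _strikes(events, limb)
    if len(strikes) < 2:
        raise InsufficientDataError(
            f"{limb}: need at least 2 strikes, got {len(strikes)}")
    xy = strikes[["x_cm", "y_cm"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise FormatError(f"{limb}: missing strike positions")
    lengths = np.hypot(*np.diff(xy, axis=0).T)
    mean = float(np.mean(lengths))
    if mean == 0.0:
        warnings.warn(f"{limb}: degenerate zero stride length", stacklevel=2)
    return mean


def travel_direction(events: pd.DataFrame) -> np.ndarray:
    """Unit direction of travel from first/last strike centroid positions.

    When a centroid track is available its principal displacement axis
    should be supplied to :func:`step_width` directly; this fallback uses
    the line through the first and last strike positions of the trial.
    """
    strikes = events[events["event"] == "strike"].sort_values("time_s")
    if len(strikes) < 2:
        raise InsufficientDataError("need at least 2 strikes for a direction")
    first = strikes[["x_cm", "y_cm"]].iloc[0].to_numpy(dtype=float)
    last = strikes[["x_cm", "y_cm"]].iloc[-1].to_numpy(dtype=float)
    disp = last - first
    norm = np.hypot(*disp)
    if norm == 0.0:
        raise ParameterError(
            "zero net displacement: direction of travel undefined")
    return disp / norm


def step_width(events: pd.DataFrame,
               direction: np.ndarray | None = None) -> float:
    """Mean perpendicular LH/RH strike separation about the travel axis, cm."""
    if direction is None:
        direction = travel_direction(events)
    direction = np.asarray(direction, dtype=float)
    norm = np.hypot(*direction)
    if norm == 0.0:
        raise ParameterError("direction of travel undefined (zero vector)")
    normal = np.array([-direction[1], direction[0]]) / norm
    lh = _strikes(events, "LH")
    rh = _strikes(events, "RH")
    if len(lh) == 0 or len(rh) == 0:
        raise InsufficientDataError("need at least one strike on each limb")
    lh_offset = lh[["x_cm", "y_cm"]].to_numpy(dtype=float) @ normal
    rh_offset = rh[["x_cm", "y_cm"]].to_numpy(dtype=float) @ normal
    return float(abs(lh_offset.mean() - rh_offset.mean()))


def stride_frequency(events: pd.DataFrame, limb: str = "LH") -> float:
    """Strides per second from mean same-limb strike interval."""
    strikes = _strikes(events, limb)["time_s"].to_numpy()
    if len(strikes) < 2:
        raise InsufficientDataError(
            f"{limb}: need at least 2 strikes, got {len(strikes)}")
    return float(1.0 / np.mean(np.diff(strikes)))


def cycle_velocities(events: pd.DataFrame, limb: str = "LH") -> np.ndarray:
    """Per-gait-cycle velocity: same-limb strike displacement over interval."""
    strikes = _strikes(events, limb)
    if len(strikes) < 2:
        raise InsufficientDataError(
            f"{limb}: need at least 2 strikes, got {len(strikes)}")
    xy = strikes[["x_cm", "y_cm"]].to_numpy(dtype=float)
    t = strikes["time_s"].to_numpy()
    distances = np.hypot(*np.diff(xy, axis=0).T)
    return distances / np.diff(t)


def validate_trial(velocities: np.ndarray, n_cycles: int,
                   min_cycles: int = MIN_CYCLES,
                   max_cycles: int = MAX_CYCLES,
                   max_drift: float = MAX_VELOCITY_DRIFT) -> TrialValidation:
    """Accept a trial iff it has 2-5 complete cycles and <15% velocity change.

    Velocity change is ``(max - min) / mean`` of the per-cycle velocities,
    compared strictly against the bound.  Rejections carry machine-readable
    reason codes: ``too_few_cycles``, ``too_many_cycles``, ``velocity_drift``.
    """
    reasons = []
    if n_cycles < min_cycles:
        reasons.append("too_few_cycles")
    if n_cycles > max_cycles:
        reasons.append("too_many_cycles")
    velocities = np.asarray(velocities, dtype=float)
    if velocities.size > 0:
        drift = (velocities.max() - velocities.min()) / velocities.mean()
        if not drift < max_drift:
            reasons.append("velocity_drift")
    return TrialValidation(accepted=not reasons, reasons=tuple(reasons))


def trial_metrics(events: pd.DataFrame,
                  direction: np.ndarray | None = None,
                  reference_limb: str = "LH") -> SpatiotemporalMetrics:
    """All spatiotemporal metrics for one trial's event table."""
    duty_lh = duty_factor(events, "LH")
    duty_rh = duty_factor(events, "RH")
    vels = cycle_velocities(events, reference_limb)
    return SpatiotemporalMetrics(
        stride_length_cm=stride_length(events, reference_limb),
        step_width_cm=step_width(events, direction),
        duty_lh_pct=duty_lh,
        duty_rh_pct=duty_rh,
        stance_time_balance_pct=stance_time_balance(duty_lh, duty_rh),
        symmetry=gait_symmetry(events, reference_limb),
        stride_frequency_hz=stride_frequency(events, reference_limb),
        velocity_cm_s=float(np.mean(vels)),
        n_cycles=len(vels))


def summarize_animal(trials: list[SpatiotemporalMetrics]) -> SpatiotemporalMetrics:
    """Unweighted mean of per-trial metrics: one record per animal-timepoint."""
    if not trials:
        raise InsufficientDataError("no accepted trials to summarize")
    means = {name: float(np.mean([getattr(t, name) for t in trials]))
             for name in SpatiotemporalMetrics.FIELDS}
    means["n_cycles"] = int(round(means["n_cycles"]))
    return SpatiotemporalMetrics(**means)
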