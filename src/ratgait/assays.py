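"""Behavioral assays: von Frey paw-withdrawal threshold and incapacitance-
meter weight distribution.

Tactile allodynia is quantified with the adaptive up-down staircase: after a
withdrawal the next-smaller filament is applied, after tolerance the
next-larger one, and testing continues for a fixed number of responses after
the first change of direction.  The 50% withdrawal threshold is the force at
which withdrawal and tolerance are equally likely; on the log10-force scale
the estimate takes the classical form ``x_f + k * delta`` (final filament
plus a pattern factor times the mean filament spacing).  Here ``k * delta``
is obtained by maximum likelihood under the same model the classical factor
tables were derived from: a cumulative-normal psychometric function on
log-force whose spread equals the filament spacing ``delta``.  Sequences
that never change direction are clamped to the bounds of the filament set.

Hindlimb weight distribution is the percentage of total hindlimb load
carried by the right limb, averaged over an animal's trials; 50% is the
balanced reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import InsufficientDataError, ParameterError, ProtocolError

#: standard log-spaced rodent filament kit, grams (~0.4-26 g)
DEFAULT_FILAMENTS_G = (0.4, 0.6, 1.0, 2.0, 4.0, 6.0, 8.0, 15.0, 26.0)

WITHDRAW = True
TOLERATE = False


@dataclass(frozen=True)
class VonFreySession:
    """One up-down staircase: ordered (filament, response) pairs.

    ``responses[i]`` is True for a paw withdrawal to ``filaments_applied[i]``.
    ``bounded`` records whether the staircase ran into an end of the
    filament set ("lower", "upper", or None).
    """

    filament_set_g: tuple[float, ...]
    filaments_applied: tuple[float, ...]
    responses: tuple[bool, ...]
    limb: str = ""
    animal: str = ""
    day: int | None = None
    bounded: str | None = None

    def __post_init__(self) -> None:
        _check_filament_set(self.filament_set_g)
        if len(self.filaments_applied) != len(self.responses):
            raise ParameterError("filaments and responses differ in length")
        if len(self.filaments_applied) == 0:
            raise ParameterError("empty session")


def _check_filament_set(filaments: Sequence[float]) -> None:
    arr = np.asarray(filaments, dtype=float)
    if arr.size < 2:
        raise ParameterError("filament set needs at least 2 filaments")
    if (arr <= 0).any():
        raise ParameterError("filament forces must be positive")
    if not (np.diff(arr) > 0).all():
        raise ParameterError("filament set must be sorted ascending")


def mean_log_spacing(filament_set_g: Sequence[float]) -> float:
    """Mean log10 spacing (delta) of the filament set."""
    logs = np.log10(np.asarray(filament_set_g, dtype=float))
    return float((logs[-1] - logs[0]) / (logs.size - 1))


def run_updown_protocol(respond: Callable[[float], bool],
                        filament_set_g: Sequence[float] = DEFAULT_FILAMENTS_G,
                        start_index: int | None = None,
                        n_after_change: int = 4,
                        max_trials: int = 50,
                        **session_kwargs) -> VonFreySession:
    """Play the up-down staircase against a responder callable.

    ``respond(force_g) -> bool`` is queried once per application.  The
    staircase starts at the middle filament, moves one step down after a
    withdrawal and one step up after tolerance, and stops once
    ``n_after_change`` responses have been recorded after the first change
    of direction.  Running off either end of the set terminates the session
    immediately with the corresponding ``bounded`` flag.
    """
    _check_filament_set(filament_set_g)
    filaments = tuple(float(f) for f in filament_set_g)
    idx = len(filaments) // 2 if start_index is None else start_index
    if not 0 <= idx < len(filaments):
        raise ParameterError(f"start_index {idx} outside the filament set")

    applied: list[float] = []
    responses: list[bool] = []
    bounded = None
    first_change_at: int | None = None
    for trial in range(max_trials):
        applied.append(filaments[idx])
        response = bool(respond(filaments[idx]))
        responses.append(response)
        if first_change_at is None and trial > 0 \
                and response != responses[trial - 1]:
            first_change_at = trial
        if first_change_at is not None \
                and trial - first_change_at >= n_after_change:
            break
        if response:
            if idx == 0:
                bounded = "lower"
                break
            idx -= 1
        else:
            if idx == len(filaments) - 1:
                bounded = "upper"
                break
            idx += 1
    return VonFreySession(filament_set_g=filaments,
                          filaments_applied=tuple(applied),
                          responses=tuple(responses),
                          bounded=bounded, **session_kwargs)


def validate_session(session: VonFreySession) -> None:
    """Check that a recorded session obeys the up-down rule.

    Each applied filament must be one set position below the previous one
    after a withdrawal and one above after tolerance (staying in place only
    when clamped at an end of the set).  Raises :class:`ProtocolError`
    naming the first offending trial.
    """
    filaments = np.asarray(session.filament_set_g)
    positions = []
    for i, f in enumerate(session.filaments_applied):
        matches = np.flatnonzero(np.isclose(filaments, f))
        if matches.size == 0:
            raise ProtocolError(
                f"trial {i}: filament {f} g is not in the set")
        positions.append(int(matches[0]))
    for i in range(1, len(positions)):
        step = positions[i] - positions[i - 1]
        expected = -1 if session.responses[i - 1] else +1
        at_bound = (positions[i - 1] == 0 and expected == -1) or \
                   (positions[i - 1] == len(filaments) - 1 and expected == +1)
        if step != expected and not (at_bound and step == 0):
            raise ProtocolError(
                f"trial {i}: applied {session.filaments_applied[i]} g after "
                f"{'withdrawal' if session.responses[i - 1] else 'tolerance'} "
                f"at {session.filaments_applied[i - 1]} g violates the "
                "up-down rule")


def updown_threshold(session: VonFreySession) -> float:
    """50% paw-withdrawal threshold in grams for one staircase session.

    Boundary sessions (every application withdrew / tolerated) return the
    lower / upper bound of the filament set.  Otherwise the threshold is the
    maximum-likelihood location of a cumulative-normal psychometric function
    on log10 force with spread fixed at the mean filament spacing, clamped
    to the bounds of the set — the likelihood construction underlying the
    classical up-down pattern-factor tables.
    """
    validate_session(session)
    responses = np.asarray(session.responses, dtype=bool)
    lo, hi = session.filament_set_g[0], session.filament_set_g[-1]
    if responses.all():
        return float(lo)
    if not responses.any():
        return float(hi)

    x = np.log10(np.asarray(session.filaments_applied, dtype=float))
    delta = mean_log_spacing(session.filament_set_g)

    def neg_loglik(mu: float) -> float:
        z = (x - mu) / delta
        # withdrawal probability increases with force
        return -float(np.sum(np.where(responses,
                                      stats.norm.logcdf(z),
                                      stats.norm.logcdf(-z))))

    lo_log, hi_log = np.log10(lo) - delta, np.log10(hi) + delta
    result = optimize.minimize_scalar(neg_loglik, bounds=(lo_log, hi_log),
                                      method="bounded",
                                      options={"xatol": 1e-8})
    mu = float(np.clip(result.x, np.log10(lo), np.log10(hi)))
    return float(10.0 ** mu)


def pattern_factor(session: VonFreySession) -> float:
    """The equivalent pattern factor k with threshold = 10^(x_f + k*delta)."""
    threshold = updown_threshold(session)
    x_f = np.log10(session.filaments_applied[-1])
    delta = mean_log_spacing(session.filament_set_g)
    return float((np.log10(threshold) - x_f) / delta)


@dataclass(frozen=True)
class IncapacitanceReading:
    """Left/right hindlimb loads (grams) over an animal's rearing trials."""

    left_g: tuple[float, ...]
    right_g: tuple[float, ...]
    animal: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        if len(self.left_g) != len(self.right_g):
            raise ParameterError("left and right trial counts differ")
        if len(self.left_g) == 0:
            raise InsufficientDataError("no incapacitance trials")
        left = np.asarray(self.left_g, dtype=float)
        right = np.asarray(self.right_g, dtype=float)
        if (left < 0).any() or (right < 0).any():
            raise ParameterError("weights must be non-negative")


def weight_distribution(reading: IncapacitanceReading) -> float:
    """Percentage of hindlimb load on the right limb, mean over trials.

    ``100 * right / (left + right)`` per trial; 50% is balanced.  Raises on
    a trial with zero total load.
    """
    left = np.asarray(reading.left_g, dtype=float)
    right = np.asarray(reading.right_g, dtype=float)
    total = left + right
    if (total <= 0).any():
        raise ParameterError("trial with zero total hindlimb load")
    return float(np.mean(100.0 * right / total))
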