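"""Force-plate dynamics: filtering, stance detection, normalization, and the
nine generalized ground-reaction-force (GRF) descriptors.

A single hindlimb contact on a small force plate produces three force
components sampled in time: fore-aft ``Fx`` (+ propulsive, - braking),
mediolateral ``Fy`` (+ toward the animal's midline), and vertical ``Fz``.
After low-pass filtering, the stance phase is located from the vertical
channel, forces are divided by body weight, and time is remapped to the
normalized stance coordinate tau in [0, 1].  On that dimensionless curve the
nine standard shape descriptors are extracted: peak braking/propulsive force
and their phase impulses, first/second mediolateral peaks and mediolateral
impulse, and peak vertical force and vertical impulse.  Impulses are
integrals over tau, so all nine descriptors are dimensionless and comparable
across animals of different weight and stance duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import (InsufficientDataError, NoContactError,
                         ParameterError)

N_GRID_POINTS = 101  # normalized stance grid resolution


@dataclass
class GRFRecording:
    """Sampled three-axis force-plate recording for one trial.

    Parameters
    ----------
    data : DataFrame with columns ``time_s, fx_N, fy_N, fz_N`` at uniform
        sampling.
    body_weight_N : animal body weight in newtons (> 0).
    sample_rate_hz : plate sampling rate.
    limb : limb label, e.g. ``"RH"``; informational.
    meta : free-form trial metadata.
    """

    data: pd.DataFrame
    body_weight_N: float
    sample_rate_hz: float
    limb: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_weight_N <= 0:
            raise ParameterError("body_weight_N must be positive")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class StanceWindow:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class NormalizedGRF:
    """Forces in body-weight units on the normalized stance grid."""

    tau: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    stance_time_s: float


@dataclass(frozen=True)
class GRFFeatures:
    """The nine dimensionless GRF descriptors.

    Peaks are magnitudes; impulses are magnitudes of the trapezoidal
    integral over normalized stance time (set ``impulse_units='bw_s'`` in
    :func:`extract_features` for body-weight-seconds instead).  Features
    whose defining phase is absent (e.g. no braking-to-propulsion zero
    crossing in fx) are NaN and named in ``flags``.
    """

    peak_braking: float
    peak_propulsive: float
    braking_impulse: float
    propulsive_impulse: float
    peak_ml_first: float
    peak_ml_second: float
    ml_impulse: float
    peak_vertical: float
    vertical_impulse: float
    flags: tuple[str, ...] = ()

    FIELDS = ("peak_braking", "peak_propulsive", "braking_impulse",
              "propulsive_impulse", "peak_ml_first", "peak_ml_second",
              "ml_impulse", "peak_vertical", "vertical_impulse")

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


def lowpass_filter(recording: GRFRecording, cutoff_hz: float = 25.0,
                   order: int = 4) -> GRFRecording:
    """Zero-phase Butterworth low-pass of all three force channels.

    The filter is applied forward and backward (``sosfiltfilt`` with
    reflective edge padding), so the effective magnitude response is the
    squared Butterworth response and the phase response is zero.  Output
    length equals input length.
    """
    nyquist = recording.sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz is not below Nyquist ({nyquist} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low",
                        fs=recording.sample_rate_hz, output="sos")
    data = recording.data.copy()
    for col in ("fx_N", "fy_N", "fz_N"):
        data[col] = signal.sosfiltfilt(sos, data[col].to_numpy(),
                                       padtype="even")
    meta = dict(recording.meta)
    meta["filter"] = {"type": "butterworth", "order": order,
                      "cutoff_hz": cutoff_hz, "phase": "zero (filtfilt)"}
    return replace(recording, data=data, meta=meta)


def detect_stance(recording: GRFRecording, threshold_frac: float = 0.025,
                  max_extend_frac: float = 0.25) -> StanceWindow:
    """Locate the stance window from the vertical channel.

    The longest contiguous run of samples with ``Fz`` above
    ``threshold_frac`` x body weight is taken as the contact, then each edge
    is walked outward (up to ``max_extend_frac`` of the run length) while the
    signal stays positive, so the window ends at the samples where the
    vertical force actually returns to zero rather than at the detection
    threshold.
    """
    fz = recording.data["fz_N"].to_numpy()
    t = recording.data["time_s"].to_numpy()
    thr = threshold_frac * recording.body_weight_N
    above = fz > thr
    if not above.any():
        raise NoContactError(
            f"no samples exceed {threshold_frac:.1%} of body weight")
    # longest contiguous suprathreshold run
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive indices
    longest = int(np.argmax(ends - starts))
    i0, i1 = int(starts[longest]), int(ends[longest])

    eps = 1e-9 * recording.body_weight_N
    limit = max(3, int(round(max_extend_frac * (i1 - i0 + 1))))
    j = i0
    while j > 0 and i0 - j < limit and fz[j - 1] > eps:
        j -= 1
    if j > 0 and fz[j - 1] <= eps:
        j -= 1  # include the zero-force touchdown sample
    k = i1
    n = len(fz)
    while k < n - 1 and k - i1 < limit and fz[k + 1] > eps:
        k += 1
    if k < n - 1 and fz[k + 1] <= eps:
        k += 1  # include the zero-force liftoff sample
    return StanceWindow(float(t[j]), float(t[k]))


def normalize(recording: GRFRecording, window: StanceWindow,
              n_points: int = N_GRID_POINTS) -> NormalizedGRF:
    """Divide forces by body weight and remap time onto tau in [0, 1].

    Forces are linearly resampled onto an ``n_points`` grid spanning the
    stance window, so resampling reproduces affine segments exactly.
    """
    t = recording.data["time_s"].to_numpy()
    if window.start_s < t[0] or window.end_s > t[-1]:
        raise ParameterError("stance window lies outside the recording")
    stance_time = window.duration_s
    if stance_time * recording.sample_rate_hz < 10:
        raise InsufficientDataError(
            f"stance of {stance_time:.4f} s spans fewer than 10 samples at "
            f"{recording.sample_rate_hz} Hz")
    tau = np.linspace(0.0, 1.0, n_points)
    t_grid = window.start_s + tau * stance_time
    bw = recording.body_weight_N
    fx = np.interp(t_grid, t, recording.data["fx_N"].to_numpy()) / bw
    fy = np.interp(t_grid, t, recording.data["fy_N"].to_numpy()) / bw
    fz = np.interp(t_grid, t, recording.data["fz_N"].to_numpy()) / bw
    return NormalizedGRF(tau=tau, fx=fx, fy=fy, fz=fz,
                         stance_time_s=stance_time)


def extract_features(norm: NormalizedGRF, crossing_skip: float = 0.05,
                     impulse_units: str = "dimensionless",
                     low_vertical_impulse: float = 0.05) -> GRFFeatures:
    """Reduce normalized force curves to the nine shape descriptors.

    The braking/propulsion split is the first fx zero crossing after the
    initial ``crossing_skip`` fraction of stance (the loading transient is
    ignored when searching for the crossing so that contact noise cannot
    split the phases spuriously).  If fx never changes sign the four fore-aft
    features are reported missing rather than zero.
    """
    if impulse_units not in ("dimensionless", "bw_s"):
        raise ParameterError(f"unknown impulse_units {impulse_units!r}")
    tau, fx, fy, fz = norm.tau, norm.fx, norm.fy, norm.fz
    scale = norm.stance_time_s if impulse_units == "bw_s" else 1.0
    flags: list[str] = []

    peak_vertical = float(np.max(fz))
    vertical_impulse = float(np.trapezoid(fz, tau)) * scale
    if vertical_impulse < low_vertical_impulse * scale:
        flags.append("low_vertical_impulse")
        warnings.warn("vertical impulse below 0.05 body-weight units; "
                      "possible partial plate contact", stacklevel=2)

    first_half = tau < 0.5
    second_half = tau > 0.5
    peak_ml_first = float(np.max(fy[first_half]))
    peak_ml_second = float(np.max(fy[second_half]))
    ml_impulse = float(np.trapezoid(fy, tau)) * scale

    crossing = _first_zero_crossing(tau, fx, crossing_skip)
    if crossing is None:
        flags.append("no_fx_zero_crossing")
        peak_braking = peak_propulsive = np.nan
        braking_impulse = propulsive_impulse = np.nan
    else:
        tau_c = crossing
        brake_t = np.concatenate((tau[tau < tau_c], [tau_c]))
        brake_f = np.concatenate((fx[tau < tau_c], [0.0]))
        prop_t = np.concatenate(([tau_c], tau[tau > tau_c]))
        prop_f = np.concatenate(([0.0], fx[tau > tau_c]))
        neg = brake_f < 0
        peak_braking = float(np.max(-brake_f[neg])) if neg.any() else np.nan
        pos = prop_f > 0
        peak_propulsive = float(np.max(prop_f[pos])) if pos.any() else np.nan
        braking_impulse = abs(float(np.trapezoid(brake_f, brake_t))) * scale
        propulsive_impulse = abs(float(np.trapezoid(prop_f, prop_t))) * scale
        if not neg.any():
            flags.append("no_braking_phase")
        if not pos.any():
            flags.append("no_propulsive_phase")

    return GRFFeatures(
        peak_braking=peak_braking, peak_propulsive=peak_propulsive,
        braking_impulse=braking_impulse,
        propulsive_impulse=propulsive_impulse,
        peak_ml_first=peak_ml_first, peak_ml_second=peak_ml_second,
        ml_impulse=ml_impulse, peak_vertical=peak_vertical,
        vertical_impulse=vertical_impulse, flags=tuple(flags))


def _first_zero_crossing(tau: np.ndarray, fx: np.ndarray,
                         skip: float) -> float | None:
    """Interpolated tau of the first fx sign change with tau >= skip."""
    for i in range(len(tau) - 1):
        if tau[i] < skip:
            continue
        a, b = fx[i], fx[i + 1]
        if a == 0.0:
            return float(tau[i])
        if a * b < 0:
            return float(tau[i] - a * (tau[i + 1] - tau[i]) / (b - a))
    return None


@dataclass(frozen=True)
class GRFAnalysis:
    features: GRFFeatures
    window: StanceWindow
    normalized: NormalizedGRF


def analyze_recording(recording: GRFRecording, lowpass: bool = True,
                      cutoff_hz: float = 25.0, order: int = 4,
                      threshold_frac: float = 0.025,
                      n_points: int = N_GRID_POINTS,
                      impulse_units: str = "dimensionless") -> GRFAnalysis:
    """Full reduction of a raw recording to the nine descriptors."""
    rec = (lowpass_filter(recording, cutoff_hz, order)
           if lowpass else recording)
    window = detect_stance(rec, threshold_frac=threshold_frac)
    norm = normalize(rec, window, n_points=n_points)
    features = extract_features(norm, impulse_units=impulse_units)
    return GRFAnalysis(features=features, window=window, normalized=norm)
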