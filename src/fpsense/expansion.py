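"""Biomechanical analysis of two-sensor cavity-length series during rapid
palatal expansion.

Each screw activation opens the midpalatal suture by a discrete step; the two
sensors sample the opening at an anterior and a posterior point separated by
a known distance ``s`` along the expander.  From the per-activation plateau
steps the module derives the per-sensor opening, the comparison with the
screw-driven expected expansion (pitch x turn fraction), the baseline
resolution, and the suture opening angle under the rigid-wedge, left-right
symmetric, small-angle model

    theta = (delta_anterior - delta_posterior) / s,

positive theta meaning the opening is wider anteriorly (V-type expansion,
apex posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demod import SensorTimeSeries
from .errors import InvalidInputError, InvalidWindowError, ReconciliationError

__all__ = [
    "ExpanderGeometry",
    "ActivationRecord",
    "ExpansionSummary",
    "expected_expansion",
    "detect_steps",
    "expansion_angle",
    "rad_to_deg",
    "baseline_noise",
    "summarize",
]

DEFAULT_MIN_STEP_UM = 20.0
DEFAULT_PLATEAU_WINDOW_S = 30.0


@dataclass(frozen=True)
class ExpanderGeometry:
    """Geometry of the instrumented expander.

    sensor_separation_um : distance s between the two sensors along the
        anteroposterior axis (um).
    screw_pitch_mm : expansion per full screw turn (mm/turn).
    activation_fraction : turn fraction applied per activation.
    """

    sensor_separation_um: float = 900.0
    screw_pitch_mm: float = 0.8
    activation_fraction: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.sensor_separation_um <= 0 or self.screw_pitch_mm <= 0:
            raise InvalidInputError("geometry lengths must be positive")
        if not (0 < self.activation_fraction <= 1):
            raise InvalidInputError("activation fraction must be in (0, 1]")


@dataclass(frozen=True)
class ActivationRecord:
    """One detected opening step in a single sensor's series."""

    index: int
    onset_s: float
    delta_um: float
    cumulative_um: float
    channel: str | None = None


@dataclass
class ExpansionSummary:
    """Per-activation expansion table plus derived statistics.

    All displacements in um; angles in rad (and degrees).  ``average`` is
    (anterior + posterior)/2 per activation, cumulative from the initial
    distance; ``expected`` is the cumulative screw-driven displacement.
    """

    anterior_channel: str
    posterior_channel: str
    expected_um: np.ndarray
    anterior_cum_um: np.ndarray
    posterior_cum_um: np.ndarray
    average_cum_um: np.ndarray
    angle_rad: np.ndarray
    angle_deg: np.ndarray
    error_mean_um: float
    error_sd_um: float
    baseline_sd_um: dict[str, float] = field(default_factory=dict)
    geometry: ExpanderGeometry = field(default_factory=ExpanderGeometry)
    schedule_turns: tuple[float, ...] = ()

    @property
    def n_activations(self) -> int:
        return int(self.expected_um.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "activation": np.arange(1, self.n_activations + 1),
                f"{self.anterior_channel}_um": self.anterior_cum_um,
                f"{self.posterior_channel}_um": self.posterior_cum_um,
                "average_um": self.average_cum_um,
                "expected_um": self.expected_um,
                "error_um": self.average_cum_um - self.expected_um,
                "angle_rad": self.angle_rad,
                "angle_deg": self.angle_deg,
            }
        )

    def to_dict(self) -> dict:
        return {
            "anterior_channel": self.anterior_channel,
            "posterior_channel": self.posterior_channel,
            "per_activation": self.to_frame().to_dict(orient="records"),
            "error_mean_um": self.error_mean_um,
            "error_sd_um": self.error_sd_um,
            "baseline_sd_um": dict(self.baseline_sd_um),
            "geometry": {
                "sensor_separation_um": self.geometry.sensor_separation_um,
                "screw_pitch_mm": self.geometry.screw_pitch_mm,
                "activation_fraction": self.geometry.activation_fraction,
            },
            "schedule_turns": list(self.schedule_turns),
        }


def expected_expansion(turns: float, geometry: ExpanderGeometry) -> float:
    """Screw-driven expansion for a number of turns, in mm (pitch x turns)."""
    if turns < 0:
        raise InvalidInputError("turn count must be >= 0")
    return geometry.screw_pitch_mm * turns


def expansion_angle(delta_anterior_um: float, delta_posterior_um: float, s_um: float) -> float:
    """Small-angle suture opening angle (rad).

    Positive when the anterior opening exceeds the posterior one (V-type,
    apex posterior); zero for parallel expansion.
    """
    if s_um <= 0:
        raise InvalidInputError("sensor separation must be positive")
    return (delta_anterior_um - delta_posterior_um) / s_um


def rad_to_deg(theta_rad: float) -> float:
    """Radians to degrees."""
    return np.degrees(theta_rad)


def detect_steps(
    series: SensorTimeSeries,
    min_step_um: float = DEFAULT_MIN_STEP_UM,
    plateau_window_s: float = DEFAULT_PLATEAU_WINDOW_S,
) -> list[ActivationRecord]:
    """Segment a cavity-length series into plateaus separated by steps.

    A new plateau opens when a sample departs from the running median of the
    current plateau by more than ``min_step_um`` and the departure persists
    (a lone excursion is treated as an outlier, not a step).  Step sizes are
    differences of plateau medians restricted to ``plateau_window_s`` next to
    the step, which makes them robust to slow drift within long plateaus.
    Returns an empty list when no step is found.
    """
    mask = series.valid_mask
    t = series.timestamps_s[mask]
    d = series.d_um[mask]
    if d.size < 2:
        return []

    plateaus: list[list[int]] = [[0]]
    for j in range(1, d.size):
        med = float(np.median(d[plateaus[-1]]))
        if abs(d[j] - med) > min_step_um:
            nxt = j + 1
            persists = nxt >= d.size or abs(d[nxt] - med) > min_step_um
            if persists:
                plateaus.append([j])
            # else: lone outlier; drop the sample from plateau statistics
        else:
            plateaus[-1].append(j)

    records: list[ActivationRecord] = []
    initial_med = _windowed_median(t, d, plateaus[0], plateau_window_s, tail=True)
    for i in range(1, len(plateaus)):
        before = _windowed_median(t, d, plateaus[i - 1], plateau_window_s, tail=True)
        after = _windowed_median(t, d, plateaus[i], plateau_window_s, tail=False)
        onset = float(t[plateaus[i][0]])
        records.append(
            ActivationRecord(
                index=i,
                onset_s=onset,
                delta_um=after - before,
                cumulative_um=after - initial_med,
                channel=series.channel,
            )
        )
    return records


def _windowed_median(
    t: np.ndarray, d: np.ndarray, idx: list[int], window_s: float, *, tail: bool
) -> float:
    """Median of a plateau restricted to a time window at its tail or head."""
    tt = t[idx]
    dd = d[idx]
    if tail:
        sel = tt >= tt[-1] - window_s
    else:
        sel = tt <= tt[0] + window_s
    return float(np.median(dd[sel]))


def baseline_noise(
    series: SensorTimeSeries,
    window: tuple[float, float],
    *,
    min_samples: int = 10,
    min_step_um: float = DEFAULT_MIN_STEP_UM,
) -> float:
    """Sample standard deviation of d over a quiet window (um).

    The window must lie within a single plateau: if any detected activation
    onset falls inside it, :class:`InvalidWindowError` is raised, as is a
    window with fewer than ``min_samples`` unflagged samples.
    """
    t0, t1 = window
    if t1 <= t0:
        raise InvalidInputError("window end must exceed window start")
    for rec in detect_steps(series, min_step_um=min_step_um):
        if t0 <= rec.onset_s <= t1:
            raise InvalidWindowError(
                f"window [{t0}, {t1}] s crosses the activation step at t={rec.onset_s} s"
            )
    mask = series.valid_mask & (series.timestamps_s >= t0) & (series.timestamps_s <= t1)
    if int(mask.sum()) < min_samples:
        raise InvalidWindowError(
            f"window holds {int(mask.sum())} unflagged samples; need >= {min_samples}"
        )
    return float(np.std(series.d_um[mask], ddof=1))


def summarize(
    anterior: SensorTimeSeries,
    posterior: SensorTimeSeries,
    geometry: ExpanderGeometry,
    schedule_turns: list[float] | None = None,
    *,
    min_step_um: float = DEFAULT_MIN_STEP_UM,
    plateau_window_s: float = DEFAULT_PLATEAU_WINDOW_S,
) -> ExpansionSummary:
    """Full two-sensor expansion summary.

    The anterior/posterior assignment is the caller's responsibility (it is a
    physical mounting fact and is never inferred from the data).
    ``schedule_turns`` lists the turn fraction of each activation; by default
    the geometry's activation fraction is assumed for every detected step.
    Raises :class:`ReconciliationError` when the two channels (or the
    schedule) disagree on the number of steps.
    """
    steps_a = detect_steps(anterior, min_step_um, plateau_window_s)
    steps_p = detect_steps(posterior, min_step_um, plateau_window_s)
    if schedule_turns is None:
        schedule_turns = [geometry.activation_fraction] * len(steps_a)
    n_sched = len(schedule_turns)
    if len(steps_a) != n_sched or len(steps_p) != n_sched:
        raise ReconciliationError(
            f"schedule has {n_sched} activations but detected "
            f"{len(steps_a)} steps on {anterior.channel or 'anterior'} and "
            f"{len(steps_p)} on {posterior.channel or 'posterior'}"
        )
    if n_sched == 0:
        raise ReconciliationError("no activation steps detected and none scheduled")

    cum_a = np.array([r.cumulative_um for r in steps_a])
    cum_p = np.array([r.cumulative_um for r in steps_p])
    average = 0.5 * (cum_a + cum_p)
    expected = np.cumsum(
        [expected_expansion(f, geometry) * 1e3 for f in schedule_turns]
    )  # mm -> um
    theta = np.array(
        [expansion_angle(a, p, geometry.sensor_separation_um) for a, p in zip(cum_a, cum_p)]
    )
    errors = average - expected

    baseline: dict[str, float] = {}
    for series, steps in ((anterior, steps_a), (posterior, steps_p)):
        t_first = steps[0].onset_s
        window = (float(series.timestamps_s[0]), t_first - 1e-9)
        try:
            baseline[series.channel or "?"] = baseline_noise(
                series, window, min_step_um=min_step_um
            )
        except InvalidWindowError:
            baseline[series.channel or "?"] = float("nan")

    return ExpansionSummary(
        anterior_channel=anterior.channel or "anterior",
        posterior_channel=posterior.channel or "posterior",
        expected_um=expected,
        anterior_cum_um=cum_a,
        posterior_cum_um=cum_p,
        average_cum_um=average,
        angle_rad=theta,
        angle_deg=np.degrees(theta),
        error_mean_um=float(np.mean(errors)),
        error_sd_um=float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0,
        baseline_sd_um=baseline,
        geometry=geometry,
        schedule_turns=tuple(schedule_turns),
    )
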