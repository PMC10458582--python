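"""Ground-truthed synthetic experiments for the two-sensor expansion setup.

Emulates the bench protocol end to end so every other module is testable
without an instrument: two Fabry-Perot sensors with initial cavity lengths of
285 and 300 um, three screw activations of ~0.13 mm each about one minute
apart, an interrogator spanning 1510-1590 nm with 2 pm wavelength
repeatability at 1 Hz.  The true cavity length is a staircase (each loading
changes the distance at once and it then holds); the first activation is
split asymmetrically (+-13.5 um about the 130 um mean) so the two channels
encode a 27 um anterior-posterior difference, i.e. a 0.03 rad opening angle
over a 900 um sensor separation.

Interrogator wavelength jitter is realized as a rigid spectral shift per
frame — equivalent at peak level to per-peak jitter, and consistent across
orders — plus additive Gaussian intensity noise.  Fixed seed implies
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, InvalidInputError
from .expansion import ExpanderGeometry
from .fp_model import (
    DEFAULT_N_SAMPLES,
    DEFAULT_WL_MAX_NM,
    DEFAULT_WL_MIN_NM,
    FPCavityParams,
    ReflectionSpectrum,
    ThermalParams,
    generate_spectrum,
    temperature_sensitivity,
)

__all__ = [
    "Activation",
    "ExperimentConfig",
    "ExperimentDataset",
    "simulate_experiment",
    "simulate_translation_stage",
    "default_config",
]

# Demodulable cavity-length window for the default 80 nm span: short cavities
# put fewer than 2 fringes in the span; very long ones under-sample fringes.
_MIN_DEMODULABLE_D_UM = 40.0
_MAX_DEMODULABLE_D_UM = 2000.0


@dataclass(frozen=True)
class Activation:
    """One screw activation: when it happens and the per-channel true step."""

    time_s: float
    steps_um: dict[str, float]


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions of a synthetic two-sensor expansion experiment.

    Defaults reproduce the bench protocol: initial cavity lengths 285/300 um,
    three activations of 130 um mean (first split 116.5/143.5 um), 1 Hz
    acquisition, 2 pm wavelength jitter, 0.001 intensity-noise SD (normalized
    units; a toolkit choice, no instrument figure exists for it).
    """

    seed: int = 0
    initial_d_um: dict[str, float] = field(
        default_factory=lambda: {"S1": 285.0, "S2": 300.0}
    )
    schedule: tuple[Activation, ...] = (
        Activation(60.0, {"S1": 116.5, "S2": 143.5}),
        Activation(120.0, {"S1": 130.0, "S2": 130.0}),
        Activation(180.0, {"S1": 130.0, "S2": 130.0}),
    )
    duration_s: float = 240.0
    rate_hz: float = 1.0
    wavelength_jitter_pm: float = 2.0
    intensity_noise_sd: float = 0.001
    geometry: ExpanderGeometry = field(default_factory=ExpanderGeometry)
    anterior_channel: str = "S2"
    cavity: FPCavityParams = field(default_factory=lambda: FPCavityParams(d_um=1.0))
    thermal: ThermalParams | None = None
    temperature_offset_c: tuple[tuple[float, float], ...] | None = None
    wl_min_nm: float = DEFAULT_WL_MIN_NM
    wl_max_nm: float = DEFAULT_WL_MAX_NM
    n_samples: int = DEFAULT_N_SAMPLES

    def __post_init__(self) -> None:
        if self.wavelength_jitter_pm < 0 or self.intensity_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigError("rate and duration must be positive")
        for act in self.schedule:
            if not (0 < act.time_s < self.duration_s):
                raise ConfigError(
                    f"activation at t={act.time_s} s falls outside the "
                    f"(0, {self.duration_s}) s run"
                )
        if self.temperature_offset_c is not None and self.thermal is None:
            raise ConfigError("a temperature profile requires thermal params")

    @property
    def channels(self) -> list[str]:
        return sorted(self.initial_d_um)


@dataclass
class ExperimentDataset:
    """Frames plus the ground truth they were generated from."""

    timestamps_s: np.ndarray
    frames: dict[str, list[ReflectionSpectrum]]
    ground_truth_d_um: dict[str, np.ndarray]
    config: ExperimentConfig


def default_config(seed: int = 0) -> ExperimentConfig:
    """The default bench-protocol configuration with a chosen seed."""
    return ExperimentConfig(seed=seed)


def _true_staircase(config: ExperimentConfig, channel: str, t: np.ndarray) -> np.ndarray:
    d = np.full(t.shape, config.initial_d_um[channel], dtype=float)
    for act in config.schedule:
        d[t >= act.time_s] += act.steps_um.get(channel, 0.0)
    return d


def _temperature_at(config: ExperimentConfig, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear temperature offset (degC) at the frame times."""
    prof = np.asarray(config.temperature_offset_c, dtype=float)
    return np.interp(t, prof[:, 0], prof[:, 1])


def simulate_experiment(config: ExperimentConfig) -> ExperimentDataset:
    """Simulate the full two-sensor activation experiment.

    The true cavity length per channel is the configured staircase, plus an
    optional linearized thermal drift (mismatch-model sensitivity at the
    initial cavity length times the temperature offset).  Each frame is a
    forward-modeled spectrum with a per-frame rigid wavelength shift drawn
    from the jitter SD and additive intensity noise.  Deterministic for a
    fixed seed.  Raises :class:`ConfigError` if the staircase leaves the
    demodulable cavity-length range of the grid.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_s, 1.0 / config.rate_hz)
    if t.size == 0:
        raise ConfigError("duration too short for one frame")
    frames: dict[str, list[ReflectionSpectrum]] = {}
    truth: dict[str, np.ndarray] = {}
    for channel in config.channels:
        d_true = _true_staircase(config, channel, t)
        if config.temperature_offset_c is not None:
            sens = temperature_sensitivity(config.thermal, config.initial_d_um[channel])
            d_true = d_true + sens * _temperature_at(config, t)
        if d_true.min() < _MIN_DEMODULABLE_D_UM or d_true.max() > _MAX_DEMODULABLE_D_UM:
            raise ConfigError(
                f"channel {channel}: true cavity length leaves the demodulable "
                f"range [{_MIN_DEMODULABLE_D_UM}, {_MAX_DEMODULABLE_D_UM}] um"
            )
        shifts_nm = rng.normal(0.0, config.wavelength_jitter_pm * 1e-3, size=t.size)
        ch_frames: list[ReflectionSpectrum] = []
        for j in range(t.size):
            spec = generate_spectrum(
                config.cavity.with_d(float(d_true[j])),
                config.wl_min_nm,
                config.wl_max_nm,
                config.n_samples,
                timestamp_s=float(t[j]),
                channel=channel,
                wavelength_shift_nm=float(shifts_nm[j]),
            )
            if config.intensity_noise_sd > 0:
                noisy = spec.intensities + rng.normal(
                    0.0, config.intensity_noise_sd, size=spec.intensities.size
                )
                spec = ReflectionSpectrum(
                    spec.wavelengths_nm,
                    np.clip(noisy, 0.0, None),
                    timestamp_s=spec.timestamp_s,
                    channel=channel,
                )
            ch_frames.append(spec)
        frames[channel] = ch_frames
        truth[channel] = d_true
    return ExperimentDataset(t, frames, truth, config)


def simulate_translation_stage(
    start_d_um: float,
    step_um: float,
    n_steps: int,
    *,
    frames_per_plateau: int = 5,
    seed: int = 0,
    wavelength_jitter_pm: float = 0.0,
    intensity_noise_sd: float = 0.0,
    cavity: FPCavityParams | None = None,
    wl_min_nm: float = DEFAULT_WL_MIN_NM,
    wl_max_nm: float = DEFAULT_WL_MAX_NM,
    n_samples: int = DEFAULT_N_SAMPLES,
    rate_hz: float = 1.0,
) -> ExperimentDataset:
    """Bench calibration scenario: equal cavity-length increments on a stage.

    Produces ``n_steps + 1`` plateaus of ``frames_per_plateau`` frames each,
    starting at ``start_d_um`` and incrementing by ``step_um``; used to check
    measured-versus-configured displacement linearity (unit slope).
    """
    if step_um <= 0:
        raise InvalidInputError("step must be positive")
    if n_steps < 0 or frames_per_plateau < 1:
        raise InvalidInputError("need n_steps >= 0 and frames_per_plateau >= 1")
    base = cavity if cavity is not None else FPCavityParams(d_um=start_d_um)
    plateau_d = start_d_um + step_um * np.arange(n_steps + 1)
    schedule = tuple(
        Activation(float((i + 1) * frames_per_plateau) / rate_hz, {"stage": step_um})
        for i in range(n_steps)
    )
    config = ExperimentConfig(
        seed=seed,
        initial_d_um={"stage": float(start_d_um)},
        schedule=schedule,
        duration_s=(n_steps + 1) * frames_per_plateau / rate_hz,
        rate_hz=rate_hz,
        wavelength_jitter_pm=wavelength_jitter_pm,
        intensity_noise_sd=intensity_noise_sd,
        cavity=replace(base, d_um=float(start_d_um)),
        wl_min_nm=wl_min_nm,
        wl_max_nm=wl_max_nm,
        n_samples=n_samples,
    )
    dataset = simulate_experiment(config)
    assert np.allclose(np.unique(dataset.ground_truth_d_um["stage"]), plateau_d)
    return dataset
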