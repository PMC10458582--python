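"""Text-format I/O: spectrum frames, peak tables, time series, summaries,
experiment configs and dataset directories.

All formats are plain text.  A spectrum frame is a two-column CSV
(``wavelength_nm,intensity``) with ``#``-prefixed header lines carrying the
channel id and timestamp.  Floats are written at full precision (%.17g) so a
write -> read round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demod import PeakSet, SensorTimeSeries
from .errors import FormatError
from .expansion import ExpanderGeometry, ExpansionSummary
from .fp_model import FPCavityParams, ReflectionSpectrum, ThermalParams
from .synthetic import Activation, ExperimentConfig, ExperimentDataset

__all__ = [
    "read_spectrum_file",
    "write_spectrum_file",
    "read_timeseries",
    "write_timeseries",
    "read_peak_table",
    "write_peak_table",
    "write_summary_json",
    "write_summary_csv",
    "read_experiment_config",
    "write_experiment_config",
    "write_dataset",
    "read_dataset_frames",
]

_FLOAT_FMT = "%.17g"


def write_spectrum_file(spectrum: ReflectionSpectrum, path: str | Path) -> None:
    """Write one spectrum frame as headered two-column CSV."""
    path = Path(path)
    with path.open("w") as fh:
        if spectrum.channel is not None:
            fh.write(f"# channel: {spectrum.channel}\n")
        if spectrum.timestamp_s is not None:
            fh.write(f"# timestamp_s: {_FLOAT_FMT % spectrum.timestamp_s}\n")
        fh.write("wavelength_nm,intensity\n")
        for wl, it in zip(spectrum.wavelengths_nm, spectrum.intensities):
            fh.write(f"{_FLOAT_FMT % wl},{_FLOAT_FMT % it}\n")


def read_spectrum_file(path: str | Path) -> ReflectionSpectrum:
    """Read and validate a spectrum frame; format errors name the line."""
    path = Path(path)
    channel: str | None = None
    timestamp: float | None = None
    wls: list[float] = []
    its: list[float] = []
    saw_header = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key == "channel":
                        channel = val.strip()
                    elif key == "timestamp_s":
                        try:
                            timestamp = float(val)
                        except ValueError:
                            raise FormatError(
                                f"{path}:{lineno}: bad timestamp {val!r}"
                            ) from None
                continue
            parts = line.split(",")
            if not saw_header:
                if [p.strip() for p in parts[:2]] != ["wavelength_nm", "intensity"]:
                    raise FormatError(
                        f"{path}:{lineno}: expected header 'wavelength_nm,intensity', "
                        f"got {line!r}"
                    )
                saw_header = True
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                wl, it = float(parts[0]), float(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value in {line!r}") from None
            if not (np.isfinite(wl) and np.isfinite(it)):
                raise FormatError(f"{path}:{lineno}: non-finite value")
            if wls and wl <= wls[-1]:
                raise FormatError(
                    f"{path}:{lineno}: wavelengths not strictly increasing "
                    f"({wl} after {wls[-1]})"
                )
            wls.append(wl)
            its.append(it)
    if not saw_header:
        raise FormatError(f"{path}:1: missing 'wavelength_nm,intensity' header")
    if len(wls) < 2:
        raise FormatError(f"{path}: fewer than two data rows")
    return ReflectionSpectrum(
        np.asarray(wls), np.asarray(its), timestamp_s=timestamp, channel=channel
    )


def write_timeseries(series: SensorTimeSeries, path: str | Path) -> None:
    """Write a cavity-length series as `timestamp_s,channel,d_um,k,flag` CSV."""
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | Path) -> SensorTimeSeries:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype={"flag": str})
    required = {"timestamp_s", "channel", "d_um", "k", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    channels = df["channel"].astype(str).unique()
    channel = str(channels[0]) if len(channels) == 1 and channels[0] else None
    flags = ["" if (isinstance(f, float) and np.isnan(f)) else str(f) for f in df["flag"]]
    return SensorTimeSeries(
        df["timestamp_s"].to_numpy(float),
        df["d_um"].to_numpy(float),
        df["k"].to_numpy(int),
        flags,
        channel=channel,
    )


def write_peak_table(peak_sets: list[PeakSet], path: str | Path) -> None:
    """Interrogator-style peak export: one row per peak across frames."""
    rows = []
    for ps in peak_sets:
        for j in range(len(ps)):
            rows.append(
                {
                    "timestamp_s": ps.timestamp_s,
                    "channel": ps.channel or "",
                    "peak_index": j + 1,
                    "wavelength_nm": ps.wavelengths_nm[j],
                    "intensity": ps.intensities[j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_peak_table(path: str | Path) -> list[PeakSet]:
    """Read a peak table, grouping rows into one PeakSet per (time, channel)."""
    df = pd.read_csv(path)
    required = {"timestamp_s", "channel", "peak_index", "wavelength_nm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: list[PeakSet] = []
    for (t, ch), grp in df.groupby(["timestamp_s", "channel"], sort=True, dropna=False):
        grp = grp.sort_values("peak_index")
        out.append(
            PeakSet(
                grp["wavelength_nm"].to_numpy(float),
                grp["intensity"].to_numpy(float),
                timestamp_s=None if pd.isna(t) else float(t),
                channel=None if (pd.isna(ch) or ch == "") else str(ch),
            )
        )
    return out


def write_summary_json(summary: ExpansionSummary, path: str | Path, *, config_echo: dict | None = None) -> None:
    doc = summary.to_dict()
    if config_echo is not None:
        doc["config_echo"] = config_echo
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_summary_csv(summary: ExpansionSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, index=False)


def _config_to_dict(config: ExperimentConfig) -> dict:
    return {
        "seed": config.seed,
        "initial_d_um": dict(config.initial_d_um),
        "schedule": [
            {"time_s": a.time_s, "steps_um": dict(a.steps_um)} for a in config.schedule
        ],
        "duration_s": config.duration_s,
        "rate_hz": config.rate_hz,
        "wavelength_jitter_pm": config.wavelength_jitter_pm,
        "intensity_noise_sd": config.intensity_noise_sd,
        "geometry": {
            "sensor_separation_um": config.geometry.sensor_separation_um,
            "screw_pitch_mm": config.geometry.screw_pitch_mm,
            "activation_fraction": config.geometry.activation_fraction,
        },
        "anterior_channel": config.anterior_channel,
        "cavity": dataclasses.asdict(config.cavity),
        "thermal": dataclasses.asdict(config.thermal) if config.thermal else None,
        "temperature_offset_c": (
            [list(p) for p in config.temperature_offset_c]
            if config.temperature_offset_c is not None
            else None
        ),
        "wl_min_nm": config.wl_min_nm,
        "wl_max_nm": config.wl_max_nm,
        "n_samples": config.n_samples,
    }


def write_experiment_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write the experiment config as YAML (units in field names)."""
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def read_experiment_config(path: str | Path) -> ExperimentConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config must be a mapping")
    defaults = ExperimentConfig()
    kwargs: dict = {}
    for key in (
        "seed",
        "duration_s",
        "rate_hz",
        "wavelength_jitter_pm",
        "intensity_noise_sd",
        "anterior_channel",
        "wl_min_nm",
        "wl_max_nm",
        "n_samples",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    if "initial_d_um" in doc:
        kwargs["initial_d_um"] = {str(k): float(v) for k, v in doc["initial_d_um"].items()}
    if "schedule" in doc:
        kwargs["schedule"] = tuple(
            Activation(float(a["time_s"]), {str(k): float(v) for k, v in a["steps_um"].items()})
            for a in doc["schedule"]
        )
    if "geometry" in doc:
        kwargs["geometry"] = ExpanderGeometry(**doc["geometry"])
    if "cavity" in doc:
        kwargs["cavity"] = FPCavityParams(**doc["cavity"])
    if doc.get("thermal") is not None:
        kwargs["thermal"] = ThermalParams(**doc["thermal"])
    if doc.get("temperature_offset_c") is not None:
        kwargs["temperature_offset_c"] = tuple(
            (float(p[0]), float(p[1])) for p in doc["temperature_offset_c"]
        )
    return dataclasses.replace(defaults, **kwargs)


def write_dataset(dataset: ExperimentDataset, outdir: str | Path) -> Path:
    """Write an experiment dataset as a directory of text files.

    Layout: one spectrum CSV per frame (``<channel>_frame<idx>.csv``),
    ``ground_truth.csv`` (timestamp_s, channel, d_um), and ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for channel, frames in sorted(dataset.frames.items()):
        for j, frame in enumerate(frames):
            write_spectrum_file(frame, outdir / f"{channel}_frame{j:05d}.csv")
    rows = []
    for channel in sorted(dataset.ground_truth_d_um):
        for t, d in zip(dataset.timestamps_s, dataset.ground_truth_d_um[channel]):
            rows.append({"timestamp_s": t, "channel": channel, "d_um": d})
    pd.DataFrame(rows).to_csv(outdir / "ground_truth.csv", index=False, float_format=_FLOAT_FMT)
    write_experiment_config(dataset.config, outdir / "config.yaml")
    return outdir


def read_dataset_frames(directory: str | Path, channel: str) -> list[ReflectionSpectrum]:
    """Load one channel's frames from a dataset directory, time-ordered."""
    directory = Path(directory)
    paths = sorted(directory.glob(f"{channel}_frame*.csv"))
    if not paths:
        raise FormatError(f"no frames for channel {channel!r} under {directory}")
    frames = [read_spectrum_file(p) for p in paths]
    frames.sort(key=lambda f: (f.timestamp_s is None, f.timestamp_s))
    return frames
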