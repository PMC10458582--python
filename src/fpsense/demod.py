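"""Cavity-length demodulation from reflected interference spectra.

The absolute cavity length of a low-finesse Fabry-Perot sensor is recovered
from the wavelengths of its interference maxima.  With phi0 neglected, the
i-th peak (counted from the shortest wavelength) satisfies

    4 n d / lambda_i = 2(k - (i - 1)) + 1,

where k is the integer fringe order of the first (shortest-wavelength) peak.
Eliminating d between the first and the i-th peak gives

    k = [(2i - 3) * lambda_i + lambda_1] / [2 * (lambda_i - lambda_1)],

which must land near an integer; the cavity length then follows from the
first peak alone,

    d = (2k + 1) * lambda_1 / (4 n).

The default pipeline uses the first and last detected peaks; a consensus mode
computes k from every (lambda_1, lambda_j) pair and takes the majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    AmbiguousOrderError,
    InsufficientFringesError,
    InvalidInputError,
)
from .fp_model import NM_PER_UM, ReflectionSpectrum

__all__ = [
    "PeakSet",
    "CavityEstimate",
    "SensorTimeSeries",
    "detect_peaks",
    "fringe_order",
    "cavity_length",
    "demodulate",
    "demodulate_peaks",
    "track",
    "DEFAULT_MIN_PROMINENCE",
    "DEFAULT_RESIDUAL_TOLERANCE",
    "DEFAULT_JUMP_THRESHOLD_UM",
]

DEFAULT_MIN_PROMINENCE = 0.25
DEFAULT_RESIDUAL_TOLERANCE = 0.3
#: Advisory continuity threshold: flags half-FSR-scale fringe-order slips
#: while letting genuine ~0.13 mm activation steps pass.
DEFAULT_JUMP_THRESHOLD_UM = 200.0

GAP_FLAG = "demod_failed"
SUSPECT_JUMP_FLAG = "suspect_jump"


@dataclass
class PeakSet:
    """Interference maxima of one frame, ascending in wavelength.

    ``edge_flags`` marks maxima lying within half a fringe of the span
    boundary; they may be truncated and bias the quadratic refinement.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    timestamp_s: float | None = None
    channel: str | None = None
    edge_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.size and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise InvalidInputError("peak wavelengths must be strictly increasing")
        if self.edge_flags is None:
            self.edge_flags = np.zeros(self.wavelengths_nm.size, dtype=bool)
        else:
            self.edge_flags = np.asarray(self.edge_flags, dtype=bool)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


@dataclass(frozen=True)
class CavityEstimate:
    """Demodulated cavity length for one frame.

    d_um : estimated cavity length (um);
    k : integer fringe order of the first (shortest-wavelength) peak;
    opd_um : optical path difference 2 n d (um);
    k_residual : distance of the raw order estimate from the nearest integer;
    consensus_spread : number of peak pairs disagreeing with the chosen k
        (0 in first/last mode).
    """

    d_um: float
    k: int
    opd_um: float
    k_residual: float
    n_peaks_used: int
    timestamp_s: float | None = None
    channel: str | None = None
    consensus_spread: int = 0


@dataclass
class SensorTimeSeries:
    """Cavity length versus time for one sensor channel.

    Frames that failed demodulation are gaps: ``d_um`` is NaN, ``k`` is -1,
    and the flag records the failure; they are never interpolated.
    """

    timestamps_s: np.ndarray
    d_um: np.ndarray
    k: np.ndarray
    flags: list[str] = field(default_factory=list)
    channel: str | None = None

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.d_um = np.asarray(self.d_um, dtype=float)
        self.k = np.asarray(self.k, dtype=int)
        n = self.timestamps_s.size
        if not (self.d_um.size == n and self.k.size == n and len(self.flags) == n):
            raise InvalidInputError("time-series fields must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise InvalidInputError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.timestamps_s.size)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.d_um)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamps_s,
                "channel": self.channel or "",
                "d_um": self.d_um,
                "k": self.k,
                "flag": self.flags,
            }
        )


def _refine_quadratic(wl: np.ndarray, y: np.ndarray, idx: int) -> tuple[float, float]:
    """Sub-sample peak position by a parabola through three points.

    Assumes locally uniform wavelength spacing (true for interrogator grids).
    Exact for noise-free symmetric fringes; ill-conditioned under intensity
    noise, where :func:`_refine_parabola_window` is used instead.
    """
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    curv = y0 - 2.0 * y1 + y2
    if curv >= 0.0:  # flat or non-concave: keep the grid point
        return float(wl[idx]), float(y1)
    offset = 0.5 * (y0 - y2) / curv
    h = wl[idx + 1] - wl[idx]
    lam = wl[idx] + offset * h
    val = y1 - 0.25 * (y0 - y2) * offset
    return float(lam), float(val)


def _refine_parabola_window(
    wl: np.ndarray, y: np.ndarray, idx: int, half_width: int
) -> tuple[float, float]:
    """Least-squares parabola vertex over +-half_width samples, recentered.

    Averages intensity noise over many samples; the vertex of a symmetric
    window around a symmetric fringe top is unbiased, and one or two
    recentering passes remove most of the residual window-asymmetry bias.
    """
    n = y.size
    lam = float(wl[idx])
    val = float(y[idx])
    for _ in range(3):
        # Keep the window symmetric about the current center: an
        # edge-clipped asymmetric window biases the vertex by tens of pm.
        hw = min(half_width, idx, n - 1 - idx)
        if hw < 1:
            return float(wl[idx]), float(y[idx])
        lo = idx - hw
        hi = idx + hw + 1
        x = wl[lo:hi] - wl[idx]
        a, b, c = np.polyfit(x, y[lo:hi], 2)
        if a >= 0.0:
            return float(wl[idx]), float(y[idx])
        vertex = -b / (2.0 * a)
        # Keep the vertex inside the fitted window.
        vertex = float(np.clip(vertex, x[0], x[-1]))
        lam = float(wl[idx] + vertex)
        val = float(c - b**2 / (4.0 * a))
        new_idx = int(np.clip(round(idx + vertex / (wl[1] - wl[0])), 1, n - 2))
        if new_idx == idx:
            break
        idx = new_idx
    return lam, val


def _dominant_fringe_samples(y: np.ndarray) -> float:
    """Samples per fringe of the dominant interference period, via FFT."""
    n = y.size
    spec = np.abs(np.fft.rfft(y - y.mean()))
    if spec.size < 2:
        return float(n)
    dom = int(np.argmax(spec[1:])) + 1  # cycles over the record
    return n / dom


def _smooth(y: np.ndarray, samples_per_fringe: float) -> np.ndarray:
    """Savitzky-Golay smoothing sized to ~1/10 of the fringe period.

    A symmetric quadratic filter leaves the position of a symmetric peak
    unchanged while suppressing sample-level intensity noise, so peak
    *detection* is stable; refinement runs on the raw samples.
    """
    n = y.size
    if n < 7:
        return y
    win = int(round(samples_per_fringe / 10.0))
    win = max(5, min(win, 201))
    if win % 2 == 0:
        win += 1
    if win >= n:
        return y
    return savgol_filter(y, win, polyorder=2)


def _recover_edge_peak(
    wl: np.ndarray, y: np.ndarray, idx: list[int], side: str
) -> int | None:
    """Look for a prominence-truncated fringe beyond the outermost peak.

    A fringe whose maximum lies close to the span boundary loses most of its
    outer descent and fails the prominence test even though it is a genuine
    resonance.  Extrapolate one local free spectral range beyond the first or
    last confident peak and accept an interior local maximum there, provided
    a full fringe valley separates it from the anchor peak (which rejects
    noise bumps riding on a flank).
    """
    if len(idx) < 2:
        return None
    if side == "right":
        anchor_idx = idx[-1]
        fsr = wl[idx[-1]] - wl[idx[-2]]
        region = np.nonzero(wl > wl[anchor_idx] + 0.5 * fsr)[0]
    else:
        anchor_idx = idx[0]
        fsr = wl[idx[1]] - wl[idx[0]]
        region = np.nonzero(wl < wl[anchor_idx] - 0.5 * fsr)[0]
    if region.size < 3:
        return None
    j = int(region[np.argmax(y[region])])
    if j <= 0 or j >= y.size - 1:
        return None  # maximum on the boundary: the resonance is outside the span
    if not (y[j] >= y[j - 1] and y[j] >= y[j + 1]):
        return None
    if not (0.5 * fsr < abs(wl[j] - wl[anchor_idx]) < 1.5 * fsr):
        return None
    lo, hi = sorted((anchor_idx, j))
    valley = float(np.min(y[lo : hi + 1]))
    amplitude = float(np.ptp(y))
    if y[j] - valley < 0.5 * amplitude:
        return None
    return j


def detect_peaks(
    spectrum: ReflectionSpectrum,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> PeakSet:
    """Find interference maxima and refine them to sub-sample precision.

    ``min_prominence`` is a fraction of the fringe amplitude (max - min of
    the smoothed frame).  Maxima are located on a Savitzky-Golay-smoothed
    copy of the spectrum, truncated edge fringes are recovered by
    extrapolating the local free spectral range, and each maximum is refined
    by 3-point quadratic interpolation.  Peaks within half a fringe of the
    span boundary are flagged as edge peaks.  Raises
    :class:`InsufficientFringesError` if fewer than two maxima survive,
    since the fringe order needs at least two peaks.
    """
    wl = spectrum.wavelengths_nm
    y = spectrum.intensities
    spf = _dominant_fringe_samples(y)
    ys = _smooth(y, spf)
    amplitude = float(np.ptp(ys))
    idx, _ = find_peaks(ys, prominence=max(min_prominence * amplitude, 1e-12))
    idx = list(idx)
    for side in ("left", "right"):
        extra = _recover_edge_peak(wl, ys, idx, side)
        if extra is not None:
            idx = sorted(idx + [extra])
    if len(idx) < 2:
        raise InsufficientFringesError(
            f"found {len(idx)} interference maxima; need >= 2 to determine the fringe order"
        )
    # Noise decides the refinement estimator: the 3-point parabola is exact
    # on clean fringes; under intensity noise a windowed least-squares
    # parabola (~0.4 fringe half-width) averages the noise down.
    noise_sd = float(np.std(y - ys))
    if noise_sd > amplitude / 200.0:
        half_width = max(2, int(round(0.38 * spf)))
        refined = np.array([_refine_parabola_window(wl, y, i, half_width) for i in idx])
    else:
        refined = np.array([_refine_quadratic(wl, y, i) for i in idx])
    lams, vals = refined[:, 0], refined[:, 1]
    order = np.argsort(lams)
    lams, vals = lams[order], vals[order]
    half_fringe = 0.5 * float(np.median(np.diff(lams))) if lams.size > 1 else 0.0
    edge = (lams - wl[0] < half_fringe) | (wl[-1] - lams < half_fringe)
    return PeakSet(
        lams,
        vals,
        timestamp_s=spectrum.timestamp_s,
        channel=spectrum.channel,
        edge_flags=edge,
    )


def fringe_order(
    lam1_nm: float,
    lami_nm: float,
    i: int,
    residual_tolerance: float = DEFAULT_RESIDUAL_TOLERANCE,
) -> tuple[int, float]:
    """Integer fringe order of the first peak from a pair of peak wavelengths.

    ``lam1_nm`` is the shortest-wavelength peak (highest order) and
    ``lami_nm`` the i-th peak counted from it; ``i >= 2``.  Returns
    ``(k, residual)`` where the residual is the distance of the raw value
    from the chosen integer.  Raises :class:`AmbiguousOrderError` when the
    residual exceeds ``residual_tolerance``.
    """
    if i < 2:
        raise InvalidInputError(f"need i >= 2 peaks to determine the order; got i={i}")
    if lami_nm <= lam1_nm:
        raise InvalidInputError(
            f"the i-th peak must lie at a longer wavelength than the first "
            f"(lam1={lam1_nm} nm, lam{i}={lami_nm} nm)"
        )
    k_raw = ((2 * i - 3) * lami_nm + lam1_nm) / (2.0 * (lami_nm - lam1_nm))
    k = int(round(k_raw))
    residual = abs(k_raw - k)
    if k < 0:
        raise InvalidInputError(f"negative fringe order ({k_raw:.3f}); peaks inconsistent")
    if residual > residual_tolerance:
        raise AmbiguousOrderError(
            f"fringe order {k_raw:.4f} is {residual:.4f} from the nearest integer "
            f"(tolerance {residual_tolerance})"
        )
    return k, residual


def cavity_length(lam1_nm: float, k: int, n: float = 1.0) -> float:
    """Cavity length d = (2k + 1) * lambda_1 / (4 n), in um."""
    if k < 0:
        raise InvalidInputError("fringe order must be >= 0")
    if lam1_nm <= 0:
        raise InvalidInputError("wavelength must be positive")
    return (2 * k + 1) * lam1_nm / (4.0 * n) / NM_PER_UM


def demodulate_peaks(
    peaks: PeakSet,
    *,
    n: float = 1.0,
    residual_tolerance: float = DEFAULT_RESIDUAL_TOLERANCE,
    method: str = "first_last",
    use_edge_peaks: bool = False,
) -> CavityEstimate:
    """Cavity length from an already-extracted peak set.

    ``method="first_last"`` uses the first and last peaks (the interrogator
    convention); ``"consensus"`` derives k from every (lambda_1, lambda_j)
    pair, takes the majority vote (recording how many pairs disagreed), and
    averages the per-peak cavity lengths implied by the resolved orders.
    Edge-flagged peaks at the ends of the set are excluded by default: their
    truncated fits can be biased by tens of pm, enough to corrupt the fringe
    order.  Pass ``use_edge_peaks=True`` to keep them.
    """
    if method not in ("first_last", "consensus"):
        raise InvalidInputError("method must be 'first_last' or 'consensus'")
    lams = peaks.wavelengths_nm
    if not use_edge_peaks and peaks.edge_flags is not None and len(peaks) > 2:
        lo, hi = 0, len(peaks)
        while lo < hi - 2 and peaks.edge_flags[lo]:
            lo += 1
        while hi - lo > 2 and peaks.edge_flags[hi - 1]:
            hi -= 1
        lams = lams[lo:hi]
    npk = int(lams.size)
    if npk < 2:
        raise InsufficientFringesError(f"peak set has {npk} usable peaks; need >= 2")
    spread = 0
    if method == "first_last":
        k, residual = fringe_order(lams[0], lams[-1], npk, residual_tolerance)
        d = cavity_length(lams[0], k, n)
    else:
        js = np.arange(2, npk + 1)
        k_raws = ((2 * js - 3) * lams[1:] + lams[0]) / (2.0 * (lams[1:] - lams[0]))
        ks = np.round(k_raws).astype(int)
        votes = np.bincount(ks[ks >= 0])
        k = int(np.argmax(votes))
        spread = int(npk - 1 - votes[k])
        # Judge ambiguity on the widest pair: close pairs are intrinsically
        # noisy in k (the divisor lambda_i - lambda_1 is small).
        residual = float(np.abs(k_raws[-1] - k))
        if residual > residual_tolerance:
            raise AmbiguousOrderError(
                f"consensus fringe order residual {residual:.4f} exceeds "
                f"tolerance {residual_tolerance}"
            )
        # Multi-peak refinement: peak j (0-based) carries order 2(k - j) + 1,
        # so every peak yields an independent cavity length; averaging them
        # suppresses per-peak wavelength noise.
        orders = 2 * (k - np.arange(npk)) + 1
        if orders[-1] <= 0:
            raise AmbiguousOrderError(f"fringe order k={k} too small for {npk} peaks")
        d = float(np.mean(orders * lams / (4.0 * n))) / NM_PER_UM
    return CavityEstimate(
        d_um=d,
        k=k,
        opd_um=2.0 * n * d,
        k_residual=residual,
        n_peaks_used=npk,
        timestamp_s=peaks.timestamp_s,
        channel=peaks.channel,
        consensus_spread=spread,
    )


def demodulate(
    spectrum: ReflectionSpectrum,
    *,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    n: float = 1.0,
    residual_tolerance: float = DEFAULT_RESIDUAL_TOLERANCE,
    method: str = "first_last",
) -> CavityEstimate:
    """Full single-frame pipeline: detect peaks, resolve k, compute d."""
    try:
        peaks = detect_peaks(spectrum, min_prominence)
        return demodulate_peaks(
            peaks, n=n, residual_tolerance=residual_tolerance, method=method
        )
    except (InsufficientFringesError, AmbiguousOrderError) as exc:
        ctx = f" (channel={spectrum.channel}, t={spectrum.timestamp_s}s)"
        raise type(exc)(str(exc) + ctx) from exc


def track(
    frames: list[ReflectionSpectrum],
    *,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    n: float = 1.0,
    residual_tolerance: float = DEFAULT_RESIDUAL_TOLERANCE,
    method: str = "first_last",
    jump_threshold_um: float | None = None,
    channel: str | None = None,
) -> SensorTimeSeries:
    """Demodulate a time-ordered frame sequence into a cavity-length series.

    Frames that fail demodulation become flagged gaps; others are unaffected.
    If ``jump_threshold_um`` is set (e.g. ``DEFAULT_JUMP_THRESHOLD_UM``),
    inter-frame changes exceeding it are flagged as suspect fringe-order
    slips — advisory only, the values are kept (activation steps are genuine
    signal).
    """
    if not frames:
        raise InvalidInputError("empty frame sequence")
    times, ds, ks, flags = [], [], [], []
    for j, frame in enumerate(frames):
        t = frame.timestamp_s if frame.timestamp_s is not None else float(j)
        times.append(t)
        try:
            est = demodulate(
                frame,
                min_prominence=min_prominence,
                n=n,
                residual_tolerance=residual_tolerance,
                method=method,
            )
            ds.append(est.d_um)
            ks.append(est.k)
            flags.append("")
        except (InsufficientFringesError, AmbiguousOrderError) as exc:
            ds.append(np.nan)
            ks.append(-1)
            flags.append(f"{GAP_FLAG}:{type(exc).__name__}")
    ds_arr = np.asarray(ds)
    if jump_threshold_um is not None:
        prev = np.nan
        for j in range(len(ds)):
            if np.isfinite(ds_arr[j]):
                if np.isfinite(prev) and abs(ds_arr[j] - prev) > jump_threshold_um:
                    flags[j] = (flags[j] + ";" if flags[j] else "") + SUSPECT_JUMP_FLAG
                prev = ds_arr[j]
    ch = channel if channel is not None else frames[0].channel
    return SensorTimeSeries(np.asarray(times), ds_arr, np.asarray(ks), flags, channel=ch)
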