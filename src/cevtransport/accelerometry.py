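"""Transport metrics from 3-axis accelerometer traces.

Blood-sample transport events (human carrier vs pneumatic tube) are
characterized by a small set of vibration metrics computed on the
gravity-removed magnitude of a 3-axis acceleration recording:

* TK  — mean Teager-Kaiser energy, ``mean(x[n]^2 - x[n-1]*x[n+1])`` (g^2),
* RMS — root mean square acceleration (g),
* VDV — vibration dose value, ``(sum x^4 dt)^(1/4)`` (g * s^0.25),
* shock count — number of contiguous excursions above 2.5 g,
* ground frequency — dominant Fourier component of a walker's gait (Hz).

Static gravity is removed by subtracting the per-axis median before taking
the Euclidean norm, so a resting sensor yields an all-zero dynamic signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "TransportMetrics",
    "dynamic_magnitude",
    "mean_teager_kaiser",
    "rms",
    "vdv",
    "count_shocks",
    "ground_frequency",
    "summarize_transport",
    "read_trace",
    "write_trace",
]

SHOCK_THRESHOLD_G = 2.5


class NoDominantFrequencyError(ValueError):
    """Raised when no dominant spectral line exists (e.g. constant signal)."""


@dataclass(frozen=True)
class AccelTrace:
    """A timed 3-axis acceleration recording of one transport event.

    Parameters
    ----------
    timestamps : array of float
        Sample times in seconds, strictly increasing.
    ax, ay, az : arrays of float
        Per-axis acceleration in g; equal lengths, clipped by the sensor
        at ``+/- clip_limit``.
    sample_rate : float
        Nominal sampling rate in Hz.
    clip_limit : float
        Per-axis saturation limit of the sensor in g.
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float = 25.0
    clip_limit: float = 16.0

    def __post_init__(self) -> None:
        for name in ("timestamps", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.timestamps)
        if n < 2:
            raise ValueError("an acceleration trace needs at least 2 samples")
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("timestamps and axis sequences must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for axis in (self.ax, self.ay, self.az):
            if np.any(np.abs(axis) > self.clip_limit + 1e-9):
                raise ValueError("axis values exceed the sensor clip limit")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_seconds(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.timestamps)))


@dataclass(frozen=True)
class TransportMetrics:
    """Summary metrics of one transport event (all on the dynamic magnitude)."""

    tk: float  # g^2
    rms: float  # g
    vdv: float  # g * s^0.25
    duration: float  # minutes
    max_amplitude: float  # g
    median_amplitude: float  # g
    shock_count: int
    ground_frequency: Optional[float] = None  # Hz; absent for shock-dominated traces

    def __post_init__(self) -> None:
        if min(self.tk, self.rms, self.vdv) < 0 or self.shock_count < 0:
            raise ValueError("metrics must be nonnegative")
        if self.ground_frequency is not None and self.ground_frequency <= 0:
            raise ValueError("ground frequency must be positive when present")

    def to_frame(self) -> pd.DataFrame:
        """One-row DataFrame, convenient for TSV export."""
        return pd.DataFrame(
            {
                "tk_g2": [self.tk],
                "rms_g": [self.rms],
                "vdv_g_s025": [self.vdv],
                "duration_min": [self.duration],
                "max_amplitude_g": [self.max_amplitude],
                "median_amplitude_g": [self.median_amplitude],
                "shock_count": [self.shock_count],
                "ground_frequency_hz": [self.ground_frequency],
            }
        )


def dynamic_magnitude(trace: AccelTrace) -> np.ndarray:
    """Gravity-removed Euclidean magnitude of the 3-axis signal.

    The static component of each axis (its median, dominated by the
    orientation-dependent projection of gravity) is subtracted, then the
    per-sample Euclidean norm is taken.
    """
    dx = trace.ax - np.median(trace.ax)
    dy = trace.ay - np.median(trace.ay)
    dz = trace.az - np.median(trace.az)
    return np.sqrt(dx * dx + dy * dy + dz * dz)


def mean_teager_kaiser(signal: Sequence[float]) -> float:
    """Mean discrete Teager-Kaiser energy ``psi[n] = x[n]^2 - x[n-1] x[n+1]``.

    Averaged over interior samples; a measure of the mean instantaneous
    energy of the signal (units g^2 for an acceleration input).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("Teager-Kaiser energy needs at least 3 samples")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(psi.mean())


def rms(signal: Sequence[float]) -> float:
    """Root mean square of the signal."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of an empty signal is undefined")
    return float(np.sqrt(np.mean(x * x)))


def vdv(signal: Sequence[float], dt: float) -> float:
    """Vibration dose value ``(sum x^4 * dt)^(1/4)``.

    Rectangle-rule discretization of the fourth-power time integral; the
    fourth power makes the metric shock-sensitive. Units g*s^0.25.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("VDV of an empty signal is undefined")
    return float((np.sum(x**4) * dt) ** 0.25)


def count_shocks(signal: Sequence[float], threshold: float = SHOCK_THRESHOLD_G) -> int:
    """Number of maximal contiguous runs strictly above ``threshold``.

    One excursion counts as one shock regardless of how many samples it
    spans, so the count does not inflate with the sampling rate.
    """
    if threshold <= 0:
        raise ValueError("shock threshold must be positive")
    above = np.asarray(signal, dtype=float) > threshold
    if not above.any():
        return 0
    # rising edges: first sample above, or above preceded by not-above
    starts = above & ~np.concatenate(([False], above[:-1]))
    return int(starts.sum())


def _uniform_resample(t: np.ndarray, x: np.ndarray, dt: float) -> np.ndarray:
    """Linear interpolation onto a uniform grid with spacing ``dt``."""
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    return np.interp(grid, t, x)


def ground_frequency(
    trace: AccelTrace,
    window: Optional[Tuple[float, float]] = None,
    fmin: float = 0.2,
) -> float:
    """Dominant Fourier frequency of the dynamic magnitude within a window.

    For walker traces this recovers the gait's ground frequency (about
    4 Hz for a typical adult carrier). The spectrum is taken on the signed,
    gravity-removed axes (magnitude spectra summed over the three axes):
    the rectified Euclidean magnitude would double a pure oscillation's
    frequency, so it is unsuitable here. The search band is
    ``(fmin, Nyquist]``; the lower bound excludes slow drift. The window
    defaults to the most stationary 60 s segment (minimal sliding-window
    RMS variability); explicit windows must span 0.5-3 min.

    Raises
    ------
    NoDominantFrequencyError
        If the windowed signal is constant (no spectral line).
    ValueError
        If the window is outside the trace or has invalid duration.
    """
    t = trace.timestamps
    if window is None:
        window = default_ground_frequency_window(trace)
    start, end = float(window[0]), float(window[1])
    dur = end - start
    if not (30.0 <= dur <= 180.0):
        raise ValueError("ground-frequency window must span 0.5-3 minutes")
    if start < t[0] - trace.dt or end > t[-1] + trace.dt:
        raise ValueError("window lies outside the trace")
    sel = (t >= start) & (t <= end)
    dt = trace.dt
    spec = None
    for axis in (trace.ax, trace.ay, trace.az):
        dyn = axis - np.median(axis)
        x = _uniform_resample(t[sel], dyn[sel], dt)
        x = x - x.mean()
        s = np.abs(np.fft.rfft(x))
        spec = s if spec is None else spec + s
        freqs = np.fft.rfftfreq(x.size, d=dt)
    if np.allclose(spec, 0.0):
        raise NoDominantFrequencyError("windowed signal is constant")
    band = freqs > fmin
    if not band.any():
        raise NoDominantFrequencyError("no frequencies inside the search band")
    idx = np.flatnonzero(band)[np.argmax(spec[band])]
    return float(freqs[idx])


def default_ground_frequency_window(
    trace: AccelTrace, length_seconds: float = 60.0
) -> Tuple[float, float]:
    """Most stationary window: the segment with minimal sliding-RMS variance.

    The trace is scanned with a window of ``length_seconds`` (shrunk to the
    trace duration if shorter, but never below 30 s); within each candidate
    the variance of 1 s-block RMS values measures non-stationarity.
    """
    mag = dynamic_magnitude(trace)
    t = trace.timestamps
    total = trace.duration_seconds
    length = min(length_seconds, total)
    if length < 30.0:
        raise ValueError("trace too short for a ground-frequency window (< 30 s)")
    dt = trace.dt
    x = _uniform_resample(t, mag, dt)
    per_block = max(int(round(1.0 / dt)), 1)
    n_win = int(round(length / dt))
    n_blocks = max(n_win // per_block, 1)
    usable = n_blocks * per_block
    # RMS of each 1 s block over the whole trace, then variance over
    # sliding windows of n_blocks blocks
    n_total_blocks = x.size // per_block
    block_rms = np.sqrt(
        np.mean(x[: n_total_blocks * per_block].reshape(n_total_blocks, per_block) ** 2, axis=1)
    )
    if n_total_blocks <= n_blocks:
        best_start = 0.0
    else:
        variances = [
            float(np.var(block_rms[i : i + n_blocks]))
            for i in range(n_total_blocks - n_blocks + 1)
        ]
        best_start = int(np.argmin(variances)) * per_block * dt
    start = t[0] + best_start
    return (float(start), float(min(start + usable * dt, t[-1])))


def summarize_transport(
    trace: AccelTrace,
    window: Optional[Tuple[float, float]] = None,
    with_ground_frequency: bool = False,
    shock_threshold: float = SHOCK_THRESHOLD_G,
) -> TransportMetrics:
    """All transport metrics of one trace, computed on the dynamic magnitude.

    Ground frequency is only meaningful for oscillation-dominated (carrier)
    traces and is computed on request; shock-dominated pneumatic-tube traces
    leave it absent.
    """
    mag = dynamic_magnitude(trace)
    dt = trace.dt
    gf: Optional[float] = None
    if with_ground_frequency:
        gf = ground_frequency(trace, window)
    return TransportMetrics(
        tk=mean_teager_kaiser(mag),
        rms=rms(mag),
        vdv=vdv(mag, dt),
        duration=trace.duration_seconds / 60.0,
        max_amplitude=float(mag.max()),
        median_amplitude=float(np.median(mag)),
        shock_count=count_shocks(mag, shock_threshold),
        ground_frequency=gf,
    )


def read_trace(path, sample_rate: float = 25.0, clip_limit: float = 16.0) -> AccelTrace:
    """Read a trace CSV with header ``t,ax,ay,az`` (seconds and g)."""
    df = pd.read_csv(path)
    expected = ["t", "ax", "ay", "az"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"trace CSV must start with columns {expected}")
    return AccelTrace(
        timestamps=df["t"].to_numpy(),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        sample_rate=sample_rate,
        clip_limit=clip_limit,
    )


def write_trace(trace: AccelTrace, path) -> None:
    """Write a trace as CSV with header ``t,ax,ay,az``."""
    pd.DataFrame(
        {"t": trace.timestamps, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    ).to_csv(path, index=False)
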