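"""Conditioning of raw activity traces before event analysis.

Neural population traces (e.g. deconvolved calcium, sampled at a few Hz) are
z-scored per neuron and low-pass filtered with a zero-phase Butterworth filter
before any event statistics are computed.  Behavioral traces are used raw:
their events are defined relative to the median of the unprocessed series.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "TimeSeries",
    "zscore",
    "lowpass_zero_phase",
    "preprocess_traces",
    "load_activity",
]


@dataclass(frozen=True)
class TimeSeries:
    """One uniformly sampled real-valued channel.

    Parameters
    ----------
    values : ndarray
        Samples, arbitrary units.  Must be finite and of length >= 2.
    dt : float
        Seconds per sample (> 0).
    label : str
        Channel name, e.g. ``"run_speed"`` or ``"subset_17"``.
    """

    values: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("TimeSeries requires a 1-D array of length >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total recording time in seconds."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        return replace(self, values=values, label=self.label if label is None else label)


def zscore(ts: TimeSeries) -> TimeSeries:
    """Z-score a series: subtract the mean, divide by the population SD.

    The population convention (divisor ``n``) is used so that repeated
    application is exactly idempotent.

    Raises
    ------
    ValueError
        If the series is constant (zero variance).
    """
    v = ts.values
    sd = v.std()  # population convention, ddof=0
    if sd == 0:
        raise ValueError(f"cannot z-score constant series {ts.label!r}: zero variance")
    return ts.with_values((v - v.mean()) / sd)


def lowpass_zero_phase(ts: TimeSeries, cutoff_hz: float = 0.2, order: int = 2) -> TimeSeries:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The forward-backward pass squares the single-pass magnitude response, so
    the effective attenuation at the cutoff frequency is |H|^2 = 1/2.  Edges
    are handled by reflective padding of ``3 * (order + 1)`` samples.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is not inside (0, Nyquist) or ``order`` < 1.
    """
    nyquist = 1.0 / (2.0 * ts.dt)
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / ts.dt, output="sos")
    padlen = min(3 * (order + 1), ts.n - 1)
    out = signal.sosfiltfilt(sos, ts.values, padtype="even", padlen=padlen)
    return ts.with_values(out)


def preprocess_traces(
    activity: np.ndarray,
    dt: float,
    cutoff_hz: float = 0.2,
    order: int = 2,
    zscore_first: bool = True,
) -> np.ndarray:
    """Z-score then low-pass filter each row of a neurons x time matrix.

    ``zscore_first=False`` swaps the order of the two steps (the filtered
    series is then z-scored), exposed because the two conventions differ
    slightly at the edges of the recording.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2:
        raise ValueError("activity must be a neurons x time matrix")
    out = np.empty_like(activity)
    for i, row in enumerate(activity):
        ts = TimeSeries(row, dt=dt, label=f"neuron_{i}")
        if zscore_first:
            out[i] = lowpass_zero_phase(zscore(ts), cutoff_hz, order).values
        else:
            out[i] = zscore(lowpass_zero_phase(ts, cutoff_hz, order)).values
    return out


def load_activity(
    path: str | os.PathLike,
    dt: float = 1.0 / 3.0,
    dataset: str = "activity",
    delimiter: str | None = None,
) -> tuple[np.ndarray, float]:
    """Read a neurons x time activity matrix from delimited text or HDF5.

    CSV/TSV files hold neurons as rows; the delimiter is inferred from the
    extension unless given.  HDF5 files are read from ``dataset``.  The
    sampling interval is metadata supplied by the caller (default 1/3 s,
    i.e. a 3 Hz frame rate).

    Returns
    -------
    (activity, dt)
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            mat = np.asarray(f[dataset], dtype=float)
    else:
        if delimiter is None:
            delimiter = "\t" if ext in {".tsv", ".txt"} else ","
        mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if mat.ndim != 2:
        raise ValueError(f"expected a 2-D matrix in {path}, got shape {mat.shape}")
    return mat, dt
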