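"""Core containers: uniformly sampled physiological traces and capillary RBC trains.

`SignalTrace` holds one uniformly sampled time series (tissue PO2, LFP,
band-limited power, treadmill velocity, thermocouple respiration, ...) together
with its sampling rate and units.  `RBCTrain` holds the passage times of red
blood cells through a single capillary as a point process; inter-RBC intervals
are derived in milliseconds, the unit in which capillary transit statistics are
conventionally reported.

Traces round-trip through a two-column CSV (time_s, value) with a JSON sidecar
carrying {sampling_rate, units, ground_truth}, or through a single HDF5 file
mirroring the same schema.  Event trains are a single-column CSV of event
times in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = [
    "SignalTrace",
    "RBCTrain",
    "read_trace_csv",
    "read_trace_hdf5",
    "read_train_csv",
]


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled time series.

    Parameters
    ----------
    values : ndarray of shape (n,)
        Sample values; must be finite and of length >= 2.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    units : str
        Physical units of the samples (e.g. ``"mmHg"``, ``"uV"``, ``"cm/s"``).
    t0 : float
        Time of the first sample, seconds.
    meta : dict
        Free-form metadata (ground truth for synthetic traces, provenance).
    """

    values: np.ndarray
    sampling_rate: float
    units: str = ""
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("SignalTrace values must be one-dimensional")
        if values.size < 2:
            raise ValueError("SignalTrace needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("SignalTrace values must be finite")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n samples at fs => n/fs)."""
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def with_values(self, values: np.ndarray, **overrides: Any) -> "SignalTrace":
        kwargs: dict[str, Any] = dict(
            sampling_rate=self.sampling_rate, units=self.units, t0=self.t0,
            meta=dict(self.meta),
        )
        kwargs.update(overrides)
        return SignalTrace(np.asarray(values, dtype=float), **kwargs)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write (time_s, value) CSV plus a JSON sidecar with rate/units/meta."""
        path = Path(path)
        arr = np.column_stack([self.times, self.values])
        header = "time_s,value"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        if sidecar:
            side = {
                "sampling_rate": self.sampling_rate,
                "units": self.units,
                "t0": self.t0,
                "ground_truth": _jsonable(self.meta),
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(side, indent=2))

    def to_hdf5(self, path: str | Path, key: str = "trace") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            if key in f:
                del f[key]
            g = f.create_group(key)
            g.create_dataset("values", data=self.values)
            g.attrs["sampling_rate"] = self.sampling_rate
            g.attrs["units"] = self.units
            g.attrs["t0"] = self.t0
            g.attrs["meta_json"] = json.dumps(_jsonable(self.meta))


def read_trace_csv(path: str | Path) -> SignalTrace:
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        fs = float(side["sampling_rate"])
        units = side.get("units", "")
        t0 = float(side.get("t0", t[0]))
        meta = side.get("ground_truth") or {}
    else:
        dt = np.median(np.diff(t))
        fs, units, t0, meta = 1.0 / dt, "", float(t[0]), {}
    return SignalTrace(v, sampling_rate=fs, units=units, t0=t0, meta=meta)


def read_trace_hdf5(path: str | Path, key: str = "trace") -> SignalTrace:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[key]
        return SignalTrace(
            g["values"][:],
            sampling_rate=float(g.attrs["sampling_rate"]),
            units=str(g.attrs.get("units", "")),
            t0=float(g.attrs.get("t0", 0.0)),
            meta=json.loads(g.attrs.get("meta_json", "{}")),
        )


MIN_INTERVAL_MS = 10.0  # intervals below the RBC transit floor are unphysical


@dataclass(frozen=True)
class RBCTrain:
    """Passage times of RBCs through one capillary (a point process).

    Event times are seconds, strictly increasing.  Intervals are exposed in
    milliseconds.  Intervals shorter than 10 ms are rejected: at capillary
    velocities of 0.3-1 mm/s an ~7 um erythrocyte cannot clear the
    measurement point faster than that.
    """

    event_times: np.ndarray
    capillary_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("RBCTrain needs at least 2 events")
        d = np.diff(t)
        if np.any(d <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(d * 1000.0 < MIN_INTERVAL_MS - 1e-9):
            raise ValueError(
                f"inter-RBC intervals below {MIN_INTERVAL_MS} ms are not allowed")
        object.__setattr__(self, "event_times", t)

    @classmethod
    def from_intervals_ms(cls, intervals_ms: np.ndarray, t0: float = 0.0,
                          **kwargs: Any) -> "RBCTrain":
        times = t0 + np.cumsum(np.asarray(intervals_ms, dtype=float)) / 1000.0
        return cls(times, **kwargs)

    @property
    def n_events(self) -> int:
        return self.event_times.size

    @property
    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.event_times) * 1000.0

    @property
    def duration(self) -> float:
        return float(self.event_times[-1] - self.event_times[0])

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.event_times, delimiter=",",
                   header="event_time_s", comments="")


def read_train_csv(path: str | Path, **kwargs: Any) -> RBCTrain:
    times = np.loadtxt(path, delimiter=",", skiprows=1)
    return RBCTrain(np.atleast_1d(times), **kwargs)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
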