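"""Uniformly sampled scalar time signals and their CSV round trip.

A :class:`TimeTrace` is the basic currency of the pipeline: pressures in
mmHg, flows in mL/s, valve areas in cm^2, all sampled on a uniform grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class TimeTrace:
    """A scalar signal sampled on a uniform time grid.

    Parameters
    ----------
    t : array of sample times, s, uniformly spaced.
    value : array of samples, in ``units``.
    units : unit string carried for I/O sidecars (not enforced).
    meta : free-form metadata (cycle time, condition label, ...).
    """

    t: np.ndarray
    value: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.value.shape:
            raise ValueError("t and value must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if dt.min() <= 0:
                raise ValueError("time grid must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("trace too short to define dt")
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    def copy(self) -> "TimeTrace":
        return TimeTrace(self.t.copy(), self.value.copy(), self.units, dict(self.meta))

    def same_grid(self, other: "TimeTrace", rtol: float = 1e-9) -> bool:
        return self.t.shape == other.t.shape and np.allclose(self.t, other.t, rtol=rtol, atol=1e-12)

    def integral(self) -> float:
        """Trapezoidal integral over the full trace."""
        return float(np.trapezoid(self.value, self.t))

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write as 2-column CSV (time_s, value) plus a JSON units sidecar."""
        path = Path(path)
        arr = np.column_stack([self.t, self.value])
        np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="")
        if sidecar:
            side = {"units": self.units, "meta": self.meta}
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeTrace":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        units, meta = "", {}
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            d = json.loads(side.read_text())
            units, meta = d.get("units", ""), d.get("meta", {})
        return cls(arr[:, 0], arr[:, 1], units, meta)


def uniform_grid(duration: float, dt: float, t0: float = 0.0) -> np.ndarray:
    """Uniform sample times covering [t0, t0 + duration) at spacing dt."""
    n = int(round(duration / dt))
    return t0 + dt * np.arange(n)
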