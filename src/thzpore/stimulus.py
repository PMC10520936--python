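"""THz unipolar picosecond pulse-train stimulus.

The applied field is a train of same-sign (unipolar) rectangular pulses of
amplitude ``E0`` at repetition frequency ``f_rep`` with duty cycle ``duty``,
truncated exactly at the stimulation duration ``t_on``.  An optional
raised-cosine edge smooths the steps for explicit time-stepping; the ideal
rectangular envelope is the default.  Because the duty cycle fixes the
on-fraction, the delivered field-time integral over ``t_on`` is independent
of the repetition frequency (to within one pulse width).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PulseTrain:
    E0: float = 5.0e7  # V/m peak field
    f_rep: float = 0.5e12  # Hz repetition frequency
    duty: float = 0.5  # on-fraction of each period
    t_on: float = 1.2e-9  # s stimulation duration
    envelope: str = "rectangular"  # or "raised-cosine"
    edge_fraction: float = 0.1  # of the pulse width, per edge (raised-cosine)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)  # polar axis

    def __post_init__(self) -> None:
        if self.E0 < 0:
            raise ValueError("E0 must be >= 0")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")
        if self.f_rep <= 0:
            raise ValueError("f_rep must be > 0")
        if self.t_on <= 0:
            raise ValueError("t_on must be > 0")
        if self.envelope not in ("rectangular", "raised-cosine"):
            raise ValueError(f"unknown envelope {self.envelope!r}")

    @property
    def period(self) -> float:
        return 1.0 / self.f_rep


def pulse_width(train: PulseTrain) -> float:
    """Width of each unipolar pulse: duty / f_rep (seconds)."""
    return train.duty / train.f_rep


def field_at(train: PulseTrain, t):
    """Applied field magnitude E(t) in V/m (scalar or array argument).

    E0 during the on-fraction of each period while t < t_on, zero otherwise;
    never negative (unipolar).  Raises for t < 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    phase = np.mod(t_arr, train.period) * train.f_rep  # in [0, 1)
    if train.envelope == "rectangular":
        on = (phase < train.duty).astype(float)
    else:
        e = train.edge_fraction * train.duty
        on = np.ones_like(phase)
        rise = phase < e
        on = np.where(rise, 0.5 * (1 - np.cos(math.pi * phase / e)), on)
        fall = (phase >= train.duty - e) & (phase < train.duty)
        on = np.where(
            fall, 0.5 * (1 + np.cos(math.pi * (phase - (train.duty - e)) / e)), on
        )
        on = np.where(phase >= train.duty, 0.0, on)
    out = train.E0 * on * (t_arr < train.t_on)
    return out if out.ndim else float(out)


def delivered_integral(train: PulseTrain, n: int = 200_001) -> float:
    """Numerical time-integral of E(t) over [0, t_on] (V s / m)."""
    t = np.linspace(0.0, train.t_on, n)
    return float(np.trapezoid(field_at(train, t), t))


def waveform(train: PulseTrain, dt: float, t_end: float | None = None):
    """(t, E) sampled arrays, e.g. for CSV export or plotting."""
    t_end = train.t_on if t_end is None else t_end
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    return t, field_at(train, t)
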