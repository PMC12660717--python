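"""Input signals: HIF-1 (or oxygen) schedules and continuous HIF-1 dynamics.

The reference experimental protocol exposes cells sequentially to
normoxia, stable hypoxia, and cycling hypoxia.  In the dimensionless
model the HIF-1 level is 0 in normoxia and 1 in hypoxia; cycling hypoxia
is a square wave of 1 h hypoxia followed by 0.5 h normoxia (period
1.5 h, duty-cycle mean 2/3).  The default schedule spans t in [-15, 30]
hours: normoxia on [-15, 0), stable hypoxia on [0, 15), and the square
wave on [15, 30).

Intervals are closed on the left and open on the right, so the signal is
right-continuous at every switch.  ``simulate_hif`` additionally offers
a continuous HIF-1 relaxation model driven by an oxygen schedule, with
constant production and oxygen-stimulated (PHD-like) degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Segment",
    "Protocol",
    "HifDynParams",
    "default_nho_protocol",
    "default_o2_protocol",
    "signal_value",
    "simulate_hif",
]


@dataclass(frozen=True)
class Segment:
    """One protocol segment: constant level or square-wave alternation.

    In oscillating mode the segment starts in its high phase
    (``level_high`` for ``period_high`` time units) then drops to
    ``level_low`` for ``period_low``, repeating from ``t_start``.
    """

    t_start: float
    t_end: float
    mode: str = "constant"  # "constant" | "oscillating"
    level_high: float = 1.0
    level_low: float = 0.0
    period_high: float = 1.0
    period_low: float = 0.5

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("segment requires t_start < t_end")
        if self.mode not in ("constant", "oscillating"):
            raise ValueError(f"unknown segment mode {self.mode!r}")
        if self.mode == "oscillating" and (self.period_high <= 0 or self.period_low <= 0):
            raise ValueError("oscillating segment requires positive phase durations")

    def value(self, t: float) -> float:
        if self.mode == "constant":
            return self.level_high
        phase = (t - self.t_start) % (self.period_high + self.period_low)
        return self.level_high if phase < self.period_high else self.level_low

    def switch_times(self) -> list[float]:
        """Interior discontinuity times, in increasing order."""
        if self.mode == "constant":
            return []
        times = []
        period = self.period_high + self.period_low
        t = self.t_start
        while t < self.t_end:
            for dt in (self.period_high, self.period_low):
                t += dt
                if self.t_start < t < self.t_end:
                    times.append(t)
            if dt <= 0:  # pragma: no cover - guarded in __post_init__
                break
        return times


@dataclass(frozen=True)
class Protocol:
    """An ordered, contiguous list of segments defining the input level."""

    segments: tuple[Segment, ...]

    def __init__(self, segments: Sequence[Segment]):
        segments = tuple(segments)
        if not segments:
            raise ValueError("protocol needs at least one segment")
        for a, b in zip(segments, segments[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ValueError(
                    f"segments must be contiguous: {a.t_end} != {b.t_start}"
                )
        object.__setattr__(self, "segments", segments)

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0].t_start, self.segments[-1].t_end

    def value(self, t: float) -> float:
        t0, t1 = self.span
        if t < t0 or t > t1:
            raise ValueError(f"t={t} outside protocol span [{t0}, {t1}]")
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg.value(t)
        return self.segments[-1].value(t)  # t == t1: extend last segment

    def breakpoints(self) -> np.ndarray:
        """All discontinuity times including segment boundaries and span ends."""
        pts = {self.span[0], self.span[1]}
        for seg in self.segments:
            pts.add(seg.t_start)
            pts.update(seg.switch_times())
        return np.array(sorted(pts))

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "mode": s.mode,
                 "level_high": s.level_high, "level_low": s.level_low,
                 "period_high": s.period_high, "period_low": s.period_low}
                for s in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls([Segment(**s) for s in d["segments"]])


def signal_value(protocol: Protocol, t: float) -> float:
    """Input level at time t; right-continuous at switches."""
    return protocol.value(t)


def default_nho_protocol(
    t_start: float = -15.0,
    t_switch_h: float = 0.0,
    t_switch_o: float = 15.0,
    t_end: float = 30.0,
    period_high: float = 1.0,
    period_low: float = 0.5,
) -> Protocol:
    """The sequential normoxia -> hypoxia -> cycling-hypoxia HIF schedule.

    HIF is 0 on [-15, 0) (normoxia), 1 on [0, 15) (stable hypoxia), and a
    1 h on / 0.5 h off square wave on [15, 30) (cycling hypoxia).
    """
    return Protocol([
        Segment(t_start, t_switch_h, "constant", level_high=0.0),
        Segment(t_switch_h, t_switch_o, "constant", level_high=1.0),
        Segment(t_switch_o, t_end, "oscillating", level_high=1.0, level_low=0.0,
                period_high=period_high, period_low=period_low),
    ])


def default_o2_protocol(**kwargs) -> Protocol:
    """Oxygen-level counterpart of the default schedule (1 = normoxic O2).

    Normoxia is O2=1, hypoxia O2=0; in the cycling segment the hypoxic
    (O2 low) phase comes first, mirroring the HIF schedule.
    """
    hif = default_nho_protocol(**kwargs)
    segs = []
    for s in hif.segments:
        if s.mode == "constant":
            segs.append(Segment(s.t_start, s.t_end, "constant",
                                level_high=1.0 - s.level_high))
        else:
            # hypoxic phase first: O2 low for period_high, then high
            segs.append(Segment(s.t_start, s.t_end, "oscillating",
                                level_high=0.0, level_low=1.0,
                                period_high=s.period_high, period_low=s.period_low))
    return Protocol(segs)


@dataclass(frozen=True)
class HifDynParams:
    """Continuous HIF-1 model: production minus oxygen-stimulated decay.

    dHIF/dt = beta_h - (alpha_0 + alpha_1 * hill(O2; k_o2, m)) * HIF

    where hill(x; k, m) = (x/k)^m / (1 + (x/k)^m).  With the defaults the
    hypoxic (O2=0) fixed point is HIF = 1 and the normoxic fixed point is
    ~0.1, relaxing on sub-hour timescales.
    """

    beta_h: float = 1.0
    alpha_0: float = 1.0
    alpha_1: float = 10.0
    k_o2: float = 0.5
    m: float = 2.0

    def __post_init__(self) -> None:
        if min(self.beta_h, self.alpha_0, self.alpha_1) < 0:
            raise ValueError("rates must be nonnegative")
        if self.k_o2 <= 0:
            raise ValueError("k_o2 must be positive")
        if self.m < 1:
            raise ValueError("Hill exponent m must be >= 1")

    def degradation(self, o2: float) -> float:
        u = (o2 / self.k_o2) ** self.m
        return self.alpha_0 + self.alpha_1 * u / (1.0 + u)


def simulate_hif(
    o2_protocol: Protocol,
    params: HifDynParams = HifDynParams(),
    grid: np.ndarray | None = None,
    hif0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate continuous HIF-1 dynamics driven by an oxygen schedule.

    The ODE is linear within each constant-O2 stretch; the integrator is
    restarted at every protocol discontinuity so switches are never
    interpolated across.  Returns (times, hif) sampled on ``grid``
    (default: step 0.05 over the protocol span).
    """
    t0, t1 = o2_protocol.span
    if grid is None:
        grid = np.round(np.arange(t0, t1 + 0.05 / 2, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < t0 - 1e-12 or grid[-1] > t1 + 1e-12:
        raise ValueError("grid extends outside the protocol span")

    brk = o2_protocol.breakpoints()
    out = np.empty_like(grid)
    state = float(hif0)
    for lo, hi in zip(brk[:-1], brk[1:]):
        o2 = o2_protocol.value(lo)
        deg = params.degradation(o2)

        def rhs(t, y, _deg=deg):
            return params.beta_h - _deg * y

        mask = (grid > lo) & (grid <= hi) if lo > brk[0] else (grid >= lo) & (grid <= hi)
        t_eval = grid[mask]
        sol = solve_ivp(rhs, (lo, hi), [state], t_eval=t_eval if t_eval.size else None,
                        rtol=rtol, atol=atol, method="RK45")
        if not sol.success:
            raise RuntimeError(f"HIF integration failed near t={lo}: {sol.message}")
        if t_eval.size:
            out[mask] = sol.y[0]
        state = float(sol.y[0, -1])
    if np.isclose(grid[0], t0):
        out[0] = hif0
    return grid, np.maximum(out, 0.0)
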