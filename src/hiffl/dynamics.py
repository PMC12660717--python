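"""ODE models of HIF-1-driven incoherent feed-forward loops.

Each circuit has three species: the input HIF (a prescribed dimensionless
level, 0 in normoxia and 1 in hypoxia), an intermediary transcription
factor TF, and the Target gene product.  Transcriptional regulation is
Hill-type with shared cooperativity ``n_hill``; the HIF-facing edges
(HIF->TF and HIF->Target) share the dissociation constant ``k_h`` and
the TF->Target edge uses ``k_tf``.

For the type 3 loop (HIF activates TF, TF activates Target, HIF
represses Target) the equations are

    dTF/dt     = beta_tf * h+(HIF; k_h) - alpha_tf * TF
    dTarget/dt = beta_t * (h+(TF; k_tf) + A) * h-(HIF; k_h)
                 - alpha_t * Target                       [multiplicative]
    dTarget/dt = beta_t * (h+(TF; k_tf) + A * h-(HIF; k_h))
                 - alpha_t * Target                       [additive]

with h+(x; k) = (x/k)^n / (1 + (x/k)^n), h- = 1 - h+, and A the
TF-independent activation weight (``a_target``).  The other three loop
types replace each Hill term by the activating or repressing form
dictated by the type's sign triple (X->Y, Y->Z, X->Z); multiplicative
mode composes the direct HIF term with the whole production rate
(transcriptional synergy), additive mode gives HIF an independent
regulatory element weighted by A.

Loop sign triples: type 1 (+, -, +), type 2 (-, -, -), type 3 (+, +, -),
type 4 (-, +, +).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .signals import Protocol, default_nho_protocol

logger = logging.getLogger(__name__)

__all__ = [
    "IFFL_SIGN_TRIPLES",
    "IFFLParams",
    "CircuitSpec",
    "Trajectory",
    "hill_act",
    "hill_rep",
    "derivatives",
    "simulate",
    "steady_state",
    "response_curve",
]

#: (X->Y, Y->Z, X->Z) sign triple of each incoherent loop type.
IFFL_SIGN_TRIPLES = {
    1: (+1, -1, +1),
    2: (-1, -1, -1),
    3: (+1, +1, -1),
    4: (-1, +1, +1),
}

_NEG_STATE_TOL = 1e-9


def hill_act(x, k, n):
    """Activating Hill response u/(1+u) with u = (x/k)^n; in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be nonnegative")
    if np.any(np.asarray(k) <= 0):
        raise ValueError("dissociation constant must be positive")
    u = (x / k) ** n
    return u / (1.0 + u)


def hill_rep(x, k, n):
    """Repressing Hill response 1/(1+u); complement of hill_act."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be nonnegative")
    if np.any(np.asarray(k) <= 0):
        raise ValueError("dissociation constant must be positive")
    u = (x / k) ** n
    return 1.0 / (1.0 + u)


def _hill(sign: int, x, k, n):
    return hill_act(x, k, n) if sign > 0 else hill_rep(x, k, n)


@dataclass(frozen=True)
class IFFLParams:
    """Rate and affinity parameters of one loop instance.

    Production/degradation rates default to 1 (dimensionless time in
    hours, expression in arbitrary units); ``n_hill`` defaults to 3
    (cooperative binding) and ``a_target`` to 1.0 (TF-independent
    activation weighted like the TF-driven arm).  At these defaults the
    (K_H, K_TF) phase diagrams of the type 3 loop exhibit every N/H/O
    ordering in both inhibition modes; see the methods note.
    """

    beta_tf: float = 1.0
    alpha_tf: float = 1.0
    beta_target: float = 1.0
    alpha_target: float = 1.0
    k_h: float = 0.5
    k_tf: float = 0.5
    a_target: float = 1.0
    n_hill: float = 3.0

    def __post_init__(self) -> None:
        if self.k_h <= 0 or self.k_tf <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.alpha_tf <= 0 or self.alpha_target <= 0:
            raise ValueError("degradation rates must be positive")
        if self.beta_tf < 0 or self.beta_target < 0 or self.a_target < 0:
            raise ValueError("production weights must be nonnegative")
        if self.n_hill < 1:
            raise ValueError("Hill coefficient must be >= 1")


@dataclass(frozen=True)
class CircuitSpec:
    """One IFFL instance: loop type (1-4), inhibition mode, parameters."""

    iffl_type: int = 3
    mode: str = "multiplicative"
    params: IFFLParams = field(default_factory=IFFLParams)

    def __post_init__(self) -> None:
        if self.iffl_type not in IFFL_SIGN_TRIPLES:
            raise ValueError(f"iffl_type must be 1-4, got {self.iffl_type}")
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError(f"mode must be multiplicative or additive, got {self.mode!r}")

    @property
    def signs(self) -> tuple[int, int, int]:
        return IFFL_SIGN_TRIPLES[self.iffl_type]

    def with_params(self, **kwargs) -> "CircuitSpec":
        return replace(self, params=replace(self.params, **kwargs))


@dataclass(frozen=True)
class Trajectory:
    """Sampled time courses of HIF, TF and Target on a common grid."""

    times: np.ndarray
    hif: np.ndarray
    tf: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.hif) == len(self.tf) == len(self.target) == n):
            raise ValueError("trajectory arrays must share one grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "hif": self.hif, "tf": self.tf, "target": self.target}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _production_terms(tf, hif, spec_signs, mode, k_h, k_tf, a_target, n):
    """(f_xy, target production factor) for the given sign triple and mode."""
    s_xy, s_yz, s_xz = spec_signs
    f_ind = _hill(s_yz, tf, k_tf, n)
    f_dir = _hill(s_xz, hif, k_h, n)
    if mode == "multiplicative":
        prod = (f_ind + a_target) * f_dir
    else:
        prod = f_ind + a_target * f_dir
    return _hill(s_xy, hif, k_h, n), prod


def derivatives(state: Sequence[float], hif: float, spec: CircuitSpec):
    """(dTF/dt, dTarget/dt) at the given state and HIF level."""
    tf, target = state
    if np.any(np.asarray(tf) < 0) or np.any(np.asarray(target) < 0):
        raise ValueError("state must be nonnegative")
    if hif < 0:
        raise ValueError("HIF level must be nonnegative")
    p = spec.params
    f_xy, prod = _production_terms(
        tf, hif, spec.signs, spec.mode, p.k_h, p.k_tf, p.a_target, p.n_hill
    )
    dtf = p.beta_tf * f_xy - p.alpha_tf * tf
    dtarget = p.beta_target * prod - p.alpha_target * target
    return dtf, dtarget


def _integrate_piecewise(
    protocol: Protocol,
    grid: np.ndarray,
    signs: tuple[int, int, int],
    mode: str,
    k_h: np.ndarray,
    k_tf: np.ndarray,
    base: IFFLParams,
    init: tuple[float, float],
    rtol: float,
    atol: float,
):
    """Integrate the loop ODEs, vectorized over broadcast (k_h, k_tf) arrays.

    The input is piecewise-constant; the integrator is restarted at every
    protocol breakpoint so the discontinuities are never stepped across.
    Returns tf, target arrays of shape (len(grid),) + broadcast shape.
    """
    k_h, k_tf = np.broadcast_arrays(np.asarray(k_h, float), np.asarray(k_tf, float))
    shape = k_h.shape
    m = int(np.prod(shape)) if shape else 1
    kh_flat = k_h.reshape(m)
    ktf_flat = k_tf.reshape(m)
    n = base.n_hill
    a = base.a_target

    tf_out = np.empty((len(grid), m))
    tgt_out = np.empty((len(grid), m))
    state = np.concatenate(
        [np.full(m, float(init[0])), np.full(m, float(init[1]))]
    )

    brk = protocol.breakpoints()
    t0 = brk[0]
    covered = np.zeros(len(grid), dtype=bool)
    for lo, hi in zip(brk[:-1], brk[1:]):
        hif = protocol.value(lo)
        f_xy = _hill(signs[0], hif, kh_flat, n)
        f_dir = _hill(signs[2], hif, kh_flat, n)
        prod_tf = base.beta_tf * f_xy

        def rhs(t, y):
            tf = y[:m]
            tgt = y[m:]
            f_ind = _hill(signs[1], np.maximum(tf, 0.0), ktf_flat, n)
            if mode == "multiplicative":
                prod = (f_ind + a) * f_dir
            else:
                prod = f_ind + a * f_dir
            return np.concatenate([
                prod_tf - base.alpha_tf * tf,
                base.beta_target * prod - base.alpha_target * tgt,
            ])

        if np.isclose(lo, t0):
            mask = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
        else:
            mask = (grid > lo + 1e-12) & (grid <= hi + 1e-12)
        mask &= ~covered
        t_eval = grid[mask]
        sol = solve_ivp(rhs, (lo, hi), state,
                        t_eval=t_eval if t_eval.size else None,
                        rtol=rtol, atol=atol, method="RK45")
        if not sol.success:
            raise RuntimeError(f"integration failed near t={lo}: {sol.message}")
        if t_eval.size:
            tf_out[mask] = sol.y[:m].T
            tgt_out[mask] = sol.y[m:].T
            covered |= mask
        state = sol.y[:, -1].copy()

    for arr, name in ((tf_out, "TF"), (tgt_out, "Target")):
        low = arr.min()
        if low < -_NEG_STATE_TOL:
            logger.warning("%s undershot to %.3e; clipping to 0", name, low)
        np.clip(arr, 0.0, None, out=arr)
    return tf_out.reshape((len(grid),) + shape), tgt_out.reshape((len(grid),) + shape)


def simulate(
    spec: CircuitSpec,
    protocol: Protocol | None = None,
    init: tuple[float, float] = (0.0, 0.0),
    grid_step: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate one circuit over a protocol, sampled on a uniform grid.

    Defaults reproduce the reference setup: the sequential N->H->O
    protocol over [-15, 30] at step 0.05 (901 samples) from zero initial
    TF and Target.  The integrator restarts at every input discontinuity.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if min(init) < 0:
        raise ValueError("initial state must be nonnegative")
    if protocol is None:
        protocol = default_nho_protocol()
    t0, t1 = protocol.span
    npts = int(round((t1 - t0) / grid_step)) + 1
    grid = np.linspace(t0, t1, npts)
    tf, tgt = _integrate_piecewise(
        protocol, grid, spec.signs, spec.mode,
        np.asarray(spec.params.k_h), np.asarray(spec.params.k_tf),
        spec.params, init, rtol, atol,
    )
    hif = np.array([protocol.value(t) for t in grid])
    return Trajectory(times=grid, hif=hif, tf=tf, target=tgt)


def steady_state(spec: CircuitSpec, hif_const: float):
    """Closed-form fixed point (TF*, Target*) under constant HIF.

    TF* = (beta_tf/alpha_tf) * h_xy(HIF); Target* follows by inserting
    TF* into the mode's production law and dividing by alpha_target.
    ``hif_const`` may be an array, in which case both outputs broadcast.
    """
    hif_const = np.asarray(hif_const, dtype=float)
    if np.any(hif_const < 0):
        raise ValueError("HIF level must be nonnegative")
    p = spec.params
    f_xy, _ = _production_terms(0.0, hif_const, spec.signs, spec.mode,
                                p.k_h, p.k_tf, p.a_target, p.n_hill)
    tf_ss = p.beta_tf / p.alpha_tf * f_xy
    _, prod = _production_terms(tf_ss, hif_const, spec.signs, spec.mode,
                                p.k_h, p.k_tf, p.a_target, p.n_hill)
    tgt_ss = p.beta_target / p.alpha_target * prod
    if hif_const.ndim == 0:
        return float(tf_ss), float(tgt_ss)
    return tf_ss, tgt_ss


def response_curve(
    spec: CircuitSpec,
    hif_levels: Sequence[float],
    rel_tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Steady-state Target* across HIF levels, with a non-monotonicity flag.

    The flag is True when some interior level's Target* exceeds both
    endpoint values (or undercuts both) by more than ``rel_tol`` times
    the curve maximum — the signature of a circuit tuned to intermediate
    (time-averaged) hypoxic signal rather than to either extreme.
    """
    levels = np.atleast_1d(np.asarray(hif_levels, dtype=float))
    if levels.size == 0:
        raise ValueError("hif_levels must be non-empty")
    _, targets = steady_state(spec, levels)
    targets = np.atleast_1d(targets)
    if levels.size < 3:
        return targets, False
    scale = float(targets.max()) if targets.max() > 0 else 1.0
    hi = max(targets[0], targets[-1])
    lo = min(targets[0], targets[-1])
    interior = targets[1:-1]
    non_monotonic = bool(
        np.any(interior > hi + rel_tol * scale) or np.any(interior < lo - rel_tol * scale)
    )
    return targets, non_monotonic
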