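"""Independent reference implementations used only by the tests.

These deliberately avoid the package's integration and enumeration code
paths: a fixed-step classical RK4 integrator with exact restarts at the
input discontinuities, an O(n^3) brute-force feed-forward-loop search,
and a plain-summation window average.
"""

from __future__ import annotations

import numpy as np


def rk4_piecewise(rhs_factory, protocol, y0, grid, dt=1e-3):
    """Fixed-step RK4 over a piecewise-constant input protocol.

    ``rhs_factory(hif_level)`` returns f(y) for that constant input; the
    stepper is restarted at every protocol breakpoint and never steps
    across a discontinuity.  Returns states sampled at ``grid`` (which
    must be a subset of breakpoint-aligned multiples of dt).
    """
    grid = np.asarray(grid, dtype=float)
    out = np.empty((len(grid), len(y0)))
    y = np.array(y0, dtype=float)
    brk = protocol.breakpoints()
    gi = 0
    if np.isclose(grid[0], brk[0]):
        out[0] = y
        gi = 1
    for lo, hi in zip(brk[:-1], brk[1:]):
        f = rhs_factory(protocol.value(lo))
        n_steps = max(1, int(round((hi - lo) / dt)))
        h = (hi - lo) / n_steps
        t = lo
        for _ in range(n_steps):
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            while gi < len(grid) and grid[gi] <= t + 1e-9:
                out[gi] = y
                gi += 1
    while gi < len(grid):  # numerical stragglers at the very end
        out[gi] = y
        gi += 1
    return out


def brute_force_ffls(edges, master):
    """All (master, y, z) triples closed by the three FFL edges.

    ``edges`` is a dict (source, target) -> sign.  Returns a sorted list
    of (y, z, sign_xy, sign_yz, sign_xz).
    """
    nodes = sorted({n for e in edges for n in e})
    found = []
    for y in nodes:
        for z in nodes:
            if len({master, y, z}) != 3:
                continue
            if (master, y) in edges and (y, z) in edges and (master, z) in edges:
                found.append((y, z, edges[(master, y)], edges[(y, z)], edges[(master, z)]))
    return sorted(found)


def window_mean(times, values, lo, hi):
    """Plain-loop mean of values with lo < t <= hi."""
    total, n = 0.0, 0
    for t, v in zip(times, values):
        if lo + 1e-12 < t <= hi + 1e-12:
            total += v
            n += 1
    return total / n
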