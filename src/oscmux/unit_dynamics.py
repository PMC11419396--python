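"""Single-node activation/refraction dynamics with pulsed inhibition.

Each hidden node carries two state variables: the activation h and a slower
refraction variable r that tracks c*h and opposes it, yielding self-sustained
relaxation oscillations for sufficiently strong constant input z:

    tau_h dh/dt = -h + sigma((z - r - alpha(t) + h) / s)
    tau_r dr/dt = -r + c * h

The scale s sharpens the sigmoid (small s -> step-like response); alpha(t) is
a rhythmic inhibitory drive

    alpha(t) = m * (1 + sin(2 pi f t + phase))

mimicking occipital alpha oscillations (default f = 10 Hz).  With
tau_h = 0.01 s, tau_r = 0.1 s, c = 10 and s = 0.1 the free-running node
oscillates in the 7-13 Hz band and entrains exactly to a 10 Hz drive of
amplitude m = 0.5.

Integration is explicit forward Euler at dt = 0.001 s throughout.

Fixed points satisfy

    h* = z/(c-1) + s/(c-1) * [log(1/h* - 1)/a - b],   r* = c h*

and for s << 1 reduce to h* ~ z/(c-1); they are found numerically by
bracketed root solving (the right-hand side of h = sigma((z-(c-1)h)/s) is
strictly decreasing in h for c > 1, so the root is unique in (0,1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .static_network import SigmoidParams, shifted_sigmoid

DT_DEFAULT = 0.001  # s, forward-Euler step


@dataclass(frozen=True)
class NodeParams:
    """ODE constants for one hidden node (shared network-wide)."""

    tau_h: float = 0.01  # s — activation time scale
    tau_r: float = 0.1   # s — refraction time scale
    c: float = 10.0      # refraction gain (r tracks c*h)
    s: float = 0.1       # input scale inside the sigmoid
    sigmoid: SigmoidParams = SigmoidParams()

    def __post_init__(self) -> None:
        if self.tau_h <= 0 or self.tau_r <= 0:
            raise ValueError("time constants must be positive")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")


@dataclass(frozen=True)
class InhibitionParams:
    """Oscillatory inhibitory drive alpha(t) = m (1 + sin(2 pi f t + phase))."""

    m: float = 0.0       # amplitude; alpha in [0, 2m]
    f: float = 10.0      # Hz
    phase: float = 0.0   # radians; generalises a per-layer delay

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")

    @property
    def period(self) -> float:
        if self.f <= 0:
            raise ValueError("period undefined for f <= 0")
        return 1.0 / self.f


def alpha_drive(t, p: InhibitionParams):
    """Evaluate the inhibition waveform; always within [0, 2m]."""
    return p.m * (1.0 + np.sin(2.0 * np.pi * p.f * np.asarray(t, dtype=float) + p.phase))


@dataclass
class NodeState:
    """Activation and refraction of one node (or vectors of nodes)."""

    h: np.ndarray | float = 0.0
    r: np.ndarray | float = 0.0


def node_step(
    state: NodeState,
    z,
    t: float,
    dt: float,
    p: NodeParams,
    inh: InhibitionParams = InhibitionParams(),
) -> NodeState:
    """One explicit forward-Euler update, both variables from the pre-step state.

    Vectorised: ``state.h``/``state.r``/``z`` may be arrays of equal shape.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    h, r = np.asarray(state.h, dtype=float), np.asarray(state.r, dtype=float)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(r))):
        raise FloatingPointError("non-finite node state")
    drive = shifted_sigmoid((z - r - alpha_drive(t, inh) + h) / p.s, p.sigmoid)
    h_new = h + (dt / p.tau_h) * (-h + drive)
    r_new = r + (dt / p.tau_r) * (-r + p.c * h)
    return NodeState(h=h_new, r=r_new)


@dataclass
class Trace:
    """Uniform-grid time series from a single-node simulation."""

    dt: float
    t: np.ndarray
    h: np.ndarray
    r: np.ndarray
    alpha: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "h": self.h, "r": self.r, "alpha": self.alpha})


def simulate_node(
    z: float,
    duration: float,
    p: NodeParams = NodeParams(),
    inh: InhibitionParams = InhibitionParams(),
    init: NodeState | None = None,
    dt: float = DT_DEFAULT,
) -> Trace:
    """Integrate one node under constant input z for ``duration`` seconds."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    state = init if init is not None else NodeState(0.0, 0.0)
    h = np.empty(n)
    r = np.empty(n)
    for k in range(n):
        h[k] = state.h
        r[k] = state.r
        state = node_step(state, z, t[k], dt, p, inh)
    return Trace(dt=dt, t=t, h=h, r=r, alpha=alpha_drive(t, inh))


@dataclass(frozen=True)
class FixedPoint:
    """Numeric equilibrium (h*, r* = c h*) plus the small-s approximation."""

    h_star: float
    r_star: float
    residual: float
    h_approx: float
    r_approx: float


def fixed_point_approx(z: float, c: float) -> tuple[float, float]:
    """Small-s approximation h* ~ z/(c-1), r* ~ c z/(c-1)."""
    if c <= 1:
        raise ValueError("approximation requires c > 1")
    h = z / (c - 1.0)
    return h, c * h


def solve_fixed_point(z: float, p: NodeParams = NodeParams()) -> FixedPoint:
    """Numeric root of the fixed-point equation with r* = c h*.

    Raises ``ValueError`` when no equilibrium with h* in (0, 1) exists for
    this input (outside the operating range).
    """
    sp = p.sigmoid

    def g(h: float) -> float:
        return h - float(
            shifted_sigmoid((z - (p.c - 1.0) * h) / p.s, sp)
        )

    lo, hi = 1e-12, 1.0 - 1e-12
    if g(lo) * g(hi) > 0:
        raise ValueError(f"no fixed point with h* in (0,1) for z={z}")
    h_star = float(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16))
    r_star = p.c * h_star
    # residuals of the two time-scaled ODE right-hand sides at (h*, r*)
    dh = (-h_star + float(shifted_sigmoid((z - r_star + h_star) / p.s, sp))) / p.tau_h
    dr = (-r_star + p.c * h_star) / p.tau_r
    residual = max(abs(dh), abs(dr))
    h_a, r_a = fixed_point_approx(z, p.c) if p.c > 1 else (h_star, r_star)
    return FixedPoint(h_star, r_star, residual, h_a, r_a)


Z_GRID_DEFAULT = tuple(np.arange(0.5, 9.0, 1.0))  # 0.5, 1.5, ..., 8.5


def parameter_sweep(
    c_grid,
    s_grid,
    z_grid,
    inh: InhibitionParams = InhibitionParams(),
    duration: float = 3.0,
    transient: float = 0.5,
    tau_h: float = 0.01,
    tau_r: float = 0.1,
    dt: float = DT_DEFAULT,
) -> pd.DataFrame:
    """Frequency/amplitude maps over (c, s, z) grids.

    Each cell simulates one node for ``duration`` seconds, discards the
    transient, and estimates oscillation frequency and amplitude.  Inputs
    that do not sustain oscillation report frequency 0.
    """
    from .analysis import estimate_amplitude, estimate_frequency

    c_grid, s_grid, z_grid = map(np.atleast_1d, (c_grid, s_grid, z_grid))
    if not (c_grid.size and s_grid.size and z_grid.size):
        raise ValueError("sweep grids must be non-empty")
    rows = []
    for c in c_grid:
        for s in s_grid:
            p = NodeParams(tau_h=tau_h, tau_r=tau_r, c=float(c), s=float(s))
            for z in z_grid:
                tr = simulate_node(float(z), duration, p, inh, dt=dt)
                rows.append(
                    {
                        "c": float(c),
                        "s": float(s),
                        "z": float(z),
                        "m": inh.m,
                        "f": inh.f,
                        "frequency_hz": estimate_frequency(tr.h, dt, transient),
                        "amplitude": estimate_amplitude(tr.h, dt, transient),
                    }
                )
    return pd.DataFrame(rows)
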