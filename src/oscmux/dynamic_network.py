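"""The trained classifier with ODE dynamics in both hidden layers.

After training, every hidden node is given the activation/refraction
dynamics of :mod:`oscmux.unit_dynamics`; the weights stay frozen.  Layer 1
receives the static image drive z1; layer 2's drive is recomputed each step
from layer 1's instantaneous activations through W2; the output softmax is
applied instantaneously to layer 2's activations.  Each hidden layer has its
own inhibition waveform, so per-layer phase delays can be studied.

Also provides the non-dynamical "bottleneck" mode (s = 1, refraction off,
no inhibition, zero initial state), in which the network relaxes to a steady
state and two simultaneous letters produce a mixed output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .static_network import (
    N_HIDDEN1,
    N_HIDDEN2,
    NetworkWeights,
    layer1_input,
    softmax,
)
from .stimuli import StimulusImage
from .unit_dynamics import (
    DT_DEFAULT,
    InhibitionParams,
    NodeParams,
    NodeState,
    alpha_drive,
    fixed_point_approx,
    node_step,
)

INIT_MODES = ("fixed_point_z2", "zeros")
#: all hidden nodes start at the small-s fixed point for this input
INIT_Z = 2.0


@dataclass
class LayerDynamicsState:
    """Dynamic state of both hidden layers."""

    layer1: NodeState
    layer2: NodeState


@dataclass
class NetworkSimConfig:
    """Everything needed to run the dynamical network once."""

    params: NodeParams = NodeParams()
    inh_layer1: InhibitionParams = InhibitionParams(m=0.5, f=10.0)
    inh_layer2: InhibitionParams = InhibitionParams(m=0.5, f=10.0)
    duration: float = 1.0
    dt: float = DT_DEFAULT
    init_mode: str = "fixed_point_z2"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must cover at least one step")
        if self.init_mode not in INIT_MODES:
            raise ValueError(
                f"unknown init_mode {self.init_mode!r}; choose from {INIT_MODES}"
            )


def init_dynamic_state(config: NetworkSimConfig) -> LayerDynamicsState:
    """Initial (h, r) for every hidden node.

    ``fixed_point_z2``: the small-s fixed point h = z/(c-1), r = c h at
    z = 2 (a quarter of the maximum input), which places the network on its
    operating branch and lets a temporal code form within the first cycles.
    ``zeros``: h = r = 0, used in the bottleneck mode.
    """
    if config.init_mode == "zeros":
        h0 = r0 = 0.0
    else:
        h0, r0 = fixed_point_approx(INIT_Z, config.params.c)
    return LayerDynamicsState(
        layer1=NodeState(np.full(N_HIDDEN1, h0), np.full(N_HIDDEN1, r0)),
        layer2=NodeState(np.full(N_HIDDEN2, h0), np.full(N_HIDDEN2, r0)),
    )


@dataclass
class SimulationResult:
    """Per-time-step state of the dynamical network."""

    t: np.ndarray
    h1: np.ndarray      # (T, 64)
    r1: np.ndarray
    h2: np.ndarray      # (T, 32)
    r2: np.ndarray
    probs: np.ndarray   # (T, 3)
    alpha1: np.ndarray
    alpha2: np.ndarray
    dt: float
    config: NetworkSimConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        """Read-out and inhibition waveforms as a tidy table."""
        return pd.DataFrame(
            {
                "t": self.t,
                "probs_A": self.probs[:, 0],
                "probs_E": self.probs[:, 1],
                "probs_T": self.probs[:, 2],
                "alpha1": self.alpha1,
                "alpha2": self.alpha2,
            }
        )


def simulate_network(
    image: StimulusImage,
    weights: NetworkWeights,
    config: NetworkSimConfig = NetworkSimConfig(),
) -> SimulationResult:
    """Integrate the full dynamical network on one (static) image.

    Synchronous explicit Euler: at each step layer 2's drive z2 is computed
    from layer 1's pre-step activation, then both layers advance together.
    The softmax read-out is recorded instantaneously from h2 at every step.
    Fully deterministic for a given image, weights and config.
    """
    weights.validate()
    p, dt = config.params, config.dt
    n = int(round(config.duration / dt))
    t = np.arange(n) * dt
    z1 = layer1_input(image, weights.kernels1)
    state = init_dynamic_state(config)

    h1 = np.empty((n, N_HIDDEN1))
    r1 = np.empty((n, N_HIDDEN1))
    h2 = np.empty((n, N_HIDDEN2))
    r2 = np.empty((n, N_HIDDEN2))
    probs = np.empty((n, 3))
    for k in range(n):
        s1, s2 = state.layer1, state.layer2
        if not (np.all(np.isfinite(s1.h)) and np.all(np.isfinite(s2.h))):
            raise FloatingPointError(f"non-finite network state at step {k}")
        h1[k], r1[k] = s1.h, s1.r
        h2[k], r2[k] = s2.h, s2.r
        probs[k] = softmax(s2.h @ weights.W3)
        z2 = s1.h @ weights.W2
        state = LayerDynamicsState(
            layer1=node_step(s1, z1, t[k], dt, p, config.inh_layer1),
            layer2=node_step(s2, z2, t[k], dt, p, config.inh_layer2),
        )
    return SimulationResult(
        t=t,
        h1=h1,
        r1=r1,
        h2=h2,
        r2=r2,
        probs=probs,
        alpha1=alpha_drive(t, config.inh_layer1),
        alpha2=alpha_drive(t, config.inh_layer2),
        dt=dt,
        config=config,
    )


def run_bottleneck(
    image: StimulusImage,
    weights: NetworkWeights,
    duration: float = 1.0,
) -> SimulationResult:
    """The network without its dynamical machinery (the bottleneck mode).

    s = 1, refraction off (c = 0 with r started at 0, so r stays 0), no
    inhibition, h = r = 0 initial state.  The system relaxes to a steady
    state satisfying h = sigma(z + h) componentwise; with two simultaneous
    letters the steady read-out is a mixture over both letters' nodes.
    """
    base = NodeParams()
    config = NetworkSimConfig(
        params=NodeParams(
            tau_h=base.tau_h, tau_r=base.tau_r, c=0.0, s=1.0, sigmoid=base.sigmoid
        ),
        inh_layer1=InhibitionParams(m=0.0),
        inh_layer2=InhibitionParams(m=0.0),
        duration=duration,
        init_mode="zeros",
    )
    return simulate_network(image, weights, config)


def sweep_phase_delay(
    image: StimulusImage,
    weights: NetworkWeights,
    config: NetworkSimConfig,
    layer: int,
    delays: list[float],
) -> list[SimulationResult]:
    """Re-run the simulation with the chosen layer's inhibition delayed.

    Each delay d (seconds) becomes a phase lag 2 pi f d subtracted from that
    layer's inhibition phase; delay 0 reproduces the baseline run exactly.
    """
    if layer not in (1, 2):
        raise ValueError("layer must be 1 or 2")
    results = []
    for d in delays:
        if d < 0:
            raise ValueError("delays must be >= 0")
        inh = config.inh_layer1 if layer == 1 else config.inh_layer2
        shifted = replace(inh, phase=inh.phase - 2.0 * np.pi * inh.f * d)
        kwargs = {"inh_layer1": shifted} if layer == 1 else {"inh_layer2": shifted}
        results.append(simulate_network(image, weights, replace(config, **kwargs)))
    return results
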