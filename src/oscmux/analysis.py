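"""Quantitative analysis of simulated dynamics.

Covers oscillation frequency and amplitude of single traces, the similarity
of time-varying hidden activations to the static single-letter patterns
(normalised dot product), threshold-crossing event detection on the softmax
read-out, and per-inhibition-cycle event counts (the temporal code).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .stimuli import LETTERS
from .unit_dynamics import InhibitionParams

#: minimum peak prominence counted as oscillation (vs numeric ripple)
PROMINENCE_FLOOR = 0.1
#: softmax probability above which a letter counts as "read out"
EVENT_THRESHOLD = 0.5


def _trim(trace: np.ndarray, dt: float, transient: float) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    start = int(round(transient / dt))
    if trace.size - start < 3:
        raise ValueError(
            f"trace too short: {trace.size} samples minus {start} transient"
        )
    return trace[start:]


def _peaks(trace: np.ndarray) -> np.ndarray:
    peaks, _ = find_peaks(trace - trace.mean(), prominence=PROMINENCE_FLOOR)
    return peaks


def estimate_frequency(trace: np.ndarray, dt: float, transient: float = 0.5) -> float:
    """Mean inverse inter-peak interval (Hz) after the transient; 0 if no oscillation."""
    x = _trim(trace, dt, transient)
    peaks = _peaks(x)
    if peaks.size < 2:
        return 0.0
    return 1.0 / (float(np.mean(np.diff(peaks))) * dt)


def estimate_period_ms(trace: np.ndarray, dt: float, transient: float = 0.5) -> float:
    """Mean inter-peak interval in milliseconds (0 if no oscillation)."""
    f = estimate_frequency(trace, dt, transient)
    return 0.0 if f == 0.0 else 1000.0 / f


def estimate_amplitude(trace: np.ndarray, dt: float, transient: float = 0.5) -> float:
    """Mean peak height relative to the post-transient minimum; 0 if constant."""
    x = _trim(trace, dt, transient)
    peaks = _peaks(x)
    if peaks.size == 0:
        return 0.0
    return float(np.mean(x[peaks]) - x.min())


def spectral_peak_frequency(
    trace: np.ndarray, dt: float, transient: float = 0.5
) -> float:
    """Dominant non-DC Fourier bin (Hz) — an independent cross-check."""
    x = _trim(trace, dt, transient)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, dt)
    return float(freqs[1:][np.argmax(spec[1:])])


@dataclass
class SimilarityTrace:
    """Normalised dot product s_X(t) = h(t).h_X / (h_X.h_X) over time."""

    reference_letter: str
    values: np.ndarray


def similarity_trace(
    h_t: np.ndarray, reference: np.ndarray, reference_letter: str = ""
) -> SimilarityTrace:
    """Project time-varying hidden activations onto a static letter pattern.

    ``h_t`` is (T, N); ``reference`` is the static-network hidden activation
    (length N) for one clean letter.  Equals 1 whenever the instantaneous
    pattern matches the reference; scale-covariant in h(t).
    """
    reference = np.asarray(reference, dtype=float)
    denom = float(reference @ reference)
    if denom == 0.0:
        raise ValueError("reference activation vector is all-zero")
    values = np.asarray(h_t, dtype=float) @ reference / denom
    return SimilarityTrace(reference_letter, values)


@dataclass(frozen=True)
class ActivationEvent:
    """One maximal interval where a node's read-out exceeds threshold."""

    node: int            # letter index (A=0, E=1, T=2)
    onset: float         # s
    offset: float        # s
    peak: float          # max probability within the event
    cycle_index: int     # inhibition cycle containing the onset

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def letter(self) -> str:
        return LETTERS[self.node]


@dataclass
class TemporalCode:
    """Suprathreshold read-out events grouped by inhibition cycle."""

    events: list[ActivationEvent]
    inhibition_freq: float
    cycle_bounds: np.ndarray     # times of alpha maxima delimiting cycles
    n_cycles: int

    def events_in_cycle(self, k: int) -> list[ActivationEvent]:
        return [e for e in self.events if e.cycle_index == k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "letter": e.letter,
                    "onset": e.onset,
                    "offset": e.offset,
                    "duration": e.duration,
                    "peak": e.peak,
                    "cycle": e.cycle_index,
                }
                for e in self.events
            ]
        )


def cycle_boundaries(inh: InhibitionParams, t_end: float) -> np.ndarray:
    """Times of alpha(t) maxima in [0, t_end] (cycle delimiters).

    Events between consecutive inhibition peaks belong to one cycle; the
    stretch before the first maximum is cycle 0.
    """
    if inh.f <= 0:
        raise ValueError("cycles undefined without inhibition (f <= 0)")
    period = 1.0 / inh.f
    # alpha max where sin(2 pi f t + phase) = 1
    t0 = (np.pi / 2.0 - inh.phase) / (2.0 * np.pi * inh.f)
    t0 = t0 % period
    return np.arange(t0, t_end, period)


def detect_events(
    probs: np.ndarray,
    dt: float,
    inh: InhibitionParams,
    threshold: float = EVENT_THRESHOLD,
) -> TemporalCode:
    """Extract read-out events from the (T, 3) softmax probability series.

    An event is a maximal run of time steps where one node's probability
    exceeds ``threshold``; onset/offset are grid times of the first/last
    suprathreshold sample.  Events are assigned to inhibition cycles by
    onset and returned in onset order.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    probs = np.asarray(probs, dtype=float)
    t_end = probs.shape[0] * dt
    bounds = cycle_boundaries(inh, t_end)
    events: list[ActivationEvent] = []
    for node in range(probs.shape[1]):
        above = probs[:, node] > threshold
        if not above.any():
            continue
        padded = np.r_[False, above, False].astype(int)
        starts = np.flatnonzero(np.diff(padded) == 1)
        stops = np.flatnonzero(np.diff(padded) == -1) - 1
        for i0, i1 in zip(starts, stops):
            onset, offset = i0 * dt, i1 * dt
            cycle = int(np.searchsorted(bounds, onset))
            events.append(
                ActivationEvent(
                    node=node,
                    onset=onset,
                    offset=offset,
                    peak=float(probs[i0 : i1 + 1, node].max()),
                    cycle_index=cycle,
                )
            )
    events.sort(key=lambda e: e.onset)
    return TemporalCode(
        events=events,
        inhibition_freq=inh.f,
        cycle_bounds=bounds,
        n_cycles=len(bounds) + 1,
    )


def items_per_cycle(code: TemporalCode) -> list[int]:
    """Event count per inhibition cycle, excluding the first (transient) cycle."""
    if code.inhibition_freq <= 0:
        raise ValueError("cycles undefined without inhibition")
    counts = [0] * code.n_cycles
    for e in code.events:
        counts[e.cycle_index] += 1
    return counts[1:]


def readout_accuracy(
    probs: np.ndarray, letter: str, transient: float, dt: float
) -> float:
    """Maximum softmax probability of ``letter`` after the transient."""
    if letter not in LETTERS:
        raise ValueError(f"unknown letter {letter!r}; valid letters are {LETTERS}")
    start = int(round(transient / dt))
    return float(np.asarray(probs)[start:, LETTERS.index(letter)].max())


def attended_first_fraction(
    code: TemporalCode, attended: str, unattended: str
) -> float:
    """Fraction of steady cycles where the attended letter's event leads.

    Only cycles (beyond the first) containing at least one event of each
    letter are counted.
    """
    ia, iu = LETTERS.index(attended), LETTERS.index(unattended)
    wins = total = 0
    for k in range(1, code.n_cycles):
        evs = code.events_in_cycle(k)
        on_a = [e.onset for e in evs if e.node == ia]
        on_u = [e.onset for e in evs if e.node == iu]
        if on_a and on_u:
            total += 1
            wins += int(min(on_a) < min(on_u))
    return wins / total if total else float("nan")
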