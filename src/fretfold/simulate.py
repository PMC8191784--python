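"""Synthetic smFRET data generator.

Forward model: a continuous-time Markov chain over conformational states
(Gillespie realization), rendered to camera frames by exact within-frame
occupancy weighting of the state FRET means, plus per-frame emission jitter,
additive Gaussian channel noise, channel backgrounds, and optional
single-step photobleaching with an exponential lifetime.

The generator is the ground-truth source for every parameter-recovery test:
dwell times are exponential with mean 1/(exit rate), long-run occupancies
match the stationary distribution of the rate matrix, and noiseless rendered
traces invert exactly to the state FRET means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .scheme import AcquisitionModel, Condition, KineticScheme, StateEvent
from .traces import IntensityTrace

__all__ = [
    "simulate_state_path",
    "render_intensity_trace",
    "simulate_dataset",
    "SimulatedDataset",
    "frame_occupancy",
    "dominant_state_per_frame",
    "path_dwells",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(
    scheme: KineticScheme, duration: float, seed: SeedLike
) -> List[StateEvent]:
    """Gillespie realization of the kinetic scheme over [0, duration].

    In each state s the waiting time is Exponential(sum_j k_sj) and the next
    state is chosen with probability k_sj / sum_j k_sj.  A state with zero
    exit rate is absorbing: the realization ends with an infinite dwell
    truncated at ``duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = _rng(seed)
    k = scheme.rates.copy()
    np.fill_diagonal(k, 0.0)
    exit_rates = k.sum(axis=1)
    # precomputed jump distributions; single-target states skip sampling
    targets = [np.flatnonzero(k[s] > 0) for s in range(scheme.n_states)]
    jump_p = [
        k[s, targets[s]] / exit_rates[s] if exit_rates[s] > 0 else None
        for s in range(scheme.n_states)
    ]

    state = int(rng.choice(scheme.n_states, p=scheme.initial_probs))
    t = 0.0
    events = [StateEvent(scheme.state_names[state], 0.0)]
    while True:
        r = exit_rates[state]
        if r <= 0.0:
            break  # absorbing
        t += rng.exponential(1.0 / r)
        if t >= duration:
            break
        cand = targets[state]
        if len(cand) == 1:
            state = int(cand[0])
        else:
            state = int(cand[rng.choice(len(cand), p=jump_p[state])])
        events.append(StateEvent(scheme.state_names[state], t))
    return events


def _validate_path(path: Sequence[StateEvent]) -> None:
    if len(path) == 0:
        raise ValueError("path must contain at least one event")
    if path[0].entry_time != 0.0:
        raise ValueError("first event must enter at t=0")
    times = [e.entry_time for e in path]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("entry times must be strictly increasing")


def frame_occupancy(
    path: Sequence[StateEvent],
    scheme: KineticScheme,
    n_frames: int,
    frame_interval: float,
) -> np.ndarray:
    """Fraction of each frame spent in each state, shape (n_frames, n_states).

    Frame f covers [f*dt, (f+1)*dt); the realization's final state is held
    to the end of the frame window.
    """
    _validate_path(path)
    dt = frame_interval
    occ = np.zeros((n_frames, scheme.n_states))
    total = n_frames * dt
    starts = np.array([e.entry_time for e in path])
    ends = np.append(starts[1:], total)
    idx = [scheme.state_index(e.state) for e in path]
    for s, (a, b) in zip(idx, zip(starts, ends)):
        if b <= a or a >= total:
            continue
        b = min(b, total)
        f0 = int(a / dt)
        f1 = min(int(np.ceil(b / dt)), n_frames)
        for f in range(f0, f1):
            lo = max(a, f * dt)
            hi = min(b, (f + 1) * dt)
            if hi > lo:
                occ[f, s] += (hi - lo) / dt
    return occ


def dominant_state_per_frame(
    path: Sequence[StateEvent],
    scheme: KineticScheme,
    n_frames: int,
    frame_interval: float,
) -> np.ndarray:
    """Majority-occupancy state index per frame (ground-truth discretization)."""
    occ = frame_occupancy(path, scheme, n_frames, frame_interval)
    return occ.argmax(axis=1)


def path_dwells(path: Sequence[StateEvent], duration: float) -> list:
    """Continuous dwells (state, duration, censored) of a realization.

    The first and last dwell are censored by the observation window.
    """
    _validate_path(path)
    starts = [e.entry_time for e in path]
    ends = starts[1:] + [duration]
    n = len(path)
    return [
        (e.state, b - a, i == 0 or i == n - 1)
        for i, (e, a, b) in enumerate(zip(path, starts, ends))
    ]


def render_intensity_trace(
    path: Sequence[StateEvent],
    scheme: KineticScheme,
    acq: AcquisitionModel,
    seed: SeedLike,
    trace_id: str = "",
    condition: Optional[Condition] = None,
) -> IntensityTrace:
    """Render a state realization to a two-channel camera trace.

    Per frame f the occupancy-weighted mean efficiency is
    ``E_f = sum_s w_fs * fret_mean_s`` with w_fs the fraction of the frame
    spent in state s; emission jitter with sd ``sum_s w_fs * fret_sd_s`` is
    added before rendering.  Then
    ``acceptor = I_tot * E_f + bg_A + noise`` and
    ``donor = I_tot * (1 - E_f) + bg_D + noise``.  If a bleach lifetime is
    set, an exponential bleach time is drawn and frames are scaled by the
    surviving fraction of the frame (full post-bleach frames carry
    background + noise only).
    """
    rng = _rng(seed)
    n = acq.n_frames
    dt = acq.frame_interval
    occ = frame_occupancy(path, scheme, n, dt)
    e_mean = occ @ scheme.fret_mean
    e_sd = occ @ scheme.fret_sd
    e = e_mean + rng.normal(0.0, 1.0, n) * e_sd

    bleach_frame: Optional[int] = None
    live = np.ones(n)
    if acq.bleach_lifetime is not None:
        t_bleach = rng.exponential(acq.bleach_lifetime)
        if t_bleach < n * dt:
            bleach_frame = int(t_bleach / dt)
            live[bleach_frame + 1 :] = 0.0
            live[bleach_frame] = (t_bleach - bleach_frame * dt) / dt

    acceptor = acq.total_intensity * e * live + acq.acceptor_background
    donor = acq.total_intensity * (1.0 - e) * live + acq.donor_background
    if acq.channel_noise_sd > 0:
        acceptor = acceptor + rng.normal(0.0, acq.channel_noise_sd, n)
        donor = donor + rng.normal(0.0, acq.channel_noise_sd, n)

    time_s = np.arange(n) * dt
    return IntensityTrace(
        time_s=time_s,
        donor=donor,
        acceptor=acceptor,
        frame_interval=dt,
        trace_id=trace_id,
        condition=condition,
        bleach_frame=None,  # detection is the analysis side's job
        provenance={"true_bleach_frame": bleach_frame},
    )


@dataclass
class SimulatedDataset:
    """Traces plus the ground truth that generated them."""

    traces: List[IntensityTrace]
    paths: List[List[StateEvent]]
    scheme: KineticScheme
    acquisition: AcquisitionModel
    condition: Condition
    seed: int

    @property
    def n_traces(self) -> int:
        return len(self.traces)

    def manifest(self) -> dict:
        return {
            "scheme": self.scheme.to_dict(),
            "acquisition": self.acquisition.to_dict(),
            "condition": self.condition.to_dict(),
            "seed": self.seed,
            "traces": [t.trace_id for t in self.traces],
        }


def simulate_dataset(
    scheme: KineticScheme,
    acq: AcquisitionModel,
    condition: Condition,
    n_traces: int,
    seed: int,
) -> SimulatedDataset:
    """Simulate ``n_traces`` independent molecules under one condition.

    Each trace uses its own child stream of the master seed via
    ``np.random.SeedSequence(seed).spawn`` (a splittable counter-based
    scheme), so datasets are bitwise reproducible and individual traces can
    be regenerated independently of dataset size.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_traces)
    width = max(4, len(str(n_traces - 1)))
    traces, paths = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        path = simulate_state_path(scheme, acq.duration, rng)
        trace = render_intensity_trace(
            path,
            scheme,
            acq,
            rng,
            trace_id=f"trace_{i:0{width}d}",
            condition=condition,
        )
        traces.append(trace)
        paths.append(path)
    return SimulatedDataset(
        traces=traces,
        paths=paths,
        scheme=scheme,
        acquisition=acq,
        condition=condition,
        seed=seed,
    )
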