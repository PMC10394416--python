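"""Synaptic weight dynamics: Kesten noise, STDP and heterosynaptic scaling.

A population of independent leaky integrate-and-fire (LIF) neurons, each
receiving ``n_inputs`` synapses, evolves under

* intrinsic plasticity — activity-independent fluctuations, an
  Euler-Maruyama step of a Kesten-type process per noise interval:
  ``w' = w (1 + m sqrt(dt) xi1) + a sqrt(dt) xi2``, clipped at zero;
* extrinsic plasticity — exponential-window spike-timing-dependent
  plasticity with additive potentiation ``w -> w + c_p exp(-|dt|/tau)``
  when a presynaptic spike precedes a postsynaptic one, and
  multiplicative depression ``w -> w (1 - c_d exp(-|dt|/tau))`` for the
  reverse order (nearest-neighbour pre/post pairing);
* uniform heterosynaptic scaling — each neuron's weights are rescaled so
  their total stays at its initial value, modelling conservation of the
  total synaptic conductance.

Spikes and STDP run on a fine grid (default 0.1 ms, needed to resolve
tau_STDP = 0.5 ms); noise and scaling are applied on a coarser interval
(default 10 ms), which is statistically equivalent for diffusive noise
and keeps full-scale runs (1000 neurons x 100 inputs) tractable.  Three
stimulation protocols are built in: silent (no input), 10 Hz Poisson
("control") and 200 Hz periodic ("hfs"), each driving only a
configurable proportion of the inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import ConfigurationError, NumericalError

# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class STDPParams:
    """Exponential STDP window. c_p in pS (additive), c_d dimensionless."""

    c_p: float = 0.007
    c_d: float = 0.003
    tau_stdp: float = 0.5  # ms

    def __post_init__(self):
        if self.c_p < 0 or not (0 <= self.c_d < 1) or self.tau_stdp <= 0:
            raise ConfigurationError("require c_p >= 0, 0 <= c_d < 1, tau_stdp > 0")


@dataclass
class NoiseParams:
    """mult_strength: proportion of size per second; add_strength: pS per second."""

    mult_strength: float = 0.15
    add_strength: float = 0.001

    def __post_init__(self):
        if self.mult_strength < 0 or self.add_strength < 0:
            raise ConfigurationError("noise strengths must be >= 0")


@dataclass
class NeuronParams:
    tau_m: float = 10.0  # ms
    threshold: float = 10.0  # mV above rest
    n_inputs: int = 100
    n_neurons: int = 1000

    def __post_init__(self):
        if min(self.tau_m, self.threshold, self.n_inputs, self.n_neurons) <= 0:
            raise ConfigurationError("all neuron parameters must be positive")


@dataclass
class StimulusProtocol:
    kind: str = "silent"  # silent | poisson | periodic
    rate: float = 0.0  # Hz
    stim_proportion: float = 0.2

    def __post_init__(self):
        if self.kind not in ("silent", "poisson", "periodic"):
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if (self.rate == 0) != (self.kind == "silent"):
            raise ConfigurationError("rate must be 0 iff the protocol is silent")
        if not 0 <= self.stim_proportion <= 1:
            raise ConfigurationError("stim_proportion must lie in [0, 1]")


SILENT = StimulusProtocol("silent", 0.0)
CONTROL_10HZ = StimulusProtocol("poisson", 10.0)
HFS_200HZ = StimulusProtocol("periodic", 200.0)


@dataclass
class SimulationConfig:
    stdp: STDPParams = field(default_factory=STDPParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    protocol: StimulusProtocol = field(default_factory=lambda: SILENT)
    duration: float = 10.0  # s
    dt: float = 1e-4  # s, fine grid for spikes/STDP
    noise_interval: float = 0.01  # s, noise + scaling grid
    coupling_gain: float = 1.0  # mV of depolarization per pS of weight
    scaling_enabled: bool = True
    stdp_enabled: bool = True
    init_weight_mean: float = 0.5  # pS; initial weights ~ U(0, 2 * mean)
    snapshot_interval: float | None = None  # s
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.dt <= 0 or self.noise_interval <= 0:
            raise ConfigurationError("duration, dt and noise_interval must be positive")
        if self.dt > 0.1 * self.neuron.tau_m * 1e-3:
            raise ConfigurationError("dt must satisfy dt <= 0.1 * tau_m")
        if self.protocol.rate > 1.0 / self.dt:
            raise ConfigurationError("stimulus rate unresolvable at this dt")


@dataclass
class SimulationResult:
    final_weights: np.ndarray  # (n_neurons, n_inputs)
    post_spike_counts: np.ndarray  # (n_neurons,)
    snapshots: list  # [(t_seconds, flat weight copy), ...]
    scaling_max_rel_dev: float  # worst |rowsum - target|/target seen after scaling
    config: SimulationConfig


# ---------------------------------------------------------------------------
# elementary operations (public, also used by the oracle tests)


def stdp_potentiate(w: float, delta_t: float, params: STDPParams) -> float:
    """Additive potentiation for pre-before-post pairings (delta_t <= 0, ms)."""
    if delta_t > 0:
        raise ConfigurationError("potentiation requires delta_t <= 0 (pre before post)")
    return w + params.c_p * math.exp(-abs(delta_t) / params.tau_stdp)


def stdp_depress(w: float, delta_t: float, params: STDPParams) -> float:
    """Multiplicative depression for post-before-pre pairings (delta_t > 0, ms)."""
    if delta_t <= 0:
        raise ConfigurationError("depression requires delta_t > 0 (post before pre)")
    return w * (1.0 - params.c_d * math.exp(-abs(delta_t) / params.tau_stdp))


def apply_intrinsic_noise(
    weights: np.ndarray, dt: float, params: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """One Euler-Maruyama step of the Kesten noise; negative results clip to 0."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    w = np.asarray(weights, dtype=float)
    sq = math.sqrt(dt)
    if params.mult_strength > 0:
        w = w * (1.0 + params.mult_strength * sq * rng.standard_normal(w.shape))
    if params.add_strength > 0:
        w = w + params.add_strength * sq * rng.standard_normal(w.shape)
    return np.clip(w, 0.0, None)


def heterosynaptic_scale(weights: np.ndarray, target_total) -> np.ndarray:
    """Rescale each neuron's weights so they sum to its target total.

    Accepts a 1-D vector (one neuron) or an (n_neurons, n_inputs) matrix
    with per-row targets.  All-zero rows cannot be scaled and are left
    unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        total = w.sum()
        if total == 0:
            return w.copy()
        return w * (float(target_total) / total)
    totals = w.sum(axis=1)
    target = np.broadcast_to(np.asarray(target_total, dtype=float), totals.shape)
    factors = np.ones_like(totals)
    ok = totals > 0
    factors[ok] = target[ok] / totals[ok]
    return w * factors[:, None]


def generate_input_spikes(
    protocol: StimulusProtocol,
    duration: float,
    n_inputs: int,
    rng: np.random.Generator,
    dt: float = 1e-4,
) -> list[np.ndarray]:
    """Spike-time arrays (seconds) per input for one neuron.

    Only the first floor(stim_proportion * n_inputs) inputs are driven:
    Poisson at ``rate`` or periodic with interval 1/rate and a random
    phase.  The remaining inputs are silent (empty arrays).
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if protocol.rate > 1.0 / dt:
        raise ConfigurationError("stimulus rate unresolvable at this dt")
    n_stim = int(math.floor(protocol.stim_proportion * n_inputs))
    trains: list[np.ndarray] = []
    for i in range(n_inputs):
        if protocol.kind == "silent" or i >= n_stim:
            trains.append(np.empty(0))
        elif protocol.kind == "poisson":
            n = rng.poisson(protocol.rate * duration)
            trains.append(np.sort(rng.uniform(0.0, duration, n)))
        else:
            period = 1.0 / protocol.rate
            phase = rng.uniform(0.0, period)
            trains.append(np.arange(phase, duration, period))
    return trains


def simulate_lif(
    neuron: NeuronParams,
    weights: np.ndarray,
    spike_trains: list[np.ndarray],
    dt: float = 1e-4,
    coupling_gain: float = 1.0,
    const_drive: float = 0.0,
    duration: float | None = None,
) -> np.ndarray:
    """Dense-grid LIF integration for a single neuron; returns spike times (s).

    The membrane potential relaxes exponentially toward ``const_drive``
    (mV, asymptotic value; 0 = rest) with time constant tau_m; each
    presynaptic spike at input i adds ``coupling_gain * weights[i]`` mV.
    Crossing ``threshold`` emits a spike and resets to rest.
    """
    if dt > 0.1 * neuron.tau_m * 1e-3:
        raise ConfigurationError("dt must satisfy dt <= 0.1 * tau_m")
    w = np.asarray(weights, dtype=float)
    if duration is None:
        duration = max((t[-1] for t in spike_trains if t.size), default=0.0) + dt
    n_steps = int(round(duration / dt))
    incr = np.zeros(n_steps)
    for i, t in enumerate(spike_trains):
        if t.size:
            steps = np.minimum((t / dt).astype(int), n_steps - 1)
            np.add.at(incr, steps, coupling_gain * w[i])
    alpha = math.exp(-dt / (neuron.tau_m * 1e-3))
    v = 0.0
    out = []
    for s in range(n_steps):
        v = const_drive + (v - const_drive) * alpha
        v += incr[s]
        if v >= neuron.threshold:
            out.append(s * dt)
            v = 0.0
    return np.asarray(out)


# ---------------------------------------------------------------------------
# event-driven population kernel


@njit(cache=True)
def _event_kernel(
    ev_step, ev_neuron, ev_input,
    w, v, last_update, last_pre, last_post,
    decay, gain, theta, c_p, c_d, tau_steps,
    post_counts, stdp_on,
):  # pragma: no cover - exercised via run_simulation
    """Process presynaptic events in order; exact inter-event decay.

    Between input events the membrane only decays, so threshold crossings
    can occur only at event steps; the potential is therefore advanced
    lazily per neuron.  Events at the same step are processed in array
    order and the threshold is checked after each one (tie-break rule).
    Nearest-neighbour STDP pairing: a postsynaptic spike potentiates every
    input against its most recent presynaptic spike; a presynaptic spike
    is depressed against the neuron's most recent postsynaptic spike.
    """
    n_inputs = w.shape[1]
    for e in range(ev_step.shape[0]):
        s = ev_step[e]
        n = ev_neuron[e]
        i = ev_input[e]
        ds = s - last_update[n]
        if ds > 0:
            v[n] = v[n] * decay ** ds
            last_update[n] = s
        v[n] += gain * w[n, i]
        if stdp_on and last_post[n] >= 0:
            dpost = s - last_post[n]
            if dpost > 0:
                w[n, i] *= 1.0 - c_d * math.exp(-dpost / tau_steps)
        last_pre[n, i] = s
        if v[n] >= theta:
            v[n] = 0.0
            post_counts[n] += 1
            last_post[n] = s
            if stdp_on:
                for j in range(n_inputs):
                    lp = last_pre[n, j]
                    if lp >= 0:
                        w[n, j] += c_p * math.exp(-(s - lp) / tau_steps)


def _block_events(
    protocol: StimulusProtocol,
    t0: float,
    t1: float,
    dt: float,
    n_neurons: int,
    n_stim: int,
    phases: np.ndarray | None,
    rng: np.random.Generator,
):
    """(step, neuron, input) arrays for all presynaptic events in [t0, t1).

    Restricting a Poisson process to sub-intervals is distributionally
    identical to drawing counts over the block and placing times
    uniformly, so events can be generated per block of noise intervals
    and sliced per interval afterwards.
    """
    if protocol.kind == "poisson":
        counts = rng.poisson(protocol.rate * (t1 - t0), size=(n_neurons, n_stim))
        total = int(counts.sum())
        if total == 0:
            return None
        times = t0 + rng.uniform(0.0, t1 - t0, total)
        flat = counts.ravel()
        idx = np.repeat(np.arange(flat.size), flat)
    else:  # periodic
        period = 1.0 / protocol.rate
        k0 = np.ceil((t0 - phases) / period).astype(np.int64)
        k1 = np.ceil((t1 - phases) / period).astype(np.int64)
        counts = k1 - k0
        total = int(counts.sum())
        if total == 0:
            return None
        flat = counts.ravel()
        idx = np.repeat(np.arange(flat.size), flat)
        starts = np.repeat(np.cumsum(flat) - flat, flat)
        k = np.arange(total) - starts + np.repeat(k0.ravel(), flat)
        times = phases.ravel()[idx] + k * period
    neurons = (idx // n_stim).astype(np.int64)
    inputs = (idx % n_stim).astype(np.int64)
    steps = np.floor(times / dt).astype(np.int64)
    order = np.argsort(steps, kind="stable")
    return steps[order], neurons[order], inputs[order]


def run_simulation(
    config: SimulationConfig, initial_weights: np.ndarray | None = None
) -> SimulationResult:
    """Run the full population simulation; deterministic per seed.

    Loop per noise interval: generate input spikes, integrate LIF and
    apply STDP on the fine grid, then one Kesten noise step, then
    heterosynaptic scaling toward each neuron's initial total.
    """
    np_ = config.neuron
    rng_init, rng_noise, rng_spikes = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    )
    if initial_weights is None:
        w = rng_init.uniform(
            0.0, 2.0 * config.init_weight_mean, size=(np_.n_neurons, np_.n_inputs)
        )
    else:
        w = np.array(initial_weights, dtype=float).reshape(np_.n_neurons, np_.n_inputs)
        if (w < 0).any():
            raise ConfigurationError("initial weights must be non-negative")
    target = w.sum(axis=1).copy()

    v = np.zeros(np_.n_neurons)
    last_update = np.zeros(np_.n_neurons, dtype=np.int64)
    last_pre = np.full((np_.n_neurons, np_.n_inputs), -1, dtype=np.int64)
    last_post = np.full(np_.n_neurons, -1, dtype=np.int64)
    post_counts = np.zeros(np_.n_neurons, dtype=np.int64)

    active = config.protocol.kind != "silent"
    n_stim = int(math.floor(config.protocol.stim_proportion * np_.n_inputs))
    phases = None
    if active and config.protocol.kind == "periodic" and n_stim > 0:
        phases = rng_spikes.uniform(
            0.0, 1.0 / config.protocol.rate, size=(np_.n_neurons, n_stim)
        )

    decay = math.exp(-config.dt / (np_.tau_m * 1e-3))
    tau_steps = (config.stdp.tau_stdp * 1e-3) / config.dt
    n_chunks = int(round(config.duration / config.noise_interval))
    snapshots: list[tuple[float, np.ndarray]] = []
    if config.snapshot_interval is not None:
        snapshots.append((0.0, w.ravel().copy()))
    snap_every = (
        max(1, int(round(config.snapshot_interval / config.noise_interval)))
        if config.snapshot_interval is not None
        else None
    )
    max_dev = 0.0

    # noise draws and input events are pre-generated per block of noise
    # intervals (statistically identical, far fewer RNG calls); capped so
    # full-scale runs stay within a few hundred MB
    block = max(1, min(64, int(4e7 // max(1, np_.n_neurons * np_.n_inputs))))
    sq = math.sqrt(config.noise_interval)
    m_str, a_str = config.noise.mult_strength, config.noise.add_strength
    ok_target = target > 0
    c_p = config.stdp.c_p if config.stdp_enabled else 0.0
    c_d = config.stdp.c_d if config.stdp_enabled else 0.0

    for b0 in range(0, n_chunks, block):
        nb = min(block, n_chunks - b0)
        tb0, tb1 = b0 * config.noise_interval, (b0 + nb) * config.noise_interval
        ev = None
        if active and n_stim > 0:
            ev = _block_events(
                config.protocol, tb0, tb1, config.dt,
                np_.n_neurons, n_stim, phases, rng_spikes,
            )
        xi_m = (
            rng_noise.standard_normal((nb, np_.n_neurons, np_.n_inputs))
            if m_str > 0 else None
        )
        xi_a = (
            rng_noise.standard_normal((nb, np_.n_neurons, np_.n_inputs))
            if a_str > 0 else None
        )
        for c in range(nb):
            chunk = b0 + c
            t1 = (chunk + 1) * config.noise_interval
            if ev is not None:
                step_hi = int(round(t1 / config.dt))
                step_lo = int(round((t1 - config.noise_interval) / config.dt))
                lo = np.searchsorted(ev[0], step_lo, side="left")
                hi = np.searchsorted(ev[0], step_hi, side="left")
                if hi > lo:
                    _event_kernel(
                        ev[0][lo:hi], ev[1][lo:hi], ev[2][lo:hi],
                        w, v, last_update, last_pre, last_post,
                        decay, config.coupling_gain, np_.threshold,
                        c_p, c_d, tau_steps, post_counts, config.stdp_enabled,
                    )
            if xi_m is not None:
                w *= 1.0 + m_str * sq * xi_m[c]
            if xi_a is not None:
                w += a_str * sq * xi_a[c]
            np.clip(w, 0.0, None, out=w)
            if config.scaling_enabled:
                totals = w.sum(axis=1)
                factors = np.where(totals > 0, target / np.where(totals > 0, totals, 1.0), 1.0)
                w *= factors[:, None]
                dev = np.abs(w.sum(axis=1)[ok_target] - target[ok_target]) / target[ok_target]
                if dev.size:
                    max_dev = max(max_dev, float(dev.max()))
            if snap_every is not None and (chunk + 1) % snap_every == 0:
                snapshots.append((t1, w.ravel().copy()))
        if not np.isfinite(w).all():
            raise NumericalError(f"non-finite weight by t={tb1:.4f}s")

    return SimulationResult(
        final_weights=w,
        post_spike_counts=post_counts,
        snapshots=snapshots,
        scaling_max_rel_dev=max_dev,
        config=config,
    )


PROTOCOLS = {"silent": SILENT, "control": CONTROL_10HZ, "hfs": HFS_200HZ}


def run_protocol_suite(
    config: SimulationConfig, seed: int | None = None
) -> dict[str, SimulationResult]:
    """Run silent / 10 Hz Poisson / 200 Hz periodic with shared parameters.

    All three runs use the same seed, hence identical initial weights and
    identical noise realizations; they differ only through the stimulus.
    """
    if seed is None:
        seed = config.seed
    out = {}
    for name, proto in PROTOCOLS.items():
        proto = replace(proto, stim_proportion=config.protocol.stim_proportion)
        cfg = replace(config, protocol=proto, seed=seed)
        out[name] = run_simulation(cfg)
    return out
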