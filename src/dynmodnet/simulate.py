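"""Synthetic ROI time series with planted dynamic community structure.

The generator emulates source-localized, alpha-band EEG trials: 80 nodes,
2 s trials sampled at 500 Hz, with pairwise phase-lagged coupling that
follows a planted, time-varying module schedule.  Each planted module owns
one continuous phase-diffusing carrier at a module-specific frequency
inside the band (distinct "individual alpha peaks"); within each analysis
window, a module's members receive that carrier at evenly spaced phase
lags, bounded away from 0 and pi so every co-module pair is visible to the
weighted phase lag index.  Cross-module pairs rotate at their carriers'
frequency offset and wash out under WPLI.  Independent band-limited noise
is added per node, so the signal stays narrowband (like band-selected EEG)
while the phase coupling is diluted at a controllable signal-to-noise
ratio.

Because WPLI only sees *lagged* coupling, a zero-lag specification is
rejected outright.  Module membership changes are cross-faded with
raised-cosine ramps (<= 20 ms) to avoid broadband clicks leaking into the
carrier band.

Every quantity downstream of the generator has a planted ground truth:
per-node flexibility follows directly from the schedule's label changes,
and planted allegiance (fraction of windows two nodes share a module)
predicts integration and recruitment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas import SystemMap
from .connectivity import WindowSpec, band_filter, make_windows


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ModuleSchedule:
    """Planted community label per node per time window (labels >= 1)."""

    assignment: np.ndarray  # (n_nodes, n_windows), int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64)
        if a.ndim != 2:
            raise SimulationError("assignment must have shape (n_nodes, n_windows)")
        if (a < 1).any():
            raise SimulationError("module labels must be positive integers")
        object.__setattr__(self, "assignment", a)

    @property
    def n_nodes(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_windows(self) -> int:
        return self.assignment.shape[1]

    def planted_flexibility(self) -> np.ndarray:
        """Per-node F = S/T on the planted labels (S = consecutive-window changes)."""
        a = self.assignment
        s = (a[:, 1:] != a[:, :-1]).sum(axis=1)
        return s / self.n_windows

    def planted_allegiance(self) -> np.ndarray:
        """Fraction of windows in which each node pair shares a planted module."""
        a = self.assignment
        same = (a[:, None, :] == a[None, :, :]).mean(axis=2)
        np.fill_diagonal(same, 1.0)
        return same


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated recordings: 80 nodes, 2 s trials at
    500 Hz, alpha-band (8-13 Hz) carriers, 300 ms / 50% overlap analysis
    windows, 20 trials per condition.
    """

    n_nodes: int = 80
    fs: float = 500.0
    trial_duration: float = 2.0
    n_trials: int = 20
    carrier_band: tuple[float, float] = (8.0, 13.0)
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    #: None spaces a module's member lags evenly over [-3pi/8, +3pi/8]; a
    #: float phi instead gives member k the lag k * phi (nonzero mod pi).
    within_module_phase_lag: float | None = None
    coupling_strength: float = 1.0
    #: Noise level relative to the unit-amplitude carriers.  The default is a
    #: deliberately favorable signal-to-noise ratio: the generator's job is
    #: to provide a recoverable ground truth, and WPLI's short-window bias
    #: floor (any two independent narrowband signals hold a near-stable lag
    #: across a 300 ms window) swallows planted structure at lower SNR.
    noise_sd: float = 0.15
    #: Lorentzian linewidth of the phase-diffusing module carriers (narrow
    #: enough that the heavy Lorentzian tails stay inside the band).
    carrier_linewidth_hz: float = 0.25
    n_modules: int = 4
    #: Module-resampling probability per window; scalar or per-system mapping.
    switch_prob: float | Mapping[str, float] = 0.3
    #: Optional (systemA, systemB) -> probability that an A-node adopts a
    #: random B-node's module in a window (plants cross-system allegiance).
    co_module_prob: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs * self.trial_duration != int(self.fs * self.trial_duration):
            raise SimulationError("fs * trial_duration must be an integer sample count")
        if not 0 <= self.coupling_strength <= 1:
            raise SimulationError("coupling_strength must lie in [0, 1]")
        if self.fs <= 2 * self.carrier_band[1]:
            raise SimulationError("fs must exceed twice the carrier-band high edge")
        if self.within_module_phase_lag is not None:
            phi = float(self.within_module_phase_lag) % np.pi
            if min(phi, np.pi - phi) < 1e-9:
                raise SimulationError(
                    "zero-lag coupling is invisible to WPLI: "
                    "within_module_phase_lag must be nonzero mod pi"
                )
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))

    @property
    def n_windows(self) -> int:
        return self.window_spec.n_windows(self.n_samples, self.fs)

    def config_hash(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k not in ("window_spec", "co_module_prob")
        }
        payload["window_ms"] = self.window_spec.window_ms
        payload["overlap"] = self.window_spec.overlap_fraction
        payload["co_module_prob"] = sorted(
            (list(k), v) for k, v in dict(self.co_module_prob).items()
        )
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Node x sample x trial array with sampling rate and provenance."""

    data: np.ndarray  # (n_nodes, n_samples, n_trials)
    fs: float
    node_labels: tuple[str, ...] = ()
    condition: str = ""
    seed: int | None = None
    config_hash: str | None = None
    schedules: tuple[ModuleSchedule, ...] | None = None  # one per trial when synthetic

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise SimulationError("data must have shape (n_nodes, n_samples, n_trials)")
        if not np.isfinite(d).all():
            raise SimulationError("data contains non-finite values")
        object.__setattr__(self, "data", d)

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def trial(self, t: int) -> np.ndarray:
        return self.data[:, :, t]

    def save(self, directory: str | Path) -> None:
        """On-disk bundle: data.npy plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "data.npy", self.data)
        meta = {
            "fs": self.fs,
            "node_labels": list(self.node_labels),
            "condition": self.condition,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        if self.schedules is not None:
            np.save(
                directory / "schedules.npy",
                np.stack([s.assignment for s in self.schedules]),
            )
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ROITimeSeriesSet":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        data = np.load(directory / "data.npy")
        schedules = None
        sched_path = directory / "schedules.npy"
        if sched_path.exists():
            schedules = tuple(ModuleSchedule(a) for a in np.load(sched_path))
        return cls(
            data=data,
            fs=meta["fs"],
            node_labels=tuple(meta["node_labels"]),
            condition=meta["condition"],
            seed=meta["seed"],
            config_hash=meta["config_hash"],
            schedules=schedules,
        )


def _resolve_switch_probs(
    switch_prob: float | Mapping[str, float],
    system_map: SystemMap | None,
    n_nodes: int,
) -> np.ndarray:
    """Per-node switch probability vector."""
    if isinstance(switch_prob, Mapping):
        if system_map is None:
            raise SimulationError("per-system switch probabilities require a SystemMap")
        probs = np.array([switch_prob.get(s, 0.0) for s in system_map.systems])
    else:
        probs = np.full(n_nodes, float(switch_prob))
    if probs.shape[0] != n_nodes:
        raise SimulationError("system map size does not match n_nodes")
    if ((probs < 0) | (probs > 1)).any():
        raise SimulationError("switch probabilities must lie in [0, 1]")
    return probs


def make_schedule(
    n_nodes: int,
    n_windows: int,
    n_modules: int,
    switch_prob: float | Mapping[str, float],
    system_map: SystemMap | None = None,
    seed: int | np.random.Generator = 0,
    co_module_prob: Mapping[tuple[str, str], float] | None = None,
) -> ModuleSchedule:
    """Draw a planted module schedule.

    Window 1 is a balanced random partition into ``n_modules``.  At each
    subsequent window every node independently resamples its module
    uniformly with its (system's) switch probability; resampling can land
    on the current module, so with K modules the realized per-window switch
    rate is p * (K-1)/K.  ``co_module_prob`` additionally lets nodes of one
    system adopt the module of a random node of another system, planting
    cross-system allegiance.
    """
    if n_modules < 1:
        raise SimulationError("n_modules must be >= 1")
    if n_modules > n_nodes:
        raise SimulationError(f"n_modules={n_modules} exceeds n_nodes={n_nodes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = _resolve_switch_probs(switch_prob, system_map, n_nodes)

    a = np.empty((n_nodes, n_windows), dtype=np.int64)
    first = 1 + (np.arange(n_nodes) % n_modules)
    rng.shuffle(first)
    a[:, 0] = first
    for w in range(1, n_windows):
        stay = a[:, w - 1]
        resample = rng.random(n_nodes) < probs
        drawn = rng.integers(1, n_modules + 1, size=n_nodes)
        a[:, w] = np.where(resample, drawn, stay)

    if co_module_prob:
        if system_map is None:
            raise SimulationError("co_module_prob requires a SystemMap")
        for (sys_a, sys_b), p in co_module_prob.items():
            if not 0 <= p <= 1:
                raise SimulationError("co-module probabilities must lie in [0, 1]")
            nodes_a = sorted(system_map.members(sys_a))
            nodes_b = sorted(system_map.members(sys_b))
            if not nodes_a or not nodes_b:
                raise SimulationError(f"empty system in co_module pair ({sys_a}, {sys_b})")
            for w in range(n_windows):
                adopt = rng.random(len(nodes_a)) < p
                donors = rng.choice(nodes_b, size=len(nodes_a))
                for ia, node in enumerate(nodes_a):
                    if adopt[ia]:
                        a[node, w] = a[donors[ia], w]
    return ModuleSchedule(assignment=a)


def _spans(windows: list[tuple[int, int]], n_samples: int) -> list[tuple[int, int]]:
    """Contiguous synthesis spans: window w owns [start_w, start_{w+1})."""
    starts = [a for a, _ in windows]
    stops = starts[1:] + [n_samples]
    return list(zip(starts, stops))


def module_frequency(band: tuple[float, float], n_modules: int, label: int) -> float:
    """Carrier center frequency of a module, evenly spaced inside the band.

    Distinct per-module frequencies (distinct "individual alpha peaks" of
    different assemblies) make cross-module phase differences rotate within
    an analysis window, so uncoupled pairs wash out under WPLI instead of
    holding a spuriously stable lag over a short window.
    """
    lo, hi = band[0] + 0.5, band[1] - 0.5
    if n_modules <= 1:
        return 0.5 * (lo + hi)
    frac = ((label - 1) % n_modules) / (n_modules - 1)
    return lo + frac * (hi - lo)


def _carrier(
    n: int, fs: float, freq: float, rng: np.random.Generator, linewidth_hz: float = 0.5
) -> np.ndarray:
    """Unit-amplitude analytic carrier: phase-diffusing oscillator.

    Brownian phase noise with the given Lorentzian linewidth keeps the
    carrier narrowband around ``freq`` while letting independent carriers
    decorrelate.
    """
    sigma = np.sqrt(2 * np.pi * linewidth_hz / fs)
    theta = np.cumsum(rng.normal(0.0, sigma, size=n)) + rng.uniform(0, 2 * np.pi)
    t = np.arange(n)
    return np.exp(1j * (2 * np.pi * freq * t / fs + theta))


def _member_lags(config: SimConfig, members: np.ndarray) -> np.ndarray:
    """Phase lags of a module's members (sorted by node id) for one window.

    Default: evenly spaced over [-3pi/8, +3pi/8], so every co-module pair
    has a lag difference bounded away from both 0 and pi and is therefore
    visible to WPLI (random independent lags would leave near-zero-lag
    pairs undetectable).  A fixed ``within_module_phase_lag`` phi instead
    assigns member k the lag k * phi.
    """
    m = len(members)
    if config.within_module_phase_lag is not None:
        return config.within_module_phase_lag * np.arange(m)
    if m == 1:
        return np.zeros(1)
    return np.linspace(-3 * np.pi / 8, 3 * np.pi / 8, m)


def _synthesize_trial(
    config: SimConfig,
    schedule: ModuleSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    n, n_samples, fs = config.n_nodes, config.n_samples, config.fs
    windows = make_windows(n_samples, fs, config.window_spec)
    if schedule.n_windows != len(windows):
        raise SimulationError(
            f"schedule has {schedule.n_windows} windows but the windowing "
            f"implied by the config has {len(windows)}"
        )
    if schedule.n_nodes != n:
        raise SimulationError("schedule node count does not match config")

    fade = min(int(round(0.020 * fs)), max(w[1] - w[0] for w in _spans(windows, n_samples)))

    # One continuous carrier per module label for the whole trial: nodes join
    # and leave it per the schedule.  Non-switching nodes therefore receive a
    # perfectly continuous signal, and cross-module pairs keep rotating at
    # their frequency offset through entire analysis windows.
    n_mod = int(schedule.assignment.max())
    carriers = {
        int(m): _carrier(
            n_samples,
            fs,
            module_frequency(config.carrier_band, n_mod, int(m)),
            rng,
            config.carrier_linewidth_hz,
        )
        for m in np.unique(schedule.assignment)
    }

    out = np.zeros((n, n_samples))
    spans = _spans(windows, n_samples)
    for w, (a, b) in enumerate(spans):
        ext_b = min(b + fade, n_samples)
        seg_len = ext_b - a
        envelope = np.ones(seg_len)
        if a > 0:  # raised-cosine ramp-up over the first `fade` samples
            r = np.arange(min(fade, seg_len))
            envelope[: len(r)] = np.sin(0.5 * np.pi * (r + 0.5) / fade) ** 2
        if ext_b > b:  # complementary ramp-down inside the next span
            r = np.arange(ext_b - b)
            envelope[seg_len - len(r):] = np.cos(0.5 * np.pi * (r + 0.5) / fade) ** 2
        for module in np.unique(schedule.assignment[:, w]):
            members = np.flatnonzero(schedule.assignment[:, w] == module)
            z = carriers[int(module)][a:ext_b]
            phasors = np.exp(-1j * _member_lags(config, members))
            seg = np.real(np.outer(phasors, z * envelope))
            out[members, a:ext_b] += config.coupling_strength * seg

    if config.noise_sd > 0:
        pad = int(round(fs))
        noise = rng.standard_normal((n, n_samples + 2 * pad))
        noise = band_filter(noise, fs, config.carrier_band, order=4)[:, pad : pad + n_samples]
        noise /= np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
        out += config.noise_sd * noise
    return out


def synthesize(
    config: SimConfig,
    schedule: ModuleSchedule | Sequence[ModuleSchedule],
    system_map: SystemMap | None = None,
    condition: str = "synthetic",
    seed: int | None = None,
) -> ROITimeSeriesSet:
    """Render a trial set from planted schedules.

    ``schedule`` may be a single schedule (reused for every trial) or one
    schedule per trial.  All randomness (carriers, lags, noise) flows from a
    single seed (``seed`` or ``config.seed``) through one child stream per
    trial, so identical (config, seed) reproduce bit-identical arrays.
    """
    root = config.seed if seed is None else seed
    if isinstance(schedule, ModuleSchedule):
        schedules = tuple(schedule for _ in range(config.n_trials))
    else:
        schedules = tuple(schedule)
        if len(schedules) != config.n_trials:
            raise SimulationError("need one schedule per trial")
    children = np.random.SeedSequence(root).spawn(config.n_trials)
    data = np.empty((config.n_nodes, config.n_samples, config.n_trials))
    for t, (sched, child) in enumerate(zip(schedules, children)):
        data[:, :, t] = _synthesize_trial(config, sched, np.random.default_rng(child))
    labels = (
        system_map.node_labels
        if system_map is not None and len(system_map.node_labels) == config.n_nodes
        else tuple(f"node{i}" for i in range(config.n_nodes))
    )
    return ROITimeSeriesSet(
        data=data,
        fs=config.fs,
        node_labels=labels,
        condition=condition,
        seed=root,
        config_hash=config.config_hash(),
        schedules=schedules,
    )


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative condition manipulation of the planted dynamics.

    ``switch_scale`` scales each system's module-switch probability in the
    second condition (e.g. {"DMN": 0.5} halves DMN switching); ``co_module_prob``
    sets cross-system module-adoption probabilities in the second condition.
    """

    switch_scale: Mapping[str, float] = field(default_factory=dict)
    co_module_prob: Mapping[tuple[str, str], float] = field(default_factory=dict)


def _scaled_switch_prob(
    config: SimConfig, effect: ConditionEffect, system_map: SystemMap
) -> Mapping[str, float]:
    base = config.switch_prob
    systems = set(system_map.systems)
    if isinstance(base, Mapping):
        base_map = {s: float(base.get(s, 0.0)) for s in systems}
    else:
        base_map = {s: float(base) for s in systems}
    scaled = dict(base_map)
    for s, factor in effect.switch_scale.items():
        if s not in scaled:
            raise SimulationError(f"effect names unknown system {s!r}")
        scaled[s] = base_map[s] * factor
        if not 0 <= scaled[s] <= 1:
            raise SimulationError(
                f"scaled switch probability {scaled[s]:.3f} for {s} outside [0, 1]"
            )
    return scaled


def make_condition_pair(
    config: SimConfig,
    effect: ConditionEffect,
    system_map: SystemMap,
    seed: int | None = None,
    conditions: tuple[str, str] = ("cond1", "cond2"),
) -> tuple[ROITimeSeriesSet, ROITimeSeriesSet]:
    """Matched trial sets whose planted dynamics differ by ``effect``.

    Condition 1 uses the config's base switch probabilities; condition 2
    applies the effect's per-system scaling and co-module probabilities.
    Schedules are drawn independently per trial, so planted per-system
    flexibility differs by the requested factor up to sampling error.
    """
    root = config.seed if seed is None else seed
    cond_seqs = np.random.SeedSequence(root).spawn(2)
    base_probs = _scaled_switch_prob(config, ConditionEffect(), system_map)
    cond2_probs = _scaled_switch_prob(config, effect, system_map)
    sets = []
    for ci, (probs, co_prob, name) in enumerate(
        [
            (base_probs, dict(config.co_module_prob), conditions[0]),
            (cond2_probs, {**dict(config.co_module_prob), **dict(effect.co_module_prob)}, conditions[1]),
        ]
    ):
        seq = cond_seqs[ci]
        sched_rng = np.random.default_rng(seq.spawn(1)[0])
        schedules = [
            make_schedule(
                config.n_nodes,
                config.n_windows,
                config.n_modules,
                probs,
                system_map,
                seed=sched_rng,
                co_module_prob=co_prob,
            )
            for _ in range(config.n_trials)
        ]
        # independent signal seed per condition, derived from the same root
        signal_seed = int(seq.generate_state(1)[0] % (2**31))
        sets.append(
            synthesize(config, schedules, system_map, condition=name, seed=signal_seed)
        )
    return sets[0], sets[1]
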