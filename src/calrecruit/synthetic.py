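"""Synthetic data generator for the basal -> 4-AP co-culture experiment.

Emulates the statistical structure the analysis pipeline assumes: Poisson
firing neurons whose spikes drive single-exponential calcium transients on a
slowly drifting baseline with additive Gaussian noise; a configurable silent
pool; a 4-AP condition that multiplies firing rates and stochastically
recruits previously silent neurons; non-neuronal artifact traces for
classifier training; and multi-culture group designs.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.SeedSequence`` children, so identical (config, seed) pairs
give bit-identical spike trains, traces and movies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import RAW, CalciumTransientModel, FluorescenceMovie, SpikeTrain, Trace
from .errors import ConfigError, LayoutError

BASAL = "basal"
FOURAP = "fourap"
WINDOWS = (BASAL, FOURAP)

NEURONAL = "neuronal"
NON_NEURONAL = "non_neuronal"

ARTIFACT_KINDS = ("flat", "slow_wave", "step")

# fixed substream indices so that adding streams never reshuffles old ones
_STREAMS = {
    "assignment": 0,
    "basal_spikes": 1,
    "fourap_spikes": 2,
    "recruitment": 3,
    "trace_noise": 4,
    "movie_noise": 5,
    "artifacts": 6,
    "gap_spikes": 7,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated culture.

    Defaults reproduce the experimental protocol the pipeline targets:
    10 min recording windows at 20 frames/s, sparse basal Poisson firing,
    a 4-AP treatment that triples firing rates and recruits 40% of the
    silent pool, 1% dF/F / 3 s calcium transients, 5%-of-baseline sinusoidal
    drift over 300 s, and Gaussian noise at one fifth of the transient
    amplitude (A/sigma = 5).
    """

    n_neurons: int = 200
    duration_s: float = 600.0
    frame_rate_hz: float = 20.0
    basal_rate_hz: float = 0.05
    silent_fraction: float = 0.5
    fourap_rate_multiplier: float = 3.0
    recruitment_prob: float = 0.4
    transient: CalciumTransientModel = field(default_factory=CalciumTransientModel)
    noise_sd: float = 0.2           # percent dF/F units
    drift_amplitude: float = 5.0    # percent of baseline
    drift_period_s: float = 300.0
    baseline_level: float = 100.0   # raw fluorescence units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ConfigError(f"n_neurons must be >= 0, got {self.n_neurons}")
        if not (self.duration_s > 0):
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        if not (self.frame_rate_hz > 0):
            raise ConfigError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        for name in ("basal_rate_hz", "fourap_rate_multiplier", "noise_sd",
                     "drift_amplitude", "drift_period_s", "baseline_level"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("silent_fraction", "recruitment_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def rng(self, stream: str, *key: int) -> np.random.Generator:
        """Named, reproducible substream of the config's master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream], *key))
        return np.random.default_rng(ss)


def silent_mask(config: SimulationConfig) -> np.ndarray:
    """Boolean mask of neurons with zero basal rate (seeded, config-stable)."""
    n_silent = int(round(config.silent_fraction * config.n_neurons))
    order = config.rng("assignment").permutation(config.n_neurons)
    mask = np.zeros(config.n_neurons, dtype=bool)
    mask[order[:n_silent]] = True
    return mask


def recruited_mask(config: SimulationConfig) -> np.ndarray:
    """Silent neurons independently recruited in the 4-AP window (Bernoulli)."""
    silent = silent_mask(config)
    draws = config.rng("recruitment").random(config.n_neurons) < config.recruitment_prob
    return silent & draws


def firing_rates(config: SimulationConfig, window: str) -> np.ndarray:
    """Per-neuron Poisson rate (Hz) in the requested window."""
    if window not in WINDOWS:
        raise ConfigError(f"window must be one of {WINDOWS}, got {window!r}")
    silent = silent_mask(config)
    rates = np.where(silent, 0.0, config.basal_rate_hz)
    if window == FOURAP:
        rates = rates * config.fourap_rate_multiplier
        boosted = config.basal_rate_hz * config.fourap_rate_multiplier
        rates[recruited_mask(config)] = boosted
    return rates


def _poisson_train(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    count = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=count))


def simulate_spike_trains(config: SimulationConfig, window: str = BASAL) -> list[SpikeTrain]:
    """Homogeneous Poisson spike trains for one recording window.

    Active neurons fire at ``basal_rate_hz`` (times ``fourap_rate_multiplier``
    in the 4-AP window); each silent neuron is independently recruited in the
    4-AP window with probability ``recruitment_prob`` and then fires at the
    boosted rate. Times are window-local, in ``[0, duration_s)``.
    """
    rates = firing_rates(config, window)
    stream = "basal_spikes" if window == BASAL else "fourap_spikes"
    trains = []
    for i, rate in enumerate(rates):
        rng = config.rng(stream, i)
        trains.append(SpikeTrain(i, _poisson_train(rng, rate, config.duration_s),
                                 config.frame_rate_hz, window=window))
    return trains


def drift_values(config: SimulationConfig, times_s: np.ndarray) -> np.ndarray:
    """Slow baseline drift in percent of baseline: a seeded-free sinusoid."""
    if config.drift_amplitude == 0 or config.drift_period_s == 0:
        return np.zeros_like(times_s)
    return config.drift_amplitude * np.sin(2 * np.pi * times_s / config.drift_period_s)


def render_trace(
    spikes: SpikeTrain,
    config: SimulationConfig,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Raw fluorescence trace implied by a spike train.

    ``F(t) = B * [1 + drift(t)/100 + sum_k (A/100) * exp(-(t - t_k)/tau)] + eps``
    with ``eps ~ N(0, (noise_sd/100 * B)^2)`` per frame. Superposition is
    linear (non-saturating); transients start exactly at the (possibly
    inter-frame) spike times.
    """
    dur = config.duration_s if duration_s is None else float(duration_s)
    if not (dur > 0):
        raise ConfigError("duration_s must be > 0")
    n = int(round(dur * config.frame_rate_hz))
    t = np.arange(n) / config.frame_rate_hz
    A = config.transient.amplitude_pct
    tau = config.transient.decay_s
    signal_pct = np.zeros(n)
    for tk in spikes.spike_times_s:
        i0 = int(np.ceil(tk * config.frame_rate_hz - 1e-9))
        if i0 >= n:
            continue
        signal_pct[i0:] += A * np.exp(-(t[i0:] - tk) / tau)
    raw = config.baseline_level * (
        1.0 + drift_values(config, t) / 100.0 + signal_pct / 100.0
    )
    if config.noise_sd > 0:
        if rng is None:
            rng = config.rng("trace_noise", spikes.roi_id)
        raw = raw + rng.normal(0.0, config.noise_sd / 100.0 * config.baseline_level, n)
    return Trace(raw, config.frame_rate_hz, RAW, spikes.roi_id)


# ---------------------------------------------------------------------------
# artifact (non-neuronal) traces

def render_artifact_trace(
    kind: str,
    config: SimulationConfig,
    roi_id: int,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Non-neuronal trace of one of three classes.

    ``flat``: baseline + drift + noise only; ``slow_wave``: an extra
    large slow oscillation (astrocyte-like calcium wave, 2-4% amplitude,
    20-60 s period); ``step``: an abrupt persistent baseline shift of
    5-10% at a random time (focus/debris artifact).
    """
    if kind not in ARTIFACT_KINDS:
        raise ConfigError(f"unknown artifact kind {kind!r}")
    if rng is None:
        rng = config.rng("artifacts", roi_id)
    n = config.n_frames
    t = np.arange(n) / config.frame_rate_hz
    pct = drift_values(config, t).copy()
    if kind == "slow_wave":
        amp = rng.uniform(2.0, 4.0)
        period = rng.uniform(20.0, 60.0)
        phase = rng.uniform(0, 2 * np.pi)
        pct += amp * np.sin(2 * np.pi * t / period + phase)
    elif kind == "step":
        at = rng.uniform(0.1, 0.9) * config.duration_s
        delta = rng.choice([-1.0, 1.0]) * rng.uniform(5.0, 10.0)
        pct += np.where(t >= at, delta, 0.0)
    raw = config.baseline_level * (1.0 + pct / 100.0)
    if config.noise_sd > 0:
        raw = raw + rng.normal(0.0, config.noise_sd / 100.0 * config.baseline_level, n)
    return Trace(raw, config.frame_rate_hz, RAW, roi_id)


# ---------------------------------------------------------------------------
# movies

def make_layout(
    n_somata: int,
    frame_shape: tuple[int, int],
    radius_px: float = 4.0,
    min_spacing_px: float | None = None,
) -> np.ndarray:
    """Grid of non-overlapping soma centers: array of (row, col, radius).

    Raises LayoutError when the canvas cannot hold ``n_somata`` at the
    requested spacing (default spacing 6 radii, guaranteeing disjoint
    footprints at the 3-sigma truncation used by :func:`render_movie`).
    """
    h, w = frame_shape
    spacing = 6.0 * radius_px if min_spacing_px is None else float(min_spacing_px)
    margin = spacing / 2.0
    rows = int((h - 2 * margin) // spacing) + 1 if h >= 2 * margin else 0
    cols = int((w - 2 * margin) // spacing) + 1 if w >= 2 * margin else 0
    if rows * cols < n_somata:
        raise LayoutError(
            f"canvas {frame_shape} holds at most {rows * cols} somata at "
            f"spacing {spacing:g}px; {n_somata} requested"
        )
    out = []
    for i in range(n_somata):
        r, c = divmod(i, cols)
        out.append((margin + r * spacing, margin + c * spacing, radius_px))
    return np.asarray(out, dtype=float)


def render_movie(
    traces: Sequence[Trace],
    layout: np.ndarray,
    frame_shape: tuple[int, int],
    background: float = 10.0,
    pixel_noise_sd: float = 0.0,
    frame_rate_hz: float | None = None,
    rng: np.random.Generator | None = None,
) -> FluorescenceMovie:
    """Movie with one 2-D Gaussian soma footprint per trace.

    Each frame is ``background + sum_i footprint_i * trace_i[t]`` plus
    optional Gaussian pixel noise (clipped at zero). Footprints have peak 1
    at the soma center, sigma = radius/2, truncated at 3 sigma.
    """
    layout = np.asarray(layout, dtype=float)
    if len(traces) != len(layout):
        raise LayoutError(f"{len(traces)} traces but {len(layout)} layout entries")
    h, w = frame_shape
    if len(layout):
        if (np.any(layout[:, 0] < 0) or np.any(layout[:, 1] < 0)
                or np.any(layout[:, 0] >= h) or np.any(layout[:, 1] >= w)):
            raise LayoutError("soma centers fall outside the canvas")
    if frame_rate_hz is None:
        frame_rate_hz = traces[0].frame_rate_hz if traces else 20.0
    n_frames = traces[0].n_frames if traces else 1
    rr, cc = np.mgrid[0:h, 0:w]
    movie = np.full((n_frames, h, w), float(background))
    for tr, (r0, c0, rad) in zip(traces, layout):
        if tr.n_frames != n_frames:
            raise LayoutError("all traces must have the same length")
        sigma = rad / 2.0
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        fp = np.exp(-d2 / (2 * sigma**2))
        fp[d2 > (3 * sigma) ** 2] = 0.0
        movie += tr.values[:, None, None] * fp[None, :, :]
    if pixel_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        movie = movie + rng.normal(0.0, pixel_noise_sd, movie.shape)
    np.clip(movie, 0.0, None, out=movie)
    return FluorescenceMovie(movie, frame_rate_hz)


# ---------------------------------------------------------------------------
# labeled trace sets, sessions, and experiment designs

def _n_artifacts(n_neurons: int, artifact_fraction: float) -> int:
    if not (0.0 <= artifact_fraction < 1.0):
        raise ConfigError("artifact_fraction must be in [0, 1)")
    return int(round(artifact_fraction / (1.0 - artifact_fraction) * n_neurons))


def label_table(trains: Sequence[SpikeTrain], artifact_kinds: Sequence[str]) -> pd.DataFrame:
    """Ground-truth labels: neuronal iff the source neuron fired >= 1 spike.

    Silent neurons produce traces indistinguishable from flat artifacts and
    are labeled non-neuronal — the classifier's target is the *neuronal
    activity* class, not anatomical identity. The ``kind`` column keeps the
    anatomical provenance for diagnostics.
    """
    rows = [
        {"roi_id": tr.roi_id,
         "label": NEURONAL if tr.n_spikes > 0 else NON_NEURONAL,
         "kind": "neuron", "source": "ground_truth"}
        for tr in trains
    ]
    next_id = (max((tr.roi_id for tr in trains), default=-1)) + 1
    for j, kind in enumerate(artifact_kinds):
        rows.append({"roi_id": next_id + j, "label": NON_NEURONAL,
                     "kind": kind, "source": "ground_truth"})
    return pd.DataFrame(rows, columns=["roi_id", "label", "kind", "source"])


@dataclass
class CultureRecord:
    """One simulated culture: spike trains, labels, and (optionally) traces."""

    culture_id: int
    genotype: str
    treatment: str  # basal | fourap
    config: SimulationConfig
    spike_trains: list[SpikeTrain]
    labels: pd.DataFrame
    traces: list[Trace] | None = None

    @property
    def window_duration_s(self) -> float:
        return self.config.duration_s


def simulate_culture(
    config: SimulationConfig,
    treatment: str,
    culture_id: int = 0,
    genotype: str = "wt",
    artifact_fraction: float = 0.10,
    render_traces: bool = False,
) -> CultureRecord:
    """Simulate one culture recorded in a single treatment window."""
    trains = simulate_spike_trains(config, window=treatment)
    n_art = _n_artifacts(config.n_neurons, artifact_fraction)
    art_rng = config.rng("artifacts")
    kinds = [ARTIFACT_KINDS[int(art_rng.integers(len(ARTIFACT_KINDS)))] for _ in range(n_art)]
    labels = label_table(trains, kinds)
    traces = None
    if render_traces:
        traces = [render_trace(tr, config) for tr in trains]
        base = config.n_neurons
        traces += [
            render_artifact_trace(kind, config, roi_id=base + j)
            for j, kind in enumerate(kinds)
        ]
    return CultureRecord(culture_id, genotype, treatment, config, trains, labels, traces)


def simulate_experiment_set(
    configs: Mapping[str, SimulationConfig],
    design: Mapping[tuple[str, str], int],
    master_seed: int = 0,
    artifact_fraction: float = 0.10,
    render_traces: bool = False,
    culture_rate_cv: float = 0.2,
) -> list[CultureRecord]:
    """Independent seeded cultures for each (genotype, treatment) design cell.

    ``configs`` maps genotype level -> its SimulationConfig (e.g. different
    recruitment probabilities); ``design`` maps (genotype, treatment) ->
    number of cultures. Culture-to-culture variability is modeled as a
    log-normal multiplier on the basal rate with coefficient of variation
    ``culture_rate_cv``. Per-culture seeds derive deterministically from
    ``master_seed``.
    """
    for (g, t), n in design.items():
        if g not in configs:
            raise ConfigError(f"design references unknown genotype {g!r}")
        if t not in WINDOWS:
            raise ConfigError(f"design treatment must be one of {WINDOWS}, got {t!r}")
        if n < 1:
            raise ConfigError("each design cell needs >= 1 culture")
    records: list[CultureRecord] = []
    cid = 0
    sigma = math.sqrt(math.log(1.0 + culture_rate_cv**2)) if culture_rate_cv > 0 else 0.0
    for (genotype, treatment), n_cultures in sorted(design.items()):
        base = configs[genotype]
        for _ in range(n_cultures):
            child = np.random.SeedSequence(master_seed, spawn_key=(cid,))
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            rate = base.basal_rate_hz
            if sigma > 0:
                jitter_rng = np.random.default_rng(
                    np.random.SeedSequence(master_seed, spawn_key=(cid, 1))
                )
                rate = rate * float(jitter_rng.lognormal(-0.5 * sigma**2, sigma))
            cfg = replace(base, seed=sub_seed, basal_rate_hz=rate)
            records.append(
                simulate_culture(cfg, treatment, culture_id=cid, genotype=genotype,
                                 artifact_fraction=artifact_fraction,
                                 render_traces=render_traces)
            )
            cid += 1
    return records


@dataclass
class SessionRecord:
    """One culture recorded through the full within-dish protocol.

    Timeline: ``[0, d)`` basal, ``[d, d + gap)`` drug diffusion /
    stabilization (excluded from analysis), ``[d + gap, 2d + gap)`` 4-AP.
    """

    config: SimulationConfig
    gap_s: float
    traces: list[Trace]
    labels: pd.DataFrame
    truth: dict[str, list[SpikeTrain]]  # window -> trains with absolute times

    @property
    def windows(self) -> list[tuple[float, float, str]]:
        d, g = self.config.duration_s, self.gap_s
        return [(0.0, d, BASAL), (d + g, 2 * d + g, FOURAP)]

    @property
    def total_duration_s(self) -> float:
        return 2 * self.config.duration_s + self.gap_s


def simulate_session(
    config: SimulationConfig,
    gap_s: float = 300.0,
    artifact_fraction: float = 0.10,
    render_traces: bool = True,
) -> SessionRecord:
    """Full basal -> 4-AP recording of one culture as a single trace set.

    The drug is present from the start of the gap, so gap and 4-AP segments
    both use the 4-AP rates; analysis windows exclude the gap.
    """
    d = config.duration_s
    basal = simulate_spike_trains(config, BASAL)
    fourap = simulate_spike_trains(config, FOURAP)
    rates_4ap = firing_rates(config, FOURAP)
    truth_basal, truth_4ap, full = [], [], []
    for i in range(config.n_neurons):
        rng_gap = config.rng("gap_spikes", i)
        gap_times = d + _poisson_train(rng_gap, rates_4ap[i], gap_s)
        t_basal = basal[i].spike_times_s
        t_4ap = d + gap_s + fourap[i].spike_times_s
        all_times = np.concatenate([t_basal, gap_times, t_4ap])
        full.append(SpikeTrain(i, all_times, config.frame_rate_hz))
        truth_basal.append(SpikeTrain(i, t_basal, config.frame_rate_hz, window=BASAL))
        truth_4ap.append(SpikeTrain(i, t_4ap, config.frame_rate_hz, window=FOURAP))
    n_art = _n_artifacts(config.n_neurons, artifact_fraction)
    art_rng = config.rng("artifacts")
    kinds = [ARTIFACT_KINDS[int(art_rng.integers(len(ARTIFACT_KINDS)))] for _ in range(n_art)]
    labels = label_table(full, kinds)
    traces: list[Trace] = []
    if render_traces:
        total = 2 * d + gap_s
        traces = [render_trace(tr, config, duration_s=total) for tr in full]
        long_cfg = replace(config, duration_s=total)
        base_id = config.n_neurons
        traces += [
            render_artifact_trace(kind, long_cfg, roi_id=base_id + j)
            for j, kind in enumerate(kinds)
        ]
    return SessionRecord(config, gap_s, traces, labels,
                         {BASAL: truth_basal, FOURAP: truth_4ap})
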