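"""Core containers shared across the calcium-imaging pipeline.

Conventions: time in seconds, rates in Hz; fluorescence is either in raw
camera units (``"raw"``/``"smoothed"`` stages) or in percent dF/F
(``"normalized"`` stage, i.e. ``100 * (F - F0) / F0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EmptyInputError

RAW = "raw"
SMOOTHED = "smoothed"
NORMALIZED = "normalized"
STAGES = (RAW, SMOOTHED, NORMALIZED)


@dataclass(frozen=True)
class CalciumTransientModel:
    """Single-spike calcium response: a decaying exponential.

    The fluorescence response to one action potential is modeled as
    ``A * exp(-t / tau)`` in percent dF/F, with linear (non-saturating)
    superposition across spikes.

    Parameters
    ----------
    amplitude_pct:
        Peak response per spike, in percent dF/F. Default 1.
    decay_s:
        Decay time constant tau in seconds. Default 3.
    saturating:
        Must be False; only linear superposition is supported.
    """

    amplitude_pct: float = 1.0
    decay_s: float = 3.0
    saturating: bool = False

    def __post_init__(self) -> None:
        if not (self.amplitude_pct > 0):
            raise ConfigError(f"amplitude_pct must be > 0, got {self.amplitude_pct}")
        if not (self.decay_s > 0):
            raise ConfigError(f"decay_s must be > 0, got {self.decay_s}")
        if self.saturating:
            raise ConfigError("only non-saturating (linear) transients are supported")


def transient_template(
    model: CalciumTransientModel,
    n_frames: int,
    frame_rate_hz: float,
    truncate_frac: float = 0.01,
) -> np.ndarray:
    """Sampled transient kernel ``k[j] = A * exp(-j / (tau * fr))``.

    The kernel is truncated where it falls below ``truncate_frac`` of the
    amplitude (default 1%), so its length is at most
    ``ceil(tau * fr * ln(1/truncate_frac))`` frames.
    """
    if n_frames < 1:
        raise ConfigError(f"n_frames must be >= 1, got {n_frames}")
    if not (frame_rate_hz > 0):
        raise ConfigError(f"frame_rate_hz must be > 0, got {frame_rate_hz}")
    j = np.arange(int(n_frames), dtype=float)
    k = model.amplitude_pct * np.exp(-j / (model.decay_s * frame_rate_hz))
    keep = k >= truncate_frac * model.amplitude_pct
    if keep.all():
        return k
    last = int(np.nonzero(keep)[0][-1])
    return k[: last + 1]


@dataclass
class Trace:
    """Per-ROI fluorescence time series at a fixed frame rate."""

    values: np.ndarray
    frame_rate_hz: float
    stage: str = RAW
    roi_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ConfigError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError(f"trace {self.roi_id} contains non-finite values")
        if not (self.frame_rate_hz > 0):
            raise ConfigError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "Trace":
        return Trace(values, self.frame_rate_hz, stage or self.stage, self.roi_id)


@dataclass
class SpikeTrain:
    """Spike times for one neuron, in seconds from recording start.

    Times are non-decreasing; several spikes may share a frame
    (non-saturating superposition permits stacked events).
    """

    roi_id: int
    spike_times_s: np.ndarray
    frame_rate_hz: float
    window: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.ndim != 1:
            raise ConfigError("spike_times_s must be 1-D")
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise ConfigError("spike times must be non-negative and sorted")
        self.spike_times_s = t
        if not (self.frame_rate_hz > 0):
            raise ConfigError("frame_rate_hz must be > 0")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    @property
    def spike_frames(self) -> np.ndarray:
        # floor with a small epsilon so times that are exact frame multiples
        # do not land on the previous frame through float round-off
        return np.floor(self.spike_times_s * self.frame_rate_hz + 1e-9).astype(int)

    def in_window(self, start_s: float, end_s: float, name: str | None = None) -> "SpikeTrain":
        """Spikes with onset time in ``[start_s, end_s)`` (absolute times kept)."""
        t = self.spike_times_s
        sel = (t >= start_s) & (t < end_s)
        return SpikeTrain(self.roi_id, t[sel], self.frame_rate_hz, window=name)


@dataclass
class FluorescenceMovie:
    """Time-ordered stack of 2-D intensity frames at a fixed frame rate."""

    frames: np.ndarray  # shape (T, H, W), nonnegative
    frame_rate_hz: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigError("movie frames must have shape (T, H, W)")
        if self.frames.shape[0] < 1:
            raise EmptyInputError("movie has no frames")
        if np.any(self.frames < 0):
            raise ConfigError("movie intensities must be nonnegative")
        if not (self.frame_rate_hz > 0):
            raise ConfigError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


@dataclass
class RoiMask:
    """Pixel footprint of one detected cell body."""

    id: int
    pixels: np.ndarray  # shape (n_px, 2), integer (row, col), 0-based

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] < 1:
            raise ConfigError("ROI pixels must be a non-empty (n, 2) array")
        self.pixels = px

    @property
    def area_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixels.mean(axis=0)
        return (float(r), float(c))
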