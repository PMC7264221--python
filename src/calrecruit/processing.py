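"""Trace smoothing, percentile-block baseline estimation, and dF/F.

The baseline F0 of each trace is estimated from one reference point per
50 s block: the sample of the smoothed trace whose value is closest to the
block's 10th percentile, kept at its own time coordinate so the point lies
on the slow drift curve. A spline through these points, evaluated at every
frame, gives F0; the original (unsmoothed) trace is then normalized to
``100 * (F - F0) / F0`` percent units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline, make_interp_spline

from .core import NORMALIZED, SMOOTHED, Trace
from .errors import DegenerateBaselineError, ParameterError


def smooth_trace(trace: Trace, window_frames: int = 5) -> Trace:
    """Centered moving average with edge truncation (length preserved).

    Near the boundaries the window shrinks to the available samples, so a
    constant trace is exactly unchanged. ``window_frames`` must be odd.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ParameterError(f"window_frames must be a positive odd count, got {window_frames}")
    if window_frames == 1:
        return trace.with_values(trace.values.copy(), SMOOTHED)
    v = trace.values
    kern = np.ones(window_frames)
    num = np.convolve(v, kern, mode="same")
    den = np.convolve(np.ones_like(v), kern, mode="same")
    return trace.with_values(num / den, SMOOTHED)


def pick_reference_points(
    trace: Trace,
    block_s: float = 50.0,
    lower_percentile: float = 0.10,
    min_partial_frac: float = 0.25,
) -> list[tuple[float, float]]:
    """One baseline reference point per block of ``block_s`` seconds.

    Per block, the 10th-percentile value (linear-interpolation convention)
    is computed and the block sample whose value is nearest to it (earliest
    on ties) becomes the reference point, at its own time. A trailing
    partial block shorter than ``min_partial_frac`` of a block is merged
    into the previous one; a trace shorter than one block yields a single
    reference point.
    """
    if not (block_s > 0):
        raise ParameterError("block_s must be > 0")
    if not (0.0 <= lower_percentile <= 1.0):
        raise ParameterError("lower_percentile must be in [0, 1]")
    v = trace.values
    n = v.size
    bs = max(int(round(block_s * trace.frame_rate_hz)), 1)
    starts = list(range(0, n, bs))
    if len(starts) > 1 and n - starts[-1] < min_partial_frac * bs:
        starts.pop()  # merge the short tail into the previous block
    points = []
    for i, a in enumerate(starts):
        b = starts[i + 1] if i + 1 < len(starts) else n
        seg = v[a:b]
        target = np.percentile(seg, lower_percentile * 100.0)
        idx = a + int(np.argmin(np.abs(seg - target)))  # argmin takes earliest tie
        points.append((idx / trace.frame_rate_hz, float(v[idx])))
    return points


@dataclass
class BaselineModel:
    """Fitted baseline: the reference points and F0 at every frame time."""

    reference_points: list[tuple[float, float]]
    baseline_values: np.ndarray

    def __post_init__(self) -> None:
        self.baseline_values = np.asarray(self.baseline_values, dtype=float)
        times = [t for t, _ in self.reference_points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("reference times must be strictly increasing")


def fit_baseline(
    reference_points: list[tuple[float, float]],
    n_frames: int,
    frame_rate_hz: float,
    smoothing: float | None = None,
    extrapolation: str = "linear",
) -> BaselineModel:
    """Spline through the reference points, evaluated at every frame time.

    With one point the baseline is constant; with 2-3 points the spline
    degree is reduced accordingly; with >= 4 points it is cubic. By default
    the spline interpolates the points (with ~12 points per 10 min window a
    smoothing penalty is redundant); pass ``smoothing`` to fit a smoothing
    spline (``scipy.interpolate.UnivariateSpline`` penalty) instead.

    Beyond the first/last reference point the baseline continues linearly
    along the spline's end tangent (``extrapolation="linear"``); pass
    ``"constant"`` to hold the end values instead. Linear continuation keeps
    edge errors second-order in the gap length when the drift has nonzero
    slope at the recording boundaries.
    """
    if not reference_points:
        raise ParameterError("need at least one reference point")
    if extrapolation not in ("linear", "constant"):
        raise ParameterError("extrapolation must be 'linear' or 'constant'")
    times = np.asarray([t for t, _ in reference_points], dtype=float)
    vals = np.asarray([v for _, v in reference_points], dtype=float)
    t = np.arange(int(n_frames)) / frame_rate_hz
    if len(times) == 1:
        base = np.full(int(n_frames), vals[0])
        return BaselineModel(list(reference_points), base)
    k = min(3, len(times) - 1)
    if smoothing is None or len(times) <= k + 1:
        spl = make_interp_spline(times, vals, k=k)
    else:
        spl = UnivariateSpline(times, vals, k=k, s=smoothing)
    tc = np.clip(t, times[0], times[-1])
    base = np.asarray(spl(tc), dtype=float)
    if extrapolation == "linear":
        d = spl.derivative()
        lo = t < times[0]
        hi = t > times[-1]
        base[lo] = float(spl(times[0])) + float(d(times[0])) * (t[lo] - times[0])
        base[hi] = float(spl(times[-1])) + float(d(times[-1])) * (t[hi] - times[-1])
    return BaselineModel(list(reference_points), base)


def normalize_trace(trace: Trace, baseline: BaselineModel) -> Trace:
    """Percent dF/F of the *original* trace: ``100 * (F - F0) / F0``.

    F0 must be strictly positive at every frame.
    """
    f0 = baseline.baseline_values
    if f0.size != trace.n_frames:
        raise ParameterError(
            f"baseline has {f0.size} frames but trace has {trace.n_frames}"
        )
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise DegenerateBaselineError(
            f"baseline is non-positive at frame {int(bad[0])} (trace {trace.roi_id})"
        )
    return trace.with_values(100.0 * (trace.values - f0) / f0, NORMALIZED)


def refine_baseline(
    raw: Trace,
    reconstruction_pct: np.ndarray,
    prior: BaselineModel,
    event_frames: np.ndarray | None = None,
    decay_s: float = 3.0,
    pad_s: float | None = None,
    block_s: float = 10.0,
    min_block_frac: float = 0.10,
    percentile: float = 0.20,
    extrapolation: str = "linear",
) -> BaselineModel:
    """Re-estimate F0 after removing inferred transients from the raw trace.

    The reconstruction (in percent dF/F, from a spike-inference pass) is
    converted to raw units with the prior baseline and subtracted; what
    remains is baseline plus noise, so F0 can be re-fitted densely — one
    reference point every ``block_s`` seconds — instead of the sparse
    points available on the uncorrected trace. This removes the
    interpolation error of widely spaced reference points.

    Two robustness measures deal with first-pass inference mistakes:

    * frames within two decay constants after an inferred event onset are
      excluded — where a spurious event was subtracted the cleaned trace
      dips below baseline, and those dips would otherwise drag the new
      baseline down and reinforce the false positive on the next pass;
    * each block contributes its ``percentile`` quantile plus the expected
      Gaussian-noise quantile offset (estimated robustly from first
      differences), not its mean — unbiased on clean blocks yet insensitive
      to transients the first pass missed, which elevate the upper part of
      the block's distribution only.

    Blocks retaining fewer than ``min_block_frac`` of their frames
    contribute no reference point.
    """
    from scipy.stats import norm as _norm

    rec = np.asarray(reconstruction_pct, dtype=float)
    if rec.size != raw.n_frames:
        raise ParameterError("reconstruction length does not match the trace")
    if not (0.0 < percentile < 0.5):
        raise ParameterError("percentile must be in (0, 0.5)")
    fr = raw.frame_rate_hz
    n = raw.n_frames
    cleaned = raw.values - prior.baseline_values * rec / 100.0
    keep = np.ones(n, dtype=bool)
    if event_frames is not None:
        pad = int(round((2.0 * decay_s if pad_s is None else pad_s) * fr))
        for f in np.asarray(event_frames, dtype=int):
            keep[max(f, 0) : min(f + pad, n)] = False
    # robust noise scale from first differences (transients are smooth at
    # the frame scale, so diffs are ~ N(0, 2 sigma^2) plus rare jumps)
    diffs = np.diff(cleaned)
    sigma = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2.0)
    bias = -float(_norm.ppf(percentile)) * sigma  # quantile -> mean offset
    bs = max(int(round(block_s * fr)), 1)
    points = []
    for a in range(0, n, bs):
        b = min(a + bs, n)
        idx = np.nonzero(keep[a:b])[0]
        if idx.size < min_block_frac * (b - a):
            continue
        vals = cleaned[a + idx]
        level = float(np.percentile(vals, percentile * 100.0)) + bias
        t_ref = (a + float(idx.mean())) / fr
        points.append((t_ref, level))
    if not points:
        return prior
    return fit_baseline(points, n, fr, extrapolation=extrapolation)


def correct_trace(
    trace: Trace,
    smooth_window: int = 5,
    block_s: float = 50.0,
    lower_percentile: float = 0.10,
    smoothing: float | None = None,
    extrapolation: str = "linear",
) -> tuple[Trace, BaselineModel]:
    """Full per-trace pipeline: smooth -> reference points -> spline -> dF/F.

    Reference points are picked on the smoothed trace; the normalization is
    applied to the raw input trace. Returns (normalized trace, baseline).
    """
    sm = smooth_trace(trace, smooth_window)
    refs = pick_reference_points(sm, block_s=block_s, lower_percentile=lower_percentile)
    model = fit_baseline(refs, trace.n_frames, trace.frame_rate_hz,
                         smoothing=smoothing, extrapolation=extrapolation)
    return normalize_trace(trace, model), model
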