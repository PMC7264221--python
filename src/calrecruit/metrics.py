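"""Culture-level activity read-outs.

Per-neuron firing rate, active-neuron count/fraction (a neuron is active
when at least one spike is detected in the analysis window), and the global
firing rate (total spikes per unit time in the culture, not divided by
neuron count). Per-culture summaries — not individual neurons — are the
statistical units passed to the group-comparison stage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import pandas as pd

from .core import SpikeTrain
from .errors import EmptyInputError, ParameterError, SchemaError
from .synthetic import CultureRecord


def firing_rate(spikes: SpikeTrain, window_duration_s: float) -> float:
    """Spikes per second in the window: ``n_spikes / duration``."""
    if not (window_duration_s > 0):
        raise ParameterError(f"window duration must be > 0, got {window_duration_s}")
    return spikes.n_spikes / window_duration_s


def count_active(
    trains: Sequence[SpikeTrain], n_classified: int | None = None
) -> tuple[int, float]:
    """Number and fraction of neurons with >= 1 spike.

    The fraction denominator defaults to ``len(trains)`` (the classified
    neurons whose trains were inferred); pass ``n_classified`` to use a
    different denominator.
    """
    denom = len(trains) if n_classified is None else int(n_classified)
    if denom <= 0:
        raise EmptyInputError("fraction of active neurons is undefined for an empty neuron set")
    n_active = sum(1 for tr in trains if tr.n_spikes > 0)
    return n_active, n_active / denom


def global_firing_rate(
    trains: Sequence[SpikeTrain], window_duration_s: float, per_neuron: bool = False
) -> float:
    """Total spikes across the culture per unit time (Hz).

    With ``per_neuron=True`` the total is additionally divided by the number
    of neurons, making it the mean individual rate.
    """
    if not (window_duration_s > 0):
        raise ParameterError(f"window duration must be > 0, got {window_duration_s}")
    total = sum(tr.n_spikes for tr in trains)
    rate = total / window_duration_s
    if per_neuron:
        if not trains:
            raise EmptyInputError("per-neuron global rate is undefined for an empty culture")
        rate /= len(trains)
    return rate


@dataclass
class ExperimentSummary:
    """One culture x window: the Fig.-style per-experiment averages."""

    culture_id: int | str
    genotype: str
    window: str
    n_neurons: int
    mean_firing_rate_hz: float
    n_active: int
    fraction_active: float
    global_firing_rate_hz: float
    total_spikes: int
    window_duration_s: float


def summarize_experiment(
    trains_by_window: Mapping[str, Sequence[SpikeTrain]],
    window_durations: Mapping[str, float],
    culture_id: int | str = 0,
    genotype: str = "wt",
    n_classified: int | None = None,
) -> list[ExperimentSummary]:
    """One summary row per analysis window of one culture."""
    out = []
    for window, trains in trains_by_window.items():
        if window not in window_durations:
            raise SchemaError(f"no duration supplied for window {window!r}")
        if not trains:
            raise EmptyInputError(f"window {window!r} has no classified neurons")
        dur = window_durations[window]
        n_active, frac = count_active(trains, n_classified)
        rates = [firing_rate(tr, dur) for tr in trains]
        total = sum(tr.n_spikes for tr in trains)
        out.append(
            ExperimentSummary(
                culture_id=culture_id,
                genotype=genotype,
                window=window,
                n_neurons=len(trains),
                mean_firing_rate_hz=sum(rates) / len(rates),
                n_active=n_active,
                fraction_active=frac,
                global_firing_rate_hz=global_firing_rate(trains, dur),
                total_spikes=int(total),
                window_duration_s=float(dur),
            )
        )
    return out


def summary_table(summaries: Sequence[ExperimentSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame, one row per (culture, window)."""
    return pd.DataFrame([asdict(s) for s in summaries])


def summarize_cultures(records: Sequence[CultureRecord]) -> pd.DataFrame:
    """Summary table for a simulated between-group experiment set.

    Each record contributes one row for its own treatment window; the
    ``window`` column doubles as the treatment factor level.
    """
    rows = []
    for rec in records:
        s = summarize_experiment(
            {rec.treatment: rec.spike_trains},
            {rec.treatment: rec.window_duration_s},
            culture_id=rec.culture_id,
            genotype=rec.genotype,
        )[0]
        rows.append(s)
    return summary_table(rows)
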