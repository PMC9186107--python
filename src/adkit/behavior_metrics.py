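"""Binned behavioral outcome rates (hit rate, false-alarm rate).

Trials end in a hit (saccade to the changed stimulus within 400 ms), a miss
(fixation held past the change), or a false alarm (saccade to an unchanged
stimulus).  Hit rate per sliding bin is hits / (hits + misses); false-alarm
rate is false alarms / all completed trials in the bin (the denominator is a
package choice, configurable via ``fa_denominator``).  The bin geometry is
shared with every other metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedSeries, window_edges

__all__ = ["BehaviorSeries", "binned_outcome_rates"]


@dataclass
class BehaviorSeries:
    hit_rate: BinnedSeries
    false_alarm_rate: BinnedSeries


def binned_outcome_rates(events: pd.DataFrame, duration_min: float,
                         window_min: float = 30.0, step_min: float = 6.0,
                         fa_denominator: str = "all") -> BehaviorSeries:
    """Sliding-window hit and false-alarm rates from the event table.

    A trial is located in time at its terminal (outcome-bearing) stimulus
    period.  Bins with an empty denominator are dropped; downstream pairwise
    bin alignment handles the gaps.  ``fa_denominator``: "all" divides false
    alarms by all completed trials in the bin, "fa_miss" by trials ending in
    a false alarm or miss.
    """
    term = events[(events.period_type == "stimulus") & (events.outcome != "")]
    if term.empty:
        raise ValueError("event table has no outcome labels")
    t_min = term.onset.to_numpy() / 60.0
    outcome = term.outcome.to_numpy()

    edges = window_edges(duration_min, window_min, step_min)
    centers = edges + window_min / 2.0

    def rate(num_mask, den_mask):
        cts, vals = [], []
        for lo in edges:
            sel = (t_min >= lo) & (t_min < lo + window_min)
            den = int((sel & den_mask).sum())
            cts.append(den)
            vals.append((sel & num_mask).sum() / den if den else np.nan)
        vals = np.asarray(vals, float)
        ok = np.asarray(cts) > 0
        return BinnedSeries(centers[ok], vals[ok])

    hits = outcome == "hit"
    misses = outcome == "miss"
    fas = outcome == "false_alarm"
    hit_rate = rate(hits, hits | misses)
    hit_rate.name = "hit_rate"
    fa_den = np.ones_like(fas) if fa_denominator == "all" else (fas | misses)
    fa_rate = rate(fas, fa_den)
    fa_rate.name = "fa_rate"
    return BehaviorSeries(hit_rate=hit_rate, false_alarm_rate=fa_rate)
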