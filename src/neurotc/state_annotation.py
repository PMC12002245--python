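"""Labeling of analysis windows: slow-wave state, IED-rate bins, ASM days.

Slow-wave-sleep-like episodes are scored on 30 s windows through a vigilance
index, the band-power ratio (theta+delta)/(alpha+beta_high+spindle); a window
counts as SWS when its index exceeds that day's mean by more than one SD.
The 30 s labels are mapped onto the 120 s TC windows by an any-of-four rule.

Interictal discharges (IEDs) are annotated events; windows are binned by
event rate into the contrast categories "none" (0 events) and "in"
(5-30 events/min), everything else being "other"; a channel is retained only
with at least 50 windows in each contrast category.

Antiseizure-medication (ASM) load is the sum of doses normalized by the
defined daily dose (DDD); the days with the highest and lowest load define
the high/low-ASM contrast, excluding days with rescue medication.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "RESCUE_DRUGS",
    "vigilance_index",
    "sws_labels",
    "map_sws_to_tc_windows",
    "ied_bin_and_filter",
    "asm_day_classes",
]

RESCUE_DRUGS = frozenset({"midazolam", "diazepam", "lorazepam"})

IED_BIN_NONE = "none"
IED_BIN_IN = "5-30"
IED_BIN_OTHER = "other"


def vigilance_index(powers: pd.DataFrame) -> pd.Series:
    """Vigilance index (theta+delta)/(alpha+beta_high+spindle) per row.

    ``powers`` must carry columns delta, theta, alpha, spindle, beta_high
    (linear band powers >= 0).  Rows with a zero denominator yield NaN (the
    window is dropped from labeling).
    """
    num = powers["theta"] + powers["delta"]
    den = powers["alpha"] + powers["beta_high"] + powers["spindle"]
    idx = num / den.where(den > 0.0)
    idx.name = "vigilance_index"
    return idx


def sws_labels(indices: pd.Series, days: pd.Series) -> pd.Series:
    """Binary SWS label per 30 s window: index > day mean + 1 day SD.

    The SD is the population SD of that day's indices (ddof=0), so constant
    days label nothing and the rule is invariant to positive rescaling of a
    day's indices.  Days with fewer than two valid windows are excluded
    (label NaN).
    """
    indices = pd.Series(indices).astype(float)
    days = pd.Series(days)
    out = pd.Series(np.nan, index=indices.index, name="sws")
    for day, grp in indices.groupby(days):
        vals = grp.dropna()
        if len(vals) < 2:
            continue
        thr = vals.mean() + vals.std(ddof=0)
        out.loc[vals.index] = (vals > thr).astype(float)
    return out


def map_sws_to_tc_windows(labels_30s: np.ndarray | pd.Series) -> np.ndarray:
    """Collapse 30 s SWS labels onto 120 s windows: SWS iff any of the four
    constituent 30 s windows is SWS; windows with partial coverage or any
    unlabeled constituent are NaN."""
    lab = np.asarray(pd.Series(labels_30s).astype(float))
    n_full = lab.size // 4
    out = np.full(n_full, np.nan)
    for i in range(n_full):
        quad = lab[4 * i : 4 * i + 4]
        if np.isnan(quad).any():
            continue
        out[i] = float(quad.any())
    return out


def ied_bin_and_filter(
    events: pd.DataFrame,
    windows: pd.DataFrame,
    window_s: float = 120.0,
    rate_lo: float = 5.0,
    rate_hi: float = 30.0,
    min_windows: int = 50,
) -> tuple[pd.DataFrame, list[str]]:
    """Bin windows by IED rate and apply the channel sampling filter.

    ``events`` has columns (channel, time_s); ``windows`` has columns
    (channel, window_start_s).  Each window is labeled ``none`` (0 events),
    ``5-30`` (rate in [5, 30] events/min) or ``other``.  Channels are
    retained only with >= ``min_windows`` windows in each of the two
    contrast categories.  Returns the labeled window table (columns +
    ied_count, ied_rate_per_min, ied_bin) and the retained channel list.
    """
    out = windows.copy()
    counts = np.zeros(len(out), dtype=int)
    for i, (ch, start) in enumerate(
        zip(out["channel"].to_numpy(), out["window_start_s"].to_numpy())
    ):
        ev = events[events["channel"] == ch]
        t = ev["time_s"].to_numpy()
        counts[i] = int(((t >= start) & (t < start + window_s)).sum())
    rate = counts / (window_s / 60.0)
    bins = np.where(
        counts == 0,
        IED_BIN_NONE,
        np.where((rate >= rate_lo) & (rate <= rate_hi), IED_BIN_IN, IED_BIN_OTHER),
    )
    out["ied_count"] = counts
    out["ied_rate_per_min"] = rate
    out["ied_bin"] = bins
    retained = []
    for ch, grp in out.groupby("channel"):
        n_none = int((grp["ied_bin"] == IED_BIN_NONE).sum())
        n_in = int((grp["ied_bin"] == IED_BIN_IN).sum())
        if n_none >= min_windows and n_in >= min_windows:
            retained.append(ch)
    return out, sorted(retained)


def asm_day_classes(schedule: pd.DataFrame) -> dict[str, object] | None:
    """Identify the high- and low-ASM days from a dose schedule.

    ``schedule`` has columns (day, drug, dose, defined_daily_dose) and
    optionally ``rescue`` (bool); rows whose drug is a rescue benzodiazepine
    are rescue-flagged automatically.  Daily load is the DDD-normalized dose
    sum.  Returns ``{"high_day", "low_day", "loads"}`` or None when fewer
    than two eligible days remain or no tapering occurred (all loads equal).
    Ties resolve to the earliest day.
    """
    sched = schedule.copy()
    if sched["defined_daily_dose"].le(0).any():
        raise ValueError("defined_daily_dose must be positive")
    if sched["dose"].lt(0).any():
        raise ValueError("doses must be non-negative")
    rescue = sched["drug"].str.lower().isin(RESCUE_DRUGS)
    if "rescue" in sched.columns:
        rescue |= sched["rescue"].fillna(False).astype(bool)
    rescue_days = set(sched.loc[rescue, "day"])
    sched = sched[~sched["day"].isin(rescue_days)]
    if sched.empty:
        return None
    loads = (
        (sched["dose"] / sched["defined_daily_dose"])
        .groupby(sched["day"])
        .sum()
        .sort_index()
    )
    if len(loads) < 2:
        return None
    if np.isclose(loads.max(), loads.min()):
        return None  # no tapering: subject excluded from ASM analyses
    return {
        "high_day": loads.idxmax(),  # idxmax/idxmin return the first (earliest) tie
        "low_day": loads.idxmin(),
        "loads": loads,
    }
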