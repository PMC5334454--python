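"""Optogenetic-stimulation analysis.

Larvae expressing a channelrhodopsin in hypocretin neurons are exposed to
three 30-min blue-light windows during the night (3-h intertrial interval).
Activity is collected in 10-s bins.  Light onset evokes a short burst in
all genotypes, so the minute before and after onset is excluded; the
offset burst is excluded by ending analysis at light-off.  Each larva's
total activity during the light window is divided by the average baseline
activity (the 30 min before onset, excluding the last minute) of all larvae
of the same genotype; trials are averaged per larva, and group means are
expressed relative to the transgene-negative sibling group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import PlateMap, PlateTraces

__all__ = [
    "OptoWindow",
    "windows_from_log",
    "normalized_opto_activity",
    "relative_to_negative_siblings",
]


@dataclass(frozen=True)
class OptoWindow:
    """One stimulation trial: [light_on, light_off) with a 30-min baseline."""

    light_on: pd.Timestamp
    light_off: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "light_on", pd.Timestamp(self.light_on))
        object.__setattr__(self, "light_off", pd.Timestamp(self.light_off))
        if self.light_off <= self.light_on:
            raise ValueError("light_off must follow light_on")

    @property
    def baseline_start(self) -> pd.Timestamp:
        return self.light_on - (self.light_off - self.light_on)


def windows_from_log(stim_log: pd.DataFrame) -> list:
    """Pair light_on / light_off events from an illumination log."""
    ons = stim_log[stim_log["kind"] == "light_on"]["event_time"].sort_values()
    offs = stim_log[stim_log["kind"] == "light_off"]["event_time"].sort_values()
    if len(ons) != len(offs) or len(ons) == 0:
        raise ValueError("illumination log must contain matched on/off events")
    return [OptoWindow(on, off) for on, off in zip(ons, offs)]


def _bin_range(traces: PlateTraces, t0, t1) -> tuple:
    step_ns = int(round(traces.bin_seconds * 1e9))
    base = traces.start.value
    lo = -(-(pd.Timestamp(t0).value - base) // step_ns)
    hi = -(-(pd.Timestamp(t1).value - base) // step_ns)
    return int(lo), int(hi)


def normalized_opto_activity(
    traces: PlateTraces,
    windows: list,
    plate_map: PlateMap,
    onset_exclusion_seconds: float = 60.0,
) -> pd.DataFrame:
    """Per-larva stimulation activity normalized by genotype-mean baseline.

    For each trial: stimulation = total activity in
    ``[on + exclusion, off)``; baseline = total activity in
    ``[on - 30 min, on - exclusion)``.  Trials are pooled per larva (mean
    over trials), then each larva's stimulation activity is divided by the
    mean baseline of all larvae of the same genotype.
    """
    plate_map.validate_against(traces)
    excl = pd.Timedelta(seconds=onset_exclusion_seconds)
    active = [w for w in plate_map.active_wells() if w in traces.wells]
    rows = []
    for trial, wdw in enumerate(windows):
        lo_s, hi_s = _bin_range(traces, wdw.light_on + excl, wdw.light_off)
        lo_b, hi_b = _bin_range(traces, wdw.baseline_start, wdw.light_on - excl)
        if lo_b < 0 or hi_s > traces.n_bins:
            raise ValueError(f"trial {trial}: window not covered by the recording")
        for well in active:
            wi = traces.wells.index(well)
            rows.append(
                {
                    "larva": well,
                    "genotype": plate_map.genotype_of(well),
                    "trial": trial,
                    "stim_activity": float(traces.activity[wi, lo_s:hi_s].sum()),
                    "baseline_activity": float(traces.activity[wi, lo_b:hi_b].sum()),
                }
            )
    per_trial = pd.DataFrame(rows)
    per_larva = (
        per_trial.groupby(["larva", "genotype"], sort=False)[
            ["stim_activity", "baseline_activity"]
        ]
        .mean()
        .reset_index()
    )
    geno_baseline = per_larva.groupby("genotype")["baseline_activity"].mean()
    if (geno_baseline == 0).any():
        bad = sorted(geno_baseline.index[geno_baseline == 0])
        raise ValueError(f"genotype-average baseline is zero for: {bad}")
    per_larva["normalized"] = per_larva["stim_activity"] / per_larva["genotype"].map(
        geno_baseline
    )
    return per_larva


def relative_to_negative_siblings(
    normalized: pd.DataFrame,
    control_genotype: str,
) -> pd.DataFrame:
    """Fold-change of each genotype's normalized activity over the control.

    The control group's own value is exactly 1.  SEM is propagated with the
    delta method for a ratio of independent group means.
    """
    if control_genotype not in set(normalized["genotype"]):
        raise ValueError(f"missing control group {control_genotype!r}")
    stats_tbl = normalized.groupby("genotype")["normalized"].agg(["mean", "sem", "count"])
    m0 = stats_tbl.loc[control_genotype, "mean"]
    s0 = stats_tbl.loc[control_genotype, "sem"]
    if m0 == 0:
        raise ValueError("control-group mean is zero")
    rows = []
    for genotype, r in stats_tbl.iterrows():
        fold = r["mean"] / m0
        if genotype == control_genotype:
            fold, sem = 1.0, np.nan
        else:
            sem = abs(fold) * np.sqrt(
                (r["sem"] / r["mean"]) ** 2 + (s0 / m0) ** 2
            ) if r["mean"] != 0 and np.isfinite(r["sem"]) and np.isfinite(s0) else np.nan
        rows.append({"genotype": genotype, "fold_change": float(fold),
                     "sem": float(sem) if sem == sem else np.nan,
                     "n": int(r["count"])})
    return pd.DataFrame(rows)
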