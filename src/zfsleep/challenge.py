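"""Environmental-challenge analyses.

Light/dark alternation: larvae are exposed to alternating 1-h periods of
light and darkness for 24 h; per-larva mean activity is quantified for each
light and each dark period, excluding the first ~10 min after each light
offset (the offset evokes a locomotor burst lasting about that long), and
averaged over the five night cycles by default.

Heat-shock pre/post design: an inducible transgene is activated by a 1-h
heat shock during the afternoon of day 6; behavior is compared between a
pre phase (day 5 and night 5) and a post phase (night 6 and day 7) with a
two-way ANOVA on phase x genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import PlateMap, PlateTraces, epoch_slice, segment_epochs
from .sleep_metrics import METRICS, score_plate

__all__ = [
    "AlternationResult",
    "PrePostDesign",
    "alternation_period_activity",
    "transition_profiles",
    "prepost_metrics",
]


@dataclass
class AlternationResult:
    """Light/dark alternation quantification.

    ``period_table``: one row per (larva, period) with the period's mean
    activity per bin (dark periods exclude the first ``exclusion_minutes``
    after offset).  ``larva_means``: per-larva mean over the selected
    periods, one column per state.
    """

    period_table: pd.DataFrame
    larva_means: pd.DataFrame
    exclusion_minutes: float
    cycles: str


def alternation_period_activity(
    traces: PlateTraces,
    plate_map: PlateMap,
    exclusion_minutes: float = 10.0,
    cycles: str = "night",
) -> AlternationResult:
    """Per-larva mean activity in light and dark alternation periods.

    ``traces`` must carry 5-s bins and a schedule with the alternating
    override intervals.  ``cycles`` selects which periods enter the
    per-larva averages: "night" (default; periods starting during the base
    night, matching the five night cycles) or "all".
    """
    if traces.bin_seconds > 10.0 + 1e-9:
        raise ValueError("alternation analysis expects 5- or 10-s bins")
    if not traces.schedule.overrides:
        raise ValueError("schedule has no alternation override intervals")
    plate_map.validate_against(traces)
    epochs = segment_epochs(traces, complete_only=False)
    periods = [e for e in epochs if e.label.startswith(("light-period", "dark-period"))]
    if not periods:
        raise ValueError("no override periods inside the recording")
    for e in periods:
        if e.state == "dark" and exclusion_minutes >= e.minutes:
            raise ValueError(
                f"exclusion of {exclusion_minutes} min exceeds the "
                f"{e.minutes}-min period {e.label}"
            )

    base = traces.schedule
    base_overrideless = type(base)(base.lights_on, base.lights_off, ())

    rows = []
    for e in periods:
        lo, hi = epoch_slice(traces, e)
        if e.state == "dark":
            lo += int(round(exclusion_minutes * 60.0 / traces.bin_seconds))
        if hi <= lo:
            continue
        seg = traces.activity[:, lo:hi]
        at_night = base_overrideless.state_at(e.start) == "dark"
        for w, well in enumerate(traces.wells):
            if well not in plate_map or plate_map.table.loc[well, "excluded"]:
                continue
            rows.append(
                {
                    "larva": well,
                    "genotype": plate_map.genotype_of(well),
                    "period": e.label,
                    "state": e.state,
                    "start": e.start,
                    "at_night": at_night,
                    "n_bins": hi - lo,
                    "mean_activity": float(seg[w].mean()),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no analyzable period data")
    sel = table if cycles == "all" else table[table["at_night"]]
    if sel.empty:
        raise ValueError(f"no periods selected by cycles={cycles!r}")
    larva_means = (
        sel.pivot_table(index=["larva", "genotype"], columns="state",
                        values="mean_activity", aggfunc="mean")
        .reset_index()
        .rename_axis(None, axis=1)
    )
    return AlternationResult(
        period_table=table, larva_means=larva_means,
        exclusion_minutes=exclusion_minutes, cycles=cycles,
    )


def transition_profiles(
    traces: PlateTraces,
    plate_map: PlateMap,
    window_minutes: float = 10.0,
) -> pd.DataFrame:
    """Mean activity vs time relative to each light on/off transition.

    A plotting aid: the quantitative unit of the alternation analysis is
    the period mean, not the profile shape.
    """
    light = traces.schedule.light_mask(traces.times)
    d = np.diff(light.astype(int))
    k = int(round(window_minutes * 60.0 / traces.bin_seconds))
    geno = plate_map.genotypes()
    rows = []
    for kind, idxs in (("light_on", np.where(d == 1)[0] + 1),
                       ("light_off", np.where(d == -1)[0] + 1)):
        for i in idxs:
            lo, hi = max(0, i - k), min(traces.n_bins, i + k)
            for w, well in enumerate(traces.wells):
                if well not in geno.index:
                    continue
                offs = (np.arange(lo, hi) - i) * traces.bin_seconds
                rows.extend(
                    {"transition": kind, "genotype": geno[well],
                     "rel_seconds": float(o), "activity": float(a)}
                    for o, a in zip(offs, traces.activity[w, lo:hi])
                )
    prof = pd.DataFrame(rows)
    return (
        prof.groupby(["transition", "genotype", "rel_seconds"])["activity"]
        .mean()
        .reset_index()
    )


@dataclass
class PrePostDesign:
    """Heat-shock windowing: pre = day 5 + night 5, post = night 6 + day 7."""

    heat_shock_time: pd.Timestamp = None
    pre_epochs: tuple = ("day-5", "night-5")
    post_epochs: tuple = ("night-6", "day-7")

    def __post_init__(self):
        if self.heat_shock_time is not None:
            self.heat_shock_time = pd.Timestamp(self.heat_shock_time)


def prepost_metrics(
    traces: PlateTraces,
    design: PrePostDesign,
    plate_map: PlateMap,
    first_day_number: int = 4,
) -> pd.DataFrame:
    """Long table (larva, genotype, phase, metric values) for two-way ANOVA.

    Every larva contributes exactly one pre and one post value per sleep
    metric; each phase value is the mean of the metric over the phase's two
    named epochs.  Missing epochs are a hard error listing them.
    """
    epochs = segment_epochs(traces, first_day_number=first_day_number)
    by_label = {}
    for e in epochs:
        by_label.setdefault(e.label, e)
    wanted = list(design.pre_epochs) + list(design.post_epochs)
    missing = [lab for lab in wanted if lab not in by_label]
    if missing:
        raise ValueError(f"recording does not cover epochs: {missing}")
    if design.heat_shock_time is not None:
        for lab in design.pre_epochs:
            if by_label[lab].end > design.heat_shock_time:
                raise ValueError(f"pre epoch {lab} ends after the heat shock")
        for lab in design.post_epochs:
            if by_label[lab].start < design.heat_shock_time:
                raise ValueError(f"post epoch {lab} starts before the heat shock")
    summaries = score_plate(traces, plate_map, [by_label[lab] for lab in wanted])
    phase_of = {lab: "pre" for lab in design.pre_epochs}
    phase_of.update({lab: "post" for lab in design.post_epochs})
    summaries = summaries.assign(phase=summaries["epoch"].map(phase_of))
    out = (
        summaries.groupby(["larva", "genotype", "phase"], sort=False)[METRICS]
        .mean()
        .reset_index()
    )
    return out
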