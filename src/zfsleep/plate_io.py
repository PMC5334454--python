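"""On-disk formats, the experiment clock, and day/night epoch segmentation.

The central observable is a 96-well plate of per-well locomotor activity
time series exported by a videotracking system in quantization mode with a
fixed integration bin (1 min for sleep scoring; 5 or 10 s for stimulus
assays).  This module defines the interchange CSV dialect for those traces,
the plate map (well -> genotype / transgenes / exclusion), the lighting
schedule, and the segmentation of a recording into day/night (or
light-period/dark-period) epochs.

Conventions
-----------
* Bins are half-open ``[start, start + bin_seconds)`` and labeled by their
  start time.
* An epoch owns a bin iff the epoch contains the bin's *start* time.
* Day/night numbering follows developmental day (days post fertilization),
  anchored by ``first_day_number`` at segmentation time.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PlateIOError",
    "LightingSchedule",
    "VideotrackerSettings",
    "PlateTraces",
    "PlateMap",
    "Epoch",
    "read_activity_table",
    "write_activity_table",
    "read_plate_map",
    "write_plate_map",
    "read_stimulus_log",
    "write_stimulus_log",
    "segment_epochs",
    "epoch_slice",
    "merge_experiments",
]


class PlateIOError(ValueError):
    """Raised on malformed input files or invalid trace geometry."""


def _parse_clock(value) -> datetime.time:
    if isinstance(value, datetime.time):
        return value
    return datetime.time.fromisoformat(str(value))


@dataclass(frozen=True)
class LightingSchedule:
    """Base 14/10-h light/dark cycle plus optional override intervals.

    Defaults follow the standard rearing cycle: lights on at 9 A.M. and off
    at 11 P.M.  ``overrides`` is an ordered list of ``(start, end, state)``
    intervals (state in {"light", "dark"}) that take precedence over the
    base cycle; they are used for challenge protocols such as alternating
    1-h light/dark periods.
    """

    lights_on: datetime.time = datetime.time(9, 0)
    lights_off: datetime.time = datetime.time(23, 0)
    overrides: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "lights_on", _parse_clock(self.lights_on))
        object.__setattr__(self, "lights_off", _parse_clock(self.lights_off))
        if self.lights_on == self.lights_off:
            raise PlateIOError("lights_on and lights_off must differ")
        ovr = []
        for start, end, state in self.overrides:
            start, end = pd.Timestamp(start), pd.Timestamp(end)
            if end <= start:
                raise PlateIOError(f"override interval {start}..{end} is empty")
            if state not in ("light", "dark"):
                raise PlateIOError(f"override state {state!r} not in {{light, dark}}")
            ovr.append((start, end, state))
        ovr.sort(key=lambda t: t[0])
        for (s0, e0, _), (s1, _, _) in zip(ovr, ovr[1:]):
            if s1 < e0:
                raise PlateIOError("override intervals overlap")
        object.__setattr__(self, "overrides", tuple(ovr))

    # -- state queries ----------------------------------------------------

    def _base_light(self, seconds_of_day: np.ndarray) -> np.ndarray:
        on = _time_to_seconds(self.lights_on)
        off = _time_to_seconds(self.lights_off)
        if on < off:
            return (seconds_of_day >= on) & (seconds_of_day < off)
        return (seconds_of_day >= on) | (seconds_of_day < off)

    def light_mask(self, times: pd.DatetimeIndex) -> np.ndarray:
        """Boolean array: True where the plate is illuminated at each time."""
        times = pd.DatetimeIndex(times)
        sod = (
            times.hour.values * 3600 + times.minute.values * 60 + times.second.values
        ).astype(np.int64)
        mask = self._base_light(sod)
        for start, end, state in self.overrides:
            sel = (times >= start) & (times < end)
            mask = np.where(sel, state == "light", mask)
        return mask

    def state_at(self, when) -> str:
        return "light" if self.light_mask(pd.DatetimeIndex([pd.Timestamp(when)]))[0] else "dark"

    def to_dict(self) -> dict:
        return {
            "lights_on": self.lights_on.isoformat(),
            "lights_off": self.lights_off.isoformat(),
            "overrides": [
                [s.isoformat(), e.isoformat(), st] for s, e, st in self.overrides
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightingSchedule":
        return cls(
            lights_on=d.get("lights_on", datetime.time(9, 0)),
            lights_off=d.get("lights_off", datetime.time(23, 0)),
            overrides=tuple(tuple(o) for o in d.get("overrides", ())),
        )


def _time_to_seconds(t: datetime.time) -> int:
    return t.hour * 3600 + t.minute * 60 + t.second


@dataclass(frozen=True)
class VideotrackerSettings:
    """Acquisition metadata carried alongside traces, never used to rescore.

    The artifact consumes already-integrated bins; these settings document
    how the tracker produced them (15-Hz capture, quantization mode, and
    the empirical movement-detection parameters).
    """

    frame_rate: float = 15.0
    integration_bin: float = 60.0
    detection_threshold: float = 15.0
    burst: float = 29.0
    freeze: float = 3.0

    def __post_init__(self):
        if self.frame_rate <= 0 or self.integration_bin <= 0:
            raise PlateIOError("frame_rate and integration_bin must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VideotrackerSettings":
        return cls(**d)


@dataclass
class PlateTraces:
    """Rectangular per-well activity matrix with clock alignment.

    ``activity`` is shaped ``(n_wells, n_bins)``; bin *k* covers
    ``[start + k * bin_seconds, start + (k + 1) * bin_seconds)``.
    """

    wells: list
    start: pd.Timestamp
    bin_seconds: float
    activity: np.ndarray
    schedule: LightingSchedule = field(default_factory=LightingSchedule)
    settings: VideotrackerSettings | None = None

    def __post_init__(self):
        self.wells = list(self.wells)
        self.start = pd.Timestamp(self.start)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 2 or self.activity.shape[0] != len(self.wells):
            raise PlateIOError(
                f"activity must be (n_wells, n_bins); got {self.activity.shape} "
                f"for {len(self.wells)} wells"
            )
        if np.any(self.activity < 0):
            raise PlateIOError("negative activity values")
        if self.bin_seconds <= 0:
            raise PlateIOError("bin_seconds must be positive")
        if len(set(self.wells)) != len(self.wells):
            raise PlateIOError("duplicate well IDs")

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def n_bins(self) -> int:
        return self.activity.shape[1]

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_bins) * self.bin_seconds, unit="s"
        )

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.n_bins * self.bin_seconds)

    def well_index(self, well: str) -> int:
        try:
            return self.wells.index(well)
        except ValueError:
            raise KeyError(f"well {well!r} not in traces") from None

    def well_activity(self, well: str) -> np.ndarray:
        return self.activity[self.well_index(well)]


@dataclass
class Epoch:
    """A labeled, half-open ``[start, end)`` interval of constant light state."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp
    state: str

    def __post_init__(self):
        self.start, self.end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if self.end <= self.start:
            raise PlateIOError(f"epoch {self.label}: end must follow start")
        if self.state not in ("light", "dark"):
            raise PlateIOError(f"epoch state {self.state!r} not in {{light, dark}}")

    @property
    def minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


class PlateMap:
    """Well -> genotype / transgenes / exclusion assignments.

    Wells flagged excluded (e.g. because plate sealing introduced an air
    bubble) never enter any downstream statistic.
    """

    COLUMNS = ["genotype", "transgenes", "excluded", "reason", "experiment_id"]

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.name != "well":
            if "well" in table.columns:
                table = table.set_index("well")
            else:
                table.index.name = "well"
        for col, default in [
            ("genotype", ""),
            ("transgenes", ""),
            ("excluded", False),
            ("reason", ""),
            ("experiment_id", "exp1"),
        ]:
            if col not in table.columns:
                table[col] = default
        table["excluded"] = table["excluded"].astype(bool)
        table["transgenes"] = table["transgenes"].map(_normalize_transgenes)
        table["reason"] = table["reason"].fillna("").astype(str)
        if table.index.duplicated().any():
            dups = sorted(table.index[table.index.duplicated()].unique())
            raise PlateIOError(f"duplicate wells in plate map: {dups}")
        self.table = table[self.COLUMNS]

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, well: str) -> bool:
        return well in self.table.index

    @property
    def wells(self) -> list:
        return list(self.table.index)

    def active_wells(self) -> list:
        return list(self.table.index[~self.table["excluded"]])

    def genotype_of(self, well: str) -> str:
        return self.table.loc[well, "genotype"]

    def genotypes(self) -> pd.Series:
        """Genotype label per non-excluded well."""
        t = self.table[~self.table["excluded"]]
        return t["genotype"]

    def carriers(self, transgene: str) -> list:
        has = self.table["transgenes"].map(lambda s: transgene in s)
        return list(self.table.index[has])

    def validate_against(self, traces: PlateTraces) -> None:
        missing = sorted(set(traces.wells) - set(self.table.index))
        if missing:
            raise PlateIOError(f"plate map missing wells: {missing}")


def _normalize_transgenes(value) -> frozenset:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    s = str(value).strip()
    return frozenset(p for p in s.split(";") if p) if s else frozenset()


# ---------------------------------------------------------------------------
# Activity table reader / writer
# ---------------------------------------------------------------------------

def read_activity_table(
    path,
    schedule: LightingSchedule | None = None,
    settings: VideotrackerSettings | None = None,
) -> PlateTraces:
    """Read an activity CSV (long or wide dialect) into :class:`PlateTraces`.

    Long dialect: columns ``well,bin_start,activity``.  Wide dialect: a
    ``bin_start`` first column and one column per well.  The bin width is
    inferred from consecutive timestamps and checked constant; ragged wells,
    non-monotone timestamps and negative activity are hard errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"well", "bin_start", "activity"} <= set(cols):
        return _traces_from_long(df, schedule, settings)
    if cols and cols[0] == "bin_start":
        return _traces_from_wide(df, schedule, settings)
    raise PlateIOError(
        "unrecognized activity table: expected long columns "
        "(well,bin_start,activity) or a wide matrix with a bin_start column"
    )


def _traces_from_long(df, schedule, settings) -> PlateTraces:
    df = df.copy()
    df["bin_start"] = pd.to_datetime(df["bin_start"])
    counts = df.groupby("well", sort=False)["bin_start"].count()
    if counts.nunique() > 1:
        full = counts.max()
        ragged = sorted(counts.index[counts != full])
        raise PlateIOError(f"ragged wells (missing bins): {ragged}")
    wells = list(dict.fromkeys(df["well"]))
    wide = df.pivot(index="bin_start", columns="well", values="activity")
    if wide.isna().any().any():
        bad = sorted(wide.columns[wide.isna().any()])
        raise PlateIOError(f"ragged wells (missing bins): {bad}")
    wide = wide[wells]
    return _traces_from_matrix(wide.index, wells, wide.to_numpy().T, schedule, settings)


def _traces_from_wide(df, schedule, settings) -> PlateTraces:
    times = pd.to_datetime(df["bin_start"])
    wells = [c for c in df.columns if c != "bin_start"]
    mat = df[wells].to_numpy(dtype=float).T
    if np.isnan(mat).any():
        bad = sorted(np.array(wells)[np.isnan(mat).any(axis=1)])
        raise PlateIOError(f"ragged wells (missing bins): {bad}")
    return _traces_from_matrix(pd.DatetimeIndex(times), wells, mat, schedule, settings)


def _traces_from_matrix(times, wells, mat, schedule, settings) -> PlateTraces:
    times = pd.DatetimeIndex(times)
    if len(times) < 2:
        raise PlateIOError("need at least two bins to infer the bin width")
    deltas = np.diff(times.asi8)
    if np.any(deltas <= 0):
        raise PlateIOError("non-monotone bin timestamps")
    if np.any(deltas != deltas[0]):
        raise PlateIOError("bin width is not constant across the recording")
    bin_seconds = deltas[0] / 1e9
    if np.any(mat < 0):
        raise PlateIOError("negative activity values")
    return PlateTraces(
        wells=wells,
        start=times[0],
        bin_seconds=bin_seconds,
        activity=mat,
        schedule=schedule or LightingSchedule(),
        settings=settings,
    )


def write_activity_table(traces: PlateTraces, path, dialect: str = "long") -> None:
    """Write traces as CSV; round-trips bit-exactly through the reader."""
    times = traces.times
    if dialect == "long":
        n = traces.n_bins
        df = pd.DataFrame(
            {
                "well": np.repeat(traces.wells, n),
                "bin_start": np.tile(times.strftime("%Y-%m-%dT%H:%M:%S"), traces.n_wells),
                "activity": traces.activity.ravel(),
            }
        )
    elif dialect == "wide":
        df = pd.DataFrame(traces.activity.T, columns=traces.wells)
        df.insert(0, "bin_start", times.strftime("%Y-%m-%dT%H:%M:%S"))
    else:
        raise PlateIOError(f"unknown dialect {dialect!r}")
    # %.17g round-trips float64 bit-exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_plate_map(path) -> PlateMap:
    return PlateMap(pd.read_csv(path, keep_default_na=False, na_values=[]))


def write_plate_map(pmap: PlateMap, path) -> None:
    out = pmap.table.copy()
    out["transgenes"] = out["transgenes"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path)


def read_stimulus_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["event_time"] = pd.to_datetime(df["event_time"])
    return df


def write_stimulus_log(log_df: pd.DataFrame, path) -> None:
    out = log_df.copy()
    out["event_time"] = pd.DatetimeIndex(out["event_time"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

def _base_intervals(schedule: LightingSchedule, start, end):
    """Base day/night intervals covering [start, end), unclipped boundaries."""
    on = pd.Timedelta(seconds=_time_to_seconds(schedule.lights_on))
    off = pd.Timedelta(seconds=_time_to_seconds(schedule.lights_off))
    day0 = start.normalize() - pd.Timedelta(days=1)
    events = []
    d = day0
    while d <= end.normalize() + pd.Timedelta(days=1):
        events.append((d + on, "light"))
        events.append((d + off, "dark"))
        d += pd.Timedelta(days=1)
    events.sort()
    out = []
    for (t0, state), (t1, _) in zip(events, events[1:]):
        if t1 <= start or t0 >= end:
            continue
        out.append((t0, t1, state))
    return out


def segment_epochs(
    traces: PlateTraces,
    span: tuple | None = None,
    first_day_number: int = 5,
    complete_only: bool = True,
) -> list:
    """Tile ``span`` (default: the whole recording) with light/dark epochs.

    Base-cycle intervals become ``day-N`` / ``night-N`` epochs, numbered by
    developmental day with ``first_day_number`` the developmental day at the
    start of the span; schedule overrides take precedence and become
    ``light-period-K`` / ``dark-period-K`` epochs.  With ``complete_only``
    (the default) partially recorded first/last epochs are trimmed and the
    trimming is logged.
    """
    if span is None:
        span = (traces.start, traces.end)
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if start < traces.start or end > traces.end or end <= start:
        raise PlateIOError(
            f"span {start}..{end} outside recording {traces.start}..{traces.end}"
        )
    schedule = traces.schedule

    base = _base_intervals(schedule, start, end)
    # Developmental-day labels, counted before clipping to the span.  A night
    # epoch carries the number of the day it follows; a span starting during
    # the night belongs to developmental day ``first_day_number``.
    labeled = []
    started_dark = base[0][2] == "dark"
    n_light = 0
    current_day = first_day_number
    for t0, t1, state in base:
        if state == "light":
            current_day = first_day_number + n_light + (1 if started_dark else 0)
            n_light += 1
            labeled.append((t0, t1, state, f"day-{current_day}"))
        else:
            labeled.append((t0, t1, state, f"night-{current_day}"))

    # Overlay overrides: split base intervals at override boundaries.
    cuts = {start, end}
    for s, e, _ in schedule.overrides:
        cuts.add(pd.Timestamp(s))
        cuts.add(pd.Timestamp(e))
    epochs = []
    counters = {"light": 0, "dark": 0}
    for t0, t1, state, label in labeled:
        clipped_lo = t0 < start
        clipped_hi = t1 > end
        lo, hi = max(t0, start), min(t1, end)
        bounds = sorted({lo, hi} | {c for c in cuts if lo < c < hi})
        for a, b in zip(bounds, bounds[1:]):
            ovr = _override_covering(schedule, a, b)
            if ovr is not None:
                counters[ovr] += 1
                epochs.append(Epoch(f"{ovr}-period-{counters[ovr]}", a, b, ovr))
            else:
                partial = (clipped_lo and a == lo) or (clipped_hi and b == hi)
                if partial and complete_only:
                    log.info("trimming partial epoch %s (%s..%s)", label, a, b)
                    continue
                epochs.append(Epoch(label, a, b, state))
    return epochs


def _override_covering(schedule, a, b):
    for s, e, state in schedule.overrides:
        if s <= a and b <= e:
            return state
    return None


def epoch_slice(traces: PlateTraces, epoch: Epoch) -> tuple:
    """Bin index range ``(lo, hi)``: bins whose start time lies in the epoch."""
    step_ns = int(round(traces.bin_seconds * 1e9))
    t0 = traces.start.value
    lo = -(-(epoch.start.value - t0) // step_ns)  # ceil division
    hi = -(-(epoch.end.value - t0) // step_ns)
    lo = int(np.clip(lo, 0, traces.n_bins))
    hi = int(np.clip(hi, 0, traces.n_bins))
    return lo, hi


# ---------------------------------------------------------------------------
# Merging experiments
# ---------------------------------------------------------------------------

def merge_experiments(pairs: list) -> tuple:
    """Merge independent experiments, re-keying wells by (experiment_id, well).

    All plates must share the bin width and bin count; experiment ids must be
    disjoint.  Downstream statistics treat larvae from different experiments
    identically.
    """
    if not pairs:
        raise PlateIOError("nothing to merge")
    traces0, _ = pairs[0]
    wells, mats, maps, seen_ids = [], [], [], set()
    for traces, pmap in pairs:
        if traces.bin_seconds != traces0.bin_seconds:
            raise PlateIOError(
                f"mismatched bin widths: {traces.bin_seconds} vs {traces0.bin_seconds}"
            )
        if traces.n_bins != traces0.n_bins:
            raise PlateIOError("mismatched recording lengths")
        pmap.validate_against(traces)
        exp_ids = set(pmap.table["experiment_id"])
        if exp_ids & seen_ids:
            raise PlateIOError(f"experiment ids not disjoint: {sorted(exp_ids & seen_ids)}")
        seen_ids |= exp_ids
        key = pmap.table["experiment_id"].to_dict()
        renamed = [f"{key[w]}:{w}" for w in traces.wells]
        wells.extend(renamed)
        mats.append(traces.activity)
        t = pmap.table.copy()
        t.index = [f"{r['experiment_id']}:{w}" for w, r in t.iterrows()]
        t.index.name = "well"
        maps.append(t)
    merged_traces = PlateTraces(
        wells=wells,
        start=traces0.start,
        bin_seconds=traces0.bin_seconds,
        activity=np.vstack(mats),
        schedule=traces0.schedule,
        settings=traces0.settings,
    )
    merged_map = PlateMap(pd.concat(maps))
    return merged_traces, merged_map
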