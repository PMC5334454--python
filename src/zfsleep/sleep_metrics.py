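"""Sleep/wake scoring of 1-min binned activity traces.

A sleep bout is a maximal run of one or more consecutive 1-min bins with
zero recorded activity (the videotracker has already thresholded movement,
so "inactive" means recorded activity exactly 0; a configurable epsilon
exists but defaults to 0).  From bouts the per-larva, per-epoch metrics
follow: total sleep, bout count, mean bout length, total activity, waking
activity (activity per waking minute, excluding sleep), and sleep latency
(time from the epoch's light transition to the first bout, censored at the
epoch length when no bout occurs).

Bouts spanning an epoch boundary are split at the boundary so that per-epoch
conservation (total sleep + waking minutes = epoch minutes) is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import PlateMap, PlateTraces, epoch_slice

log = logging.getLogger(__name__)

__all__ = [
    "SleepBout",
    "SleepSummary",
    "detect_sleep_bouts",
    "score_epoch",
    "score_plate",
    "genotype_summary_table",
    "METRICS",
]

METRICS = [
    "total_sleep",
    "n_bouts",
    "mean_bout_length",
    "total_activity",
    "waking_activity",
    "sleep_latency",
]


@dataclass(frozen=True)
class SleepBout:
    start_bin: int
    length: int
    epoch: str = ""


@dataclass
class SleepSummary:
    larva: str
    epoch: str
    epoch_minutes: int
    total_sleep: float
    n_bouts: int
    mean_bout_length: float  # nan when n_bouts == 0
    total_activity: float
    waking_activity: float   # nan when the whole epoch is asleep
    sleep_latency: float
    latency_censored: bool


def detect_sleep_bouts(
    activity,
    bounds: tuple | None = None,
    bin_seconds: float = 60.0,
    epoch_label: str = "",
    eps: float = 0.0,
) -> list:
    """Maximal runs of zero-activity 1-min bins within ``bounds``.

    ``bounds`` is a half-open bin-index range (default: the whole vector);
    runs crossing the boundary are clipped there, so each epoch owns only
    its own part of a spanning bout.
    """
    if abs(bin_seconds - 60.0) > 1e-9:
        raise ValueError("sleep scoring requires 1-min bins")
    x = np.asarray(activity, dtype=float).ravel()
    lo, hi = bounds if bounds is not None else (0, x.size)
    if not (0 <= lo <= hi <= x.size):
        raise ValueError(f"bounds {bounds} outside trace of {x.size} bins")
    seg = x[lo:hi] <= eps
    if seg.size == 0:
        return []
    # run-length extraction over the inactivity mask
    padded = np.concatenate(([False], seg, [False]))
    d = np.diff(padded.astype(int))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return [
        SleepBout(start_bin=int(lo + s), length=int(e - s), epoch=epoch_label)
        for s, e in zip(starts, ends)
    ]


def score_epoch(
    activity,
    bounds: tuple,
    epoch_label: str = "",
    larva: str = "",
    eps: float = 0.0,
) -> SleepSummary:
    """Score one larva over one epoch's bin range."""
    lo, hi = bounds
    bouts = detect_sleep_bouts(activity, bounds, epoch_label=epoch_label, eps=eps)
    minutes = hi - lo
    total_sleep = sum(b.length for b in bouts)
    n_bouts = len(bouts)
    x = np.asarray(activity, dtype=float)[lo:hi]
    total_activity = float(x.sum())
    waking_minutes = minutes - total_sleep
    if waking_minutes > 0:
        waking_activity = total_activity / waking_minutes
    else:
        waking_activity = float("nan")  # all-sleep epoch: undefined, flagged
    if n_bouts:
        latency = float(bouts[0].start_bin - lo)
        censored = False
        mean_len = total_sleep / n_bouts
    else:
        latency = float(minutes)  # censored at the epoch length
        censored = True
        mean_len = float("nan")
    return SleepSummary(
        larva=larva,
        epoch=epoch_label,
        epoch_minutes=minutes,
        total_sleep=float(total_sleep),
        n_bouts=n_bouts,
        mean_bout_length=mean_len,
        total_activity=total_activity,
        waking_activity=waking_activity,
        sleep_latency=latency,
        latency_censored=censored,
    )


def score_plate(
    traces: PlateTraces,
    plate_map: PlateMap,
    epochs: list,
    eps: float = 0.0,
) -> pd.DataFrame:
    """Score every non-excluded larva over every epoch.

    Returns a long table with one row per (larva, epoch); excluded wells
    never appear.  Censored latencies are included at the epoch length and
    logged.
    """
    if abs(traces.bin_seconds - 60.0) > 1e-9:
        raise ValueError("sleep scoring requires 1-min bins")
    plate_map.validate_against(traces)
    rows = []
    n_censored = 0
    for well in plate_map.active_wells():
        if well not in traces.wells:
            continue
        x = traces.well_activity(well)
        for ep in epochs:
            bounds = epoch_slice(traces, ep)
            if bounds[1] <= bounds[0]:
                continue
            s = score_epoch(x, bounds, epoch_label=ep.label, larva=well, eps=eps)
            n_censored += s.latency_censored
            rows.append(
                {
                    "larva": well,
                    "genotype": plate_map.genotype_of(well),
                    "epoch": ep.label,
                    "state": ep.state,
                    "epoch_minutes": s.epoch_minutes,
                    "total_sleep": s.total_sleep,
                    "n_bouts": s.n_bouts,
                    "mean_bout_length": s.mean_bout_length,
                    "total_activity": s.total_activity,
                    "waking_activity": s.waking_activity,
                    "sleep_latency": s.sleep_latency,
                    "latency_censored": s.latency_censored,
                }
            )
    if n_censored:
        log.info("%d larva x epoch latencies censored at the epoch length", n_censored)
    return pd.DataFrame(rows)


def genotype_summary_table(summaries: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Per-genotype, per-epoch mean +/- SEM for each metric (long format).

    SEM is NaN for single-larva groups (flagged undefined); empty genotypes
    are simply absent.  Row count = genotypes x epochs x metrics.
    """
    metrics = list(metrics) if metrics is not None else METRICS
    rows = []
    for (genotype, epoch), grp in summaries.groupby(["genotype", "epoch"], sort=False):
        for metric in metrics:
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                log.warning("genotype %s epoch %s: no defined %s values",
                            genotype, epoch, metric)
                continue
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
            rows.append(
                {"genotype": genotype, "epoch": epoch, "metric": metric,
                 "mean": mean, "sem": sem, "n": int(vals.size)}
            )
    return pd.DataFrame(rows)
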