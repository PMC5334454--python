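"""Arousal-threshold analysis of mechano-acoustic (tap) stimulation.

The assay delivers taps of 14 solenoid power settings (1-36.31 on a
0.01-40.95 scale) in random order, 30 trials per power, at a 1-min
intertrial interval.  Per genotype, the background movement probability is
the fraction of (larva, event) 5-s pre-windows with movement; the corrected
response at a power is the raw post-window response fraction minus that
background.  Corrected responses are fitted with a variable-slope
log(dose) 4PL curve whose EC50 is the arousal threshold; genotypes are
compared with the extra sum-of-squares F test (fully pooled null vs one
curve per genotype).

A companion assay with a 5-min intertrial interval and a single power
probes sleeping larvae: a larva counts as sleeping at an event iff it shows
zero movement throughout the 60 s preceding the tap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import PlateMap, PlateTraces
from .stats import FourPLFit, StatsError, extra_ss_f, fit_fourpl, one_way_anova

log = logging.getLogger(__name__)

__all__ = [
    "ExtraSSResult",
    "build_response_matrix",
    "background_move_prob",
    "corrected_response",
    "fit_dose_response",
    "compare_dose_response",
    "sleeping_response",
]


def build_response_matrix(
    traces: PlateTraces,
    stim_log: pd.DataFrame,
    plate_map: PlateMap,
    pre_window: float = 5.0,
    post_window: float = 5.0,
) -> pd.DataFrame:
    """Per (larva, tap event): pre-/post-window movement flags and power.

    ``moved_pre`` is movement in the ``pre_window`` seconds before the tap;
    ``moved_post`` in the ``post_window`` seconds from the tap onward.
    Excluded wells never enter the matrix.
    """
    taps = stim_log[stim_log["kind"] == "tap"].reset_index(drop=True)
    if taps.empty:
        raise ValueError("stimulus log contains no taps")
    if np.any(taps["power"].to_numpy(dtype=float) <= 0):
        raise ValueError("tap power must be positive (log-dose undefined)")
    plate_map.validate_against(traces)
    step = traces.bin_seconds
    kpre = int(round(pre_window / step))
    kpost = int(round(post_window / step))
    if kpre < 1 or kpost < 1:
        raise ValueError("windows must cover at least one bin")
    t0 = traces.start.value
    step_ns = int(round(step * 1e9))
    idx = ((pd.DatetimeIndex(taps["event_time"]).asi8 - t0) // step_ns).astype(int)
    ok = (idx - kpre >= 0) & (idx + kpost <= traces.n_bins)
    if not ok.all():
        raise ValueError("tap events fall outside the recorded trace")
    active = [w for w in plate_map.active_wells() if w in traces.wells]
    rows = []
    act = traces.activity
    for well in active:
        wi = traces.wells.index(well)
        x = act[wi] > 0
        pre = np.array([x[j - kpre : j].any() for j in idx])
        post = np.array([x[j : j + kpost].any() for j in idx])
        rows.append(
            pd.DataFrame(
                {
                    "larva": well,
                    "genotype": plate_map.genotype_of(well),
                    "event": np.arange(len(taps)),
                    "power": taps["power"].to_numpy(dtype=float),
                    "moved_pre": pre,
                    "moved_post": post,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def background_move_prob(matrix: pd.DataFrame, grouping: str = "genotype"):
    """Background movement probability per group and per larva.

    Per larva: the fraction of its pre-windows (one per delivered stimulus,
    e.g. 14 powers x 30 trials = 420) with movement.  Per group: the mean
    over its larvae.  Returns ``(group_series, larva_series)``.
    """
    if matrix.empty:
        raise StatsError("empty response matrix")
    per_larva = matrix.groupby(["larva", grouping], sort=False)["moved_pre"].mean()
    per_larva = per_larva.reset_index().set_index("larva")
    group = per_larva.groupby(grouping, sort=False)["moved_pre"].mean()
    if (per_larva.groupby(grouping).size() == 0).any():
        raise StatsError("empty group in background computation")
    return group, per_larva["moved_pre"]


def corrected_response(
    matrix: pd.DataFrame,
    grouping: str = "genotype",
    background: pd.Series | None = None,
) -> pd.DataFrame:
    """Background-corrected response fraction per group per power.

    corrected = (fraction of post-windows with movement) - group background.
    May be negative; trial counts are reported alongside.
    """
    if background is None:
        background, _ = background_move_prob(matrix, grouping)
    raw = (
        matrix.groupby([grouping, "power"], sort=False)["moved_post"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "response", "count": "n_trials"})
    )
    missing = set(raw[grouping]) - set(background.index)
    if missing:
        raise StatsError(f"background not computed for groups: {sorted(missing)}")
    raw["background"] = raw[grouping].map(background)
    raw["corrected"] = raw["response"] - raw["background"]
    return raw.sort_values([grouping, "power"]).reset_index(drop=True)


def fit_dose_response(powers, corrected, weights=None) -> FourPLFit:
    """Variable-slope log(dose) 4PL fit of corrected response vs tap power."""
    powers = np.asarray(powers, dtype=float).ravel()
    if np.any(powers <= 0):
        raise StatsError("powers must be positive (log-dose model)")
    return fit_fourpl(np.log10(powers), corrected, weights=weights)


@dataclass
class ExtraSSResult:
    """Nested curve comparison: pooled 4PL vs one 4PL per group."""

    f: float
    df_num: int
    df_den: int
    p: float
    rss_null: float
    rss_alt: float
    fit_null: FourPLFit
    fits_alt: dict


def compare_dose_response(datasets: dict) -> ExtraSSResult:
    """Extra sum-of-squares F test across genotype dose-response datasets.

    ``datasets`` maps group label -> (powers, corrected fractions).  The
    null model fits one shared 4PL to all points (all four parameters
    pooled); the alternative fits a separate 4PL per group.
    """
    if len(datasets) < 2:
        raise StatsError("need at least two groups to compare")
    all_p, all_y = [], []
    fits = {}
    rss_alt = 0.0
    df_alt = 0
    power_sets = set()
    for label, (powers, y) in datasets.items():
        powers = np.asarray(powers, dtype=float).ravel()
        power_sets.add(tuple(np.sort(np.unique(powers))))
        fit = fit_dose_response(powers, y)
        fits[label] = fit
        rss_alt += fit.rss
        df_alt += fit.df
        all_p.append(powers)
        all_y.append(np.asarray(y, dtype=float).ravel())
    if len(power_sets) > 1:
        raise StatsError("groups were probed at different power sets")
    pooled = fit_dose_response(np.concatenate(all_p), np.concatenate(all_y))
    if df_alt <= 0:
        raise StatsError("alternative model has no residual degrees of freedom")
    f_stat, df_num, df_den, p = extra_ss_f(pooled.rss, pooled.df, rss_alt, df_alt)
    return ExtraSSResult(
        f=f_stat, df_num=df_num, df_den=df_den, p=p,
        rss_null=pooled.rss, rss_alt=rss_alt, fit_null=pooled, fits_alt=fits,
    )


def sleeping_response(
    traces: PlateTraces,
    stim_log: pd.DataFrame,
    plate_map: PlateMap,
    pre_sleep_seconds: float = 60.0,
    post_window: float = 5.0,
    min_iti_seconds: float = 300.0,
):
    """Fraction of sleeping larvae that respond to a single-intensity tap.

    A larva is sleeping at an event iff it shows zero movement throughout
    the ``pre_sleep_seconds`` before the tap.  The assay requires a single
    tap power and an intertrial interval of at least ``min_iti_seconds``.
    Returns ``(per_larva, per_group, anova)`` where per_group lists each
    genotype's pooled sleeping-response fraction; groups with no sleeping
    trials are flagged and excluded from the one-way ANOVA with a warning.
    """
    taps = stim_log[stim_log["kind"] == "tap"].reset_index(drop=True)
    if taps.empty:
        raise ValueError("stimulus log contains no taps")
    powers = np.unique(taps["power"].to_numpy(dtype=float))
    if powers.size != 1:
        raise ValueError("sleeping-response assay uses a single tap power")
    times = pd.DatetimeIndex(taps["event_time"]).asi8
    if len(times) > 1 and np.diff(np.sort(times)).min() < min_iti_seconds * 1e9:
        raise ValueError(f"intertrial interval below {min_iti_seconds} s")
    step = traces.bin_seconds
    kpre = int(round(pre_sleep_seconds / step))
    kpost = int(round(post_window / step))
    t0 = traces.start.value
    step_ns = int(round(step * 1e9))
    idx = ((times - t0) // step_ns).astype(int)
    ok = (idx - kpre >= 0) & (idx + kpost <= traces.n_bins)
    idx = idx[ok]
    rows = []
    for well in plate_map.active_wells():
        if well not in traces.wells:
            continue
        x = traces.well_activity(well) > 0
        sleeping = np.array([not x[j - kpre : j].any() for j in idx])
        responded = np.array([x[j : j + kpost].any() for j in idx])
        rows.append(
            {
                "larva": well,
                "genotype": plate_map.genotype_of(well),
                "n_sleeping_trials": int(sleeping.sum()),
                "n_responding": int((sleeping & responded).sum()),
            }
        )
    per_larva = pd.DataFrame(rows)
    per_larva["fraction"] = np.where(
        per_larva["n_sleeping_trials"] > 0,
        per_larva["n_responding"] / per_larva["n_sleeping_trials"].replace(0, 1),
        np.nan,
    )
    groups_frames = []
    anova_groups, anova_labels = [], []
    for genotype, grp in per_larva.groupby("genotype", sort=False):
        n_sleep = int(grp["n_sleeping_trials"].sum())
        frac = float(grp["n_responding"].sum() / n_sleep) if n_sleep else np.nan
        flagged = n_sleep == 0
        groups_frames.append(
            {"genotype": genotype, "n_sleeping_trials": n_sleep,
             "fraction": frac, "flagged_no_sleep": flagged}
        )
        vals = grp["fraction"].dropna().to_numpy()
        if flagged or vals.size == 0:
            log.warning("genotype %s has no sleeping trials; excluded from ANOVA",
                        genotype)
            continue
        anova_groups.append(vals)
        anova_labels.append(genotype)
    per_group = pd.DataFrame(groups_frames)
    anova = one_way_anova(anova_groups) if len(anova_groups) >= 2 else None
    return per_larva, per_group, anova
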