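"""Seeded synthetic plate experiments emulating larval-zebrafish recordings.

The generative model is a two-state (sleep/wake) Markov chain at 1-min
resolution with light-state-dependent transition probabilities and
state-dependent emissions: sleeping minutes emit zero activity; waking
minutes emit a gamma-distributed activity amount (truncated at the bin
capacity), optionally augmented by light-transition transients (a
single-bin pulse at lights-on; an exponentially decaying burst after
lights-off).  Sub-minute traces for stimulus assays are derived from the
same latent process by seeded Bernoulli thinning, and tap-evoked responses
follow a logistic (4PL-shaped) probability curve on log tap power.

Everything is deterministic given a configuration and a seed.  The
generator is a test harness emulating the structure of real recordings; it
is not an inference model and its activity distribution is an arbitrary
(but realistic-looking) choice.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plate_io import (
    LightingSchedule,
    PlateMap,
    PlateTraces,
    VideotrackerSettings,
)

__all__ = [
    "BehaviorParams",
    "GenotypeEffect",
    "GroupSpec",
    "SimulationConfig",
    "SimulatedPlate",
    "default_tap_powers",
    "simulate_trace",
    "simulate_plate",
    "simulate_tap_responses",
    "thin_to_subbins",
]

WELL_IDS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]

#: 14 tap-power settings spanning the protocol's 1-36.31 range (log-spaced).
def default_tap_powers() -> np.ndarray:
    return np.round(np.logspace(0.0, math.log10(36.31), 14), 2)


@dataclass(frozen=True)
class BehaviorParams:
    """Per-larva behavioral parameters of the generative model.

    Transition probabilities are per minute; activity emissions are gamma
    distributed (shape, scale in activity units per waking minute) and
    truncated at ``activity_cap`` units per minute.  Startle parameters
    define the tap-evoked response probability curve on log10 power;
    ``move_background`` is the spontaneous per-5-s movement probability.
    """

    p_ws_day: float = 0.03
    p_ws_night: float = 0.15
    p_sw_day: float = 0.25
    p_sw_night: float = 0.10
    wake_activity_shape: float = 2.0
    wake_activity_scale_day: float = 3.0
    wake_activity_scale_night: float = 1.5
    startle_top: float = 0.8
    startle_logec50: float = math.log10(8.0)
    startle_hill: float = 1.8
    move_background: float = 0.08
    opto_activity_multiplier: float = 2.0
    transient_on_amp: float = 20.0
    transient_off_amp: float = 30.0
    transient_off_tau: float = 3.0
    activity_cap: float = 60.0

    def __post_init__(self):
        for name in ("p_ws_day", "p_ws_night", "p_sw_day", "p_sw_night",
                     "move_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("wake_activity_shape", "wake_activity_scale_day",
                     "wake_activity_scale_night", "transient_off_tau",
                     "activity_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.startle_top + self.move_background > 1.0:
            raise ValueError("startle_top + move_background must not exceed 1")

    def modified(self, modifiers: dict) -> "BehaviorParams":
        """Apply multiplicative modifiers; probabilities are clipped to 1."""
        changes = {}
        for name, mult in modifiers.items():
            if mult <= 0:
                raise ValueError(f"modifier for {name} must be positive")
            value = getattr(self, name) * mult
            if name.startswith(("p_ws", "p_sw", "move_background")):
                value = min(value, 1.0)
            changes[name] = value
        return replace(self, **changes)


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative modifiers attached to a genotype.

    ``modifiers`` apply for the whole recording; ``heat_shock_modifiers``
    apply only after the configured heat-shock time and only to carriers of
    the heat-shock transgene (emulating inducible overexpression).
    """

    modifiers: dict = field(default_factory=dict)
    heat_shock_modifiers: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GroupSpec:
    """One genotype group on the plate: label, count, transgenes, effect."""

    label: str
    n: int
    transgenes: frozenset = frozenset()
    effect: GenotypeEffect = field(default_factory=GenotypeEffect)

    def __post_init__(self):
        object.__setattr__(self, "transgenes", frozenset(self.transgenes))
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass
class SimulationConfig:
    """Full description of a simulated experiment.

    ``protocol`` is one of baseline, alternation, heatshock, tap, opto.
    Protocol-specific fields default to the study's stated designs: taps of
    14 powers x 30 trials at a 1-min ITI starting 12:30 A.M.; three 30-min
    blue-light windows starting 1 A.M. with a 3-h (onset-to-onset) ITI;
    heat shock during the afternoon of day 6.
    """

    groups: list
    protocol: str = "baseline"
    baseline: BehaviorParams = field(default_factory=BehaviorParams)
    start: str = "2017-01-09 18:00:00"  # evening of 4 dpf
    n_minutes: int = 3 * 1440
    first_day_number: int = 4
    schedule: LightingSchedule = field(default_factory=LightingSchedule)
    experiment_id: str = "exp1"
    n_excluded: int = 0
    # heat shock
    heat_shock_time: str | None = None
    heat_shock_transgene: str = "hsp:hcrt"
    # taps
    tap_powers: np.ndarray = field(default_factory=default_tap_powers)
    tap_trials_per_power: int = 30
    tap_iti_seconds: float = 60.0
    tap_session_start: str | None = None
    sleeping_response_multiplier: float | None = None
    # opto
    opto_transgene: str = "hcrt:reachr"
    opto_onsets: list | None = None
    opto_duration_minutes: float = 30.0
    # alternation
    alternation_start: str | None = None
    alternation_hours: int = 24

    def __post_init__(self):
        known = {"baseline", "alternation", "heatshock", "tap", "opto"}
        if self.protocol not in known:
            raise ValueError(f"unknown protocol {self.protocol!r}; choose from {sorted(known)}")
        total = sum(g.n for g in self.groups)
        if total + self.n_excluded > 96:
            raise ValueError(f"{total}+{self.n_excluded} wells exceed one 96-well plate")

    def total_wells(self) -> int:
        return sum(g.n for g in self.groups) + self.n_excluded


@dataclass
class SimulatedPlate:
    """Bundle returned by :func:`simulate_plate`."""

    traces: PlateTraces            # 1-min activity
    plate_map: PlateMap
    stim_log: pd.DataFrame         # event_time, kind, power
    states: np.ndarray             # latent wake (True) / sleep per 1-min bin
    sub_traces: PlateTraces | None = None  # 5-/10-s traces for stimulus assays


# ---------------------------------------------------------------------------
# Core Markov engine
# ---------------------------------------------------------------------------

def _transient_vector(light: np.ndarray, on_amp, off_amp, tau) -> np.ndarray:
    """Per-minute transient added to waking emissions around transitions."""
    n = light.size
    out = np.zeros(n)
    d = np.diff(light.astype(int))
    for i in np.where(d == 1)[0]:
        out[i + 1] += on_amp  # single-bin lights-on pulse
    horizon = int(math.ceil(4 * tau))
    for i in np.where(d == -1)[0]:
        js = np.arange(i + 1, min(n, i + 1 + horizon))
        out[js] += off_amp * np.exp(-(js - (i + 1)) / tau)
    return out


def _simulate_matrix(
    par: list,
    light: np.ndarray,
    rng: np.random.Generator,
    switch_minute: int | None = None,
    par_post: list | None = None,
    multiplier: np.ndarray | None = None,
):
    """Simulate W wells over N minutes; returns (activity, wake_states).

    ``par`` is a list of per-well :class:`BehaviorParams`; ``par_post``
    optionally replaces it from ``switch_minute`` onward (heat shock).
    ``multiplier`` is an optional (W, N) emission multiplier (optogenetic
    stimulation windows).
    """
    n = light.size
    w = len(par)

    def arrays(ps):
        return {
            "p_ws": np.array([[p.p_ws_day, p.p_ws_night] for p in ps]),
            "p_sw": np.array([[p.p_sw_day, p.p_sw_night] for p in ps]),
            "scale": np.array(
                [[p.wake_activity_scale_day, p.wake_activity_scale_night] for p in ps]
            ),
        }

    pre = arrays(par)
    post = arrays(par_post) if par_post is not None else pre
    shape = np.array([p.wake_activity_shape for p in par])
    cap = np.array([p.activity_cap for p in par])
    trans = np.array(
        [
            _transient_vector(light, p.transient_on_amp, p.transient_off_amp,
                              p.transient_off_tau)
            for p in par
        ]
    )
    gam = rng.gamma(shape[:, None], 1.0, size=(w, n))
    u = rng.random(size=(w, n))

    phase = np.where(light, 0, 1)  # column index: 0 = day params, 1 = night
    activity = np.zeros((w, n))
    states = np.zeros((w, n), dtype=bool)

    # initial state from the stationary distribution of the first bin's phase
    p_ws0 = pre["p_ws"][:, phase[0]]
    p_sw0 = pre["p_sw"][:, phase[0]]
    denom = p_ws0 + p_sw0
    p_sleep0 = np.where(denom > 0, p_ws0 / np.where(denom > 0, denom, 1.0), 0.0)
    awake = u[:, 0] >= p_sleep0

    for i in range(n):
        cur = pre if (switch_minute is None or i < switch_minute) else post
        ph = phase[i]
        if i > 0:
            p_ws = cur["p_ws"][:, ph]
            p_sw = cur["p_sw"][:, ph]
            awake = np.where(awake, u[:, i] >= p_ws, u[:, i] < p_sw)
        states[:, i] = awake
        a = gam[:, i] * cur["scale"][:, ph] + trans[:, i]
        if multiplier is not None:
            a = a * multiplier[:, i]
        activity[:, i] = np.where(awake, np.minimum(a, cap), 0.0)
    return activity, states


def simulate_trace(
    params: BehaviorParams,
    schedule: LightingSchedule,
    n_minutes: int,
    seed,
    start="2017-01-09 18:00:00",
):
    """Simulate one larva; returns (activity, wake_states), each length n_minutes."""
    if n_minutes < 1:
        raise ValueError("n_minutes must be >= 1")
    rng = np.random.default_rng(seed)
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(n_minutes), unit="min")
    light = schedule.light_mask(times)
    activity, states = _simulate_matrix([params], light, rng)
    return activity[0], states[0]


# ---------------------------------------------------------------------------
# Plate-level simulation
# ---------------------------------------------------------------------------

def _resolve_params(config: SimulationConfig):
    """Per-group resolved (pre, post) parameter sets."""
    out = {}
    for g in config.groups:
        pre = config.baseline.modified(g.effect.modifiers)
        if (
            config.protocol == "heatshock"
            and config.heat_shock_transgene in g.transgenes
            and g.effect.heat_shock_modifiers
        ):
            post = pre.modified(g.effect.heat_shock_modifiers)
        else:
            post = pre
        out[g.label] = (pre, post)
    return out


def _assign_wells(config: SimulationConfig, rng: np.random.Generator):
    """Seeded shuffle of genotype (and exclusion) assignments over wells."""
    labels = []
    for g in config.groups:
        labels.extend([g.label] * g.n)
    labels.extend([None] * config.n_excluded)  # excluded wells get a genotype too
    order = rng.permutation(len(labels))
    wells = WELL_IDS[: len(labels)]
    rows = []
    spec_by_label = {g.label: g for g in config.groups}
    fill_cycle = [g.label for g in config.groups]
    for well, idx in zip(wells, order):
        lab = labels[idx]
        excluded = lab is None
        if excluded:  # an excluded well still holds a larva of some genotype
            lab = fill_cycle[int(rng.integers(len(fill_cycle)))]
        g = spec_by_label[lab]
        rows.append(
            {
                "well": well,
                "genotype": lab,
                "transgenes": g.transgenes,
                "excluded": excluded,
                "reason": "air bubble" if excluded else "",
                "experiment_id": config.experiment_id,
            }
        )
    return PlateMap(pd.DataFrame(rows))


def _schedule_for(config: SimulationConfig) -> LightingSchedule:
    """Protocol-adjusted lighting schedule (alternation overrides; opto dark)."""
    sched = config.schedule
    start = pd.Timestamp(config.start)
    if config.protocol == "alternation":
        alt_start = pd.Timestamp(
            config.alternation_start
            or (start.normalize() + pd.Timedelta(hours=17) + pd.Timedelta(days=1))
        )
        overrides = []
        state = "light"  # protocol starts with a light period at 5 P.M.
        t = alt_start
        for _ in range(config.alternation_hours):
            overrides.append((t, t + pd.Timedelta(hours=1), state))
            state = "dark" if state == "light" else "light"
            t += pd.Timedelta(hours=1)
        sched = LightingSchedule(sched.lights_on, sched.lights_off, tuple(overrides))
    return sched


def _opto_onsets(config: SimulationConfig, start: pd.Timestamp) -> list:
    if config.opto_onsets is not None:
        return [pd.Timestamp(t) for t in config.opto_onsets]
    # three trials starting 1 A.M. of the night after recording start,
    # onset-to-onset 3 h
    base = start.normalize() + pd.Timedelta(days=1, hours=1)
    return [base + pd.Timedelta(hours=3 * k) for k in range(3)]


def simulate_plate(config: SimulationConfig, seed) -> SimulatedPlate:
    """Simulate a full plate experiment under the configured protocol.

    Deterministic given (config, seed): identical inputs produce
    byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    pmap = _assign_wells(config, rng)
    sched = _schedule_for(config)
    start = pd.Timestamp(config.start)
    times = start + pd.to_timedelta(np.arange(config.n_minutes), unit="min")
    light = sched.light_mask(times)

    resolved = _resolve_params(config)
    par_pre = [resolved[pmap.table.loc[w, "genotype"]][0] for w in pmap.wells]
    par_post = [resolved[pmap.table.loc[w, "genotype"]][1] for w in pmap.wells]

    switch_minute = None
    stim_rows = []
    if config.protocol == "heatshock":
        hs = pd.Timestamp(
            config.heat_shock_time
            or (start.normalize() + pd.Timedelta(days=2, hours=15))
        )
        if not (start <= hs <= times[-1]):
            raise ValueError("heat_shock_time outside the recording")
        switch_minute = int((hs - start).total_seconds() // 60)
        stim_rows.append({"event_time": hs, "kind": "heat_shock", "power": np.nan})

    multiplier = None
    opto_windows = []
    if config.protocol == "opto":
        multiplier = np.ones((len(pmap.wells), config.n_minutes))
        onsets = _opto_onsets(config, start)
        dur = pd.Timedelta(minutes=config.opto_duration_minutes)
        carrier = np.array(
            [config.opto_transgene in pmap.table.loc[w, "transgenes"] for w in pmap.wells]
        )
        mult_by_well = np.array(
            [
                resolved[pmap.table.loc[w, "genotype"]][0].opto_activity_multiplier
                for w in pmap.wells
            ]
        )
        for on in onsets:
            off = on + dur
            if not (start <= on and off <= times[-1] + pd.Timedelta(minutes=1)):
                raise ValueError("opto window outside the recording")
            lo = int((on - start).total_seconds() // 60)
            hi = int((off - start).total_seconds() // 60)
            multiplier[carrier, lo:hi] = mult_by_well[carrier, None]
            opto_windows.append((on, off))
            stim_rows.append({"event_time": on, "kind": "light_on", "power": np.nan})
            stim_rows.append({"event_time": off, "kind": "light_off", "power": np.nan})

    if config.protocol == "alternation":
        for s, e, state in sched.overrides:
            stim_rows.append(
                {"event_time": s, "kind": f"light_{'on' if state == 'light' else 'off'}",
                 "power": np.nan}
            )

    activity, states = _simulate_matrix(
        par_pre, light, rng,
        switch_minute=switch_minute,
        par_post=par_post if switch_minute is not None else None,
        multiplier=multiplier,
    )
    traces = PlateTraces(
        wells=pmap.wells, start=start, bin_seconds=60.0, activity=activity,
        schedule=sched, settings=VideotrackerSettings(),
    )

    sub = None
    if config.protocol == "tap":
        session_start = pd.Timestamp(
            config.tap_session_start
            or (start.normalize() + pd.Timedelta(days=1, minutes=30))  # 12:30 A.M.
        )
        tap_log = _tap_schedule(config, session_start, rng)
        stim_rows.extend(tap_log.to_dict("records"))
        sub = simulate_tap_responses(
            wells=pmap.wells,
            params=[resolved[pmap.table.loc[w, "genotype"]][0] for w in pmap.wells],
            stim_log=tap_log,
            schedule=sched,
            rng=rng,
            bin_seconds=5.0,
            sleeping_response_multiplier=config.sleeping_response_multiplier,
        )
    elif config.protocol == "opto":
        lo_min = int((opto_windows[0][0] - start).total_seconds() // 60) - 35
        hi_min = int((opto_windows[-1][1] - start).total_seconds() // 60) + 5
        lo_min = max(lo_min, 0)
        hi_min = min(hi_min, config.n_minutes)
        sub = thin_to_subbins(
            traces, states, sub_seconds=10.0, rng=rng,
            minute_range=(lo_min, hi_min),
        )
    elif config.protocol == "alternation":
        sub = thin_to_subbins(traces, states, sub_seconds=5.0, rng=rng)

    stim_log = pd.DataFrame(stim_rows, columns=["event_time", "kind", "power"])
    if len(stim_log):
        stim_log = stim_log.sort_values("event_time", kind="stable").reset_index(drop=True)
    return SimulatedPlate(traces=traces, plate_map=pmap, stim_log=stim_log,
                          states=states, sub_traces=sub)


def _tap_schedule(config: SimulationConfig, session_start, rng) -> pd.DataFrame:
    powers = np.asarray(config.tap_powers, dtype=float)
    if np.any(powers <= 0):
        raise ValueError("tap powers must be positive (log-dose model)")
    seq = np.repeat(powers, config.tap_trials_per_power)
    seq = seq[rng.permutation(seq.size)]  # random order over the session
    times = session_start + pd.to_timedelta(
        np.arange(seq.size) * config.tap_iti_seconds, unit="s"
    )
    return pd.DataFrame({"event_time": times, "kind": "tap", "power": seq})


# ---------------------------------------------------------------------------
# Sub-minute traces
# ---------------------------------------------------------------------------

def thin_to_subbins(
    traces: PlateTraces,
    states: np.ndarray,
    sub_seconds: float,
    rng: np.random.Generator,
    p_active: float = 0.5,
    minute_range: tuple | None = None,
) -> PlateTraces:
    """Distribute each waking minute's activity over sub-bins by thinning.

    Each sub-bin of a waking minute is independently flagged active with
    probability ``p_active``; the minute's activity is split equally among
    active sub-bins (one seeded sub-bin is forced active if none are).
    Sleeping minutes stay all-zero, so 1-min inactivity is preserved.
    """
    k = int(round(60.0 / sub_seconds))
    if abs(k * sub_seconds - 60.0) > 1e-9:
        raise ValueError("sub_seconds must divide 60")
    lo, hi = minute_range if minute_range is not None else (0, traces.n_bins)
    act = traces.activity[:, lo:hi]
    st = states[:, lo:hi]
    w, n = act.shape
    flags = rng.random(size=(w, n, k)) < p_active
    counts = flags.sum(axis=2)
    none = counts == 0
    if none.any():
        forced = rng.integers(k, size=int(none.sum()))
        idx = np.argwhere(none)
        flags[idx[:, 0], idx[:, 1], forced] = True
        counts = flags.sum(axis=2)
    share = np.where(st, act / counts, 0.0)
    sub = flags * share[:, :, None]
    sub = sub.reshape(w, n * k)
    return PlateTraces(
        wells=traces.wells,
        start=traces.start + pd.Timedelta(minutes=lo),
        bin_seconds=sub_seconds,
        activity=sub,
        schedule=traces.schedule,
        settings=traces.settings,
    )


# ---------------------------------------------------------------------------
# Tap-evoked responses
# ---------------------------------------------------------------------------

def evoked_probability(power, params: BehaviorParams) -> float:
    """Evoked component of the tap-response curve at a power setting."""
    if np.any(np.asarray(power) <= 0):
        raise ValueError("tap power must be positive (log-dose undefined at 0)")
    z = (params.startle_logec50 - np.log10(power)) * params.startle_hill
    return params.startle_top / (1.0 + 10.0 ** z)


def simulate_tap_responses(
    wells: list,
    params: list,
    stim_log: pd.DataFrame,
    schedule: LightingSchedule,
    rng: np.random.Generator,
    bin_seconds: float = 5.0,
    pad_minutes: float = 2.0,
    sleeping_response_multiplier: float | None = None,
) -> PlateTraces:
    """Simulate 5-s movement traces over a tap session.

    Outside response windows each larva moves spontaneously with
    probability ``move_background`` per sub-bin; in the bin following each
    tap of power P it moves with probability
    ``min(1, move_background + startle_top / (1 + 10**((logEC50 - log10 P) * hill)))``.
    With ``sleeping_response_multiplier`` set, larvae that were still for
    the full minute preceding a tap have their evoked component scaled.
    """
    taps = stim_log[stim_log["kind"] == "tap"]
    if taps.empty:
        raise ValueError("stimulus log contains no taps")
    t0 = taps["event_time"].min() - pd.Timedelta(minutes=pad_minutes)
    t1 = taps["event_time"].max() + pd.Timedelta(minutes=pad_minutes)
    n = int(math.ceil((t1 - t0).total_seconds() / bin_seconds))
    w = len(wells)
    bg = np.array([p.move_background for p in params])
    move = rng.random(size=(w, n)) < bg[:, None]

    step_ns = int(round(bin_seconds * 1e9))
    pre_bins = int(round(60.0 / bin_seconds))
    for t, power in zip(taps["event_time"], taps["power"]):
        j = int((pd.Timestamp(t).value - t0.value) // step_ns)
        if not 0 <= j < n:
            continue
        evoked = np.array([evoked_probability(power, p) for p in params])
        if sleeping_response_multiplier is not None and j >= pre_bins:
            asleep = ~move[:, j - pre_bins : j].any(axis=1)
            evoked = np.where(asleep, evoked * sleeping_response_multiplier, evoked)
        p_resp = np.minimum(1.0, bg + evoked)
        move[:, j] = rng.random(w) < p_resp
    return PlateTraces(
        wells=wells, start=t0, bin_seconds=bin_seconds,
        activity=move.astype(float), schedule=schedule,
        settings=VideotrackerSettings(integration_bin=bin_seconds),
    )
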