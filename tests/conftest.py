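import numpy as np
import pandas as pd
import pytest

from zfsleep.plate_io import LightingSchedule, PlateMap, PlateTraces
from zfsleep.synthetic import GroupSpec, SimulationConfig, simulate_plate


def make_traces(activity, start="2017-01-09 09:00:00", bin_seconds=60.0,
                schedule=None, wells=None):
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    if wells is None:
        wells = [f"A{i+1}" for i in range(activity.shape[0])]
    return PlateTraces(
        wells=wells, start=pd.Timestamp(start), bin_seconds=bin_seconds,
        activity=activity, schedule=schedule or LightingSchedule(),
    )


def make_map(wells, genotypes=None, excluded=(), experiment_id="exp1"):
    rows = []
    for w in wells:
        rows.append({
            "well": w,
            "genotype": (genotypes or {}).get(w, "wt") if isinstance(genotypes, dict)
            else (genotypes[wells.index(w)] if genotypes else "wt"),
            "transgenes": "",
            "excluded": w in excluded,
            "reason": "air bubble" if w in excluded else "",
            "experiment_id": experiment_id,
        })
    return PlateMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def baseline_plate():
    """A small two-genotype plate over two full days, seeded."""
    cfg = SimulationConfig(
        groups=[GroupSpec("wt", 8), GroupSpec("hdc-/-", 8)],
        n_minutes=2 * 1440 + 360,
        n_excluded=1,
    )
    return simulate_plate(cfg, seed=20170109)
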