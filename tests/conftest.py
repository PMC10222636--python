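import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seazit.simdata import default_config, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: 6 singleton substances + 1 duplicate pair, 3 labs."""
    cfg = default_config(seed=20210104)
    return cfg.model_copy(
        update={"n_singleton_substances": 6, "n_duplicate_pairs": 1}
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def lab_b_wells(small_study):
    return small_study.wells["Lab-B"]


def make_wells(
    rows,
    plate_id="P1",
    run_date="2021-01-04",
    substance_id="S01",
    recordings=("edema", "axis"),
):
    """Hand-build a tidy wells table from (conc, alive_24, alive_120, flags)
    tuples; flags is a dict recording -> bool, or None for not assessed."""
    data = []
    for i, (conc, a24, a120, flags) in enumerate(rows):
        row = {
            "plate_id": plate_id,
            "run_date": run_date,
            "well": f"A{i + 1}",
            "substance_id": substance_id,
            "conc_uM": conc,
            "alive_24": a24,
            "alive_120": a120,
        }
        for rec in recordings:
            row[rec] = (flags or {}).get(rec, False if a120 else pd.NA)
        data.append(row)
    df = pd.DataFrame(data)
    for rec in recordings:
        df[rec] = pd.array(df[rec], dtype="boolean")
    return df
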