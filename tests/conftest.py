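import numpy as np
import pandas as pd
import pytest

from bcrpipe import simulate


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a rearrangement table from sparse row dicts with sane defaults."""
    defaults = {
        "sequence": "ATGGCT",
        "productive": True,
        "v_call": "IGHV3-23*01",
        "d_call": "IGHD3-10*01",
        "j_call": "IGHJ4*01",
        "c_call": "IGHM",
        "junction_aa": "CARDYW",
        "germline_alignment": "ATGGCT",
        "duplicate_count": 1,
        "subject_id": "S1",
    }
    columns = ["sequence_id", *defaults]
    if not rows:
        return pd.DataFrame(columns=columns).astype({"productive": bool, "duplicate_count": int})
    out = []
    for i, row in enumerate(rows):
        record = {"sequence_id": f"seq{i:04d}", **defaults, **row}
        out.append(record)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3+3-subject simulated cohort with ground truth, reused across tests."""
    config = simulate.default_config(
        seed=11, group_sizes={"HC": 3, "ME_mm": 3}, umis_per_subject=(1500, 1900)
    )
    return simulate.simulate_cohort(config)


@pytest.fixture(scope="session")
def recovery_results():
    """Monte-Carlo recovery study shared by the parameter-recovery and
    statistical-calibration acceptance checks (expensive; computed once)."""
    from bcrpipe import experiments

    return experiments.run_recovery_experiment(
        n_effect_seeds=500, n_null_seeds=300, base_seed=7
    )
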