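import numpy as np
import pandas as pd
import pytest

import torcourse as tc


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    return tc.build_design(tc.DesignConfig(n_participants=6, seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_design) -> tc.BehavioralDataset:
    return tc.simulate_dataset(small_design, tc.SimulationParams(seed=12))


@pytest.fixture(scope="session")
def small_clean(small_dataset) -> tc.CleanDataset:
    return tc.preprocess(small_dataset)


def make_dataset(records: list[dict]) -> tc.BehavioralDataset:
    """Construct a BehavioralDataset from terse per-trial dicts.

    Unspecified fields get legal main-trial defaults; trial_index is assigned
    densely per participant in the given order.
    """
    defaults = {
        "is_filler": False,
        "cue_informativity": "informative",
        "interruption": "absent",
        "task": "speed_change",
        "start_lane": "middle-left",
        "start_speed": 80,
        "video_version": 1,
        "jitter_s": 2,
        "correct_response": "left",
        "ldt_stimulus_class": "none",
        "rt_ms": 600.0,
        "correct": True,
        "rt_ldt_ms": np.nan,
        "correct_ldt": pd.NA,
    }
    rows = []
    counters: dict = {}
    for rec in records:
        row = {**defaults, **rec}
        pid = row["participant_id"]
        counters[pid] = counters.get(pid, 0) + 1
        row.setdefault("trial_index", counters[pid])
        row["trial_index"] = counters[pid]
        row["block"] = 1
        if row["interruption"] == "present" and row["ldt_stimulus_class"] == "none":
            row["ldt_stimulus_class"] = "word"
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("correct", "correct_ldt"):
        df[col] = pd.array(df[col], dtype="boolean")
    return tc.BehavioralDataset(df, provenance={"source": "constructed"})
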