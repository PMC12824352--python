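"""Counterbalanced trial-sequence construction for the cued take-over paradigm.

A session crosses two within-subject factors on main trials: cue informativity
(the take-over cue either names the upcoming task or merely announces that a
task will follow) and presence of an interrupting lexical decision task (LDT)
between cue and take-over stimulus. The take-over task is a speed change or a
lane change on a four-lane road. Main trials start from a middle lane at
80/100 km/h so both response alternatives are meaningful; filler trials start
from an outer lane or at 60/120 km/h, admit a single meaningful response, and
exist only to block stimulus-response learning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LANES = ("left", "middle-left", "middle-right", "right")
SPEEDS = (60, 80, 100, 120)
MIDDLE_LANES = ("middle-left", "middle-right")
OUTER_LANES = ("left", "right")
MAIN_SPEEDS = (80, 100)
FILLER_SPEEDS = (60, 120)
INFORMATIVITY = ("informative", "non_informative")
INTERRUPTION = ("present", "absent")
TASKS = ("speed_change", "lane_change")
RESPONSES = ("left", "right")
JITTER_SET = (2, 3, 4, 5, 6, 7)

#: column order of a design table (one row per planned trial)
DESIGN_COLUMNS = [
    "participant_id",
    "trial_index",
    "block",
    "is_filler",
    "cue_informativity",
    "interruption",
    "task",
    "start_lane",
    "start_speed",
    "video_version",
    "jitter_s",
    "correct_response",
    "ldt_stimulus_class",
]


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the experimental design.

    Defaults reproduce the reference session: 8 blocks of 30 trials per
    participant, 20% fillers (48 of 240), a 2x2 crossing of cue informativity
    and interruption balanced within the 192 main trials, four lanes, four
    speeds, four video versions per driving scene, and cue-onset jitters of
    2-7 s.
    """

    n_participants: int = 45
    n_blocks: int = 8
    trials_per_block: int = 30
    filler_fraction: float = 0.20
    lanes: tuple[str, ...] = LANES
    speeds: tuple[int, ...] = SPEEDS
    video_versions: int = 4
    jitter_set: tuple[int, ...] = JITTER_SET
    interruption_probability: float = 0.5
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_filler(self) -> int:
        return int(round(self.filler_fraction * self.n_trials))

    @property
    def n_main(self) -> int:
        return self.n_trials - self.n_filler

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        exact = self.filler_fraction * self.n_trials
        if abs(exact - round(exact)) > 1e-9:
            raise ValueError(
                f"filler_fraction x total trials must be an integer, got {exact}"
            )
        if self.n_main % 8 != 0:
            raise ValueError(
                "main trials cannot be balanced: count per participant "
                f"({self.n_main}) must be divisible by 8 (informativity x "
                "interruption x task cells)"
            )
        if self.n_filler % 2 != 0:
            raise ValueError(
                "filler trials cannot be split equally between speed and "
                f"lane tasks (got {self.n_filler})"
            )
        if self.video_versions < 1:
            raise ValueError("video_versions must be >= 1")
        if not self.jitter_set:
            raise ValueError("jitter_set must be non-empty")
        if not 0 <= self.interruption_probability <= 1:
            raise ValueError("interruption_probability must lie in [0, 1]")


def enumerate_videos(config: DesignConfig) -> pd.DataFrame:
    """One descriptor per lane x speed x version combination of driving scene."""
    rows = itertools.product(config.lanes, config.speeds, range(1, config.video_versions + 1))
    return pd.DataFrame(rows, columns=["start_lane", "start_speed", "video_version"])


def _main_trial_state(task: str, combo_idx: int) -> dict:
    """Start state + correct response for a main trial.

    Main trials are two-alternative: from a middle lane both lane changes are
    possible, and from 80/100 km/h both acceleration and deceleration are
    possible. Combinations of (lane, speed, response) cycle so that each is
    used equally often within a cell.
    """
    combos = list(itertools.product(MIDDLE_LANES, MAIN_SPEEDS, RESPONSES))
    lane, speed, resp = combos[combo_idx % len(combos)]
    return {"task": task, "start_lane": lane, "start_speed": speed, "correct_response": resp}


def _filler_trial_state(task: str, combo_idx: int) -> dict:
    """Start state + (forced) correct response for a filler trial.

    Lane fillers start on an outer lane and must change inwards; speed fillers
    drive 60 or 120 km/h and can only accelerate or decelerate, respectively.
    """
    if task == "lane_change":
        lane = OUTER_LANES[combo_idx % 2]
        speed = MAIN_SPEEDS[(combo_idx // 2) % 2]
        resp = "right" if lane == "left" else "left"
    else:
        speed = FILLER_SPEEDS[combo_idx % 2]
        lane = MIDDLE_LANES[(combo_idx // 2) % 2]
        resp = "right" if speed == FILLER_SPEEDS[0] else "left"
    return {"task": task, "start_lane": lane, "start_speed": speed, "correct_response": resp}


def _assign_counterbalanced(rows: list[dict], config: DesignConfig, rng: np.random.Generator) -> None:
    """Cycle jitter, video version and LDT stimulus class through each cell.

    Within every informativity x interruption x filler cell the balanced sets
    are cycled and then shuffled, so assignment is as even as the integer
    counts allow without being confounded with serial position.
    """
    keyfn = lambda r: (r["is_filler"], r["cue_informativity"], r["interruption"])
    rows.sort(key=keyfn)
    for _, group in itertools.groupby(rows, key=keyfn):
        cell = list(group)
        jitters = [config.jitter_set[i % len(config.jitter_set)] for i in range(len(cell))]
        versions = [1 + i % config.video_versions for i in range(len(cell))]
        classes = [("word", "pseudoword")[i % 2] for i in range(len(cell))]
        rng.shuffle(jitters)
        rng.shuffle(versions)
        rng.shuffle(classes)
        for row, j, v, c in zip(cell, jitters, versions, classes):
            row["jitter_s"] = j
            row["video_version"] = v
            row["ldt_stimulus_class"] = c if row["interruption"] == "present" else "none"


def _participant_design(pid: str, pidx: int, config: DesignConfig) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, pidx])
    rows: list[dict] = []

    n_cell = config.n_main // 4
    n_task = n_cell // 2
    for info, intr in itertools.product(INFORMATIVITY, INTERRUPTION):
        for task in TASKS:
            for j in range(n_task):
                row = {"is_filler": False, "cue_informativity": info, "interruption": intr}
                row.update(_main_trial_state(task, j))
                rows.append(row)

    # fillers: the 2x2 crossing cycles across fillers (exact balance only when
    # the filler count divides by 8); tasks alternate for exact parity
    conds = list(itertools.product(INFORMATIVITY, INTERRUPTION))
    per_task_counter = {t: 0 for t in TASKS}
    for i in range(config.n_filler):
        task = TASKS[i % 2]
        info, intr = conds[(i // 2) % 4]
        row = {"is_filler": True, "cue_informativity": info, "interruption": intr}
        row.update(_filler_trial_state(task, per_task_counter[task]))
        per_task_counter[task] += 1
        rows.append(row)

    _assign_counterbalanced(rows, config, rng)

    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "participant_id", pid)
    df.insert(1, "trial_index", np.arange(1, len(df) + 1))
    df.insert(2, "block", (np.arange(len(df)) // config.trials_per_block) + 1)
    return df[DESIGN_COLUMNS]


def participant_ids(config: DesignConfig) -> list[str]:
    width = max(2, len(str(config.n_participants)))
    return [f"P{i + 1:0{width}d}" for i in range(config.n_participants)]


def build_design(config: DesignConfig) -> pd.DataFrame:
    """Build the full counterbalanced design, one row per planned trial.

    Per participant: exactly ``filler_fraction x N`` fillers; within main
    trials all four cells of informativity x interruption are equally frequent
    and speed/lane tasks are equally frequent within each cell; trial order is
    randomized by a per-participant stream derived from the master seed.
    """
    config.validate()
    frames = [
        _participant_design(pid, i, config)
        for i, pid in enumerate(participant_ids(config))
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class BalanceReport:
    """Outcome of design validation for a single participant's sequence."""

    violations: list[str] = field(default_factory=list)
    cell_counts: pd.DataFrame | None = None

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_balance(trials: pd.DataFrame) -> BalanceReport:
    """Check one participant's sequence against the design constraints."""
    if trials is None or len(trials) == 0:
        raise ValueError("cannot validate an empty trial collection")
    if trials["participant_id"].nunique() != 1:
        raise ValueError("validate_balance expects trials of a single participant")

    report = BalanceReport()
    v = report.violations
    main = trials[~trials["is_filler"]]
    filler = trials[trials["is_filler"]]

    idx = np.sort(trials["trial_index"].to_numpy())
    if not np.array_equal(idx, np.arange(1, len(trials) + 1)):
        v.append("trial_index is not dense 1..N")

    if len(main) == 0:
        v.append("no main trials (all cells empty)")
    else:
        cells = main.groupby(["cue_informativity", "interruption"], observed=True).size()
        report.cell_counts = cells.rename("n").reset_index()
        if cells.reindex(
            itertools.product(INFORMATIVITY, INTERRUPTION), fill_value=0
        ).nunique() != 1:
            v.append("main-trial cells of informativity x interruption are unequal")
        tasks = main.groupby(["cue_informativity", "interruption", "task"], observed=True).size()
        by_cell = tasks.groupby(level=[0, 1]).nunique()
        if (by_cell != 1).any() or tasks.groupby(level=[0, 1]).size().lt(2).any():
            v.append("speed/lane tasks are not balanced within every cell")

        bad_lane = ~main["start_lane"].isin(MIDDLE_LANES)
        bad_speed = ~main["start_speed"].isin(MAIN_SPEEDS)
        if (bad_lane | bad_speed).any():
            v.append("main trial with outer lane or non-80/100 speed (single-alternative start)")

    lane_f = filler[filler["task"] == "lane_change"]
    if not lane_f["start_lane"].isin(OUTER_LANES).all():
        v.append("lane-change filler not starting on an outer lane")
    forced = lane_f["start_lane"].map({"left": "right", "right": "left"})
    if not (lane_f["correct_response"] == forced).all():
        v.append("lane-change filler with a response other than the forced inward change")
    speed_f = filler[filler["task"] == "speed_change"]
    if not speed_f["start_speed"].isin(FILLER_SPEEDS).all():
        v.append("speed-change filler not starting at 60/120 km/h")
    forced_s = speed_f["start_speed"].map({FILLER_SPEEDS[0]: "right", FILLER_SPEEDS[1]: "left"})
    if not (speed_f["correct_response"] == forced_s).all():
        v.append("speed-change filler with a response other than the forced one")

    absent = trials["interruption"] == "absent"
    if not (trials.loc[absent, "ldt_stimulus_class"] == "none").all():
        v.append("LDT stimulus class assigned although no interrupting task is present")
    if (trials.loc[~absent, "ldt_stimulus_class"] == "none").any():
        v.append("interrupting task present without an LDT stimulus class")

    return report


def write_design(design: pd.DataFrame, path) -> None:
    """Write a design table as comma-delimited text (1-based trial_index)."""
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table is missing required columns: {missing}")
    return df[DESIGN_COLUMNS]
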