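"""Trial-level behavioral simulator for the cued take-over paradigm.

The generator attaches reaction times, correctness flags and omissions to a
planned design so that every downstream stage (exclusion cascade, mean-level
inference, effect-course analysis) can be exercised with known ground truth.

RT model (take-over task), all terms in milliseconds::

    rt = mu * exp(N(-sigma^2/2, sigma))          # mean-one lognormal noise
    mu = base + intercept_p
         + practice_a * t_cond^(-practice_b)     # power-law practice decline
         + benefit_p * [non-informative cue]     # informative cues are faster
         + interruption_shift * [LDT present]
         + modulation * [informative & LDT present & onset <= t_cond <= offset]

where ``t_cond`` is the trial's ordered position within its own condition
cell — the same axis the effect-course analysis uses — and ``intercept_p`` and
``benefit_p`` vary normally across participants. The modulation term raises
informative-cue RTs under interruption inside a hard-edged window, i.e. it
shrinks the informativity benefit there without touching the non-informative
baseline. Interrupting-task (LDT) RTs follow the same structure with their own
intercept and a fixed slowing after informative cues. RTs are truncated at the
response deadline; omissions are coded as missing, never as the deadline value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DESIGN_COLUMNS

DEADLINE_MS = 2500.0

#: columns appended to a design table by the simulator
BEHAVIOR_COLUMNS = ["rt_ms", "correct", "rt_ldt_ms", "correct_ldt"]
DATASET_COLUMNS = DESIGN_COLUMNS + BEHAVIOR_COLUMNS


def _default_takeover_errors() -> dict:
    # low error rates, slightly higher under interruption / non-informative cues
    return {
        ("informative", "absent"): 0.007,
        ("informative", "present"): 0.009,
        ("non_informative", "absent"): 0.008,
        ("non_informative", "present"): 0.011,
    }


def _default_ldt_errors() -> dict:
    return {"informative": 0.039, "non_informative": 0.034}


@dataclass(frozen=True)
class SimulationParams:
    """Generator parameters (ms unless stated otherwise).

    Defaults emulate the reference study's magnitudes: take-over means near
    585/628 ms for informative/non-informative cues, LDT means near 787/756 ms,
    a ~45 ms informativity benefit, a practice decline of ``a * t^(-b)``, and a
    35 ms reduction of the benefit under interruption confined to ordered
    trials 7-23 (about a 13 ms session-average interaction).
    """

    base_rt_takeover_ms: float = 520.0
    base_rt_ldt_ms: float = 695.0
    informativity_benefit_ms: float = 45.0
    interruption_shift_ms: float = 0.0
    modulation_amplitude_ms: float = 35.0
    modulation_onset_trial: int = 7
    modulation_offset_trial: int = 23
    practice_a_ms: float = 150.0
    practice_b: float = 0.35
    participant_sd_ms: float = 80.0
    benefit_sd_ms: float = 25.0
    residual_sigma: float = 0.15
    takeover_error_rate: dict = field(default_factory=_default_takeover_errors)
    ldt_error_rate: dict = field(default_factory=_default_ldt_errors)
    omission_rate: float = 0.005
    ldt_info_slowing_ms: float = 30.0
    deadline_ms: float = DEADLINE_MS
    seed: int = 0

    def validate(self) -> None:
        probs = [self.omission_rate, *self.takeover_error_rate.values(), *self.ldt_error_rate.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.residual_sigma < 0 or self.participant_sd_ms < 0 or self.benefit_sd_ms < 0:
            raise ValueError("noise scales must be non-negative")
        if self.modulation_onset_trial > self.modulation_offset_trial:
            raise ValueError("modulation_onset_trial must be <= modulation_offset_trial")
        if self.deadline_ms <= 0:
            raise ValueError("deadline_ms must be positive")


@dataclass
class BehavioralDataset:
    """Long-format trial-level data: one row per (participant, trial_index)."""

    trials: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def participants(self) -> list:
        return sorted(self.trials["participant_id"].unique())

    def validate(self) -> None:
        dup = self.trials.duplicated(["participant_id", "trial_index"])
        if dup.any():
            raise ValueError("duplicate (participant, trial_index) rows")
        for pid, g in self.trials.groupby("participant_id", observed=True):
            idx = np.sort(g["trial_index"].to_numpy())
            if not np.array_equal(idx, np.arange(1, len(g) + 1)):
                raise ValueError(f"trial_index not dense from 1 for participant {pid}")


def _lognormal_noise(rng: np.random.Generator, sigma: float, size: int) -> np.ndarray:
    # E[exp(N(-s^2/2, s))] = 1, so mu is the expected RT; sigma = 0 is the
    # exact noise-free limit
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def _condition_rank(df: pd.DataFrame, keys: list[str]) -> np.ndarray:
    """1-based ordered position of each trial within its condition cell."""
    return df.groupby(keys, observed=True).cumcount().to_numpy() + 1


def simulate_dataset(design: pd.DataFrame, params: SimulationParams) -> BehavioralDataset:
    """Draw behavior for every planned trial of ``design``.

    Reproducible: identical (design, params, seed) gives identical data.
    """
    params.validate()
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing required columns: {missing}")

    df = design.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)
    rng = np.random.default_rng(params.seed)
    pids = sorted(df["participant_id"].unique())
    intercept = dict(zip(pids, rng.normal(0.0, params.participant_sd_ms, len(pids))))
    benefit = dict(
        zip(pids, rng.normal(params.informativity_benefit_ms, params.benefit_sd_ms, len(pids)))
    )

    n = len(df)
    icpt = df["participant_id"].map(intercept).to_numpy(float)
    bene = df["participant_id"].map(benefit).to_numpy(float)
    noninfo = (df["cue_informativity"] == "non_informative").to_numpy()
    present = (df["interruption"] == "present").to_numpy()

    t_cond = _condition_rank(df, ["participant_id", "is_filler", "cue_informativity", "interruption"])
    in_window = (t_cond >= params.modulation_onset_trial) & (t_cond <= params.modulation_offset_trial)

    mu = (
        params.base_rt_takeover_ms
        + icpt
        + params.practice_a_ms * t_cond ** (-params.practice_b)
        + np.where(noninfo, bene, 0.0)
        + np.where(present, params.interruption_shift_ms, 0.0)
        + np.where(~noninfo & present & in_window, params.modulation_amplitude_ms, 0.0)
    )
    mu = np.maximum(mu, 50.0)
    rt = np.minimum(mu * _lognormal_noise(rng, params.residual_sigma, n), params.deadline_ms)

    err_p = np.array(
        [params.takeover_error_rate[(i, j)] for i, j in zip(df["cue_informativity"], df["interruption"])]
    )
    correct = rng.random(n) >= err_p
    omitted = rng.random(n) < params.omission_rate
    rt[omitted] = np.nan

    # interrupting task: same participant intercept, own base and practice axis
    mask = present
    t_ldt = _condition_rank(df, ["participant_id", "is_filler", "cue_informativity"])
    mu_ldt = (
        params.base_rt_ldt_ms
        + icpt
        + params.practice_a_ms * t_ldt ** (-params.practice_b)
        + np.where(~noninfo, params.ldt_info_slowing_ms, 0.0)
    )
    mu_ldt = np.maximum(mu_ldt, 50.0)
    rt_ldt = np.minimum(mu_ldt * _lognormal_noise(rng, params.residual_sigma, n), params.deadline_ms)
    err_ldt = df["cue_informativity"].map(params.ldt_error_rate).to_numpy(float)
    correct_ldt = rng.random(n) >= err_ldt
    omitted_ldt = rng.random(n) < params.omission_rate
    rt_ldt[omitted_ldt | ~mask] = np.nan

    correct_arr = pd.array(correct, dtype="boolean")
    correct_arr[omitted] = pd.NA
    correct_ldt_arr = pd.array(correct_ldt, dtype="boolean")
    correct_ldt_arr[omitted_ldt | ~mask] = pd.NA

    out = df.copy()
    out["rt_ms"] = rt
    out["correct"] = correct_arr
    out["rt_ldt_ms"] = rt_ldt
    out["correct_ldt"] = correct_ldt_arr

    return BehavioralDataset(
        trials=out[DATASET_COLUMNS],
        provenance={"source": "simulate_dataset", "params": dataclasses.asdict(params)},
    )


def expected_informativity_course(params: SimulationParams, interruption: str, t) -> np.ndarray:
    """Noise-free informative-minus-non-informative expectation at ordered trial t.

    The package-wide sign convention makes a benefit negative: outside the
    modulation window the difference is ``-informativity_benefit_ms``; inside
    it, with the interrupting task present, ``modulation_amplitude_ms`` is
    added back. Practice terms cancel because both conditions share t.
    """
    t = np.asarray(t)
    if (t < 1).any():
        raise ValueError("ordered trial index t must be >= 1")
    diff = np.full(t.shape, -params.informativity_benefit_ms, dtype=float)
    if interruption == "present":
        win = (t >= params.modulation_onset_trial) & (t <= params.modulation_offset_trial)
        diff[win] += params.modulation_amplitude_ms
    elif interruption != "absent":
        raise ValueError("interruption must be 'present' or 'absent'")
    return diff


def null_params(params: SimulationParams) -> SimulationParams:
    """Copy of ``params`` with every condition and modulation effect zeroed."""
    return dataclasses.replace(
        params,
        informativity_benefit_ms=0.0,
        benefit_sd_ms=0.0,
        modulation_amplitude_ms=0.0,
        interruption_shift_ms=0.0,
        ldt_info_slowing_ms=0.0,
    )


def simulate_null_dataset(design: pd.DataFrame, params: SimulationParams) -> BehavioralDataset:
    """Simulate under the global null (for type-I-error calibration)."""
    return simulate_dataset(design, null_params(params))
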