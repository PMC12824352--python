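"""Participant- and trial-level exclusion cascade.

Order of the cascade on main trials, per analysis set:

1. drop filler trials;
2. drop omissions (no response before the deadline);
3. drop RT outliers: responses outside the individual's mean +/- k*SD,
   with mean/SD computed per participant and task family (take-over vs.
   interrupting) on responded main trials, errors included;
4. for RT sets only, drop incorrect responses;
5. carry-over rule for the take-over sets: drop trials whose within-trial
   interrupting LDT was answered incorrectly, omitted, or was itself an RT
   outlier (judged with the LDT task's outlier bounds).

Participant exclusion (before the cascade) removes participants whose mean RT
is more than k SDs slower than the sample mean in BOTH tasks; one-sided, slow
tail only. Every removal is counted in an ExclusionReport whose per-rule
counts plus retained trials reconstruct the input exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import BehavioralDataset, DEADLINE_MS


@dataclass(frozen=True)
class PreprocessConfig:
    trial_outlier_k: float = 2.0
    participant_outlier_k: float = 3.0
    deadline_ms: float = DEADLINE_MS
    carry_over_exclusion: bool = True
    #: sensitivity switch: compute outlier bounds per condition cell instead of
    #: pooled across conditions within a task family
    outlier_per_condition: bool = False

    def validate(self) -> None:
        if self.trial_outlier_k <= 0 or self.participant_outlier_k <= 0:
            raise ValueError("SD multipliers must be > 0")


@dataclass
class ExclusionReport:
    """Auditable per-rule removal counts.

    ``takeover`` and ``ldt`` hold one row per participant with the columns
    n_input, omitted, rt_outlier, carry_over (take-over only), retained_er,
    error_trials, retained_rt; removals + retained reconstruct n_input.
    """

    participants_excluded: list = field(default_factory=list)
    participant_stats: pd.DataFrame | None = None
    takeover: pd.DataFrame | None = None
    ldt: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)

    def totals(self) -> pd.DataFrame:
        frames = {}
        for name, df in (("takeover", self.takeover), ("ldt", self.ldt)):
            if df is not None:
                frames[name] = df.drop(columns="participant_id").sum()
        return pd.DataFrame(frames).T


@dataclass
class CleanDataset:
    """Post-exclusion analysis sets (views of the input trial table).

    RT sets are the ER sets minus incorrect responses; no filler trials in
    either. LDT sets contain interruption-present trials only.
    """

    takeover_rt: pd.DataFrame
    takeover_er: pd.DataFrame
    ldt_rt: pd.DataFrame
    ldt_er: pd.DataFrame
    report: ExclusionReport


def exclude_participants(
    data: BehavioralDataset, config: PreprocessConfig = PreprocessConfig()
) -> tuple[BehavioralDataset, ExclusionReport]:
    """Remove participants slower than mean + k*SD in both tasks.

    Participant means are computed over responded trials; the cut is one-sided
    (extraordinarily slow only) and requires exceedance in both the take-over
    and the interrupting task.
    """
    config.validate()
    df = data.trials
    if df["participant_id"].nunique() < 3:
        raise ValueError("participant exclusion requires at least 3 participants")

    m_to = df.groupby("participant_id", observed=True)["rt_ms"].mean()
    m_ldt = df.groupby("participant_id", observed=True)["rt_ldt_ms"].mean()
    k = config.participant_outlier_k
    slow_to = m_to > m_to.mean() + k * m_to.std(ddof=1)
    slow_ldt = m_ldt > m_ldt.mean() + k * m_ldt.std(ddof=1)
    excluded = sorted(m_to.index[(slow_to & slow_ldt).reindex(m_to.index, fill_value=False)])

    if len(excluded) == df["participant_id"].nunique():
        raise ValueError("participant exclusion removed every participant")

    report = ExclusionReport(
        participants_excluded=excluded,
        participant_stats=pd.DataFrame(
            {"mean_rt_takeover": m_to, "mean_rt_ldt": m_ldt, "excluded": (slow_to & slow_ldt)}
        ).reset_index(),
    )
    kept = df[~df["participant_id"].isin(excluded)].reset_index(drop=True)
    return BehavioralDataset(kept, dict(data.provenance)), report


def _outlier_bounds(sub: pd.DataFrame, col: str, k: float, per_condition: bool) -> pd.Series:
    keys = ["participant_id"]
    if per_condition:
        keys += ["cue_informativity", "interruption"]
    grp = sub.groupby(keys, observed=True)[col]
    mean = grp.transform("mean")
    sd = grp.transform("std")
    lo, hi = mean - k * sd, mean + k * sd
    # a zero-SD (constant) series has no outliers; guards against the mean
    # differing from the constant by one ulp
    return ((sub[col] < lo) | (sub[col] > hi)) & (sd > 0)


def filter_trials(
    data: BehavioralDataset,
    config: PreprocessConfig = PreprocessConfig(),
    report: ExclusionReport | None = None,
) -> CleanDataset:
    """Apply the trial-level cascade; see the module docstring for the order."""
    config.validate()
    if report is None:
        report = ExclusionReport()
    df = data.trials
    if len(df) == 0:
        raise ValueError("empty dataset")
    main = df[~df["is_filler"]].copy()
    k = config.trial_outlier_k

    # take-over family ------------------------------------------------------
    to_omitted = main["rt_ms"].isna()
    responded = main[~to_omitted]
    to_outlier = pd.Series(False, index=main.index)
    to_outlier.loc[responded.index] = _outlier_bounds(
        responded, "rt_ms", k, config.outlier_per_condition
    )

    # interrupting-task family (present trials only)
    present = main["interruption"] == "present"
    ldt_omitted = present & main["rt_ldt_ms"].isna()
    ldt_responded = main[present & ~main["rt_ldt_ms"].isna()]
    ldt_outlier = pd.Series(False, index=main.index)
    ldt_outlier.loc[ldt_responded.index] = _outlier_bounds(
        ldt_responded, "rt_ldt_ms", k, config.outlier_per_condition
    )

    carry_over = pd.Series(False, index=main.index)
    if config.carry_over_exclusion:
        bad_ldt = ldt_omitted | ldt_outlier | (main["correct_ldt"] == False)  # noqa: E712
        carry_over = present & bad_ldt

    keep_er = ~to_omitted & ~to_outlier & ~carry_over
    takeover_er = main[keep_er]
    takeover_rt = takeover_er[takeover_er["correct"] == True]  # noqa: E712

    keep_ldt_er = present & ~ldt_omitted & ~ldt_outlier
    ldt_er = main[keep_ldt_er]
    ldt_rt = ldt_er[ldt_er["correct_ldt"] == True]  # noqa: E712

    # per-participant audit -------------------------------------------------
    def _audit(omit, outl, carry, er_set, rt_set, base_mask) -> pd.DataFrame:
        g = lambda s: s.groupby(main["participant_id"], observed=True).sum()
        n_input = main.loc[base_mask].groupby("participant_id", observed=True).size()
        rows = pd.DataFrame(
            {
                "n_input": n_input,
                "omitted": g(omit),
                "rt_outlier": g(outl),
                "carry_over": g(carry),
                "retained_er": er_set.groupby("participant_id", observed=True).size(),
                "retained_rt": rt_set.groupby("participant_id", observed=True).size(),
            }
        ).fillna(0).astype(int)
        rows["error_trials"] = rows["retained_er"] - rows["retained_rt"]
        return rows.reset_index().rename(columns={"index": "participant_id"})

    all_true = pd.Series(True, index=main.index)
    report.takeover = _audit(to_omitted, to_outlier & ~to_omitted, carry_over & ~to_omitted & ~to_outlier, takeover_er, takeover_rt, all_true)
    report.ldt = _audit(ldt_omitted, ldt_outlier, pd.Series(False, index=main.index), ldt_er, ldt_rt, present)

    for pid, grp in takeover_rt.groupby("participant_id", observed=True):
        cells = grp.groupby(["cue_informativity", "interruption"], observed=True).size()
        if len(cells) < 4 or (cells == 0).any():
            msg = f"participant {pid} has an empty take-over RT cell after exclusions"
            report.warnings.append(msg)
            warnings.warn(msg)

    return CleanDataset(
        takeover_rt=takeover_rt.reset_index(drop=True),
        takeover_er=takeover_er.reset_index(drop=True),
        ldt_rt=ldt_rt.reset_index(drop=True),
        ldt_er=ldt_er.reset_index(drop=True),
        report=report,
    )


def preprocess(
    data: BehavioralDataset, config: PreprocessConfig = PreprocessConfig()
) -> CleanDataset:
    """Participant exclusion followed by the trial-level cascade."""
    kept, report = exclude_participants(data, config)
    return filter_trials(kept, config, report)


def retention_summary(clean: CleanDataset) -> pd.DataFrame:
    """Mean retained trials per participant for each of the four analysis sets."""
    rep = clean.report
    rows = []
    for name, df, col, n_in in (
        ("takeover_rt", clean.takeover_rt, "retained_rt", rep.takeover),
        ("takeover_er", clean.takeover_er, "retained_er", rep.takeover),
        ("ldt_rt", clean.ldt_rt, "retained_rt", rep.ldt),
        ("ldt_er", clean.ldt_er, "retained_er", rep.ldt),
    ):
        if len(df) == 0:
            raise ValueError(f"analysis set {name} is empty")
        retained = n_in[col]
        rows.append(
            {
                "analysis_set": name,
                "mean_retained": retained.mean(),
                "sd_retained": retained.std(ddof=1),
                "mean_fraction": (retained / n_in["n_input"]).mean(),
            }
        )
    return pd.DataFrame(rows)
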