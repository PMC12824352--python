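"""Condition-wise aggregation and mean-level inference.

Covers the conventional analyses of the paradigm: per-participant cell means,
paired t-tests with the paired effect size d_z = mean difference / SD of the
paired differences (= t/sqrt(n)), and a 2x2 repeated-measures ANOVA computed
from explicit within-subject sums of squares, each effect tested against its
own participant-by-effect error term. Because both factors have two levels,
each F has (1, n-1) degrees of freedom and equals the square of the paired t
on the corresponding contrast scores — a property the test suite pins.

Two effect sizes are reported for ANOVA contrasts: d_z (as above) and
d_av (mean difference divided by the average of the two condition SDs), which
are answers to different questions and can differ substantially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CleanDataset

INFO_LEVELS = ("informative", "non_informative")
INTR_LEVELS = ("absent", "present")


@dataclass
class CellMeans:
    """Per-participant condition means.

    Take-over frames are participant x (informativity, interruption) pivots
    pooling the speed and lane tasks; LDT frames are participant x
    informativity. Cells with no trials are NaN (absent), never zero.
    """

    takeover_rt: pd.DataFrame
    takeover_er: pd.DataFrame
    ldt_rt: pd.DataFrame
    ldt_er: pd.DataFrame
    absent_cells: list = field(default_factory=list)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float
    d_z: float
    n: int
    degenerate: bool = False


@dataclass
class AnovaResult:
    """2x2 within-subject ANOVA summary.

    ``table`` has one row per effect (informativity, interruption,
    interaction) with F, df, p and both effect sizes; ``simple_effects`` gives
    the informativity contrast at each interruption level.
    """

    table: pd.DataFrame
    cell_means: pd.DataFrame
    marginal_means: dict
    simple_effects: pd.DataFrame
    n: int


def _pivot(df: pd.DataFrame, value: str, cols: list[str]) -> pd.DataFrame:
    return df.pivot_table(index="participant_id", columns=cols, values=value, aggfunc="mean")


def condition_means(clean: CleanDataset) -> CellMeans:
    """Per-participant means of RT and error per condition cell.

    RT means come from the RT analysis sets, error rates from the ER sets
    (error rate = 1 - mean(correct)).
    """
    if len(clean.takeover_rt) == 0:
        raise ValueError("empty CleanDataset")
    er = clean.takeover_er.copy()
    er["error"] = 1.0 - er["correct"].astype(float)
    ldt_er = clean.ldt_er.copy()
    ldt_er["error"] = 1.0 - ldt_er["correct_ldt"].astype(float)

    cells = CellMeans(
        takeover_rt=_pivot(clean.takeover_rt, "rt_ms", ["cue_informativity", "interruption"]),
        takeover_er=_pivot(er, "error", ["cue_informativity", "interruption"]),
        ldt_rt=_pivot(clean.ldt_rt, "rt_ldt_ms", ["cue_informativity"]),
        ldt_er=_pivot(ldt_er, "error", ["cue_informativity"]),
    )
    for frame_name in ("takeover_rt", "takeover_er", "ldt_rt", "ldt_er"):
        frame = getattr(cells, frame_name)
        nan_mask = frame.isna()
        if nan_mask.any().any():
            for pid, row in nan_mask.iterrows():
                for cell in frame.columns[row]:
                    cells.absent_cells.append((frame_name, pid, cell))
            warnings.warn(
                f"absent cells in {frame_name}; affected participants are "
                "excluded pairwise downstream"
            )
    return cells


def paired_t(x, y) -> TTestResult:
    """Classical paired t-test with two-sided p and d_z.

    Pairs with a missing value in either member are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    ok = ~np.isnan(x) & ~np.isnan(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 3:
        raise ValueError("paired_t requires at least 3 complete pairs")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, n - 1, 1.0, 0.0, 0.0, 0.0, n)
        t = np.inf if mean > 0 else -np.inf
        return TTestResult(t, n - 1, 0.0, mean, 0.0, np.sign(mean) * np.inf, n, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), float(mean), float(sd), float(t / np.sqrt(n)), n)


def effect_size_dz(t: float, n: int) -> float:
    """Paired effect size from a t statistic: d_z = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t) / np.sqrt(n)


def _d_av(a: np.ndarray, b: np.ndarray) -> float:
    """Mean difference scaled by the average of the two condition SDs."""
    denom = (a.std(ddof=1) + b.std(ddof=1)) / 2.0
    if denom == 0:
        return np.nan
    return float((a.mean() - b.mean()) / denom)


def rm_anova_2x2(cells: pd.DataFrame) -> AnovaResult:
    """Within-subject 2x2 ANOVA from sums of squares.

    ``cells`` is a participant x (informativity, interruption) pivot with one
    mean per cell. Participants with any absent cell are dropped (with a
    warning). Factor A is cue informativity, factor B interruption.
    """
    wide = cells.reindex(columns=pd.MultiIndex.from_product([INFO_LEVELS, INTR_LEVELS]))
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"dropping {dropped} participant(s) with absent cells from the ANOVA")
    n = len(complete)
    if n < 3:
        raise ValueError("rm_anova_2x2 requires at least 3 complete participants")

    y = complete.to_numpy(float).reshape(n, 2, 2)  # participants x A x B
    gm = y.mean()
    p_mean = y.mean(axis=(1, 2))
    a_mean = y.mean(axis=(0, 2))
    b_mean = y.mean(axis=(0, 1))
    pa = y.mean(axis=2)
    pb = y.mean(axis=1)
    ab = y.mean(axis=0)

    ss_a = 2 * n * ((a_mean - gm) ** 2).sum()
    ss_b = 2 * n * ((b_mean - gm) ** 2).sum()
    ss_ab = n * ((ab - a_mean[:, None] - b_mean[None, :] + gm) ** 2).sum()
    ss_ap = 2 * ((pa - p_mean[:, None] - a_mean[None, :] + gm) ** 2).sum()
    ss_bp = 2 * ((pb - p_mean[:, None] - b_mean[None, :] + gm) ** 2).sum()
    resid = (
        y
        - pa[:, :, None]
        - pb[:, None, :]
        - ab[None, :, :]
        + p_mean[:, None, None]
        + a_mean[None, :, None]
        + b_mean[None, None, :]
        - gm
    )
    ss_abp = (resid**2).sum()

    df_err = n - 1
    rows = []
    contrasts = {
        "informativity": (y[:, 0, :].mean(1), y[:, 1, :].mean(1), ss_a, ss_ap),
        "interruption": (y[:, :, 0].mean(1), y[:, :, 1].mean(1), ss_b, ss_bp),
        "interaction": (y[:, 0, 0] - y[:, 1, 0], y[:, 0, 1] - y[:, 1, 1], ss_ab, ss_abp),
    }
    for effect, (u, v, ss_eff, ss_err) in contrasts.items():
        f = (ss_eff / 1.0) / (ss_err / df_err) if ss_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        p = stats.f.sf(f, 1, df_err) if np.isfinite(f) else 0.0
        diff = u - v
        sd = diff.std(ddof=1)
        dz = diff.mean() / sd if sd > 0 else np.nan
        rows.append(
            {
                "effect": effect,
                "F": float(f),
                "df1": 1,
                "df2": df_err,
                "p": float(p),
                "mean_diff": float(diff.mean()),
                "d_z": float(dz) if sd > 0 else np.nan,
                "d_av": _d_av(u, v),
            }
        )

    simple = []
    for j, level in enumerate(INTR_LEVELS):
        res = paired_t(y[:, 0, j], y[:, 1, j])
        simple.append(
            {
                "interruption": level,
                "mean_diff": res.mean_diff,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "d_z": res.d_z,
                "d_av": _d_av(y[:, 0, j], y[:, 1, j]),
            }
        )

    return AnovaResult(
        table=pd.DataFrame(rows),
        cell_means=pd.DataFrame(ab, index=list(INFO_LEVELS), columns=list(INTR_LEVELS)),
        marginal_means={
            "informativity": dict(zip(INFO_LEVELS, a_mean)),
            "interruption": dict(zip(INTR_LEVELS, b_mean)),
        },
        simple_effects=pd.DataFrame(simple),
        n=n,
    )
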