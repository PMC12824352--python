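"""Trial-ordered effect courses with cluster-based permutation inference.

The procedure tracks how a within-subject condition difference evolves over a
session: per participant, the trials of each condition are ordered by their
occurrence, smoothed with a centered moving average (edge windows truncated to
the available neighbors, so the output keeps the input length), and the two
conditions are contrasted at each ordered index with a paired t-test across
participants. Runs of adjacent indices that are individually significant at
the sample alpha and share the t sign form clusters; only the cluster mass
T (the sum of member t-values) is tested, against a permutation null obtained
by randomly exchanging each participant's two condition series. Because the
exchange unit is a participant's whole series, a label exchange is exactly a
sign flip of that participant's difference vector, which is how permutations
are executed. The per-permutation statistic is the maximum |mass| over that
permutation's clusters (family-wise control); a pooled alternative that ranks
an observed cluster within all permutation clusters is available as a
sensitivity switch.

Sign convention: course = condition A minus condition B, so with A =
informative and B = non-informative a cue benefit yields a negative course and
negative cluster masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Condition = dict  # column -> required value, e.g. {"cue_informativity": "informative"}


@dataclass(frozen=True)
class EffectCourseConfig:
    window: int = 11
    sample_alpha: float = 0.1
    n_permutations: int = 5000
    seed: int = 0
    max_cluster_rule: bool = True
    two_sided: bool = True

    def validate(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd count >= 1")
        if not 0 < self.sample_alpha < 1:
            raise ValueError("sample_alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class EffectCourse:
    """Per ordered-trial-index paired contrast between two conditions."""

    condition_a: Condition
    condition_b: Condition
    mean_diff: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    d_z: np.ndarray
    n: int
    analyzed_length: int
    participants: list
    diffs: np.ndarray  # participants x analyzed_length difference matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ordered_trial": np.arange(1, self.analyzed_length + 1),
                "mean_diff": self.mean_diff,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "d_z": self.d_z,
                "n": self.n,
            }
        )


@dataclass
class Cluster:
    start_index: int  # 1-based inclusive
    end_index: int
    mass_T: float
    sign: int
    p_perm: float | None = None


@dataclass
class PermutationResult:
    course: EffectCourse
    clusters: list[Cluster]
    null_quantiles: dict
    config: EffectCourseConfig
    seed: int

    def cluster_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "start": c.start_index,
                    "end": c.end_index,
                    "mass_T": c.mass_T,
                    "sign": c.sign,
                    "p_perm": c.p_perm,
                }
                for c in self.clusters
            ]
        )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows truncate to available neighbors."""
    x = np.asarray(x, dtype=float)
    if window == 1 or x.size == 0:
        return x.copy()
    half = window // 2
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def _matches(df: pd.DataFrame, condition: Condition) -> pd.Series:
    mask = pd.Series(True, index=df.index)
    for col, val in condition.items():
        mask &= df[col] == val
    return mask


def order_and_smooth(
    data: pd.DataFrame,
    condition: Condition,
    config: EffectCourseConfig = EffectCourseConfig(),
    value_col: str = "rt_ms",
) -> dict:
    """Per participant: condition trials ordered by occurrence, then smoothed.

    Returns ``{participant_id: np.ndarray}``; participants without any trial
    in the condition are omitted.
    """
    config.validate()
    sub = data[_matches(data, condition)].sort_values(["participant_id", "trial_index"])
    courses = {}
    for pid, grp in sub.groupby("participant_id", observed=True):
        vals = grp[value_col].to_numpy(float)
        if vals.size:
            courses[pid] = moving_average(vals, config.window)
    return courses


def _one_sample_course(
    diffs: np.ndarray, condition_a: Condition, condition_b: Condition, participants: list
) -> EffectCourse:
    n, length = diffs.shape
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / se, 0.0)
        dz = np.where(sd > 0, mean / sd, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return EffectCourse(
        condition_a=condition_a,
        condition_b=condition_b,
        mean_diff=mean,
        se=se,
        t=t,
        p=p,
        d_z=dz,
        n=n,
        analyzed_length=length,
        participants=participants,
        diffs=diffs,
    )


def trialwise_tests(
    courses_a: dict, courses_b: dict, config: EffectCourseConfig = EffectCourseConfig()
) -> EffectCourse:
    """Paired t across participants at every ordered index.

    The analyzed length is the minimum number of ordered trials available in
    both conditions across contributing participants.
    """
    pids = sorted(set(courses_a) & set(courses_b))
    if not pids:
        raise ValueError("no participant contributes to both conditions")
    length = min(min(len(courses_a[p]), len(courses_b[p])) for p in pids)
    if length == 0:
        raise ValueError("analyzed length is zero")
    diffs = np.array([courses_a[p][:length] - courses_b[p][:length] for p in pids])
    return _one_sample_course(diffs, {}, {}, pids)


def _clusters_from_t(t: np.ndarray, p: np.ndarray, alpha: float) -> list[Cluster]:
    sig = p < alpha
    clusters: list[Cluster] = []
    i = 0
    length = t.size
    while i < length:
        if not sig[i]:
            i += 1
            continue
        sign = 1 if t[i] > 0 else -1
        j = i
        while j + 1 < length and sig[j + 1] and (t[j + 1] > 0) == (sign > 0):
            j += 1
        clusters.append(Cluster(i + 1, j + 1, float(t[i : j + 1].sum()), sign))
        i = j + 1
    return clusters


def form_clusters(course: EffectCourse, config: EffectCourseConfig = EffectCourseConfig()) -> list[Cluster]:
    """Maximal runs of same-sign indices significant at the sample alpha."""
    config.validate()
    return _clusters_from_t(course.t, course.p, config.sample_alpha)


def _sign_flip_cluster_test(
    diffs: np.ndarray,
    condition_a: Condition,
    condition_b: Condition,
    participants: list,
    config: EffectCourseConfig,
) -> PermutationResult:
    """Cluster permutation on a participants x index difference matrix.

    Each permutation flips the sign of each participant's whole difference
    vector with a fair coin — equivalent to exchanging the two condition
    series within that participant — and reruns the t/cluster stage.
    """
    config.validate()
    if diffs.shape[0] < 2:
        raise ValueError("permutation test requires at least 2 participants")
    course = _one_sample_course(diffs, condition_a, condition_b, participants)
    observed = _clusters_from_t(course.t, course.p, config.sample_alpha)

    rng = np.random.default_rng(config.seed)
    n, length = diffs.shape
    n_perm = config.n_permutations
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))

    # For sign-flipped rows the second moment per index is unchanged, so the
    # permuted t-vector needs only the flipped means.
    m2 = (diffs**2).sum(axis=0)
    means = signs @ diffs / n
    var = np.maximum(m2 - n * means**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmat = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    pmat = 2.0 * stats.t.sf(np.abs(tmat), n - 1)

    max_stats = np.zeros(n_perm)
    pooled: list[float] = []
    for k in range(n_perm):
        cl = _clusters_from_t(tmat[k], pmat[k], config.sample_alpha)
        masses = [abs(c.mass_T) for c in cl]
        if masses:
            max_stats[k] = max(masses)
            if not config.max_cluster_rule:
                pooled.extend(masses)

    if config.max_cluster_rule:
        ref = max_stats
    else:
        ref = np.asarray(pooled) if pooled else np.zeros(0)
    for c in observed:
        exceed = int((ref >= abs(c.mass_T)).sum()) if ref.size else 0
        c.p_perm = (exceed + 1) / (ref.size + 1)

    qs = {q: float(np.quantile(max_stats, q)) for q in (0.5, 0.9, 0.95, 0.99)}
    return PermutationResult(
        course=course, clusters=observed, null_quantiles=qs, config=config, seed=config.seed
    )


def permutation_test(
    data,
    condition_a: Condition,
    condition_b: Condition,
    config: EffectCourseConfig = EffectCourseConfig(),
    value_col: str = "rt_ms",
) -> PermutationResult:
    """Full pipeline: order + smooth both conditions, contrast, cluster, permute.

    ``data`` is a long-format trial table (e.g. a CleanDataset analysis set).
    """
    courses_a = order_and_smooth(data, condition_a, config, value_col)
    courses_b = order_and_smooth(data, condition_b, config, value_col)
    ec = trialwise_tests(courses_a, courses_b, config)
    return _sign_flip_cluster_test(ec.diffs, condition_a, condition_b, ec.participants, config)


def difference_course(
    data,
    pair_a: tuple[Condition, Condition],
    pair_b: tuple[Condition, Condition],
    config: EffectCourseConfig = EffectCourseConfig(),
    value_col: str = "rt_ms",
) -> PermutationResult:
    """Effect-course analysis of the difference of two effect courses.

    Per participant the interaction score (A1 - A2) - (B1 - B2) is built from
    the smoothed series truncated to the common analyzed length; inference is
    a one-sample trial-wise t against zero with per-participant sign-flip
    permutations of the interaction score.
    """
    courses = [order_and_smooth(data, c, config, value_col) for c in (*pair_a, *pair_b)]
    pids = sorted(set.intersection(*(set(c) for c in courses)))
    if not pids:
        raise ValueError("no participant contributes to all four conditions")
    length = min(min(len(c[p]) for c in courses) for p in pids)
    if length == 0:
        raise ValueError("analyzed length is zero")
    a1, a2, b1, b2 = courses
    diffs = np.array(
        [(a1[p][:length] - a2[p][:length]) - (b1[p][:length] - b2[p][:length]) for p in pids]
    )
    return _sign_flip_cluster_test(diffs, pair_a[0], pair_b[0], pids, config)
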