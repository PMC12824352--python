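"""End-to-end orchestration, configuration, and delimited-text interfaces.

A full run executes design -> (simulate | load) -> preprocessing ->
mean-level statistics -> three effect-course analyses: the cue-informativity
effect with the interrupting task absent, the same effect with it present,
and the difference of the two courses (the practice trajectory of the
interaction). One master seed deterministically derives the per-stage seeds,
so the whole run and each stage are individually reproducible. Every output
table carries the configuration echo and seed in '#' header comments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignConfig, build_design
from .effect_course import EffectCourseConfig, PermutationResult, difference_course, permutation_test
from .mean_stats import AnovaResult, TTestResult, condition_means, paired_t, rm_anova_2x2
from .preprocess import CleanDataset, PreprocessConfig, preprocess, retention_summary
from .simulate import (
    DATASET_COLUMNS,
    DEADLINE_MS,
    BehavioralDataset,
    SimulationParams,
    simulate_dataset,
)

REQUIRED_COLUMNS = [
    "participant_id",
    "trial_index",
    "is_filler",
    "cue_informativity",
    "interruption",
    "task",
    "rt_ms",
    "correct",
    "rt_ldt_ms",
    "correct_ldt",
]

INFO = "cue_informativity"
INTR = "interruption"


def write_dataset(ds: BehavioralDataset, path, header: dict | None = None) -> None:
    """Write a BehavioralDataset as delimited text, missing values empty."""
    path = Path(path)
    meta = {"writer": f"torcourse {__version__}", **(header or {})}
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        cols = [c for c in DATASET_COLUMNS if c in ds.trials.columns]
        extra = [c for c in ds.trials.columns if c not in cols]
        ds.trials[cols + extra].to_csv(fh, index=False, na_rep="")


def read_dataset(path, deadline_ms: float = DEADLINE_MS, column_map: dict | None = None) -> BehavioralDataset:
    """Read and validate a long-format trial table.

    ``column_map`` renames source columns to the package's schema (useful for
    deposits with other naming conventions). Unknown columns are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path} is missing required column(s): {missing}")

    df["is_filler"] = df["is_filler"].astype(bool)
    for col in ("correct", "correct_ldt"):
        df[col] = pd.array(df[col], dtype="boolean")
    for col in ("rt_ms", "rt_ldt_ms"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        too_slow = df.index[df[col] > deadline_ms]
        if len(too_slow):
            raise ValueError(
                f"{col} exceeds the {deadline_ms:.0f} ms response deadline on "
                f"row(s) {list(too_slow[:5])} — omissions must be empty fields"
            )

    ds = BehavioralDataset(df, provenance={"source": str(path)})
    ds.validate()
    return ds


@dataclass
class RunConfig:
    mode: str = "simulate"  # or "reanalyze"
    input_path: str | None = None
    output_dir: str | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    sim: SimulationParams = field(default_factory=SimulationParams)
    prep: PreprocessConfig = field(default_factory=PreprocessConfig)
    course: EffectCourseConfig = field(default_factory=EffectCourseConfig)
    seed: int = 0
    column_map: dict | None = None

    def validate(self) -> None:
        if self.mode not in ("simulate", "reanalyze"):
            raise ValueError("mode must be 'simulate' or 'reanalyze'")
        if self.mode == "reanalyze" and not self.input_path:
            raise ValueError("reanalyze mode requires input_path")


@dataclass
class AnalysisReport:
    clean: CleanDataset
    retention: pd.DataFrame
    ldt_rt_test: TTestResult
    ldt_er_test: TTestResult
    anova_rt: AnovaResult
    anova_er: AnovaResult
    course_absent: PermutationResult
    course_present: PermutationResult
    interaction: PermutationResult
    provenance: dict


def _stage_seeds(master: int, n: int = 6) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the whole pipeline and (optionally) write all result tables."""
    config.validate()
    seeds = _stage_seeds(config.seed)

    if config.mode == "simulate":
        design = build_design(dataclasses.replace(config.design, seed=seeds[0]))
        data = simulate_dataset(design, dataclasses.replace(config.sim, seed=seeds[1]))
    else:
        data = read_dataset(config.input_path, config.prep.deadline_ms, config.column_map)

    clean = preprocess(data, config.prep)
    retention = retention_summary(clean)

    cells = condition_means(clean)
    ldt_rt = paired_t(cells.ldt_rt["informative"], cells.ldt_rt["non_informative"])
    ldt_er = paired_t(cells.ldt_er["informative"], cells.ldt_er["non_informative"])
    anova_rt = rm_anova_2x2(cells.takeover_rt)
    anova_er = rm_anova_2x2(cells.takeover_er)

    informative = {INFO: "informative"}
    non_informative = {INFO: "non_informative"}
    cc = config.course
    course_absent = permutation_test(
        clean.takeover_rt,
        {**informative, INTR: "absent"},
        {**non_informative, INTR: "absent"},
        dataclasses.replace(cc, seed=seeds[2]),
    )
    course_present = permutation_test(
        clean.takeover_rt,
        {**informative, INTR: "present"},
        {**non_informative, INTR: "present"},
        dataclasses.replace(cc, seed=seeds[3]),
    )
    interaction = difference_course(
        clean.takeover_rt,
        ({**informative, INTR: "absent"}, {**non_informative, INTR: "absent"}),
        ({**informative, INTR: "present"}, {**non_informative, INTR: "present"}),
        dataclasses.replace(cc, seed=seeds[4]),
    )

    provenance = {
        "package_version": __version__,
        "mode": config.mode,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "n_participants": len(data.participants),
        "participants_excluded": clean.report.participants_excluded,
    }
    report = AnalysisReport(
        clean=clean,
        retention=retention,
        ldt_rt_test=ldt_rt,
        ldt_er_test=ldt_er,
        anova_rt=anova_rt,
        anova_er=anova_er,
        course_absent=course_absent,
        course_present=course_present,
        interaction=interaction,
        provenance=provenance,
    )
    if config.output_dir:
        write_report(report, config)
    return report


def _write_table(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, na_rep="")


def mean_stats_table(report: AnalysisReport) -> pd.DataFrame:
    """Tidy table of all mean-level statistics in one frame."""
    rows = []
    for label, res in (("ldt_rt_info_vs_noninfo", report.ldt_rt_test), ("ldt_er_info_vs_noninfo", report.ldt_er_test)):
        rows.append(
            {"analysis": label, "effect": "informativity", "statistic": "t", "value": res.t,
             "df1": np.nan, "df2": res.df, "p": res.p, "mean_diff": res.mean_diff, "d_z": res.d_z,
             "d_av": np.nan}
        )
    for label, res in (("takeover_rt_anova", report.anova_rt), ("takeover_er_anova", report.anova_er)):
        for _, r in res.table.iterrows():
            rows.append(
                {"analysis": label, "effect": r["effect"], "statistic": "F", "value": r["F"],
                 "df1": r["df1"], "df2": r["df2"], "p": r["p"], "mean_diff": r["mean_diff"],
                 "d_z": r["d_z"], "d_av": r["d_av"]}
            )
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {
        "package": f"torcourse {__version__}",
        "mode": config.mode,
        "seed": config.seed,
        "window": config.course.window,
        "sample_alpha": config.course.sample_alpha,
        "n_permutations": config.course.n_permutations,
    }
    _write_table(report.retention, outdir / "retention.csv", header)
    _write_table(report.clean.report.takeover, outdir / "exclusions_takeover.csv", header)
    _write_table(report.clean.report.ldt, outdir / "exclusions_ldt.csv", header)
    _write_table(mean_stats_table(report), outdir / "mean_stats.csv", header)
    for name, res in (
        ("informativity_interruption_absent", report.course_absent),
        ("informativity_interruption_present", report.course_present),
        ("interaction", report.interaction),
    ):
        _write_table(res.course.to_frame(), outdir / f"course_{name}.csv", header)
        _write_table(res.cluster_frame(), outdir / f"clusters_{name}.csv", header)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2)


def run_config_from_file(path) -> RunConfig:
    """Build a RunConfig from a flat key-value (YAML) file.

    Keys of the nested configs are given flat with a stage prefix, e.g.
    ``design.n_participants: 45`` or ``course.window: 11``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups: dict[str, dict] = {"design": {}, "sim": {}, "prep": {}, "course": {}}
    top: dict = {}
    for key, val in raw.items():
        if "." in key:
            stage, name = key.split(".", 1)
            if stage not in groups:
                raise ValueError(f"unknown config stage '{stage}' in key '{key}'")
            groups[stage][name] = val
        else:
            top[key] = val
    return RunConfig(
        design=DesignConfig(**groups["design"]),
        sim=SimulationParams(**groups["sim"]),
        prep=PreprocessConfig(**groups["prep"]),
        course=EffectCourseConfig(**groups["course"]),
        **top,
    )
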