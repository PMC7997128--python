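"""Experiment orchestration: simulate or load ratings, extract windowed
effects, and run the inference chain of the offset/onset paradigm.

One run executes, per experiment: (1) last-13-s window means per subject ×
condition; (2) two 1 × 3 repeated-measures ANOVAs — the OA model over
{OA1, OA2, control} and the OH model over {OH1, OH2, control}; (3) when an
ANOVA reaches significance (raw p < alpha), the three BH-corrected paired
comparisons of its family; (4) within-subject SEMs for error bars; (5) when
both sexes are present, two-sample t-tests on control-subtracted means per
experimental condition.  A separate entry point merges cohorts and
correlates the subtracted offset and onset effects per stimulus range.
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
from .effects import (
    AnalysisWindows,
    condition_mean_table,
    hypo_hyper_responses,
    subtracted_effect_table,
)
from .protocol import CONDITION_NAMES, ProtocolConstants
from .stats import (
    RmAnovaResult,
    bh_adjust,
    paired_t,
    pearson_corr,
    rm_anova_1way,
    two_sample_t,
    within_subject_sem,
)
from .synthetic_data import PopulationConfig, simulate_experiment

__all__ = [
    "RunConfig",
    "ExperimentResult",
    "run_experiment",
    "run_symmetry_analysis",
    "read_ratings",
    "write_results",
]

REQUIRED_COLUMNS = (
    "subject_id", "sex", "condition", "time_s", "temperature_c", "rating_nrs",
)

#: ANOVA model -> (conditions, ordered post-hoc comparisons)
ANOVA_MODELS: dict[str, tuple[list[str], list[tuple[str, str]]]] = {
    "OA": (["OA1", "OA2", "control"],
           [("OA1", "control"), ("OA2", "control"), ("OA2", "OA1")]),
    "OH": (["OH1", "OH2", "control"],
           [("OH1", "control"), ("OH2", "control"), ("OH2", "OH1")]),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    protocol: ProtocolConstants = field(default_factory=ProtocolConstants)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    alpha: float = 0.05
    t_test_variant: str = "pooled"
    sample_rate_hz: float = 10.0
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        # one seed governs the whole run
        self.population = dataclasses.replace(self.population, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "protocol": dataclasses.asdict(self.protocol),
            "simulation": dataclasses.asdict(self.population),
            "analysis": {
                "alpha": self.alpha,
                "t_test_variant": self.t_test_variant,
                "t2_window": list(self.windows.t2_window),
                "t3_window": list(self.windows.t3_window),
            },
            "sample_rate_hz": self.sample_rate_hz,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        analysis = d.get("analysis", {})
        windows = AnalysisWindows(
            t2_window=tuple(analysis.get("t2_window", (9.0, 20.0))),
            t3_window=tuple(analysis.get("t3_window", (20.0, 33.0))),
        )
        return cls(
            protocol=ProtocolConstants(**d.get("protocol", {})),
            population=PopulationConfig(**d.get("simulation", {})),
            windows=windows,
            alpha=float(analysis.get("alpha", 0.05)),
            t_test_variant=str(analysis.get("t_test_variant", "pooled")),
            sample_rate_hz=float(d.get("sample_rate_hz", 10.0)),
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "results")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ExperimentResult:
    """Bundle of everything one run computed."""

    config: RunConfig
    dataset: pd.DataFrame
    mean_table: pd.DataFrame
    anova: dict[str, RmAnovaResult]
    posthoc: pd.DataFrame
    responses: pd.DataFrame
    subtracted_effects: pd.DataFrame
    sems: pd.DataFrame
    sex: pd.DataFrame | None
    log: list[str]


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Load and validate a long-format ratings CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings file missing required columns: {missing}")
    bad = df.index[(df["rating_nrs"] < 0) | (df["rating_nrs"] > 10)]
    if len(bad):
        raise ValueError(
            f"ratings outside [0, 10] at rows {bad[:5].tolist()}"
            + ("…" if len(bad) > 5 else "")
        )
    unknown = set(df["condition"].unique()) - set(CONDITION_NAMES)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    return df


def _wide_means(mean_table: pd.DataFrame, conditions: list[str]) -> pd.DataFrame:
    wide = mean_table.pivot(index="subject_id", columns="condition", values="window_mean")
    missing = [c for c in conditions if c not in wide.columns]
    if missing:
        raise ValueError(f"conditions absent from dataset: {missing}")
    return wide[conditions].dropna()


def _posthoc_family(
    wide: pd.DataFrame, comparisons: list[tuple[str, str]], model: str
) -> pd.DataFrame:
    rows = []
    for a, b in comparisons:
        res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append(
            {"model": model, "comparison": f"{a} vs {b}", "t_stat": res.t_stat,
             "df": res.df, "p_raw": res.p_raw, "mean_difference": res.mean_difference}
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def _sex_comparison(
    dataset: pd.DataFrame, responses: pd.DataFrame, variant: str, log: list[str]
) -> pd.DataFrame | None:
    sex_map = dataset.groupby("subject_id")["sex"].first()
    resp = responses.assign(sex=responses["subject_id"].map(sex_map))
    reported = resp[resp["sex"].isin(["F", "M"])]
    n_f = reported.loc[reported["condition"] == "OA1", "sex"].eq("F").sum() \
        if not reported.empty else 0
    counts = reported.groupby("sex")["subject_id"].nunique()
    if counts.get("F", 0) < 2 or counts.get("M", 0) < 2:
        log.append("sex comparison skipped: need at least 2 subjects of each sex")
        return None
    n_excluded = resp.loc[~resp["sex"].isin(["F", "M"]), "subject_id"].nunique()
    if n_excluded:
        log.append(f"sex comparison: excluded {n_excluded} subject(s) with unreported sex")
    rows = []
    for cond, g in reported.groupby("condition", sort=True):
        f = g.loc[g["sex"] == "F", "response"].to_numpy()
        m = g.loc[g["sex"] == "M", "response"].to_numpy()
        res = two_sample_t(f, m, variant=variant)
        rows.append(
            {"condition": cond, "t_stat": res.t_stat, "df": res.df,
             "p_raw": res.p_raw, "mean_difference": res.mean_difference,
             "n_female": f.size, "n_male": m.size}
        )
    return pd.DataFrame(rows)


def run_experiment(
    config: RunConfig, dataset: pd.DataFrame | None = None
) -> ExperimentResult:
    """Run one experiment end to end.

    When ``dataset`` is None a cohort is simulated from the config;
    otherwise the provided (validated) long-format dataset is analyzed.
    """
    log: list[str] = []
    if dataset is None:
        dataset = simulate_experiment(
            config.population, config.protocol, config.sample_rate_hz
        )
        log.append(
            f"simulated {config.population.n_subjects} subjects (seed {config.seed})"
        )

    mean_table = condition_mean_table(dataset, config.windows)
    anova: dict[str, RmAnovaResult] = {}
    posthoc_frames = []
    sems_rows = []
    for model, (conds, comparisons) in ANOVA_MODELS.items():
        wide = _wide_means(mean_table, conds)
        res = rm_anova_1way(wide.to_numpy())
        anova[model] = res
        sem = within_subject_sem(wide.to_numpy())
        for c, s in zip(conds, sem):
            sems_rows.append({"model": model, "condition": c, "within_subject_sem": s})
        if res.p_raw < config.alpha:
            posthoc_frames.append(_posthoc_family(wide, comparisons, model))
        else:
            log.append(
                f"{model} ANOVA not significant (p = {res.p_raw:.3f} ≥ "
                f"{config.alpha:g}); post-hoc tests skipped"
            )
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(
            columns=["model", "comparison", "t_stat", "df", "p_raw",
                     "mean_difference", "p_adjusted"]
        )
    )
    responses = hypo_hyper_responses(mean_table)
    subtracted = subtracted_effect_table(dataset, config.windows)
    sex = _sex_comparison(dataset, responses, config.t_test_variant, log)
    return ExperimentResult(
        config=config, dataset=dataset, mean_table=mean_table, anova=anova,
        posthoc=posthoc, responses=responses, subtracted_effects=subtracted,
        sems=pd.DataFrame(sems_rows), sex=sex, log=log,
    )


def run_symmetry_analysis(
    datasets: list[pd.DataFrame], windows: AnalysisWindows | None = None
) -> pd.DataFrame:
    """Merge cohorts and correlate subtracted offset vs onset effects per range.

    Subject ids colliding across datasets are re-keyed with a dataset
    prefix before merging.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    w = windows if windows is not None else AnalysisWindows()
    seen: set[str] = set()
    merged = []
    for i, ds in enumerate(datasets):
        ids = set(ds["subject_id"].unique())
        if ids & seen:
            ds = ds.assign(subject_id="d" + str(i) + ":" + ds["subject_id"].astype(str))
            ids = set(ds["subject_id"].unique())
        seen |= ids
        merged.append(ds)
    effects = subtracted_effect_table(pd.concat(merged, ignore_index=True), w)
    rows = []
    for rng_c, g in effects.groupby("range", sort=True):
        wide = g.pivot(index="subject_id", columns="paradigm", values="subtracted_effect")
        wide = wide.dropna()
        res = pearson_corr(wide["offset"].to_numpy(), wide["onset"].to_numpy())
        rows.append(
            {"range_c": rng_c, "r": res.r, "df": res.df, "p_raw": res.p_raw,
             "n": len(wide)}
        )
    return pd.DataFrame(rows)


def _anova_frame(anova: dict[str, RmAnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"model": m, "f_stat": r.f_stat, "df_num": r.df_num, "df_den": r.df_den,
             "p_raw": r.p_raw, "ss_condition": r.ss_condition,
             "ss_subject": r.ss_subject, "ss_error": r.ss_error}
            for m, r in anova.items()
        ]
    )


def write_results(result: ExperimentResult, out_dir: str | Path) -> Path:
    """Write the result bundle as CSV tables plus JSON run metadata.

    Output is deterministic: identical config + seed produce byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _anova_frame(result.anova).to_csv(out / "anova.csv", index=False)
    result.posthoc.to_csv(out / "posthoc.csv", index=False)
    result.mean_table.to_csv(out / "effects.csv", index=False)
    result.subtracted_effects.to_csv(out / "subtracted_effects.csv", index=False)
    result.sems.to_csv(out / "sems.csv", index=False)
    if result.sex is not None:
        result.sex.to_csv(out / "sex.csv", index=False)
    metadata = {
        "package_version": __version__,
        "config": result.config.to_dict(),
        "log": result.log,
        "n_subjects": int(result.dataset["subject_id"].nunique()),
        "sphericity_correction": "none",
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
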