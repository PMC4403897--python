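"""End-to-end pipeline: simulate or load traces, extract, aggregate, analyse.

Traces are exchanged as plain CSV (``time_s,pressure_mmHg``) with a
manifest CSV linking files to participant, gender, age, task and trial —
human-auditable and diff-friendly. A run is fully determined by its
configuration and seed; every artifact carries the configuration hash.

A participant is retained as long as at least one valid trial per task
survives (individual unreadable or malformed trace files are logged and
marked missing; the run aborts only when the cohort ends up empty).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import stats as st
from .synthetic import CohortConfig, SimulatedCohort, simulate_cohort

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "write_cohort",
    "extract_manifest",
    "analyze_features",
    "run_pipeline",
]

log = logging.getLogger("linguapress")

TRACE_COLUMNS = ("time_s", "pressure_mmHg")
FEATURE_COLUMNS = (
    "participant_id", "gender", "age", "task",
    "pmax_mmHg", "pmax_kPa", "t100_s", "pt100_mmHg_s",
    "excluded_flag", "aggregation_rule",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: a manifest CSV of recorded traces, or a
    simulation config. Statistics options select the t-test variant and
    the screening alpha; the threshold and aggregation rule parameterise
    extraction.
    """

    manifest: str | None = None
    simulation: CohortConfig | None = None
    threshold: float = ft.DEFAULT_THRESHOLD_MMHG
    aggregation: str = "max"
    test_variant: str = "pooled"
    alpha_screen: float = 0.05
    output_dir: str = "linguapress_run"
    seed: int = 0

    def __post_init__(self):
        if (self.manifest is None) == (self.simulation is None):
            raise ValueError("exactly one input source: manifest XOR simulation")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        d = dataclasses.asdict(self)
        d.pop("output_dir")  # where results land does not change what they are
        payload = json.dumps(d, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_trace(path, *, task: str = "ITS", trial_index: int = 1,
               sample_period: float = 0.01) -> ft.PressureTrace:
    """Read a ``time_s,pressure_mmHg`` CSV into a validated trace.

    Malformed rows are reported with their line numbers; missing columns,
    non-numeric cells and non-monotone time are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    for col in TRACE_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric or empty {col} at line(s) {rows}")
        df[col] = numeric
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise ValueError(f"{path}: time_s not strictly increasing at line {i + 3}")
    return ft.PressureTrace(
        times=t, pressures=df["pressure_mmHg"].to_numpy(),
        sample_period=sample_period, task=task, trial_index=trial_index,
    )


def write_trace(trace: ft.PressureTrace, path) -> None:
    """Write a trace as ``time_s,pressure_mmHg`` CSV (round-trips to 1e-6)."""
    pd.DataFrame({
        "time_s": trace.times, "pressure_mmHg": trace.pressures,
    }).to_csv(path, index=False, float_format="%.6f")


def write_cohort(cohort: SimulatedCohort, out_dir) -> Path:
    """Write every trace of a simulated cohort plus the manifest CSV."""
    out = Path(out_dir)
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        for task, trials in (("ITS", p.its_trials), ("ITE", p.ite_trials)):
            for trace in trials:
                name = f"{p.participant_id}_{task}_t{trace.trial_index}.csv"
                write_trace(trace, traces_dir / name)
                rows.append({
                    "participant_id": p.participant_id, "gender": p.gender,
                    "age": round(p.age, 1), "task": task,
                    "trial": trace.trial_index, "path": f"traces/{name}",
                })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _aggregate_rows(trial_features, threshold, rule):
    """Per participant-task aggregation; None when all trials failed/excluded."""
    usable = [f for f in trial_features if f is not None and not f.excluded]
    if not usable:
        return None
    return ft.aggregate_trials(usable, rule=rule)


def extract_manifest(manifest_path, *, threshold=ft.DEFAULT_THRESHOLD_MMHG,
                     aggregation="max") -> pd.DataFrame:
    """Extract and aggregate features for every participant in a manifest.

    Returns the aggregated feature table (one row per participant-task).
    Unreadable traces are logged and treated as missing trials.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"participant_id", "gender", "age", "task", "trial", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing column(s) {sorted(missing)}")
    rows = []
    for (pid, gender, age, task), group in manifest.groupby(
        ["participant_id", "gender", "age", "task"], sort=True
    ):
        trial_features = []
        for _, row in group.iterrows():
            path = manifest_path.parent / row["path"]
            try:
                trace = read_trace(path, task=task, trial_index=int(row["trial"]))
            except (OSError, ValueError) as exc:
                log.warning("skipping trial %s/%s/%s: %s", pid, task, row["trial"], exc)
                trial_features.append(None)
                continue
            trial_features.append(ft.extract_features(trace, threshold))
        agg = _aggregate_rows(trial_features, threshold, aggregation)
        if agg is None:
            log.warning("participant %s missing for task %s (no usable trial)", pid, task)
            continue
        rows.append({
            "participant_id": pid, "gender": gender, "age": age, "task": task,
            "pmax_mmHg": agg.pmax, "pmax_kPa": agg.pmax_kPa,
            "t100_s": agg.t100, "pt100_mmHg_s": agg.pt100,
            "excluded_flag": agg.excluded, "aggregation_rule": agg.aggregation_rule,
        })
    if not rows:
        raise ValueError("empty cohort: no participant has a usable trial")
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def _cohort_to_feature_table(cohort: SimulatedCohort, threshold, aggregation):
    rows = []
    for p in cohort.participants:
        for task, trials in (("ITS", p.its_trials), ("ITE", p.ite_trials)):
            feats = [ft.extract_features(tr, threshold) for tr in trials]
            agg = _aggregate_rows(feats, threshold, aggregation)
            if agg is None:
                continue
            rows.append({
                "participant_id": p.participant_id, "gender": p.gender,
                "age": p.age, "task": task,
                "pmax_mmHg": agg.pmax, "pmax_kPa": agg.pmax_kPa,
                "t100_s": agg.t100, "pt100_mmHg_s": agg.pt100,
                "excluded_flag": agg.excluded, "aggregation_rule": agg.aggregation_rule,
            })
    if not rows:
        raise ValueError("empty cohort: no participant has a usable trial")
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def _descriptives_block(d: st.Descriptives) -> dict:
    return {k: getattr(d, k) for k in (
        "n", "mean", "sd", "ci95_low", "ci95_high",
        "median", "iqr_low", "iqr_high", "skewness", "excess_kurtosis",
    )}


def analyze_features(table: pd.DataFrame, *, test_variant="pooled",
                     alpha_screen=0.05) -> dict:
    """Screening, descriptives and gender comparisons for a feature table.

    For each outcome (PmaxS, PmaxE, t100, Pt100): Shapiro-Wilk screening,
    per-gender and overall descriptives, and a gender comparison — the
    independent-samples t-test, plus an age-adjusted ANOVA and a
    Mann-Whitney U as the nonparametric route. No multiple-testing
    correction is applied; the report carries the number of tests run.
    """
    from scipy import stats as sps

    outcomes = {
        "PmaxS": ("ITS", "pmax_mmHg"),
        "PmaxE": ("ITE", "pmax_mmHg"),
        "t100": ("ITE", "t100_s"),
        "Pt100": ("ITE", "pt100_mmHg_s"),
    }
    results = {}
    n_tests = 0
    for name, (task, col) in outcomes.items():
        sub = table[table["task"] == task]
        males = sub.loc[sub["gender"] == "male", col].to_numpy(dtype=float)
        females = sub.loc[sub["gender"] == "female", col].to_numpy(dtype=float)
        if len(males) < 2 or len(females) < 2:
            results[name] = {"note": "insufficient data for gender comparison"}
            continue
        pooled = np.concatenate([males, females])
        screen = st.normality_screen(pooled, alpha_screen) if 3 <= len(pooled) <= 5000 else None
        hint = "normal" if screen is None or screen["route"] == "parametric" else "skewed"
        t_res = st.t_test_independent(males, females, variant=test_variant)
        u_stat, u_p = sps.mannwhitneyu(males, females, alternative="two-sided")
        block = {
            "screening": screen,
            "descriptives": {
                "all": _descriptives_block(st.describe(pooled, hint)),
                "male": _descriptives_block(st.describe(males, hint)),
                "female": _descriptives_block(st.describe(females, hint)),
            },
            "t_test": {
                "statistic": t_res.statistic, "df": t_res.df,
                "p_value": t_res.p_value, "test_name": t_res.test_name,
            },
            "mann_whitney": {"statistic": float(u_stat), "p_value": float(u_p)},
        }
        n_tests += 2
        ages = sub.set_index("participant_id")["age"]
        try:
            a_res = st.anova_gender_adjusted_age(
                sub[col].to_numpy(dtype=float), sub["gender"], sub["age"].to_numpy(dtype=float)
            )
            block["anova_age_adjusted"] = {
                "F": a_res.statistic, "df": list(a_res.df),
                "p_value": a_res.p_value,
                "observed_power": a_res.extra["observed_power"],
            }
            n_tests += 1
        except ValueError as exc:
            block["anova_age_adjusted"] = {"note": str(exc)}
        results[name] = block
    results["n_tests_run"] = n_tests
    results["multiple_testing_correction"] = "none"
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> extract -> aggregate -> screen -> test.

    Writes ``features.csv``, ``stats.json`` and ``run_log.json`` (config
    hash, seed, threshold, aggregation rule, test variant) to the output
    directory and returns the statistics dict. Re-running the same config
    reproduces identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("run %s: threshold=%g aggregation=%s variant=%s",
             chash, config.threshold, config.aggregation, config.test_variant)
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim)
        table = _cohort_to_feature_table(cohort, config.threshold, config.aggregation)
    else:
        table = extract_manifest(config.manifest, threshold=config.threshold,
                                 aggregation=config.aggregation)
    results = analyze_features(table, test_variant=config.test_variant,
                               alpha_screen=config.alpha_screen)
    results["config_hash"] = chash
    results["seed"] = config.seed
    table.to_csv(out / "features.csv", index=False, float_format="%.6f")
    (out / "stats.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(json.dumps({
        "config_hash": chash, "seed": config.seed,
        "threshold_mmHg": config.threshold, "aggregation_rule": config.aggregation,
        "test_variant": config.test_variant, "alpha_screen": config.alpha_screen,
        "n_participant_tasks": int(len(table)),
    }, indent=2, sort_keys=True))
    return results
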