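"""End-to-end study orchestration.

``run_study`` takes a study configuration, generates (or loads) a plan
cohort, runs the circulating-blood Monte Carlo for every plan condition,
computes plan-quality (HI/CI) and blood-DVH metrics, performs the paired
constraint-level statistics within each modality, summarizes percent
reductions, and writes the whole report bundle (tidy CSVs, markdown tables,
a JSON run manifest) to an output directory. Everything is seeded, and a
rerun with the same configuration reproduces the numeric outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circulation import build_reference_model
from .cohort import (CONSTRAINT_LEVELS, MODALITIES, CohortConfig,
                     PlanCondition, generate_cohort, load_cohort)
from .dvh import conformity_index, homogeneity_index, write_dvh_csv
from .errors import ConfigurationError
from .simulator import (BLOOD_METRICS, SimulationConfig, simulate_course)
from .stats import compare_levels, reduction_summary, wilcoxon_signed_rank

__all__ = ["StudyConfig", "StudyResult", "run_study", "report_tables",
           "compute_plan_metrics"]

log = logging.getLogger("hemodose")

LEVEL_LABELS = {"conv": "Conv", "bvs90": "BVS-90%", "bvs80": "BVS-80%"}


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None  # load a serialized cohort instead
    n_particles: int = 10_000
    dt: float = 0.05
    seed: int = 0
    residence_mode: str = "fixed"
    fraction_mode: str = "resample_each_fraction"
    bin_width: float = 0.01
    out_dir: str = "study_output"
    write_blood_dvhs: bool = False  # per-plan blood DVH CSVs (bulky)


@dataclass
class StudyResult:
    """In-memory results of a study run."""

    metrics: pd.DataFrame  # tidy: patient, sex, modality, level, structure, metric, value
    statistics: dict
    reductions: dict[str, pd.DataFrame]
    manifest: dict


def _plan_seed(base_seed: int, plan: PlanCondition) -> int:
    """Stable per-plan seed derived from the study seed and plan identity."""
    key = f"{base_seed}:{plan.patient_id}:{plan.condition}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def compute_plan_metrics(plan: PlanCondition, sim_cfg: SimulationConfig):
    """Simulate one plan condition; return (blood result, metric records)."""
    model = build_reference_model(plan.sex)
    result = simulate_course(model, plan.organ_dvhs, plan.schedule, sim_cfg)
    records = []
    base = dict(patient=plan.patient_id, sex=plan.sex, modality=plan.modality,
                level=plan.constraint_level, is_outlier=plan.is_outlier)
    for name, value in result.metrics.items():
        records.append({**base, "structure": "blood", "metric": name,
                        "value": float(value)})
    for ptv, dvh in plan.ptv_dvhs.items():
        records.append({**base, "structure": ptv, "metric": "HI",
                        "value": homogeneity_index(dvh)})
        records.append({**base, "structure": ptv, "metric": "CI",
                        "value": conformity_index(plan.isodose95_volumes[ptv],
                                                  plan.ptv_volumes[ptv])})
    return result, records


def _pivot(metrics: pd.DataFrame, structure: str, metric: str,
           modality: str) -> pd.DataFrame:
    """patients x constraint-level table for one metric within a modality."""
    sub = metrics[(metrics["structure"] == structure)
                  & (metrics["metric"] == metric)
                  & (metrics["modality"] == modality)]
    t = sub.pivot(index="patient", columns="level", values="value")
    return t[[lv for lv in CONSTRAINT_LEVELS if lv in t.columns]]


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full pipeline and write the report bundle to disk."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=cohort start")
    if config.cohort_dir:
        plans = load_cohort(config.cohort_dir)
    else:
        plans = generate_cohort(config.cohort)
    log.info("stage=cohort done n_plans=%d", len(plans))

    records = []
    for plan in plans:
        sim_cfg = SimulationConfig(
            n_particles=config.n_particles, dt=config.dt,
            seed=_plan_seed(config.seed, plan),
            residence_mode=config.residence_mode,
            fraction_mode=config.fraction_mode, bin_width=config.bin_width)
        result, recs = compute_plan_metrics(plan, sim_cfg)
        records.extend(recs)
        if config.write_blood_dvhs:
            ddir = out / "blood_dvhs"
            ddir.mkdir(exist_ok=True)
            write_dvh_csv({"blood": result.blood_dvh},
                          ddir / f"{plan.patient_id}_{plan.condition}.csv")
        log.info("stage=simulate plan=%s/%s dmean=%.4f",
                 plan.patient_id, plan.condition, result.metrics["Dmean"])
    metrics = pd.DataFrame.from_records(records).sort_values(
        ["patient", "modality", "level", "structure", "metric"]
    ).reset_index(drop=True)

    # Paired statistics: three constraint levels within each modality, for
    # every blood metric and every HI/CI endpoint; modality contrast at each
    # level reported descriptively with an optional Wilcoxon p.
    statistics: dict = {}
    reductions: dict[str, pd.DataFrame] = {}
    for modality in MODALITIES:
        statistics[modality] = {}
        for metric in BLOOD_METRICS:
            table = _pivot(metrics, "blood", metric, modality)
            statistics[modality][f"blood {metric}"] = compare_levels(table)
            if metric in ("Dmean", "D90%"):
                reductions[f"{modality} blood {metric}"] = reduction_summary(
                    table, baseline="conv")
        for ptv in ("PTV1", "PTV2"):
            for metric in ("HI", "CI"):
                table = _pivot(metrics, ptv, metric, modality)
                statistics[modality][f"{ptv} {metric}"] = compare_levels(table)
    statistics["IMPT vs IMRT"] = {}
    for level in CONSTRAINT_LEVELS:
        a = _pivot(metrics, "blood", "Dmean", "IMRT")[level]
        b = _pivot(metrics, "blood", "Dmean", "IMPT")[level]
        statistics["IMPT vs IMRT"][f"blood Dmean @ {LEVEL_LABELS[level]}"] = {
            "median_imrt": float(a.median()),
            "median_impt": float(b.median()),
            "mean_percent_reduction": float((100 * (a - b) / a).mean()),
            "wilcoxon_p": wilcoxon_signed_rank(a, b).p,
        }

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_particles": config.n_particles,
        "config": _jsonable(asdict(config)),
        "n_plan_conditions": len(plans),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {},
    }

    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.17g")
    tables = report_tables(metrics, statistics, reductions)
    (out / "report.md").write_text(tables["markdown"])
    for name, df in tables["csv"].items():
        df.to_csv(out / f"{name}.csv", float_format="%.17g")
    (out / "statistics.json").write_text(json.dumps(_jsonable(statistics), indent=2))
    for f in sorted(out.glob("*.csv")) + [out / "report.md"]:
        manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("stage=report done elapsed=%.1fs", time.time() - t0)
    return StudyResult(metrics=metrics, statistics=statistics,
                       reductions=reductions, manifest=manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _median_range(vals: pd.Series) -> str:
    return f"{vals.median():.3f} ({vals.min():.3f}-{vals.max():.3f})"


def report_tables(metrics: pd.DataFrame, statistics: dict,
                  reductions: dict[str, pd.DataFrame]) -> dict:
    """Build the three report tables as DataFrames plus a markdown digest.

    (i) target coverage: HI/CI median (range) per condition with Friedman and
    post-hoc p-values; (ii) blood metrics: median (range) of Dmean,
    D90%...D2%, V0.9Gy per condition; (iii) percent-reduction summaries.
    """
    for modality in MODALITIES:
        for ptv in ("PTV1", "PTV2"):
            if metrics[(metrics["modality"] == modality)
                       & (metrics["structure"] == ptv)].empty:
                raise ConfigurationError(
                    f"missing condition in results: {modality}/{ptv}")

    coverage_rows = []
    for modality in MODALITIES:
        for ptv in ("PTV1", "PTV2"):
            for metric in ("HI", "CI"):
                row = {"modality": modality, "structure": ptv, "index": metric}
                for level in CONSTRAINT_LEVELS:
                    t = _pivot(metrics, ptv, metric, modality)
                    row[LEVEL_LABELS[level]] = _median_range(t[level])
                st = statistics[modality][f"{ptv} {metric}"]
                row["friedman_p"] = st["friedman_p"]
                for pair, ps in st["posthoc"].items():
                    row[f"p {pair}"] = ps["p_adjusted"]
                coverage_rows.append(row)
    coverage = pd.DataFrame(coverage_rows).set_index(["modality", "structure", "index"])

    blood_rows = []
    for modality in MODALITIES:
        for level in CONSTRAINT_LEVELS:
            row = {"modality": modality, "level": LEVEL_LABELS[level]}
            for metric in BLOOD_METRICS:
                t = _pivot(metrics, "blood", metric, modality)
                row[metric] = _median_range(t[level])
            blood_rows.append(row)
    blood = pd.DataFrame(blood_rows).set_index(["modality", "level"])

    red_rows = []
    for name, df in reductions.items():
        for cond, r in df.iterrows():
            red_rows.append({"comparison": name, "condition": LEVEL_LABELS.get(cond, cond),
                             **r.to_dict()})
    reduction = pd.DataFrame(red_rows).set_index(["comparison", "condition"])

    def fence(df: pd.DataFrame) -> str:
        return "```\n" + df.reset_index().to_string(index=False) + "\n```"

    md = ["# Study report", "", "## Target coverage (HI/CI)", "",
          fence(coverage), "",
          "## Circulating-blood DVH metrics", "",
          fence(blood), "",
          "## Percent reductions vs Conv", "",
          fence(reduction), ""]
    return {"csv": {"target_coverage": coverage, "blood_metrics": blood,
                    "reductions": reduction},
            "markdown": "\n".join(md)}
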