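"""Desk-scale replication of the method-comparison study design.

``run_study`` generates a synthetic cohort, measures inclination with all
three transverse-axis constructions for every simulated rater, and emits:

* a per-(case, rater, method) inclination table;
* per-method descriptive statistics on rater-averaged values;
* per-method four-rater ICC(2,1) computed on the *pre-averaging* values;
* pairwise between-method concordance reports on rater-averaged values;
* lone-outlier counts and pairwise >=5 deg disagreement rates.

The scapular frontal plane, the glenoid mediolateral axis and the
``y_axis`` transverse axis are software-side constructions: they are
computed once per case from the mesh and the exact (software-identified)
glenoid center, so every ``y_axis`` rater column holds the identical
value.  A rater's picks enter only the *transverse axis* of the manual
methods — the Glenoid-Trigonum line through the rater's glenoid center
and trigonum, and the Best-Fit Line Fossa through the rater's five fossa
picks — which are then combined with the shared automatic glenoid axis and
averaged across raters for between-method comparison.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .agreement import (
    AgreementReport,
    OutlierSummary,
    concordance_workflow,
    discrepancy_outliers,
    icc_absolute_agreement,
)
from .errors import DegenerateDataError, GlenaxError
from .fitting import fit_line, fit_sphere
from .inclination import (
    bflf_axis,
    frontal_plane,
    glenoid_axis,
    glenoid_center,
    gt_line,
    inclination,
    measure_inclination,
    measurement_frame,
    spine_body_intersection_points,
)
from .synthetic import (
    FOSSA_TILT_SD_DEG,
    OFFSET_SD_TYPICAL_MM,
    OFFSET_SD_WORST_MM,
    WORST_CASE_PROB,
    RaterNoiseModel,
    ScapulaParams,
    generate_cohort,
)
from .types import METHODS

__all__ = ["StudyConfig", "StudyResult", "run_study", "summarize"]

METHOD_NAMES = {
    "y_axis": "Y-axis",
    "gt_line": "Glenoid-Trigonum line",
    "bflf": "Best-Fit Line Fossa",
}

#: Between-method pairs reported, in presentation order.
PAIRS: Tuple[Tuple[str, str], ...] = (
    ("y_axis", "gt_line"),
    ("bflf", "gt_line"),
    ("y_axis", "bflf"),
)


@dataclass
class StudyConfig:
    """Cohort design constants and decision thresholds."""

    n_cases: int = 82
    n_raters: int = 4
    seed: int = 0
    inclination_range: Tuple[float, float] = (-15.0, 21.0)
    noise: RaterNoiseModel = field(default_factory=RaterNoiseModel)
    scapula: ScapulaParams = field(default_factory=ScapulaParams)
    fossa_tilt_sd: float = FOSSA_TILT_SD_DEG
    offset_sd_typical: float = OFFSET_SD_TYPICAL_MM
    offset_sd_worst: float = OFFSET_SD_WORST_MM
    worst_case_prob: float = WORST_CASE_PROB
    r_gate: float = 0.7
    bias_threshold: float = 3.0
    ci_threshold: float = 5.0
    outlier_threshold: float = 5.0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.n_raters < 2:
            raise DegenerateDataError("n_raters must be >= 2")
        for name in ("r_gate", "bias_threshold", "ci_threshold", "outlier_threshold"):
            if getattr(self, name) <= 0:
                raise DegenerateDataError(f"{name} must be positive")
        self.noise = dataclasses.replace(self.noise, n_raters=self.n_raters)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "noise" in raw:
            raw["noise"] = RaterNoiseModel(**raw["noise"])
        if "scapula" in raw:
            raw["scapula"] = ScapulaParams(**raw["scapula"])
        if "inclination_range" in raw:
            raw["inclination_range"] = tuple(raw["inclination_range"])
        return cls(**raw)


@dataclass
class StudyResult:
    """Everything the study computes, at full precision."""

    table: pd.DataFrame  # case, rater, method, inclination_deg
    averaged: pd.DataFrame  # case x method (rater-averaged)
    truth: pd.DataFrame  # case, per-method ground truth + generator params
    summary: pd.DataFrame  # mean/min/max/sd x method
    icc: Dict[str, Tuple[float, float, float]]
    agreements: Dict[str, AgreementReport]
    outliers: OutlierSummary
    n_failed: int
    failures: List[Tuple[int, str]]


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full simulated study; deterministic given ``config.seed``."""
    def offset_distribution(rng: np.random.Generator) -> float:
        worst = rng.random() < config.worst_case_prob
        sd = config.offset_sd_worst if worst else config.offset_sd_typical
        return float(rng.normal(0.0, sd)) if sd > 0 else 0.0

    cohort = generate_cohort(
        n_cases=config.n_cases,
        inclination_range=config.inclination_range,
        offset_distribution=offset_distribution,
        noise=config.noise,
        seed=config.seed,
        base_params=config.scapula,
        fossa_tilt_sd=config.fossa_tilt_sd,
    )
    rows = []
    truth_rows = []
    failures: List[Tuple[int, str]] = []
    for case_id, (case, raters) in enumerate(cohort):
        mesh = case.mesh
        try:
            fp = frontal_plane(mesh)
            boundary = fit_line(spine_body_intersection_points(mesh))
            sphere = fit_sphere(mesh.region_vertices("glenoid"))
            auto_center = glenoid_center(case.true_landmarks)
            g_ml = glenoid_axis(mesh, auto_center, sphere=sphere)
            y_val = measure_inclination(
                mesh, case.true_landmarks, "y_axis",
                frontal=fp, boundary_line=boundary, sphere=sphere,
            ).inclination_deg
            for r_idx, lms in enumerate(raters):
                rows.append((case_id, r_idx, "y_axis", y_val))
                rater_center = glenoid_center(lms)
                for method, transverse in (
                    ("gt_line", gt_line(rater_center, lms.trigonum)),
                    ("bflf", bflf_axis(lms, rater_center)),
                ):
                    frame = measurement_frame(
                        mesh, transverse, lms.inferior_angle, auto_center, frontal=fp
                    )
                    val = inclination(transverse, g_ml, frame, method=method).inclination_deg
                    rows.append((case_id, r_idx, method, val))
        except GlenaxError as exc:
            failures.append((case_id, str(exc)))
            continue
        truth_rows.append(
            {
                "case": case_id,
                "true_inclination_deg": case.params.true_inclination_deg,
                "trigonum_offset_si": case.params.trigonum_offset_si,
                "fossa_tilt_deg": case.params.fossa_tilt_deg,
                "laterality": case.params.laterality,
                **{f"truth_{m}": case.truth[m] for m in METHODS},
            }
        )
    if not rows:
        raise DegenerateDataError("run_study: every case failed; nothing to analyse")
    table = pd.DataFrame(rows, columns=["case", "rater", "method", "inclination_deg"])
    truth = pd.DataFrame(truth_rows)

    wide = table.pivot_table(
        index=["case", "rater"], columns="method", values="inclination_deg"
    )
    icc = {}
    for m in METHODS:
        mat = wide[m].unstack("rater").to_numpy()
        icc[m] = icc_absolute_agreement(mat)

    averaged = table.groupby(["case", "method"])["inclination_deg"].mean().unstack()
    averaged = averaged[list(METHODS)]
    summary = pd.DataFrame(
        {
            m: {
                "mean_deg": averaged[m].mean(),
                "min_deg": averaged[m].min(),
                "max_deg": averaged[m].max(),
                "sd_deg": averaged[m].std(ddof=1),
            }
            for m in METHODS
        }
    )
    agreements = {
        f"{a}_vs_{b}": concordance_workflow(
            averaged[a], averaged[b],
            r_gate=config.r_gate,
            bias_threshold=config.bias_threshold,
            ci_threshold=config.ci_threshold,
        )
        for a, b in PAIRS
    }
    outliers = discrepancy_outliers(
        averaged["y_axis"], averaged["gt_line"], averaged["bflf"],
        outlier_threshold=config.outlier_threshold,
        agree_threshold=config.outlier_threshold,
    )
    result = StudyResult(
        table=table,
        averaged=averaged,
        truth=truth,
        summary=summary,
        icc=icc,
        agreements=agreements,
        outliers=outliers,
        n_failed=len(failures),
        failures=failures,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _report_to_dict(rep: AgreementReport) -> dict:
    return dataclasses.asdict(rep)


def _write_outputs(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "inclinations.csv", index=False)
    result.averaged.to_csv(out_dir / "averaged.csv")
    result.truth.to_csv(out_dir / "truth.csv", index=False)
    payload = {
        "summary": {m: result.summary[m].to_dict() for m in METHODS},
        "icc": {m: dict(zip(("icc", "ci_low", "ci_high"), result.icc[m])) for m in METHODS},
        "agreements": {k: _report_to_dict(v) for k, v in result.agreements.items()},
        "outliers": {
            "counts": result.outliers.counts,
            "pairwise_rates_pct": result.outliers.pairwise_rates_pct,
            "max_pairwise_diff_deg": float(result.outliers.max_pairwise_diff.max()),
        },
        "n_failed": result.n_failed,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(summarize(result))


def _fmt(x, nd=1) -> str:
    return "" if x is None else f"{x:.{nd}f}"


def summarize(result: StudyResult) -> str:
    """Human-readable report: descriptive table, ICC table, concordance
    table and the lone-outlier paragraph.  Angles are rounded to 0.1 deg,
    coefficients to 0.01, percentages to integers (full precision stays in
    the CSV/JSON outputs)."""
    if result.table.empty:
        raise DegenerateDataError("summarize: empty study result")
    cols = [METHOD_NAMES[m] for m in METHODS]
    lines = []
    lines.append("Inclination values according to the transverse-axis method")
    lines.append("  (rater-averaged, degrees)")
    header = f"  {'':<22}" + "".join(f"{c:>24}" for c in cols)
    lines.append(header)
    for label, key in (
        ("Mean", "mean_deg"), ("Minimum", "min_deg"),
        ("Maximum", "max_deg"), ("Standard Deviation", "sd_deg"),
    ):
        row = f"  {label:<22}" + "".join(
            f"{result.summary[m][key]:>24.1f}" for m in METHODS
        )
        lines.append(row)
    lines.append("")
    lines.append("Interobserver ICC (absolute agreement, single rater)")
    for m in METHODS:
        icc, lo, hi = result.icc[m]
        lines.append(f"  {METHOD_NAMES[m]:<24} ICC {icc:.2f}  95%CI ({lo:.2f}; {hi:.2f})")
    lines.append("")
    lines.append("Between-method correlation and concordance (rater-averaged)")
    lines.append(
        f"  {'pair':<34}{'r':>6}{'bias':>8}{'LoA low':>9}{'LoA high':>9}"
        f"{'CCC':>7}{'LoP%':>6}{'LoA%':>6}  verdict"
    )
    for key, rep in result.agreements.items():
        a, b = key.split("_vs_")
        name = f"{METHOD_NAMES[a]} vs {METHOD_NAMES[b]}"
        lop = "" if rep.lop_pct is None else f"{rep.lop_pct:.0f}"
        loa = "" if rep.loa_pct is None else f"{rep.loa_pct:.0f}"
        lines.append(
            f"  {name:<34}{rep.r:>6.2f}{_fmt(rep.bias_deg):>8}{_fmt(rep.loa_low_deg):>9}"
            f"{_fmt(rep.loa_high_deg):>9}{_fmt(rep.ccc, 2):>7}{lop:>6}{loa:>6}  {rep.verdict}"
        )
    lines.append("")
    counts = result.outliers.counts
    rates = result.outliers.pairwise_rates_pct
    lines.append("Discrepancy analysis (threshold 5 deg unless configured otherwise)")
    lines.append(
        "  lone-outlier cases: "
        + ", ".join(f"{METHOD_NAMES[m]} {counts[m]}" for m in METHODS)
    )
    lines.append(
        "  pairwise >= threshold rates: "
        + ", ".join(f"{k} {v:.0f}%" for k, v in rates.items())
    )
    lines.append(
        f"  largest between-method difference: "
        f"{result.outliers.max_pairwise_diff.max():.1f} deg"
    )
    if result.n_failed:
        lines.append(f"  cases excluded after measurement failure: {result.n_failed}")
    return "\n".join(lines) + "\n"
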