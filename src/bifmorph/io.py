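"""CSV/YAML interchange, report writing, and end-to-end pipeline chaining.

Two tabular dialects are supported (plain CSV, header required, one row per
bifurcation, undefined values as empty fields):

* the *landmark* table — identifiers, the four 3D points (mm) and the three
  best-fit diameters, i.e. what an upstream mesh/centreline tool exports;
* the *morphometry* table — radii, observed angles, PMW indices and
  deviations, i.e. what :func:`measure_landmarks` computes.

Every analysis run emits a deterministic file set (group-comparison tables,
odds-ratio tables, ROC summary) plus a manifest with the config hash, seed
and library versions, sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import (BifurcationLandmarks, compute_observed_angles,
                       radius_from_diameter, ValidationError)
from .pmw import RadiiTriple, measure_bifurcation
from .simulate import SimulationConfig, SyntheticCohort, generate_cohort
from .stats import (CohortRecord, InsufficientDataError, cohort_frame,
                    compare_groups, multivariate_logistic, roc_analysis,
                    univariate_logistic)

logger = logging.getLogger("bifmorph")

CONFIG_SCHEMA_VERSION = "1"

LANDMARK_COLUMNS = [
    "subject_id", "site", "group", "aneurysm",
    "Ax", "Ay", "Az", "Bx", "By", "Bz", "Cx", "Cy", "Cz", "Ox", "Oy", "Oz",
    "d0_mm", "d1_mm", "d2_mm",
]

MORPHOMETRY_COLUMNS = [
    "subject_id", "site", "group", "aneurysm",
    "r0_mm", "r1_mm", "r2_mm",
    "alpha_deg", "phi1_obs_deg", "phi2_obs_deg",
    "asymmetry_ratio", "area_ratio", "junction_exponent",
    "phi1_opt_deg", "phi2_opt_deg", "total_opt_deg",
    "dev_total_deg", "dev_phi1_deg", "dev_phi2_deg", "domain_status",
]

#: parameters tabulated in the per-vessel group-comparison tables
COMPARISON_PARAMETERS = [
    "alpha_deg", "phi1_obs_deg", "phi2_obs_deg",
    "r0_mm", "r1_mm", "r2_mm",
    "asymmetry_ratio", "area_ratio", "junction_exponent",
    "dev_total_deg", "dev_phi1_deg", "dev_phi2_deg",
]

#: univariate screen (odds-ratio table shape)
UNIVARIATE_PREDICTORS = [
    ("r0_mm", "continuous"), ("r1_mm", "continuous"), ("r2_mm", "continuous"),
    ("area_ratio", "continuous"), ("asymmetry_ratio", "continuous"),
    ("junction_exponent", "continuous"),
    ("alpha_deg", "continuous"), ("alpha_deg", "tertile"),
    ("phi1_obs_deg", "continuous"), ("phi1_obs_deg", "tertile"),
    ("phi2_obs_deg", "continuous"), ("phi2_obs_deg", "tertile"),
]

#: the two multivariate model templates: A uses the branch angles in
#: tertiles plus both radii; B uses the total angle in tertiles plus radii
MODEL_A = [("phi1_obs_deg", "tertile"), ("phi2_obs_deg", "tertile"),
           ("r0_mm", "continuous"), ("r1_mm", "continuous")]
MODEL_B = [("alpha_deg", "tertile"), ("r0_mm", "continuous"),
           ("r1_mm", "continuous")]

ROC_PREDICTORS = ["alpha_deg", "phi1_obs_deg", "phi2_obs_deg", "r0_mm"]


class SchemaError(ValueError):
    """The CSV header does not match the expected dialect."""


@dataclass
class RowReport:
    """Row-numbered diagnostics for rejected input rows."""

    rejected: list = field(default_factory=list)  # (row_number, reason)

    def add(self, row: int, reason: str) -> None:
        self.rejected.append((row, reason))
        logger.warning("row %d rejected: %s", row, reason)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_landmark_csv(path) -> tuple[list, RowReport]:
    """Read the landmark table; returns ``(records, report)`` where each
    record is ``(ident_dict, BifurcationLandmarks)`` and the report lists
    every rejected row with its reason."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: empty landmark file")
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    records, report = [], RowReport()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # header is line 1
        try:
            pts = {
                k: np.array([float(row[f"{k}x"]), float(row[f"{k}y"]),
                             float(row[f"{k}z"])])
                for k in ("A", "B", "C", "O")
            }
            lm = BifurcationLandmarks(
                point_A=pts["A"], point_B=pts["B"], point_C=pts["C"],
                point_O=pts["O"],
                d0=float(row["d0_mm"]), d1=float(row["d1_mm"]),
                d2=float(row["d2_mm"]),
            )
        except (ValueError, TypeError) as exc:
            report.add(rownum, str(exc))
            continue
        ident = {
            "subject_id": str(row["subject_id"]),
            "site": str(row["site"]),
            "group": str(row["group"]),
            "aneurysm": int(row["aneurysm"]),
        }
        records.append((ident, lm))
    return records, report


def write_landmark_csv(path, cohort: SyntheticCohort) -> None:
    if cohort.landmarks is None:
        raise ValidationError("cohort was generated without landmarks")
    rows = []
    for rec, lm in zip(cohort.records, cohort.landmarks):
        row = {"subject_id": rec.subject_id, "site": rec.site,
               "group": rec.group, "aneurysm": rec.aneurysm}
        for key, pt in (("A", lm.point_A), ("B", lm.point_B),
                        ("C", lm.point_C), ("O", lm.point_O)):
            row[f"{key}x"], row[f"{key}y"], row[f"{key}z"] = pt
        row.update(d0_mm=lm.d0, d1_mm=lm.d1, d2_mm=lm.d2)
        rows.append(row)
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def measure_landmarks(
    records: Sequence[tuple], clamp_mode: bool = False
) -> pd.DataFrame:
    """Geometry + PMW measurement of landmark records into the morphometry
    table."""
    cohort_records = []
    for ident, lm in records:
        obs = compute_observed_angles(lm)
        radii = RadiiTriple(
            radius_from_diameter(lm.d0),
            radius_from_diameter(lm.d1),
            radius_from_diameter(lm.d2),
        )
        morph = measure_bifurcation(radii, obs, clamp_mode=clamp_mode)
        cohort_records.append(CohortRecord(
            subject_id=ident["subject_id"], site=ident["site"],
            group=ident["group"], aneurysm=ident["aneurysm"],
            morphometry=morph,
        ))
    return cohort_frame(cohort_records)


def write_morphometry_csv(path, frame: pd.DataFrame) -> None:
    """Undefined values serialise as empty fields, full float precision."""
    frame.to_csv(path, index=False, columns=MORPHOMETRY_COLUMNS,
                 float_format="%.17g", na_rep="")


def read_morphometry_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: empty morphometry file")
    missing = [c for c in MORPHOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_simulation_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SimulationConfig.from_dict(d)


# ---------------------------------------------------------------------------
# analysis + report
# ---------------------------------------------------------------------------

def _vessel_family(site: str) -> str:
    return site.split("_")[0]


@dataclass
class AnalysisReport:
    comparisons: list  # (family, GroupComparison)
    univariate: list  # UnivariateResult
    model_a: Optional[object]
    model_b: Optional[object]
    roc: list  # RocResult
    n_records: int
    n_undefined: dict  # parameter -> count of undefined values
    notes: list = field(default_factory=list)


def analyze_cohort(
    frame: pd.DataFrame,
    entry_p: float = 0.1,
    correlation_exclusion_r: float = 0.7,
) -> AnalysisReport:
    """Run the full statistical layer on a morphometry table.

    Group comparisons are run per vessel family (site label up to the first
    underscore) for every tabulated parameter; the univariate screen, the
    two multivariate models and the ROC analysis pool all records with the
    aneurysm flag as outcome.  Stages that cannot run on a given cohort
    (too few records, no surviving predictor) are recorded as notes, not
    crashes.
    """
    notes: list = []
    comparisons = []
    fam = frame["site"].map(_vessel_family)
    for family in sorted(fam.unique()):
        sub = frame[fam == family]
        if sub["group"].nunique() < 2:
            continue
        for param in COMPARISON_PARAMETERS:
            try:
                comparisons.append((family, compare_groups(sub, param)))
            except InsufficientDataError as exc:
                notes.append(f"comparison {family}/{param}: {exc}")

    univariate = []
    for pred, coding in UNIVARIATE_PREDICTORS:
        try:
            univariate.append(univariate_logistic(frame, pred, coding))
        except InsufficientDataError as exc:
            notes.append(f"univariate {pred} ({coding}): {exc}")

    model_a = model_b = None
    try:
        model_a = multivariate_logistic(frame, MODEL_A, entry_p,
                                        correlation_exclusion_r)
    except InsufficientDataError as exc:
        notes.append(f"model A: {exc}")
    try:
        model_b = multivariate_logistic(frame, MODEL_B, entry_p,
                                        correlation_exclusion_r)
    except InsufficientDataError as exc:
        notes.append(f"model B: {exc}")

    roc = []
    for pred in ROC_PREDICTORS:
        try:
            roc.append(roc_analysis(frame, pred))
        except InsufficientDataError as exc:
            notes.append(f"roc {pred}: {exc}")

    n_undefined = {
        p: int(frame[p].isna().sum()) for p in COMPARISON_PARAMETERS
    }
    return AnalysisReport(
        comparisons=comparisons, univariate=univariate,
        model_a=model_a, model_b=model_b, roc=roc,
        n_records=len(frame), n_undefined=n_undefined, notes=notes,
    )


def _comparison_frames(report: AnalysisReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, ph_rows = [], []
    for family, cmp_ in report.comparisons:
        for g, (n, mean, sd) in sorted(cmp_.group_stats.items()):
            rows.append({
                "vessel": family, "parameter": cmp_.parameter, "group": g,
                "n": n, "mean": mean, "sd": sd,
                "n_undefined": report.n_undefined.get(cmp_.parameter, 0),
                "test": cmp_.test_used, "omnibus_p": cmp_.omnibus_p,
            })
        for (g1, g2), p in cmp_.posthoc:
            ph_rows.append({
                "vessel": family, "parameter": cmp_.parameter,
                "group_1": g1, "group_2": g2, "p": p,
            })
    return pd.DataFrame(rows), pd.DataFrame(
        ph_rows, columns=["vessel", "parameter", "group_1", "group_2", "p"])


def _or_frame(results: list) -> pd.DataFrame:
    rows = []
    for res in results:
        for r in res.rows:
            row = {
                "predictor": r.predictor, "level": r.level,
                "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "p_value": r.p_value,
                "separation_flag": int(r.separation), "n": res.n,
            }
            if res.tertiles is not None:
                row["tertile_lower_boundary"] = res.tertiles.lower_boundary
                row["tertile_upper_boundary"] = res.tertiles.upper_boundary
            rows.append(row)
    return pd.DataFrame(rows)


def _multivariate_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for name, model in (("A", report.model_a), ("B", report.model_b)):
        if model is None:
            continue
        for r in model.rows:
            rows.append({
                "model": name, "predictor": r.predictor, "level": r.level,
                "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "p_value": r.p_value,
                "separation_flag": int(r.separation), "n": model.n,
            })
    return pd.DataFrame(rows, columns=[
        "model", "predictor", "level", "odds_ratio", "ci_low", "ci_high",
        "p_value", "separation_flag", "n"])


def _roc_frame(report: AnalysisReport) -> pd.DataFrame:
    return pd.DataFrame([{
        "predictor": r.predictor, "auc": r.auc, "cutoff": r.cutoff,
        "sensitivity": r.sensitivity, "specificity": r.specificity,
        "youden_j": r.youden_j, "n_cases": r.n_cases,
        "n_controls": r.n_controls,
    } for r in report.roc])


def _format_text_tables(report: AnalysisReport) -> str:
    lines = [f"bifmorph analysis report ({report.n_records} records)", ""]
    comp, _ = _comparison_frames(report)
    if not comp.empty:
        for vessel, sub in comp.groupby("vessel"):
            lines.append(f"== {vessel} bifurcations: group comparison ==")
            lines.append(sub.to_string(index=False,
                                       float_format=lambda v: f"{v:.4g}"))
            lines.append("")
    roc = _roc_frame(report)
    if not roc.empty:
        lines.append("== ROC summary ==")
        lines.append(roc.to_string(index=False,
                                   float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    if report.notes:
        lines.append("== notes ==")
        lines.extend(f"- {n}" for n in report.notes)
        lines.append("")
    return "\n".join(lines)


def write_report(
    report: AnalysisReport,
    outdir,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
    make_plots: bool = False,
    frame: Optional[pd.DataFrame] = None,
) -> list:
    """Write the deterministic report file set; returns the paths written.

    Fails before writing anything if the report is empty or the directory
    cannot be created.
    """
    if not (report.comparisons or report.univariate or report.roc):
        raise ValidationError("empty analysis report: nothing to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    comp, posthoc = _comparison_frames(report)
    targets = {
        "group_comparisons.csv": comp,
        "posthoc_pairs.csv": posthoc,
        "univariate_or.csv": _or_frame(report.univariate),
        "multivariate_or.csv": _multivariate_frame(report),
        "roc_summary.csv": _roc_frame(report),
    }
    for name, df in targets.items():
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    text_path = outdir / "report.txt"
    text_path.write_text(_format_text_tables(report))
    written.append(text_path)

    cfg_json = json.dumps(config or {}, sort_keys=True)
    manifest = {
        "package": "bifmorph",
        "version": __version__,
        "config_schema_version": CONFIG_SCHEMA_VERSION,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "n_records": report.n_records,
        "n_undefined": report.n_undefined,
        "notes": report.notes,
        "versions": _library_versions(),
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(man_path)

    if make_plots and frame is not None and report.roc:
        written.append(_plot_roc(frame, report, outdir / "roc_curves.png"))
    return written


def _library_versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _plot_roc(frame: pd.DataFrame, report: AnalysisReport, path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in report.roc:
        data = frame[[r.predictor, "aneurysm"]].dropna()
        fpr, tpr, _ = roc_curve(data["aneurysm"], data[r.predictor])
        ax.plot(fpr, tpr, label=f"{r.predictor} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_ground_truth(path, cohort: SyntheticCohort) -> None:
    Path(path).write_text(
        json.dumps(cohort.ground_truth, indent=2, sort_keys=True) + "\n")


def run_full_pipeline(cfg: SimulationConfig, outdir,
                      entry_p: float = 0.1,
                      correlation_exclusion_r: float = 0.7,
                      make_plots: bool = False) -> AnalysisReport:
    """simulate -> (landmarks ->) measure -> analyze -> report, one call."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    if cfg.output_mode == "landmarks":
        write_landmark_csv(outdir / "landmarks.csv", cohort)
        records, _ = read_landmark_csv(outdir / "landmarks.csv")
        frame = measure_landmarks(records, clamp_mode=cfg.clamp_mode)
    else:
        frame = cohort_frame(cohort.records)
    write_morphometry_csv(outdir / "morphometry.csv", frame)
    write_ground_truth(outdir / "ground_truth.json", cohort)
    report = analyze_cohort(frame, entry_p=entry_p,
                            correlation_exclusion_r=correlation_exclusion_r)
    write_report(report, outdir, config=cfg.to_dict(), seed=cfg.seed,
                 make_plots=make_plots, frame=frame)
    return report
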