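"""End-to-end validation pipeline and report I/O.

Reads patient-level cohort tables, runs scoring → score customization →
base/combined model fits → the discrimination/calibration battery, and
emits a seven-row validation report (NIRIS, Marshall, Helsinki, Base,
Base+NIRIS, Base+Marshall, Base+Helsinki):

* AUC with 95% CI per model;
* DeLong p versus the reference model — NIRIS for the CT-only models,
  the clinical base model for the combined models;
* Hosmer–Lemeshow p where applicable (models with fewer than ``groups``
  distinct risk levels, i.e. the few-category CT scores, get NA);
* Nagelkerke R² per model;
* IDI (with CI) of each combined model over the base model.

Note the DeLong comparisons between nested models fitted on the same data
(Base vs Base+CT) are anticonservative; they are reported this way because
that is the comparison the validation design specifies.

Rows that cannot be computed honestly are reported as NA rather than
guessed: models needing clinical covariates when the input (e.g. a
printed-table expansion) has none, and Marshall/Helsinki rows when the
findings are category-representative placeholders carrying no information
beyond the NIRIS category itself.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import (CrossTab, MetricError, PerformanceReport,
                      auc_mann_whitney, delong_compare, hosmer_lemeshow, idi,
                      nagelkerke_r2)
from .models import (LogisticFit, ModelError, PatientRecord,
                     build_base_model, build_combined_model,
                     customize_ct_model)
from .scoring import (BASAL_STATES, CTFindings, FindingsValidationError,
                      HERNIATION_GRADES, HYDROCEPHALUS_GRADES,
                      SUPRASELLAR_STATES, score_all)

__all__ = [
    "ValidationConfig",
    "ValidationReport",
    "PipelineError",
    "COHORT_COLUMNS",
    "MODEL_ROWS",
    "read_cohort",
    "write_cohort",
    "run_validation",
    "write_report",
    "read_report",
    "render_report_text",
]

logger = logging.getLogger(__name__)

FINDINGS_COLUMNS = tuple(f.name for f in dc_fields(CTFindings))
CLINICAL_COLUMNS = ("age_years", "gcs", "saps2_modified",
                    "chronic_comorbidity", "dead_6mo")
#: Documented cohort-table header, one column per record field.
COHORT_COLUMNS = ("patient_id",) + CLINICAL_COLUMNS + FINDINGS_COLUMNS

MODEL_ROWS = ("NIRIS", "Marshall", "Helsinki", "Base",
              "Base+NIRIS", "Base+Marshall", "Base+Helsinki")

REPORT_COLUMNS = ("model", "auc", "auc_lo", "auc_hi", "delong_p", "hl_p",
                  "nagelkerke_r2", "idi", "idi_lo", "idi_hi")

_BOOL_FINDINGS = ("sah_present", "ivh_present", "dai_present",
                  "skull_fracture", "pneumocephalus", "duret_hemorrhage",
                  "mass_lesion_evacuated")
_ENUM_DOMAINS = {
    "suprasellar_cisterns": SUPRASELLAR_STATES,
    "basal_cisterns": BASAL_STATES,
    "hydrocephalus": HYDROCEPHALUS_GRADES,
    "herniation": HERNIATION_GRADES,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class ValidationConfig:
    """Run configuration; defaults mirror the validation design."""

    hl_groups: int = 10
    idi_ci_method: str = "analytic"
    idi_bootstrap_reps: int = 2000
    seed: int = 0


@dataclass
class ValidationReport:
    """All outputs of one validation run."""

    rows: dict  # model name -> PerformanceReport, in MODEL_ROWS order
    summary: dict
    niris_outcome: Optional[CrossTab]
    niris_marshall: Optional[np.ndarray]
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("true", "1", "1.0"):
        return True
    if s in ("false", "0", "0.0"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _parse_optional_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float)
                                        and math.isnan(value)):
        return None
    return float(value)


def _record_from_row(row: dict) -> PatientRecord:
    kwargs = {}
    for name in FINDINGS_COLUMNS:
        v = row[name]
        if name in _BOOL_FINDINGS:
            b = _parse_bool(v)
            if b is None:
                raise ValueError(f"{name} missing")
            kwargs[name] = b
        elif name in _ENUM_DOMAINS:
            s = str(v).strip().lower()
            if s not in _ENUM_DOMAINS[name]:
                raise ValueError(f"{name} invalid value {v!r}")
            kwargs[name] = s
        else:
            kwargs[name] = float(v)
    findings = CTFindings(**kwargs)

    gcs = _parse_optional_float(row["gcs"])
    return PatientRecord(
        patient_id=row["patient_id"],
        findings=findings,
        age_years=_parse_optional_float(row["age_years"]),
        gcs=None if gcs is None else int(gcs),
        saps2_modified=_parse_optional_float(row["saps2_modified"]),
        chronic_comorbidity=_parse_bool(row["chronic_comorbidity"]),
        dead_6mo=_parse_bool(row["dead_6mo"]),
    )


def read_cohort(path, return_dropped: bool = False):
    """Read a delimited cohort table (comma; tab accepted) into records.

    Rows failing validation (out-of-range GCS, invalid enum values,
    negative volumes, …) are dropped and logged with reasons; set
    ``return_dropped=True`` to also get the ``(row_index, reason)`` list.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError("read_cohort", f"file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str},
                     float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError("read_cohort",
                            f"missing mandatory columns: {missing}")
    if df.empty:
        logger.warning("cohort file %s contains a header but no rows", path)

    records: list[PatientRecord] = []
    dropped: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_record_from_row(row))
        except (ValueError, FindingsValidationError, ModelError) as exc:
            reason = str(exc)
            dropped.append((i, reason))
            logger.warning("row %d dropped: %s", i, reason)
    if dropped:
        logger.info("read_cohort: %d of %d rows dropped", len(dropped),
                    len(df))
    return (records, dropped) if return_dropped else records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records as a UTF-8 comma-delimited table (round-trips through
    :func:`read_cohort`)."""
    lines = [",".join(COHORT_COLUMNS)]
    for r in records:
        cells = [str(r.patient_id)]
        for name in CLINICAL_COLUMNS:
            cells.append(_format_cell(getattr(r, name)))
        for name in FINDINGS_COLUMNS:
            cells.append(_format_cell(getattr(r.findings, name)))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Validation run
# ---------------------------------------------------------------------------

def _findings_degenerate(records: Sequence[PatientRecord],
                         niris: Sequence[int]) -> bool:
    """True when findings are category-representative placeholders: each
    NIRIS category maps to a single findings value, so other CT scores are
    mere relabelings of the category."""
    distinct = {}
    for r, c in zip(records, niris):
        distinct.setdefault(c, set()).add(r.findings)
    return (len(records) > sum(len(v) for v in distinct.values())
            and all(len(v) == 1 for v in distinct.values()))


def _quantiles(values) -> tuple[float, float, float]:
    a = np.asarray(values, float)
    return (float(np.median(a)), float(np.percentile(a, 25)),
            float(np.percentile(a, 75)))


def run_validation(records: Sequence[PatientRecord],
                   config: Optional[ValidationConfig] = None,
                   n_excluded: int = 0) -> ValidationReport:
    """Run the full validation pipeline and assemble the report.

    Stage failures raise :class:`PipelineError` with the stage name;
    honestly uncomputable rows (see module docstring) are NA instead.
    """
    config = config or ValidationConfig()
    if not records:
        raise PipelineError("input", "no records")

    try:
        scores = score_all(records)
    except Exception as exc:
        raise PipelineError("score_all", str(exc)) from exc
    if any(r.dead_6mo is None for r in records):
        raise PipelineError("input", "records lack the dead_6mo outcome")
    y = np.array([bool(r.dead_6mo) for r in records])
    niris = [s.niris for s in scores]

    degenerate = _findings_degenerate(records, niris)
    has_clinical = not any(
        r.age_years is None or r.gcs is None or r.saps2_modified is None
        or r.chronic_comorbidity is None for r in records)

    fits: dict[str, Optional[LogisticFit]] = {}

    def _fit(stage, func, *args):
        try:
            return func(*args)
        except (ModelError, MetricError) as exc:
            raise PipelineError(stage, str(exc)) from exc

    fits["NIRIS"] = _fit("customize_ct_model[niris]", customize_ct_model,
                         records, "niris")
    if degenerate:
        logger.info("findings are category-representative placeholders; "
                    "Marshall and Helsinki rows reported as NA")
        fits["Marshall"] = fits["Helsinki"] = None
    else:
        fits["Marshall"] = _fit("customize_ct_model[marshall]",
                                customize_ct_model, records, "marshall")
        fits["Helsinki"] = _fit("customize_ct_model[helsinki]",
                                customize_ct_model, records, "helsinki")
    if has_clinical:
        fits["Base"] = _fit("build_base_model", build_base_model, records)
        for system in ("niris", "marshall", "helsinki"):
            if degenerate and system != "niris":
                fits[f"Base+{system.capitalize()}"] = None
                continue
            fits[f"Base+{system.capitalize()}"] = _fit(
                f"build_combined_model[{system}]", build_combined_model,
                records, system)
        fits["Base+NIRIS"] = fits.pop("Base+Niris")
    else:
        logger.info("clinical covariates absent; Base and combined rows "
                    "reported as NA")
        for name in ("Base", "Base+NIRIS", "Base+Marshall", "Base+Helsinki"):
            fits[name] = None

    rows: dict[str, PerformanceReport] = {}
    for name in MODEL_ROWS:
        fit = fits.get(name)
        row = PerformanceReport(model=name)
        if fit is not None:
            p = fit.fitted_probabilities
            a = auc_mann_whitney(p, y)
            row.auc, row.auc_ci_low, row.auc_ci_high = a.auc, a.ci_low, a.ci_high
            row.nagelkerke_r2 = nagelkerke_r2(fit)
            try:
                row.hl_chi2, _, row.hl_p = hosmer_lemeshow(
                    p, y, groups=config.hl_groups)
            except MetricError as exc:
                logger.info("Hosmer-Lemeshow NA for %s: %s", name, exc)
            ref = None
            if name in ("Marshall", "Helsinki"):
                ref = "NIRIS"
            elif name.startswith("Base+"):
                ref = "Base"
            if ref is not None and fits.get(ref) is not None:
                row.reference = ref
                row.delong_p = delong_compare(
                    p, fits[ref].fitted_probabilities, y).p_value
                if ref == "Base":
                    res = idi(p, fits["Base"].fitted_probabilities, y,
                              ci_method=config.idi_ci_method,
                              n_boot=config.idi_bootstrap_reps,
                              seed=config.seed)
                    row.idi, row.idi_ci_low, row.idi_ci_high = (
                        res.idi, res.ci_low, res.ci_high)
        rows[name] = row

    cat_counts = np.bincount(niris, minlength=5)
    events = np.array([int(y[np.array(niris) == c].sum()) for c in range(5)])
    niris_outcome = CrossTab(labels=(0, 1, 2, 3, 4),
                             events=tuple(int(e) for e in events),
                             nonevents=tuple(int(t - e) for t, e in
                                             zip(cat_counts, events)))
    marshall_levels = ("I", "II", "III", "IV", "V", "VI")
    nm = np.zeros((5, 6))
    for s in scores:
        nm[s.niris, marshall_levels.index(s.marshall)] += 1

    summary = {
        "n": len(records),
        "n_dead_6mo": int(y.sum()),
        "mortality_6mo": float(y.mean()),
        "niris_counts": [int(c) for c in cat_counts],
    }
    if has_clinical:
        summary["age_median_iqr"] = _quantiles([r.age_years for r in records])
        summary["gcs_median_iqr"] = _quantiles([r.gcs for r in records])
        summary["comorbidity_rate"] = float(
            np.mean([r.chronic_comorbidity for r in records]))
    summary["helsinki_median_by_niris"] = [
        float(np.median([s.helsinki for s in scores if s.niris == c]))
        if cat_counts[c] else None for c in range(5)]

    return ValidationReport(
        rows=rows, summary=summary, niris_outcome=niris_outcome,
        niris_marshall=nm,
        metadata={"seed": config.seed, "n": len(records),
                  "n_excluded": n_excluded,
                  "hl_groups": config.hl_groups,
                  "idi_ci_method": config.idi_ci_method})


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def _row_values(row: PerformanceReport) -> list:
    return [row.model, row.auc, row.auc_ci_low, row.auc_ci_high,
            row.delong_p, row.hl_p, row.nagelkerke_r2, row.idi,
            row.idi_ci_low, row.idi_ci_high]


def _machine_cell(v) -> str:
    return "NA" if v is None else (v if isinstance(v, str) else repr(float(v)))


def _display(v, digits) -> str:
    return "NA" if v is None else f"{v:.{digits}f}"


def render_report_text(report: ValidationReport) -> str:
    """Human-readable validation table (AUC to 2 dp, R²/IDI to 3 dp)."""
    out = io.StringIO()
    meta = report.metadata
    out.write(f"Validation report  (n={meta.get('n')}, "
              f"seed={meta.get('seed')}, "
              f"excluded={meta.get('n_excluded', 0)})\n")
    out.write(f"6-month deaths: {report.summary['n_dead_6mo']} "
              f"({100 * report.summary['mortality_6mo']:.1f}%)\n\n")
    header = (f"{'Model':<15}{'AUC (95% CI)':<22}{'DeLong p':<10}"
              f"{'HL p':<8}{'R2':<8}{'IDI (95% CI)':<24}\n")
    out.write(header)
    out.write("-" * (len(header) - 1) + "\n")
    for name, row in report.rows.items():
        if row.auc is None:
            auc_s = "NA"
        else:
            auc_s = (f"{_display(row.auc, 2)} "
                     f"({_display(row.auc_ci_low, 2)}-"
                     f"{_display(row.auc_ci_high, 2)})")
        if row.idi is None:
            idi_s = "NA" if row.reference != "Base" or row.model == "Base" \
                else "NA"
        else:
            idi_s = (f"{_display(row.idi, 3)} "
                     f"({_display(row.idi_ci_low, 3)}-"
                     f"{_display(row.idi_ci_high, 3)})")
        if row.model in ("NIRIS", "Base") and row.auc is not None:
            delong_s = "Ref"
        else:
            delong_s = _display(row.delong_p, 3)
        out.write(f"{name:<15}{auc_s:<22}{delong_s:<10}"
                  f"{_display(row.hl_p, 2):<8}"
                  f"{_display(row.nagelkerke_r2, 3):<8}{idi_s:<24}\n")
    return out.getvalue()


def write_report(report: ValidationReport, path, format: str = "csv") -> None:
    """Write the report: ``format`` "csv" (machine-readable, full
    precision, re-parses to equal values), "text" (rendered table with the
    printed display precision) or "both" (``path`` plus ``path`` with a
    ``.txt`` suffix)."""
    path = Path(path)
    if format not in ("csv", "text", "both"):
        raise PipelineError("write_report", f"unknown format {format!r}")
    if format in ("csv", "both"):
        lines = [",".join(REPORT_COLUMNS)]
        for row in report.rows.values():
            lines.append(",".join(_machine_cell(v) for v in _row_values(row)))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if format in ("text", "both"):
        tpath = path.with_suffix(".txt") if format == "both" else path
        tpath.write_text(render_report_text(report), encoding="utf-8")


def read_report(path) -> dict[str, dict]:
    """Parse a machine-readable report back into ``{model: {col: value}}``
    with ``None`` for NA cells."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    out: dict[str, dict] = {}
    for rec in df.to_dict(orient="records"):
        model = rec.pop("model")
        out[model] = {k: (None if pd.isna(v) else float(v))
                      for k, v in rec.items()}
    return out
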