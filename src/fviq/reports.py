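"""Patient assessments, longitudinal change reports and cohort summaries.

A :class:`PatientAssessment` collects whichever of the four metrics were
acquired at one timepoint: FVI (image-derived, reported on the percent
scale), F-VASI (fingertip-unit estimate, % BSA), and the vDLQI and VitiQoL
questionnaire totals.  A change report compares two timepoints of the same
patient metric-by-metric using the percent-decline convention (positive =
improvement), and a cohort summary averages the per-patient percentages.

Every number in an emitted report is recomputable from the stored inputs in
the same report: before/after values are kept verbatim and percent changes
are their rounded percent_change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ValidationError
from .filters import FilterSpec
from .index import FvasiEstimate, FVIResult, percent_change

logger = logging.getLogger(__name__)

METRICS = ("fvi_percent", "fvasi", "vdlqi", "vitiqol")


@dataclass(frozen=True)
class PatientAssessment:
    """Metrics for one patient at one timepoint; at least one is required."""

    patient_id: str
    timepoint: str
    fvi: FVIResult | None = None
    fvi_percent: float | None = None  # scalar alternative when only the
    # percent value is available (e.g. an assessment loaded from JSON)
    fvasi: FvasiEstimate | None = None
    vdlqi: int | None = None
    vitiqol: int | None = None
    filter_spec: FilterSpec | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.fvi, self.fvi_percent, self.fvasi, self.vdlqi,
                      self.vitiqol)
        ):
            raise ValidationError(
                f"assessment {self.patient_id}/{self.timepoint} carries no "
                "metric"
            )

    def metric_values(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.fvi is not None:
            out["fvi_percent"] = self.fvi.fvi_percent
        elif self.fvi_percent is not None:
            out["fvi_percent"] = float(self.fvi_percent)
        if self.fvasi is not None:
            out["fvasi"] = self.fvasi.fvasi
        if self.vdlqi is not None:
            out["vdlqi"] = float(self.vdlqi)
        if self.vitiqol is not None:
            out["vitiqol"] = float(self.vitiqol)
        return out


@dataclass(frozen=True)
class MetricChange:
    before: float
    after: float

    @property
    def percent_change(self) -> float:
        """Percent decline, one decimal, as printed in reports."""
        return round(percent_change(self.before, self.after), 1)


@dataclass(frozen=True)
class ChangeReport:
    """Longitudinal change for one patient between two timepoints."""

    patient_id: str
    before_timepoint: str
    after_timepoint: str
    metrics: dict[str, MetricChange]
    notes: tuple[str, ...] = ()
    n_views: int | None = None
    filter_spec: FilterSpec | None = None

    def to_dict(self) -> dict:
        doc: dict = {
            "patient_id": self.patient_id,
            "before_timepoint": self.before_timepoint,
            "after_timepoint": self.after_timepoint,
            "metrics": {
                name: {
                    "before": mc.before,
                    "after": mc.after,
                    "percent_change": mc.percent_change,
                }
                for name, mc in self.metrics.items()
            },
            "notes": list(self.notes),
        }
        if self.n_views is not None:
            doc["n_views"] = self.n_views
        if self.filter_spec is not None:
            doc["filter_spec"] = self.filter_spec.to_dict()
        return doc

    def to_rows(self) -> list[dict]:
        """Flat rows (one per metric) for CSV emission."""
        return [
            {
                "patient_id": self.patient_id,
                "metric": name,
                "before": mc.before,
                "after": mc.after,
                "percent_change": mc.percent_change,
            }
            for name, mc in self.metrics.items()
        ]


def build_change_report(
    before: PatientAssessment, after: PatientAssessment
) -> ChangeReport:
    """Compare two assessments of the same patient.

    Metrics present at only one timepoint are omitted with a logged note,
    as is a metric whose baseline is 0 (its relative change is undefined).
    """
    if before.patient_id != after.patient_id:
        raise ValidationError(
            f"patient ids differ: {before.patient_id!r} vs {after.patient_id!r}"
        )
    if before.timepoint == after.timepoint:
        raise ValidationError("before and after timepoints must differ")
    b_vals = before.metric_values()
    a_vals = after.metric_values()
    metrics: dict[str, MetricChange] = {}
    notes: list[str] = []
    for name in METRICS:
        in_b, in_a = name in b_vals, name in a_vals
        if in_b and in_a:
            if b_vals[name] <= 0:
                notes.append(
                    f"{name}: baseline is 0, percent change undefined "
                    f"(absolute change {a_vals[name] - b_vals[name]:+g})"
                )
                continue
            metrics[name] = MetricChange(b_vals[name], a_vals[name])
        elif in_b or in_a:
            tp = before.timepoint if in_b else after.timepoint
            notes.append(f"{name}: present only at {tp}, omitted")
    if not metrics and not notes:
        raise ValidationError("no metric present in both assessments")
    for note in notes:
        logger.info("change report %s: %s", before.patient_id, note)
    n_views = after.fvi.n_views if after.fvi is not None else None
    return ChangeReport(
        patient_id=before.patient_id,
        before_timepoint=before.timepoint,
        after_timepoint=after.timepoint,
        metrics=metrics,
        notes=tuple(notes),
        n_views=n_views,
        filter_spec=after.filter_spec or before.filter_spec,
    )


def cohort_summary(reports: list[ChangeReport]) -> dict[str, float]:
    """Per-metric unweighted mean of the rounded per-patient percent changes.

    Averaging the one-decimal per-patient figures (rather than the unrounded
    values) matches how clinical reports typically aggregate printed
    percentages; the result is again reported to one decimal.
    """
    if not reports:
        raise ValidationError("cohort summary needs at least one report")
    means: dict[str, float] = {}
    for name in METRICS:
        changes = [
            r.metrics[name].percent_change for r in reports if name in r.metrics
        ]
        if changes:
            means[name] = round(sum(changes) / len(changes), 1)
    return means
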