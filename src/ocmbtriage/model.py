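"""Model/results front end tying the analysis stages together.

:class:`OcmbTriage` holds a labelled cohort (OCMB status plus the two
indices); :meth:`OcmbTriage.fit` runs the full analysis — marker correlation,
ROC curves with DeLong AUC inference and paired comparison,
specificity-constrained cutoff selection with grid snapping, construction and
evaluation of the candidate model grid, and lexicographic selection of the
optimal model — returning an :class:`OcmbTriageResults` that carries every
intermediate object and renders a text summary.

The default candidate grid mimics clinical practice: the selected (snapped)
cutoff and the next grid step up for each marker, crossed into four models
named A (low/low), B (high/high), C (low/high) and D (high/low).
"""

from __future__ import annotations

import json
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InsufficientDataError, InvalidValueError, MissingLabelError
from .decision import (
    DecisionModel,
    DiagnosticReport,
    evaluate_grid,
    format_report_table,
    select_optimal,
)
from .indices import PairedSample, attach_panels, read_cohort_csv, samples_to_frame
from .roc import (
    AucEstimate,
    DelongComparison,
    RocCurve,
    SpearmanResult,
    delong_ci,
    delong_paired_test,
    rank_correlation,
    roc_curve,
    select_cutoff,
)

__all__ = ["OcmbTriage", "OcmbTriageResults"]


class OcmbTriage:
    """Triage-rule model for predicting oligoclonal IgM band positivity.

    Parameters
    ----------
    ocmb : array-like of bool
        OCMB status per patient (True = isoelectric-focusing pattern 2 or 3).
    igmi, fklci : array-like of float
        The two dimensionless indices per patient.
    patient_ids : array-like, optional
        Identifiers carried through to error messages and reports.
    """

    def __init__(self, ocmb, igmi, fklci, patient_ids=None):
        ocmb = pd.Series(ocmb)
        if ocmb.isna().any():
            ids = patient_ids if patient_ids is not None else ocmb.index
            raise MissingLabelError(np.asarray(ids)[ocmb.isna().to_numpy()])
        self.data = pd.DataFrame(
            {
                "patient_id": (
                    np.asarray(patient_ids)
                    if patient_ids is not None
                    else np.arange(len(ocmb))
                ),
                "ocmb": ocmb.astype(bool).to_numpy(),
                "igmi": np.asarray(igmi, dtype=float),
                "fklci": np.asarray(fklci, dtype=float),
            }
        )
        if len(self.data) < 3:
            raise InsufficientDataError("need at least 3 labelled patients")
        if not (self.data["ocmb"].any() and (~self.data["ocmb"]).any()):
            raise InsufficientDataError("both OCMB classes must be present")
        if not np.all(np.isfinite(self.data[["igmi", "fklci"]])) or np.any(
            self.data[["igmi", "fklci"]] <= 0
        ):
            raise InvalidValueError("indices must be strictly positive and finite")

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OcmbTriage":
        """Build from a cohort frame.

        Accepts either precomputed ``igmi``/``fklci`` columns or the six raw
        concentration columns (indices are then derived).  Rows without an
        OCMB label are dropped.
        """
        if not {"igmi", "fklci"}.issubset(df.columns):
            df = attach_panels(df)
        label_col = "ocmb" if "ocmb" in df.columns else "ocmb_status"
        if label_col not in df.columns:
            raise InvalidValueError("frame lacks an 'ocmb'/'ocmb_status' column")
        labelled = df[df[label_col].notna()]
        return cls(
            ocmb=labelled[label_col],
            igmi=labelled["igmi"],
            fklci=labelled["fklci"],
            patient_ids=(
                labelled["patient_id"] if "patient_id" in labelled.columns else labelled.index
            ),
        )

    @classmethod
    def from_samples(cls, samples: Sequence[PairedSample]) -> "OcmbTriage":
        return cls.from_dataframe(samples_to_frame(samples))

    @classmethod
    def from_csv(cls, path) -> "OcmbTriage":
        return cls.from_samples(read_cohort_csv(path))

    # ------------------------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.data)

    def fit(
        self,
        min_specificity: float = 0.85,
        snap_igmi: float = 0.05,
        snap_fklci: float = 25.0,
        level: float = 0.95,
        ci_method: str = "clopper-pearson",
        models: Optional[Sequence[DecisionModel]] = None,
    ) -> "OcmbTriageResults":
        """Run the full analysis and return the results object.

        ``min_specificity`` is a strict floor (specificity must exceed it);
        ``snap_igmi``/``snap_fklci`` round the selected cutoffs up to
        clinically round values.  An explicit ``models`` list bypasses the
        default A–D grid.
        """
        d = self.data
        pos = d[d["ocmb"]]
        neg = d[~d["ocmb"]]

        correlation = rank_correlation(d["igmi"], d["fklci"])
        curves = {
            "igmi": roc_curve(d["igmi"], d["ocmb"]),
            "fklci": roc_curve(d["fklci"], d["ocmb"]),
        }
        aucs = {
            m: delong_ci(pos[m], neg[m], level=level) for m in ("igmi", "fklci")
        }
        comparison = delong_paired_test(d["igmi"], d["fklci"], d["ocmb"])

        cut_igmi = select_cutoff(curves["igmi"], min_specificity, snap_grid=snap_igmi)
        cut_fklci = select_cutoff(curves["fklci"], min_specificity, snap_grid=snap_fklci)

        singles = [
            ("igmi", cut_igmi),
            ("igmi", cut_igmi + snap_igmi),
            ("fklci", cut_fklci),
            ("fklci", cut_fklci + snap_fklci),
        ]
        if models is None:
            lo1, hi1 = cut_igmi, cut_igmi + snap_igmi
            lo2, hi2 = cut_fklci, cut_fklci + snap_fklci
            models = [
                DecisionModel("Model A", lo1, lo2),
                DecisionModel("Model B", hi1, hi2),
                DecisionModel("Model C", lo1, hi2),
                DecisionModel("Model D", hi1, lo2),
            ]
        reports = evaluate_grid(d, models, singletons=singles, level=level, ci_method=ci_method)
        optimal = select_optimal(reports)

        return OcmbTriageResults(
            model=self,
            min_specificity=min_specificity,
            level=level,
            ci_method=ci_method,
            correlation=correlation,
            curves=curves,
            aucs=aucs,
            auc_comparison=comparison,
            cutoffs={"igmi": cut_igmi, "fklci": cut_fklci},
            reports=reports,
            optimal_model=optimal,
        )


class OcmbTriageResults:
    """Container for a fitted triage analysis; see :meth:`summary`."""

    def __init__(
        self,
        model: OcmbTriage,
        min_specificity: float,
        level: float,
        ci_method: str,
        correlation: SpearmanResult,
        curves: dict[str, RocCurve],
        aucs: dict[str, AucEstimate],
        auc_comparison: DelongComparison,
        cutoffs: dict[str, float],
        reports: list[DiagnosticReport],
        optimal_model: DecisionModel,
    ):
        self.model = model
        self.min_specificity = min_specificity
        self.level = level
        self.ci_method = ci_method
        self.correlation = correlation
        self.curves = curves
        self.aucs = aucs
        self.auc_comparison = auc_comparison
        self.cutoffs = cutoffs
        self.reports = reports
        self.optimal_model = optimal_model

    # ------------------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """Machine-readable metric table (raw fractions, one rule per row)."""
        rows = []
        for r in self.reports:
            rows.append(
                {
                    "name": r.name,
                    "igmi_cutoff": r.model.igmi_cutoff if r.model else math.nan,
                    "fklci_cutoff": r.model.fklci_cutoff if r.model else math.nan,
                    "tp": r.counts.tp,
                    "fp": r.counts.fp,
                    "fn": r.counts.fn,
                    "tn": r.counts.tn,
                    "sensitivity": r.sensitivity.value,
                    "sensitivity_lo": r.sensitivity.ci_low,
                    "sensitivity_hi": r.sensitivity.ci_high,
                    "specificity": r.specificity.value,
                    "specificity_lo": r.specificity.ci_low,
                    "specificity_hi": r.specificity.ci_high,
                    "ppv": r.ppv.value,
                    "ppv_lo": r.ppv.ci_low,
                    "ppv_hi": r.ppv.ci_high,
                    "npv": r.npv.value,
                    "npv_lo": r.npv.ci_low,
                    "npv_hi": r.npv.ci_high,
                    "prom": r.prom,
                }
            )
        return pd.DataFrame(rows)

    def plot_roc(self, ax=None):
        """ROC curves of both markers with their AUCs in the legend."""
        for marker, label in (("igmi", "IgMi"), ("fklci", "FKLCi")):
            est = self.aucs[marker]
            ax = self.curves[marker].plot(
                ax=ax, label=f"{label}: AUC {est.auc:.2f} ({est.ci_low:.2f}–{est.ci_high:.2f})"
            )
        return ax

    def summary(self) -> str:
        """Plain-text report in the style of a fitted-model summary."""
        d = self.model.data
        n = len(d)
        n_pos = int(d["ocmb"].sum())
        pct = 100 * self.level
        lines = [
            "OCMB triage rule — cohort analysis",
            "=" * 70,
            f"Patients: {n}   OCMB+: {n_pos} ({100 * n_pos / n:.1f} %)",
            f"Spearman rho(IgMi, FKLCi): {self.correlation.correlation:.3f}"
            f"  (p = {self.correlation.pvalue:.3g})",
            "",
            f"AUC ({pct:.0f} % CI, DeLong):",
        ]
        for marker, label in (("igmi", "IgMi"), ("fklci", "FKLCi")):
            a = self.aucs[marker]
            lines.append(
                f"  {label:<6} {a.auc:.2f} ({a.ci_low:.2f}–{a.ci_high:.2f})  se {a.se:.3f}"
            )
        lines += [
            f"Paired DeLong test: z = {self.auc_comparison.statistic:.3f}, "
            f"p = {self.auc_comparison.pvalue:.3f}",
            "",
            f"Cutoffs (specificity > {100 * self.min_specificity:.0f} %, snapped): "
            f"IgMi >= {self.cutoffs['igmi']:g}, FKLCi >= {self.cutoffs['fklci']:g}",
            "",
            format_report_table(self.reports).to_string(index=False),
            "",
            f"Optimal model: {self.optimal_model.name} "
            f"(IgMi >= {self.optimal_model.igmi_cutoff:g} OR "
            f"FKLCi >= {self.optimal_model.fklci_cutoff:g})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable digest of the fit (no curves)."""
        return {
            "n": int(self.model.nobs),
            "n_ocmb_pos": int(self.model.data["ocmb"].sum()),
            "min_specificity": self.min_specificity,
            "level": self.level,
            "ci_method": self.ci_method,
            "correlation": {
                "spearman_rho": self.correlation.correlation,
                "pvalue": self.correlation.pvalue,
            },
            "auc": {
                m: {
                    "auc": a.auc,
                    "se": a.se,
                    "ci_low": a.ci_low,
                    "ci_high": a.ci_high,
                }
                for m, a in self.aucs.items()
            },
            "auc_comparison": {
                "statistic": self.auc_comparison.statistic,
                "pvalue": self.auc_comparison.pvalue,
            },
            "cutoffs": self.cutoffs,
            "optimal_model": {
                "name": self.optimal_model.name,
                "igmi_cutoff": self.optimal_model.igmi_cutoff,
                "fklci_cutoff": self.optimal_model.fklci_cutoff,
            },
            "table": json.loads(self.table.to_json(orient="records")),
        }
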