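"""The two-marker OR triage rule and its diagnostic-accuracy report.

A patient is flagged as predicted OCMB-positive (and would skip oligoclonal
IgM band testing) when IgMi >= cutoff_1 OR FKLCi >= cutoff_2, both
comparisons inclusive.  For a labelled cohort the rule yields a confusion
table, the usual accuracy metrics with exact binomial confidence intervals,
and PROM — the fraction of determinations the rule would spare, i.e. the
flagged fraction of the cohort.

Useful identities (asserted in the test suite):
    PROM = sens * prev + (1 - spec) * (1 - prev)
    PPV  = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
and OR-dominance: a two-marker model is at least as sensitive (and at most
as specific) as either of its single-marker components, because its flagged
set contains theirs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._exceptions import InvalidValueError, MissingLabelError
from .indices import IndexPanel

__all__ = [
    "DecisionModel",
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticReport",
    "apply_rule",
    "flag_cohort",
    "confusion",
    "proportion_ci",
    "diagnostics",
    "evaluate_grid",
    "select_optimal",
    "round_half_away",
    "format_report_table",
]

CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}


@dataclass(frozen=True)
class DecisionModel:
    """A named pair of inclusive cutoffs defining the OR rule.

    A single-marker rule is expressed with the unused cutoff at +inf.
    """

    name: str
    igmi_cutoff: float
    fklci_cutoff: float

    def __post_init__(self):
        if not (self.igmi_cutoff > 0 and self.fklci_cutoff > 0):
            raise InvalidValueError("cutoffs must be > 0")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise InvalidValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n_total


class MetricEstimate(NamedTuple):
    value: float
    ci_low: float
    ci_high: float
    defined: bool = True


_UNDEFINED = MetricEstimate(math.nan, math.nan, math.nan, defined=False)


@dataclass(frozen=True)
class DiagnosticReport:
    """Accuracy metrics of one rule on one labelled cohort."""

    name: str
    counts: ConfusionCounts
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    prom: float
    prom_ci: Optional[tuple[float, float]]
    level: float
    model: Optional[DecisionModel] = None

    @property
    def n_total(self) -> int:
        return self.counts.n_total


def apply_rule(panel: IndexPanel, model: DecisionModel) -> bool:
    """True when either index reaches its cutoff (flag: skip OCMB testing)."""
    return panel.igmi >= model.igmi_cutoff or panel.fklci >= model.fklci_cutoff


def flag_cohort(cohort: pd.DataFrame, model: DecisionModel) -> pd.Series:
    """Vectorised OR rule over a cohort frame with ``igmi``/``fklci`` columns."""
    for col in ("igmi", "fklci"):
        if col not in cohort.columns:
            raise InvalidValueError(f"cohort frame lacks column {col!r}")
    return (cohort["igmi"] >= model.igmi_cutoff) | (cohort["fklci"] >= model.fklci_cutoff)


def confusion(cohort: pd.DataFrame, model: DecisionModel) -> ConfusionCounts:
    """Confusion counts of the rule against the ``ocmb`` label column.

    Every row must carry a label; unlabelled rows raise with their
    patient ids so the caller can pre-filter deliberately.
    """
    label_col = "ocmb" if "ocmb" in cohort.columns else "ocmb_status"
    if label_col not in cohort.columns:
        raise InvalidValueError("cohort frame lacks an 'ocmb'/'ocmb_status' column")
    labels = cohort[label_col]
    missing = labels.isna()
    if missing.any():
        ids = (
            cohort["patient_id"][missing]
            if "patient_id" in cohort.columns
            else cohort.index[missing]
        )
        raise MissingLabelError(ids)
    truth = labels.astype(bool).to_numpy()
    flagged = flag_cohort(cohort, model).to_numpy()
    return ConfusionCounts(
        tp=int(np.sum(flagged & truth)),
        fp=int(np.sum(flagged & ~truth)),
        fn=int(np.sum(~flagged & truth)),
        tn=int(np.sum(~flagged & ~truth)),
    )


def proportion_ci(
    successes: int, n: int, level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Binomial confidence interval; exact Clopper–Pearson by default.

    The exact interval comes from beta quantiles: at successes = 0 it is
    (0, upper); at successes = n it is ((alpha/2)^(1/n), 1).
    """
    if method not in CI_METHODS:
        raise InvalidValueError(f"unknown CI method {method!r}; choose from {sorted(CI_METHODS)}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise InvalidValueError(f"n must be a positive integer, got {n!r}")
    if not (isinstance(successes, (int, np.integer)) and 0 <= successes <= n):
        raise InvalidValueError(f"successes must be an integer in [0, {n}], got {successes!r}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=CI_METHODS[method])
    return float(lo), float(hi)


def _metric(successes: int, n: int, level: float, method: str) -> MetricEstimate:
    if n == 0:
        return _UNDEFINED
    lo, hi = proportion_ci(successes, n, level=level, method=method)
    return MetricEstimate(successes / n, lo, hi)


def _bootstrap_prom_ci(
    counts: ConfusionCounts, level: float, n_boot: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    draws = rng.binomial(counts.n_total, counts.n_flagged / counts.n_total, n_boot)
    q = np.quantile(draws / counts.n_total, [(1 - level) / 2, (1 + level) / 2])
    return float(q[0]), float(q[1])


def diagnostics(
    counts: ConfusionCounts,
    level: float = 0.95,
    ci_method: str = "clopper-pearson",
    name: str = "",
    model: Optional[DecisionModel] = None,
    prom_bootstrap: bool = False,
    n_boot: int = 2000,
    boot_seed: int = 0,
) -> DiagnosticReport:
    """Sensitivity, specificity, PPV, NPV (each with a CI) and PROM.

    PROM = (tp + fp) / n carries no CI by default (an optional seeded
    bootstrap interval can be requested).  A metric with a zero denominator
    is reported as undefined (NaN with ``defined=False``), not raised.
    """
    if not 0 < level < 1:
        raise InvalidValueError(f"level must be in (0, 1), got {level}")
    if counts.n_total == 0:
        raise InvalidValueError("empty confusion table")
    prom = counts.n_flagged / counts.n_total
    prom_ci = (
        _bootstrap_prom_ci(counts, level, n_boot, boot_seed) if prom_bootstrap else None
    )
    return DiagnosticReport(
        name=name,
        counts=counts,
        sensitivity=_metric(counts.tp, counts.n_pos, level, ci_method),
        specificity=_metric(counts.tn, counts.n_neg, level, ci_method),
        ppv=_metric(counts.tp, counts.n_flagged, level, ci_method),
        npv=_metric(counts.tn, counts.tn + counts.fn, level, ci_method),
        prom=prom,
        prom_ci=prom_ci,
        level=level,
        model=model,
    )


def evaluate_grid(
    cohort: pd.DataFrame,
    models: Sequence[DecisionModel],
    singletons: Sequence[tuple[str, float]] = (),
    level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> list[DiagnosticReport]:
    """One report per single-marker cutoff and per two-marker model.

    ``singletons`` lists ("igmi" | "fklci", cutoff) pairs evaluated as
    one-marker rules (the other cutoff at +inf); the report rows come in the
    order given, singletons first, mirroring the usual presentation.
    """
    if len(models) == 0:
        raise InvalidValueError("models list is empty")
    reports: list[DiagnosticReport] = []
    for marker, cutoff in singletons:
        if marker not in ("igmi", "fklci"):
            raise InvalidValueError(f"unknown marker {marker!r}")
        m = DecisionModel(
            name=f"{'IgMi' if marker == 'igmi' else 'FKLCi'} >= {cutoff:g}",
            igmi_cutoff=cutoff if marker == "igmi" else math.inf,
            fklci_cutoff=cutoff if marker == "fklci" else math.inf,
        )
        reports.append(
            diagnostics(confusion(cohort, m), level, ci_method, name=m.name, model=m)
        )
    for m in models:
        reports.append(
            diagnostics(confusion(cohort, m), level, ci_method, name=m.name, model=m)
        )
    return reports


def _is_two_marker(report: DiagnosticReport) -> bool:
    m = report.model
    return m is not None and math.isfinite(m.igmi_cutoff) and math.isfinite(m.fklci_cutoff)


def select_optimal(
    table: Union[Sequence[DiagnosticReport], pd.DataFrame]
) -> Union[DecisionModel, str]:
    """Pick the best two-marker model: max specificity, then PPV, then PROM.

    Ties beyond the three criteria break deterministically by model name.
    The lexicographic criterion formalises "prefer the most specific, most
    predictive rule, sparing the most tests only after that".  Accepts either
    the report list from :func:`evaluate_grid` (returns the
    :class:`DecisionModel`) or a plain frame with columns
    name/specificity/ppv/prom (returns the winning name) so that published
    metric tables can be re-ranked directly.
    """
    if isinstance(table, pd.DataFrame):
        if table.empty:
            raise InvalidValueError("empty model table")
        rows = sorted(
            table.to_dict("records"),
            key=lambda r: (-r["specificity"], -r["ppv"], -r["prom"], str(r["name"])),
        )
        return str(rows[0]["name"])
    reports = [r for r in table if _is_two_marker(r)]
    if not reports:
        raise InvalidValueError("no two-marker models in the table")
    ranked = sorted(
        reports,
        key=lambda r: (-r.specificity.value, -r.ppv.value, -r.prom, r.name),
    )
    return ranked[0].model


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (55.67 -> 56)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _fmt_metric(m: MetricEstimate) -> str:
    if not m.defined:
        return "–"
    return "%d (%d–%d)" % (
        round_half_away(100 * m.value),
        round_half_away(100 * m.ci_low),
        round_half_away(100 * m.ci_high),
    )


def format_report_table(reports: Sequence[DiagnosticReport]) -> pd.DataFrame:
    """Readable table of integer percentages with CI ranges, one rule per row.

    Raw fractions remain available on the :class:`DiagnosticReport` objects;
    this is presentation only (percentages rounded half away from zero).
    """
    rows = []
    for r in reports:
        rows.append(
            {
                "Rule": r.name,
                "Specificity, %": _fmt_metric(r.specificity),
                "Sensitivity, %": _fmt_metric(r.sensitivity),
                "PPV, %": _fmt_metric(r.ppv),
                "NPV, %": _fmt_metric(r.npv),
                "PROM, %": str(round_half_away(100 * r.prom)),
            }
        )
    return pd.DataFrame(rows)
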