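"""CSF/serum quotients and albumin-normalised immunoglobulin indices.

The decision rule operates on two dimensionless indices derived from paired
cerebrospinal-fluid (CSF) and serum concentrations:

* ``QAlb``  — albumin quotient, CSF albumin / serum albumin, a proxy for
  blood–CSF barrier permeability;
* ``IgMi``  — IgM index, (CSF IgM / serum IgM) / QAlb;
* ``FKLCi`` — free kappa light chain index, (CSF FKLC / serum FKLC) / QAlb.

All concentrations are handled in mg/L internally; the CSV reader converts
g/L and mg/dL columns when a units line is present.  Because the indices are
ratios of ratios they are invariant to the unit chosen per analyte, but a
single canonical unit prevents silent mixed-unit bugs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._exceptions import InvalidValueError

logger = logging.getLogger(__name__)

#: QAlb above this is physiologically implausible for an MS work-up cohort and
#: triggers a warning (never an error: no exclusion rule is applied).
QALB_PLAUSIBLE_MAX = 0.05

CONCENTRATION_FIELDS = (
    "csf_igm",
    "serum_igm",
    "csf_fklc",
    "serum_fklc",
    "csf_albumin",
    "serum_albumin",
)

#: Canonical cohort CSV column order.
COHORT_COLUMNS = ("patient_id", *CONCENTRATION_FIELDS, "ocmb_status", "activity")

#: Accepted concentration units and their factor to mg/L.
UNIT_FACTORS = {"mg/l": 1.0, "g/l": 1000.0, "mg/dl": 10.0}


def _require_positive(value: float, name: str) -> float:
    if value is None or not math.isfinite(value) or value <= 0:
        raise InvalidValueError(f"{name} must be a strictly positive finite number, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class PairedSample:
    """One patient's paired CSF/serum concentrations (mg/L) and optional labels.

    ``ocmb_status`` is True for isoelectric-focusing patterns 2 or 3
    (CSF-restricted or CSF-excess IgM bands, i.e. intrathecal IgM synthesis).
    """

    patient_id: str
    csf_igm: float
    serum_igm: float
    csf_fklc: float
    serum_fklc: float
    csf_albumin: float
    serum_albumin: float
    ocmb_status: Optional[bool] = None
    activity: Optional[bool] = None

    def __post_init__(self):
        for name in CONCENTRATION_FIELDS:
            _require_positive(getattr(self, name), name)


@dataclass(frozen=True)
class IndexPanel:
    """The three derived dimensionless indices for one patient."""

    qalb: float
    igmi: float
    fklci: float

    def __post_init__(self):
        for name in ("qalb", "igmi", "fklci"):
            _require_positive(getattr(self, name), name)


def albumin_quotient(csf_albumin: float, serum_albumin: float) -> float:
    """QAlb = CSF albumin / serum albumin (same unit both sides)."""
    return _require_positive(csf_albumin, "csf_albumin") / _require_positive(
        serum_albumin, "serum_albumin"
    )


def igm_index(sample: PairedSample) -> float:
    """IgMi = (CSF IgM / serum IgM) / QAlb."""
    q_igm = _require_positive(sample.csf_igm, "csf_igm") / _require_positive(
        sample.serum_igm, "serum_igm"
    )
    return q_igm / albumin_quotient(sample.csf_albumin, sample.serum_albumin)


def fklc_index(sample: PairedSample) -> float:
    """FKLCi = (CSF FKLC / serum FKLC) / QAlb."""
    q_fklc = _require_positive(sample.csf_fklc, "csf_fklc") / _require_positive(
        sample.serum_fklc, "serum_fklc"
    )
    return q_fklc / albumin_quotient(sample.csf_albumin, sample.serum_albumin)


def compute_panel(sample: PairedSample) -> IndexPanel:
    """Bundle QAlb, IgMi and FKLCi for one sample.

    A QAlb above :data:`QALB_PLAUSIBLE_MAX` produces a warning, never an
    error: the analysis applies no plausibility exclusion.
    """
    qalb = albumin_quotient(sample.csf_albumin, sample.serum_albumin)
    if qalb > QALB_PLAUSIBLE_MAX:
        warnings.warn(
            f"QAlb={qalb:.4g} for patient {sample.patient_id} exceeds the plausible "
            f"range (> {QALB_PLAUSIBLE_MAX}); value kept",
            stacklevel=2,
        )
    return IndexPanel(qalb=qalb, igmi=igm_index(sample), fklci=fklc_index(sample))


# ---------------------------------------------------------------------------
# Cohort container helpers
# ---------------------------------------------------------------------------

def samples_to_frame(samples: Iterable[PairedSample]) -> pd.DataFrame:
    """Tabulate samples as a DataFrame in canonical column order."""
    rows = []
    for s in samples:
        rows.append({f.name: getattr(s, f.name) for f in fields(PairedSample)})
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return df


def attach_panels(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``df`` with ``qalb``, ``igmi`` and ``fklci`` columns.

    Vectorised equivalent of :func:`compute_panel` applied row-wise; rows must
    already satisfy the positivity invariants.
    """
    missing = [c for c in CONCENTRATION_FIELDS if c not in df.columns]
    if missing:
        raise InvalidValueError(f"cohort frame lacks concentration columns: {missing}")
    bad = (df[list(CONCENTRATION_FIELDS)] <= 0).any(axis=1) | df[
        list(CONCENTRATION_FIELDS)
    ].isna().any(axis=1)
    if bad.any():
        raise InvalidValueError(
            f"non-positive or missing concentrations in rows {list(df.index[bad])}"
        )
    out = df.copy()
    out["qalb"] = df["csf_albumin"] / df["serum_albumin"]
    out["igmi"] = (df["csf_igm"] / df["serum_igm"]) / out["qalb"]
    out["fklci"] = (df["csf_fklc"] / df["serum_fklc"]) / out["qalb"]
    return out


def _parse_units_line(line: str) -> Mapping[str, float]:
    # "# units: serum_albumin=g/L, serum_igm=mg/dL"
    body = line.split(":", 1)[1]
    factors = {}
    for token in body.replace(",", " ").split():
        if "=" not in token:
            raise InvalidValueError(f"malformed units token {token!r}")
        col, unit = token.split("=", 1)
        key = unit.strip().lower()
        if key not in UNIT_FACTORS:
            raise InvalidValueError(
                f"unknown unit {unit!r} for column {col!r}; accepted: {sorted(UNIT_FACTORS)}"
            )
        factors[col.strip()] = UNIT_FACTORS[key]
    return factors


def _parse_optional_bool(value) -> Optional[bool]:
    if pd.isna(value):
        return None
    return bool(int(value))


def read_cohort_csv(path) -> list[PairedSample]:
    """Read a cohort CSV into validated :class:`PairedSample` records.

    The file is one row per patient with columns
    ``patient_id, csf_igm, serum_igm, csf_fklc, serum_fklc, csf_albumin,
    serum_albumin, ocmb_status, activity`` (``ocmb_status`` in {0, 1, NA}).
    An optional first line ``# units: <column>=<unit> ...`` declares per-column
    units (g/L, mg/dL, mg/L); values are converted to mg/L on read.

    Rows with a missing or non-positive concentration are excluded and logged,
    not imputed: the analysis uses complete pairs only.
    """
    factors: Mapping[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.lstrip().startswith("#") and "units" in first.split(":", 1)[0].lower():
            factors = _parse_units_line(first)
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns and c != "activity"]
    if missing_cols:
        raise InvalidValueError(f"cohort CSV lacks required columns: {missing_cols}")
    if "activity" not in df.columns:
        df["activity"] = pd.NA
    for col, factor in factors.items():
        if col not in CONCENTRATION_FIELDS:
            raise InvalidValueError(f"units declared for unknown column {col!r}")
        df[col] = df[col] * factor

    samples: list[PairedSample] = []
    excluded: list[str] = []
    for _, row in df.iterrows():
        try:
            samples.append(
                PairedSample(
                    patient_id=str(row["patient_id"]),
                    **{c: float(row[c]) for c in CONCENTRATION_FIELDS},
                    ocmb_status=_parse_optional_bool(row["ocmb_status"]),
                    activity=_parse_optional_bool(row["activity"]),
                )
            )
        except (InvalidValueError, ValueError, TypeError):
            excluded.append(str(row["patient_id"]))
    if excluded:
        logger.warning(
            "excluded %d sample(s) with missing/invalid concentrations: %s",
            len(excluded),
            ", ".join(excluded),
        )
    return samples


def write_cohort_csv(samples: Sequence[PairedSample], path) -> None:
    """Write samples in the canonical cohort CSV dialect (mg/L, UTF-8)."""
    df = samples_to_frame(samples)
    for col in ("ocmb_status", "activity"):
        df[col] = df[col].map(lambda v: "" if v is None else int(v))
    df.to_csv(path, index=False)
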