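"""Synthetic cohort generator with a calibrated binormal latent structure.

No patient-level data accompany the study this package operationalises, so
every downstream stage is exercised on simulated cohorts that reproduce the
statistical structure the analysis assumes:

* OCMB status is Bernoulli with prevalence 54/97 (or an exact fixed split);
* log-IgMi and log-FKLCi are bivariate normal with a shared within-class
  covariance and a pure location shift for OCMB+ patients.  Under this
  log-location-shift model the population AUC of each marker has the closed
  binormal form Phi(delta / sqrt(sigma_pos^2 + sigma_neg^2)), which makes the
  generator exactly calibratable to target AUCs (defaults 0.71 and 0.64);
* QAlb and the three serum concentrations are independent log-normals at
  plausible clinical magnitudes; CSF concentrations are back-computed so that
  recomputing the index panel recovers the drawn indices exactly.

The indices are therefore right-skewed (log-normal marginals) and positively
correlated, matching the qualitative description of the source cohort; all
dispersion and location defaults other than prevalence and the AUC targets
are conventions, documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from ._exceptions import InvalidValueError
from .indices import PairedSample

__all__ = [
    "CohortParams",
    "binormal_auc",
    "calibrate_delta",
    "backfill_concentrations",
    "generate_cohort",
]

#: AUC targets used to calibrate the default class separation (IgMi, FKLCi).
DEFAULT_TARGET_AUCS = (0.71, 0.64)


def binormal_auc(delta: float, sigma_pos: float, sigma_neg: float) -> float:
    """Exact AUC of a threshold rule on normal class scores.

    If positive-class scores are N(mu + delta, sigma_pos^2) and negative-class
    scores are N(mu, sigma_neg^2), the probability that a random positive
    exceeds a random negative is Phi(delta / sqrt(sigma_pos^2 + sigma_neg^2)).
    """
    if not (sigma_pos > 0 and sigma_neg > 0):
        raise InvalidValueError("sigma_pos and sigma_neg must be > 0")
    return float(norm.cdf(delta / math.hypot(sigma_pos, sigma_neg)))


def calibrate_delta(target_auc: float, sigma_pos: float, sigma_neg: float) -> float:
    """Inverse of :func:`binormal_auc`: the location shift yielding ``target_auc``."""
    if not 0 < target_auc < 1:
        raise InvalidValueError(f"target_auc must be in (0, 1), got {target_auc}")
    if not (sigma_pos > 0 and sigma_neg > 0):
        raise InvalidValueError("sigma_pos and sigma_neg must be > 0")
    return float(norm.ppf(target_auc) * math.hypot(sigma_pos, sigma_neg))


def _default_delta() -> Tuple[float, float]:
    return tuple(calibrate_delta(a, 1.0, 1.0) for a in DEFAULT_TARGET_AUCS)


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: n=97 patients, OCMB prevalence
    54/97, marker AUCs 0.71 (IgMi) and 0.64 (FKLCi), OCMB-negative medians
    IgMi 0.08 and FKLCi 60, QAlb median 0.005, serum medians 1000 mg/L IgM,
    15 mg/L FKLC, 42000 mg/L albumin.
    """

    n: int = 97
    prevalence: float = 54 / 97
    log_mu_neg: Tuple[float, float] = (math.log(0.08), math.log(60.0))
    log_sigma: Tuple[float, float] = (1.0, 1.0)
    delta: Tuple[float, float] = field(default_factory=_default_delta)
    rho: float = 0.5
    qalb_log_mu: float = math.log(0.005)
    qalb_log_sigma: float = 0.35
    serum_log_mu: Tuple[float, float, float] = (
        math.log(1000.0),
        math.log(15.0),
        math.log(42000.0),
    )
    serum_log_sigma: Tuple[float, float, float] = (0.30, 0.30, 0.15)
    activity_rate: Optional[float] = 81 / 97
    fixed_counts: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise InvalidValueError(f"n must be >= 2, got {self.n}")
        if not 0 < self.prevalence < 1:
            raise InvalidValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not -1 < self.rho < 1:
            raise InvalidValueError(f"rho must be in (-1, 1), got {self.rho}")
        sigmas = (*self.log_sigma, self.qalb_log_sigma, *self.serum_log_sigma)
        if any(s <= 0 for s in sigmas):
            raise InvalidValueError("all log-scale sigmas must be > 0")
        if self.activity_rate is not None and not 0 <= self.activity_rate <= 1:
            raise InvalidValueError("activity_rate must be in [0, 1] or None")


def backfill_concentrations(
    igmi: float,
    fklci: float,
    qalb: float,
    serum_igm: float,
    serum_fklc: float,
    serum_albumin: float,
    patient_id: str = "synthetic",
    ocmb_status: Optional[bool] = None,
    activity: Optional[bool] = None,
) -> PairedSample:
    """Invert the index panel: choose CSF concentrations realising the indices.

    ``csf_albumin = qalb * serum_albumin``; ``csf_igm = igmi * qalb * serum_igm``;
    ``csf_fklc = fklci * qalb * serum_fklc``.  Recomputing the panel from the
    returned sample reproduces (qalb, igmi, fklci) to round-off.
    """
    for name, value in (
        ("igmi", igmi),
        ("fklci", fklci),
        ("qalb", qalb),
        ("serum_igm", serum_igm),
        ("serum_fklc", serum_fklc),
        ("serum_albumin", serum_albumin),
    ):
        if not (np.isfinite(value) and value > 0):
            raise InvalidValueError(f"{name} must be strictly positive and finite, got {value!r}")
    return PairedSample(
        patient_id=patient_id,
        csf_igm=igmi * qalb * serum_igm,
        serum_igm=serum_igm,
        csf_fklc=fklci * qalb * serum_fklc,
        serum_fklc=serum_fklc,
        csf_albumin=qalb * serum_albumin,
        serum_albumin=serum_albumin,
        ocmb_status=ocmb_status,
        activity=activity,
    )


def generate_cohort(params: CohortParams) -> list[PairedSample]:
    """Draw a synthetic cohort; deterministic given ``params`` (incl. seed).

    With ``fixed_counts`` the positive count is exactly
    ``round(n * prevalence)`` (54 of 97 at the defaults) in a seeded random
    order; otherwise it is Binomial(n, prevalence).
    """
    if not isinstance(params, CohortParams):
        raise InvalidValueError("params must be a CohortParams instance")
    rng = np.random.default_rng(params.seed)
    n = params.n

    if params.fixed_counts:
        n_pos = int(round(n * params.prevalence))
        status = np.zeros(n, dtype=bool)
        status[:n_pos] = True
        rng.shuffle(status)
    else:
        status = rng.random(n) < params.prevalence

    s1, s2 = params.log_sigma
    cov = np.array(
        [[s1 * s1, params.rho * s1 * s2], [params.rho * s1 * s2, s2 * s2]]
    )
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2)) @ chol.T
    log_idx = np.asarray(params.log_mu_neg) + np.outer(status, params.delta) + z
    igmi = np.exp(log_idx[:, 0])
    fklci = np.exp(log_idx[:, 1])

    qalb = np.exp(rng.normal(params.qalb_log_mu, params.qalb_log_sigma, n))
    serum = np.exp(
        rng.normal(
            np.asarray(params.serum_log_mu),
            np.asarray(params.serum_log_sigma),
            size=(n, 3),
        )
    )
    if params.activity_rate is None:
        activity = [None] * n
    else:
        activity = (rng.random(n) < params.activity_rate).tolist()

    width = len(str(n))
    return [
        backfill_concentrations(
            igmi=igmi[i],
            fklci=fklci[i],
            qalb=qalb[i],
            serum_igm=serum[i, 0],
            serum_fklc=serum[i, 1],
            serum_albumin=serum[i, 2],
            patient_id=f"S{i + 1:0{width}d}",
            ocmb_status=bool(status[i]),
            activity=activity[i],
        )
        for i in range(n)
    ]
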