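# Methods

## The triage problem

In people with multiple sclerosis, intrathecal IgM synthesis is evidenced by
oligoclonal IgM bands (OCMB) on isoelectric focusing + immunoblotting;
patterns with CSF-restricted or CSF-excess bands count as positive. The
assay is slow and specialist-bound, so the package operationalises a triage
rule on two quantitative surrogates, the IgM index (IgMi) and the free kappa
light chain index (FKLCi), both albumin-quotient-normalised CSF/serum
ratios. Patients flagged by the rule are predicted OCMB-positive and skip
the immunoblot; everyone else is tested conventionally. Because unflagged
patients are still tested, low sensitivity is tolerable; the rule is tuned
for high specificity and positive predictive value.

## Indices

For one patient with paired CSF/serum concentrations (all mg/L internally;
the CSV reader converts g/L and mg/dL when a units line is present):

    QAlb  = CSF albumin / serum albumin
    IgMi  = (CSF IgM  / serum IgM)  / QAlb
    FKLCi = (CSF FKLC / serum FKLC) / QAlb

The indices are dimensionless and invariant to per-analyte unit changes
(asserted as a property test). Samples missing any of the six
concentrations are excluded with a log message, never imputed. A QAlb above
0.05 is implausible for this setting and warns, but no exclusion rule is
applied.

## Decision rule and metrics

A rule is an inclusive disjunction: flag iff IgMi ≥ c₁ OR FKLCi ≥ c₂
(single-marker rules set the other cutoff to +∞). On a labelled cohort this
yields a confusion table and

* sensitivity, specificity, PPV, NPV — each with a binomial CI, exact
  Clopper–Pearson by default (the conservative convention for small
  diagnostic studies; Wilson available via `ci_method="wilson"`), at level
  0.95 by default;
* PROM, the percentage reduction of OCMB measurements, = (TP+FP)/n — the
  flagged fraction. PROM is reported without a CI by default; a seeded
  percentile bootstrap is available (`prom_bootstrap=True`, 2000 draws).

Two identities follow from the counts and are enforced in tests:
PROM = sens·prev + (1−spec)(1−prev) and the Bayes form of PPV. Because the
OR rule's flagged set contains each component's flagged set, a two-marker
model always has sensitivity and PROM at least, and specificity at most,
those of its components (OR-dominance); and raising either cutoff shrinks
the flagged set monotonically.

Report tables print integer percentages rounded half away from zero, the
usual clinical-table convention; note that convention is not universal (a
count of 81/97 = 83.5 % prints as 84 here, while truncating conventions
print 83), so the rounding function is an injectable parameter of
`cohort_summary`. Raw fractions are always retained in machine-readable
output. Medians/IQRs use linear interpolation (NumPy default, type 7).

## ROC analysis and cutoff selection

AUCs are Mann–Whitney estimates (ties ½), computed from midranks and
verified in tests against a brute-force pairwise count. Variance is
DeLong's structural-components estimator; CIs are normal-approximation on
the plain AUC scale clipped to [0,1] — deliberately not logit-scale, to
match common ROC tooling defaults. Two markers on the same patients are
compared with the paired DeLong z-test (two-sided). Implementation was
cross-checked against an independent reference ROC implementation on a
frozen fixture, and the paired test's null rejection rate is verified by
simulation to sit at the nominal 5 %.

Cutoffs are selected per marker on the empirical ROC curve: among finite
operating points whose specificity **strictly** exceeds the floor (default
0.85), take the threshold of maximal sensitivity; break ties toward higher
specificity, then the higher threshold. The chosen threshold is then
snapped **up** to the next multiple of a clinical grid (defaults 0.05 for
IgMi, 25 for FKLCi), which can only tighten the rule; the constraint is
re-verified after snapping. If no operating point qualifies, a
`NoFeasibleCutoffError` is raised rather than silently relaxing the floor.

The default candidate grid crosses each marker's snapped cutoff (low) with
the next grid step up (high): Model A = (low, low), B = (high, high),
C = (low, high), D = (high, low). The optimal model maximises specificity,
then PPV, then PROM, lexicographically, with a deterministic name
tie-break. This criterion is a formalisation of "prefer the most specific,
most predictive rule" and is a swappable design choice — no formal selection
rule is standard in this setting; pass `models=` to `fit()` to rank an
explicit list instead.

## Synthetic cohort generator

No patient-level dataset is released for this problem, so the generator
emulates the documented cohort structure and is itself first-class, tested
code:

* n = 97, OCMB prevalence 54/97 ≈ 0.557 (Bernoulli by default;
  `fixed_counts=True` reproduces an exact 54/43 split);
* (log IgMi, log FKLCi) bivariate normal, correlation ρ = 0.5, shared
  within-class σ = 1 per marker, plus a pure location shift δ for
  OCMB-positives. Under this model the population AUC is
  Φ(δ/√(σ²₊+σ²₋)) exactly, so δ is calibrated by inverting that formula for
  target AUCs 0.71 (IgMi) and 0.64 (FKLCi);
* OCMB-negative medians IgMi 0.08 and FKLCi 60 (below the clinically round
  cutoffs the rule tends to select), QAlb log-normal with median 0.005
  (σ_log 0.35), serum log-normal medians 1000 mg/L IgM, 15 mg/L FKLC,
  42 000 mg/L albumin, disease-activity flag at rate 81/97;
* CSF concentrations are back-computed from the drawn indices
  (`backfill_concentrations`), so recomputing the panel from the emitted
  concentrations recovers the drawn indices to round-off — a tested
  round-trip.

Only the prevalence and the two AUC targets are anchored to documented
cohort facts; every dispersion, location, and the correlation are
conventions chosen once at plausible clinical magnitudes (the source cohort
reports right-skewed, non-normal, positively correlated indices but no
medians, spreads or coefficients). Consequences for interpretation: passing
tests show the pipeline is correct and calibrated **under this log-normal
location-shift structure**. Real cohorts may have class-dependent
dispersion, heavier tails, assay floors/ceilings, or correlation between
indices and QAlb, none of which the generator emulates; selected cutoffs on
real data are expected to differ from any synthetic run, which is why the
rule is re-fit per laboratory rather than shipping fixed cutoffs.

## Numerical choices and degenerate inputs

* Inclusive (≥) thresholding everywhere — rule, ROC operating points,
  cutoff application — so printed cutoffs mean "this value flags".
* Strictly-greater specificity constraint (spec > floor, not ≥).
* AUC from midranks, O(n log n); DeLong components via the explicit ψ
  matrix (cohort sizes here are ≤ a few hundred).
* All scores tied: DeLong variance is exactly 0; the estimate is returned
  flagged `degenerate=True` rather than raising. Equal AUCs with zero
  variance difference give z = 0, p = 1.
* Zero-denominator PPV/NPV are reported as undefined (NaN, `defined=False`)
  rather than raising, so grid tables always render.
* Snap-to-grid uses a 1e-9 absolute tolerance so an already-on-grid cutoff
  is not pushed a full step up by floating-point noise.
* Simulation problem sizes in the test suite and acceptance script (e.g.
  10,000 replicates at n = 54/43 for the AUC-calibration check, 2,000
  replicates for test-size and CI-coverage checks) were chosen so that
  Monte-Carlo standard errors are several times smaller than the asserted
  tolerances.

## Known limitations

* The generator's independence of QAlb and serum levels from OCMB status is
  a simplification; in reality barrier dysfunction correlates with disease
  activity.
* DeLong inference is asymptotic; at n ≈ 100 with AUCs near 1 the normal CI
  can clip at the boundary (it is clipped deliberately).
* The lexicographic model-selection rule ignores costs; a utility-weighted
  criterion is out of scope.
* The Reibergram (hyperbolic reference range for intrathecal IgM) and
  IgG-index analyses are out of scope; OCMB status enters as a given binary
  label, and assay-level QC is not modelled.
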