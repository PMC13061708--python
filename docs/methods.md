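# Methods

This note documents the models, conventions, parameters and numerical
choices behind `auxokit`, and what its synthetic-data tests do and do not
demonstrate.

## Somatic maturation model

**Decimal age.** Elapsed days from birth divided by the mean Gregorian
year, 365.2425 d. This convention is deterministic and leap-year robust;
it differs from "divide by 365.25" by under half a day over an adolescence
and is applied uniformly (no conversion anywhere else in the package).

**Maturity offset.** The sex-specific interaction-term regressions of
Mirwald, Baxter-Jones, Bailey & Beunen (2002), predicting signed years to
peak height velocity from decimal age, stature (Ht), sitting height (SH),
subischial leg length (LL = Ht − SH) and weight (Wt):

```
male:   MO = −9.236 + 0.0002708·LL·SH − 0.001663·age·LL
             + 0.007216·age·SH + 0.02292·(Wt/Ht·100)
female: MO = −9.376 + 0.0001882·LL·SH + 0.0022·age·LL
             + 0.005841·age·SH − 0.002658·age·Wt + 0.07693·(Wt/Ht·100)
```

The coefficients are packaged as data
(`data/maturity_offset_coefficients.json`) and preserved exactly as
published — including the female-only age×weight term — with no
re-fitting. The validated age range is taken as [8, 18] yr; outside it the
default policy computes best-effort and attaches a flag to the result,
while `strict`/`age_policy="error"` raises. Cross-sectional MO prediction
is known to be least reliable far from PHV and near the range edges; the
toolkit reports, it does not correct.

**PHV age** is the identity `decimal age − MO`. In floating point the
identity is exact by definition (PHV age is literally computed as that
difference); the round trip `PHV age + MO == age` holds to double
precision (~1e−15 relatively), which is how tests state it.

**Predicted adult height.** The Khamis–Roche functional form: a linear
combination of current stature, weight and midparent stature with
intercept, per sex at half-year tabulated ages 4.0–17.5 yr, nearest-grid
lookup (ties round up; linear interpolation available via
`interpolate=True`). Midparent stature is the unadjusted mean of the two
parental statures — the sex adjustment lives in the coefficient table in
the published method — and one-parent profiles yield "unavailable" rather
than an imputation.

The packaged table (`data/pah_coefficients_synthetic.csv`) is a
**synthetic stand-in**, not the published coefficients: it was constructed
from standard percent-of-adult-height anchors as
`β₁(age) = 0.75 / p(age)` (p = monotone-PCHIP percent-of-mature-height
curve per sex), `β₃ = 0.25`, `β₂` a small linear trend (+0.05 → −0.05
across the age range), and `β₀ = ±1.625` cm so that a mature athlete on
the classical midparent ± 6.5 cm track predicts their own stature. It has
the published method's structure and realistic outputs (the worked 13-yr
male predicts 181 cm), and every structural property asserted in tests
(β₃ > 0 monotonicity in midparent stature, nearest-half-year lookup
semantics) holds for it; numerical PAH values should not be quoted as
Khamis–Roche predictions. Users with access to the published table can
supply it as a CSV with columns `sex, age_yr, b0, b1, b2, b3`.

**Classification.** Status is a total, monotone function of MO:
pre-pubertal below −1.0 yr, post-pubertal above +1.0 yr, the closed band
between them pubertal (both boundaries pubertal). The ±1 yr circa-PHV
band is the conventional choice and is configurable
(`ClassificationConfig`), as is whether a deployment prefers %PAH-based
staging (compute %PAH and classify externally). Timing compares PHV age
with sex-specific population norms, default mean ± SD of 13.8 ± 1.0 yr
(male) and 11.8 ± 1.0 yr (female) — conventional values from longitudinal
growth studies, deliberately exposed in config because norms are
population specific. The status × timing → recommendation mapping ships
with a neutral default table that is documentation of the mechanism, not
sports-science advice.

## Photogrammetry

A fronto-parallel single-plane pinhole model: the subject stands against
the background wall, the camera is levelled at a known height (defaults:
wall at 200 cm, lens at 100 cm — the standard capture protocol), and a
vertical pixel separation Δy maps to `Δy · wall_distance / focal_px` cm.
Image origin is top-left with y downward; the principal point defaults to
the image centre; the focal length in pixels must come from calibration
(no EXIF parsing). Lens distortion and the subject's offset from the wall
plane are ignored by design and are the dominant known error sources: a
subject 10 cm in front of a 200 cm wall is over-estimated by ~5%. The
floor-consistency check (`validate_calibration`) flags captures whose
floor keypoint does not image at world height 0 within a tolerance
(default 2 cm). Keypoint detection itself is out of scope — the module
consumes keypoints from any upstream detector.

## Agreement statistics

Differences are `expert − app` throughout. The sample SD of differences
uses n−1. TEM uses the classic √(Σd²/2n); the relative TEM divides by the
grand mean of all 2n values (a convention choice — other denominators
exist — and meaningless for signed near-zero metrics like MO, where the
reported percentage explodes; the absolute TEM is the interpretable
number there). When the grand mean is exactly zero the relative TEM is
returned as None with a warning.

The ICC is the two-way, absolute-agreement, **single-measure** form
(ICC(A,1) / ICC(2,1)) — the only reading consistent with a mixed-effects,
absolute-agreement comparison of two fixed methods over random subjects:

```
ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E)),  k = 2
```

with subject (MS_R), method (MS_C) and residual (MS_E) mean squares from
the crossed two-way layout. The 95% CI is the standard F-based
construction with Satterthwaite degrees of freedom; bounds are clipped to
[−1, 1] (some implementations report lower bounds below −1, which have no
interpretation as a correlation). Degenerate inputs: all 2n values
identical → ICC undefined (raises); perfect agreement with
between-subject spread → ICC = 1 with a degenerate (1, 1) CI. The
implementation is verified in tests against explicit brute-force ANOVA
sums (200 random instances, 1e−10) and against pingouin's ICC(A,1).

Cohen's kappa is unweighted, with chance agreement from marginal
products. Degenerate case: if both methods place everyone in one category
(pₑ = 1), kappa is defined as 1.0 under perfect agreement and 0.0
otherwise, keeping "kappa = 1 iff perfect agreement" total. Kappa is
labelled "derived" in reports: it is computable from any status
cross-tab but is an addition to the classical battery above.

## Synthetic cohort generator

The generator emulates a cross-sectional validation cohort: 144
adolescent athletes (76 male, 68 female) aged 10–17, each measured once
by both arms. What it simulates:

- **Growth truth**: Preece–Baines model 1,
  `h(t) = h₁ − 2(h₁ − h_θ)/(exp(s₀(t−θ)) + exp(s₁(t−θ)))`, chosen because
  it has an explicit adolescent spurt and a well-defined true PHV age.
  Sex-specific priors (means ± SD): male h₁ 178 ± 6 cm, h₁ − h_θ 15 ± 2 cm,
  s₀ 0.11 ± 0.01, s₁ 1.10 ± 0.10 /yr, θ 14.0 ± 0.9 yr (clipped to
  [10, 16]); female h₁ 165 ± 6, drop 13 ± 2, θ 12.0 ± 0.9. These are
  loosely anthropometric synthetic defaults, not population reference
  values. True PHV age is found numerically: the analytic PB1 velocity is
  evaluated on a 0.01-yr grid over [θ−4, θ+6] (PB1 is not a valid infancy
  model, so the search brackets the spurt; the curve's early-childhood
  velocity tail would otherwise dominate), and the interior local maximum
  nearest θ is refined by bounded scalar minimisation to 1e−4 yr. With
  these priors the true PHV age sits ~0.5 yr before θ.
- **Auxiliary anthropometry**: sitting height as an age-linear fraction
  of stature (0.53 at age 10 → 0.52 at 18) plus N(0, 0.5) cm individual
  variation; weight via BMI ~ N(16.5 + 0.45·(age−10), 1.8) kg/m²
  (floored at 13); parental statures drawn consistent with the athlete's
  adult stature around the classical midparent ± 6.5 cm relation. Simple
  documented stand-ins with no claim of auxological accuracy.
- **Measurement**: expert arm noise SD 0.3 cm (trained anthropometrist
  with a stadiometer), app arm SD 0.8 cm with optional bias (image-based
  measurement), weight SD 0.1 kg in both arms (both use a scale); all
  heights recorded to 0.1 cm, weights to 0.1 kg, like the field protocol.
  Sessions violating type invariants (sitting ≥ standing) are redrawn and
  counted (`n_redraws`; zero under defaults).
- **Determinism**: one seed feeds a `SeedSequence` spawned per athlete,
  so athlete k's draw is independent of cohort size and ordering, and
  regeneration is byte-identical.
- **Keypoints**: `project_keypoints` inverts the photogrammetric formula
  exactly (zero-noise round trip to 1e−9 cm) with optional pixel noise.

What passing tests on synthetic data do **not** show: that the
maturity-offset or PAH equations are valid for any real population, that
the error model matches a real app's error structure (real image-based
error is not i.i.d. Gaussian — it has posture, clothing and distance
components), or that agreement statistics measured here transfer to real
cohorts. The parameter-recovery tests (TEM recovers an injected noise SD;
predicted PHV age rank-correlates with the simulator's true PHV age,
Spearman ρ ≈ 0.78 at n = 500 zero-noise) are joint consistency checks on
the simulator **and** the equations, not validity claims about either.

## Problem sizes

Chosen as comfortable desk-scale sizes: the ICC oracle comparison uses
200 random datasets of 3–12 subjects; TEM recovery uses 5 000 pairs
(10 000 for the pipeline-level version and the kappa shuffle); the
PHV-age rank-correlation uses a 500-athlete zero-noise cohort; everything
else runs on the 144-athlete default design. The full test suite runs in
about ten seconds.

## Known limitations

- The packaged PAH table is synthetic (above); quantitative PAH values
  are structural, not Khamis–Roche.
- Maturity-offset regressions carry their published caveats: shrinking
  reliability away from PHV, population specificity, and systematic error
  in early/late maturers.
- The photogrammetric model ignores distortion and subject-to-wall
  offset; it is a physically-motivated geometry, not a reconstruction of
  any particular app's computer-vision pipeline.
- Only the anthropometric assessment pathway is implemented;
  questionnaire-based adjuncts sometimes used alongside it have no
  published computational specification to implement.
- Single-measure ICC assumes one observation per subject-method cell;
  replicate sessions must be aggregated or compared per wave.
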