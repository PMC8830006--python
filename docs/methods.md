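# Methods

## Geometry

Angles are measured in true 3D at the centreline-intersection point O, the
apex of every angle: α between the arms O→B and O→C, β between O→A and
O→B, γ between O→A and O→C, with Φ1 = 180° − β and Φ2 = 180° − γ the
branch angles relative to the extended parent axis. Projecting to a plane
first would systematically shrink out-of-plane angles; the 3D convention
matches how CAD centreline tools report them. All angles are stored in
degrees; radians appear only inside trigonometric calls.

The landmarks A, B, C are taken as given inputs (points of largest vessel
curvature, nominally ≥ 5 mm from the bifurcation). The 5 mm rule is
checked but violating records are only warned about, not rejected, since
landmark extraction happens upstream of this package. The larger branch is
identified by diameter (d1 ≥ d2); when the input has them the other way
round the branches are swapped, with the swap recorded on the record and
logged — never silently.

Numerics: the cosine of an angle may overshoot ±1 by floating-point noise;
overshoot up to 1e−12 is clamped, anything larger raises, because a large
overshoot means broken inputs rather than rounding. A landmark coinciding
with O is a degenerate-geometry error naming the offending point.

## Minimum-work indices

The junction exponent solves r0ⁿ = r1ⁿ + r2ⁿ. We work with
f(n) = (r1/r0)ⁿ + (r2/r0)ⁿ − 1, which for r0 > r1 ≥ r2 is strictly
decreasing from f(0) = 1 towards −1, so a unique positive root exists and
bracketed Brent iteration on [0.05, 50] (expanded tenfold up to 3 times if
needed) is globally convergent; relative tolerance 1e−9. When r0 ≤ r1
there is no positive root and the exponent is reported as undefined with a
reason string — not an exception, because such triples occur in real
cohorts.

The optimal angles use the law-of-cosines forms, e.g.
cos φ1 = (r0⁴ + r1⁴ − r2⁴)/(2 r0² r1²). All three cosines lie in [−1, 1]
exactly when the squared radii satisfy the triangle inequality. Outside
that domain no real optimal angle exists; the default flags the record
(`domain_status = angles_undefined`) and every downstream summary excludes
it pairwise and counts it. An explicit `clamp_mode` clamps cosines to ±1
and marks the record `angles_clamped` instead, for users who prefer
boundary angles to missing data; clamping is never the default because
some published mean radii (e.g. basilar-artery triples like
1.58/1.12/0.92 mm) violate the domain, and guessing silently would hide
that. Cosine overshoot within 1e−12 of ±1 is treated as the boundary
itself (angles of exactly 0°), consistent with the geometry clamp rule.

Deviations are signed, predicted − observed, and undefined predictions
propagate to undefined deviations.

## Statistical layer

* Normality gate: one-way ANOVA (with Tukey–Kramer post-hoc, valid for
  unequal group sizes) is used only when *every* group passes Shapiro–Wilk
  at p ≥ 0.05; otherwise Kruskal–Wallis with Dunn's rank-based multiple
  comparisons, Bonferroni-adjusted (the tie-corrected pooled-rank
  variance). Post-hoc p-values are reported only when the omnibus test is
  significant at 0.05.
* Tertiles: boundaries at the empirical 33.33rd/66.67th percentiles with
  linear interpolation between order statistics; a value exactly on a
  boundary joins the lower tertile (the virtual index is snapped to an
  order statistic when integral to 1e−9, so exact ties resolve downward
  despite floating-point division). Fewer than three distinct values, or a
  distribution so discrete that the two boundaries coincide, is an error.
* Logistic regression: maximum-likelihood fits with Wald 95% CIs (the
  standard default). Tertile-coded predictors use the 1st tertile as
  reference, giving two odds-ratio rows. Quasi-complete separation is
  detected (runaway coefficients or a failed Newton fit, retried with a
  tiny L1 penalty) and flagged on the result rather than raised. The
  multivariate model filters candidates at entry p < 0.1, drops the
  higher-p member of any pair correlated beyond |r| > 0.7 (both
  thresholds configurable), then adds predictors forward by
  likelihood-ratio p-value. The model is single-level: bifurcations from
  the same patient are treated as independent; a clustered/multilevel
  variant would need the patient-level grouping structure, which the
  emulated design leaves unspecified.
* ROC: the AUC is the tie-corrected Mann–Whitney rank statistic, which is
  identical to the trapezoidal area under the empirical ROC curve (the
  test suite asserts this equivalence against exhaustive pair counting).
  Candidate cut-offs are midpoints between consecutive sorted unique
  values, a record counting positive at value ≥ cut-off; the reported
  cut-off maximises Youden's J = sensitivity + specificity − 1 with ties
  broken towards the lowest cut-off.

## Synthetic cohorts

The generator emulates a three-group (MCA-aneurysm, BA-aneurysm, control),
five-site case-control cohort of 1126 bifurcations, with per-site blocks
calibrated to published group means ± SD for the radii and angles. What it
reproduces: marginal means/SDs per group and site, the anatomical ordering
r0 > r1 ≥ r2, positive correlation within the radius triple, and an
additive "aneurysm effect" (α widening, r0 enlargement) on designated
sites. What it does not reproduce: the true joint distribution of angles
and radii (angles are sampled independently of radii by default),
within-patient correlation across sites, measurement error of centreline
fitting, and any non-Gaussian shape of the real data. Passing
recovery tests therefore demonstrate that the *pipeline* detects effects
of the configured size under these assumptions — not that real cohorts
behave this way.

Choices, made once:

* truncated normal marginals (the emulated study reports mean ± SD and
  applied normality tests; the true generative law is unknowable);
* exchangeable radius correlation ρ = 0.5 (parent and branch calibres
  co-vary anatomically; configurable, an assumption recorded in the
  ground-truth sidecar);
* ordering enforced by rejection sampling, at most 1000 attempts per
  record before an informative failure (reached only when the configured
  means themselves violate the ordering);
* angles truncated to (0°, 180°), radii to > 0.2 mm;
* an optional `pmw_coupled` angle mode draws angles around the minimum-
  work optimum of the sampled radii for generating PMW-consistent cohorts.
* the effect-recovery design uses n = 120 bifurcations per arm with a
  +25° α shift and +0.15 mm r0 shift — effects of the size separating
  aneurysmal from control means in the calibration tables; null checks
  use the same design with zero shifts.

Landmark output inverts the angle construction: the extended parent axis
goes along +x, the larger branch at Φ1 from it, and the smaller branch is
rotated about the axis by the dihedral angle θ solving
cos α = cos Φ1 cos Φ2 + sin Φ1 sin Φ2 cos θ, then the whole frame gets a
random rigid pose (Haar-uniform rotation + translation) and 10 mm arms. A
solution exists only for |Φ1 − Φ2| ≤ α ≤ 180° − |Φ1 + Φ2 − 180°|; both
ends of the band are checked (the upper bound folds back below 180° when
Φ1 + Φ2 exceeds 180°, since the angle between two rays cannot). In
landmark output mode the angle sampler rejects unrealisable triples.

Determinism: one `numpy` generator seeded from the config drives every
draw; identical configs produce byte-identical tables.

## Interchange and reports

CSV is the interchange format in both directions (upstream mesh tools
export tabular landmarks; no imaging formats are touched). Undefined
values are empty fields, never sentinel numbers; floats are written with
17 significant digits and parsed with round-trip precision, so
write-then-read preserves values exactly. Every analysis run writes a
manifest (package and library versions, seed, SHA-256 of the canonical
config JSON) sufficient to reproduce it, and group-comparison tables carry
an explicit undefined-value exclusion count per parameter.

## Problem sizes in the test suite

Property tests run 1 000–10 000 random radius triples and constructions;
oracle equivalences use 500 random small ROC samples; the effect-recovery
cohort is 120 bifurcations per arm, the null AUC check 400 per arm, and
the type-I-rate check 500 replicates of 30 per arm. These sizes give the
checks comfortable statistical resolution while keeping the default suite
fast on a single CPU.

## Known limitations

* The observed↔predicted comparison assumes the radii and angles refer to
  the same physiological state; digitally removing an aneurysm upstream
  may bias both.
* The out-of-domain rate of the optimal-angle formulas is itself
  informative (circle-of-Willis bifurcations often violate the squared-
  radius triangle inequality); this package reports it but takes no stance
  on how published analyses obtained finite predictions there.
* Wald CIs and single-level logistic regression understate uncertainty
  when several bifurcations per patient enter the model.
* The generator's truncation slightly shifts effective means/SDs relative
  to the configured values (the sample-mean tests bound this at standard-
  error scale); heavy truncation configurations would widen the gap.
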