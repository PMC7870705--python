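# Methods

This note records the statistical models implemented in `segdist`, the
choices made where the design was genuinely open, and what the synthetic
populations do and do not emulate.

## Gametophytic transmission model

A gametophytic sterility allele determines the fate of the haploid pollen
grain that carries it, regardless of the diploid parent's genotype. The
model has two layers:

* **Abortion layer.** A grain carrying the sterile allele, with no rescue,
  aborts with probability σ ∈ [0, 1] (default 1: fully penetrant).
* **Transmission layer.** Surviving grains compete equally, so the sterile
  allele's realized transmission through pollen is
  k = (1 − σ)/(2 − σ) ∈ [0, 0.5]. The map is invertible on that range;
  k > 0.5 (enhanced transmission, e.g. by drive) cannot be expressed as
  abortion and the σ↔k map rejects it, while the estimation and test layers
  accept any k ∈ [0, 1].

Female transmission f is a free parameter defaulting to 0.5 — embryo sacs
are unaffected by pollen-acting alleles — and every reproduction of the
published tables fixes f = 0.5. Selfing a heterozygote gives genotype
probabilities ((1−f)(1−k), (1−f)k + f(1−k), f·k) for (TT, TG, GG); at
f = 0.5 this is ((1−k)/2, 1/2, k/2), so the heterozygote class carries no
information about k and the 1:1:0 ratio appears at k = 0.

## Estimation of k

The counts are multinomial, so conditional on m = n_TT + n_GG the
homozygous-wild count is Binomial(m, k) and the MLE is the closed form
k̂ = n_GG/m, returned exactly at the boundary (no clipping). The n_TG term
is retained in the likelihood — it matters once f ≠ 0.5, where the MLE is
found by bounded numerical maximization instead.

Confidence intervals: the default is the exact Clopper–Pearson interval on
(n_GG, m) via beta quantiles, exact at all sample sizes including zero
counts (boundary estimates yield one-sided intervals, flagged); a
profile-likelihood interval inverting the χ²₁ cutoff is available. The
likelihood-ratio test of k₀ uses the χ²₁ reference; for boundary nulls
(k₀ ∈ {0, 1}) the null is the ½δ₀ + ½χ²₁ mixture, so the p-value is halved
(and set to 1 when the statistic is exactly 0); a null incompatible with
the data (positive count in a zero-probability class) reports infinite
deviance and p = 0, flagged.

Report-layer rounding is decimal half-up, 2 decimals for the S22B
complementation table and 3 for the S22A table, matching the printed
precision; the engines always carry full precision.

## Exact complementation tests

The primary reading of "does the transgenic family segregate like the
control" is the Fisher–Freeman–Halton test on the 2×3 table of the two
families' counts: conditional on the margins each table has a multivariate
hypergeometric probability, and the two-sided p sums all tables no more
probable than the observed one. Ties are absorbed with a 1e-7 relative
tolerance; probabilities are computed in log space (log-gamma), safe at the
n ≈ 170 totals involved. For 2×2 tables this reduces exactly to Fisher's
classical test, which is used as one of the test oracles.

The alternative reading — exact multinomial goodness-of-fit of one family's
counts against fixed proportions (e.g. the control's empirical 42:43:5) —
is implemented with full enumeration up to n = 200 and seeded Monte Carlo
above (the enumeration refuses larger n rather than silently switching).
A Pearson χ² version exists as the asymptotic cross-check. Significance
stars are applied only in the report layer, with configurable thresholds.
Mid-p corrections are documented as out of scope and not applied.

## Pollen fertility under transgene rescue

Expected fertility is an exact enumeration over gamete classes: alleles at
each heterozygous sterility locus (meiotic 1/2), inheritance of each
transgene insertion (hemizygous 1/2, homozygous 1; linked insertions use
the recombination fraction r and a phase saying which homolog carries the
transgene), abortion σ per unrescued sterile allele, per-copy rescue
efficiency. With σ = rescue = 1 this produces the dosage series 50% / 75% /
100% for zero, one hemizygous, and homozygous insertions. With several
sterile alleles in one gamete, abortion acts per allele independently and
rescue success is evaluated per allele given the copies present — a
modeling choice; the published material involves only single-locus
heterozygotes, where no choice is needed. At most one insertion may be
linked to the (single) sterility locus.

For two linked sterility loci, pollen haplotype transmission weights each
meiotic haplotype by per-locus factors 2k (sterile) and 2(1−k)
(functional), combined multiplicatively by default and renormalized. The
"minimum" rule (the more severe locus dominates) is offered because no
published observation constrains how two sterile alleles combine in one
grain; neither rule is a claim about the real double heterozygote.

## Locus delimitation from recombinants

Under the 1:1:0 model a semi-sterile (SS) plant is heterozygous at the
locus and a normal-fertile (N) plant homozygous cultivated; three-way
sterile-morphology labels are accepted and collapse to SS. Each plant
confines the locus to the region where its calls match the implied call,
**open out to the nearest positively excluding marker on each side**: the
breakpoint may fall anywhere in that gap, including between the flanking
marker and the locus itself. This continuous reading is essential — the
most informative pair of recombinants is precisely two plants whose
breakpoints fall on opposite sides of the locus inside the same
marker gap, which a marker-span-only intersection would misreport as a
conflict. Missing calls never tighten a constraint. The reported interval
is the intersection's hull, bounded by flanking markers (open) or map ends
(closed), with the plants that set each flank listed as supporting; a
physical length is attached when the map carries bp positions.

Degenerate cases are errors, not silent results: an empty intersection
names the plants involved (phenotyping/genotyping error or a second
locus), and a homozygous-wild call strictly inside the candidate span
conflicts with the 1:1:0 model. Homozygous-wild calls outside the span are
legitimate (selection acts only at the locus). Non-recombinant plants are
uninformative and leave the interval unchanged.

## Synthetic populations

All generators are pure functions of (parameters, seed); a single root
seed is combined with a fixed per-stage label into independent named
substreams, so adding one stage never perturbs another's draws.

* **Selfed T1 counts** are one multinomial draw from the model
  frequencies. Defaults mirror the study conditions: k = 0.11 (the
  non-transgenic control estimate) and family sizes of ~100.
* **Mapping populations** simulate one selfing meiosis pair per plant:
  per-interval crossovers without interference, with the locus placed
  inside an interval by splitting its recombination fraction so the
  marker-to-marker fraction is preserved; viability selection on the male
  gamete's locus allele realizes the requested k. Phenotypes follow the
  locus genotype (H→SS, TT→N); homozygous-wild plants, undefined under the
  1:1:0 design, are excluded by redrawing (at the k = 0 defaults they
  never arise). The `allow_double_crossover=False` switch removes both
  within-gamete double crossovers around the locus and the plant-level
  configuration (one gamete recombining left of the locus, the other
  right) that hides the locus genotype from every marker — with it, the
  delimited interval is guaranteed to contain the true locus.
* **Complementation T1 families** act at the gamete level: the transgene
  segregates Mendelianly from its own insertion locus; a sterile-allele
  male gamete is viable if it carries the transgene and rescue succeeds,
  otherwise it survives with probability 1 − σ where σ is implied by the
  base k. The expected marginal transmission under rescue is computed by
  exact enumeration (`expected_rescued_k`) and used to validate the
  sampler: rescue = 0 reduces exactly to the plain selfing model, and a
  homozygous fully rescuing insertion restores k = 0.5.
* **The recovery harness** summarizes estimator bias, RMSE, and exact-CI
  coverage over a k grid (≥100 replicates enforced).

What the simulators do *not* emulate: genotyping error, segregation of
more than one sterility locus at once, crossover interference, certation /
differential pollen-tube growth, or the cytological pollen morphology
classes — so passing tests demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
complications.

## Numerical choices and problem sizes

Frequency vectors are validated to sum to 1 within 1e-12; the σ↔k round
trip holds to 1e-12. Exact-test tie handling uses a 1e-7 relative
tolerance. The grid-search oracle used in tests is a two-stage
(1e-3 then 1e-6) scan, exact for this strictly concave likelihood. The
validation suite uses 1,000 replicates of n = 500 families per grid point
for estimator recovery, 2,000 replicates for profile-interval coverage,
and 500 replicates of 500-plant populations for the mapping round trip —
sizes chosen to make Monte-Carlo error small relative to the assertion
bands while keeping the default test run fast.

## Known limitations

* k and f are confounded within a single selfed family; joint estimation
  is deliberately not offered.
* The enumeration-based exact tests are for small tables (2×C, C ≤ ~5) and
  n ≤ 200 goodness-of-fit; larger problems need the Monte-Carlo path or an
  asymptotic test.
* The two-locus viability rules are modeling choices, not measured
  biology; simulator output for double heterozygotes should be treated as
  scenario analysis.
* Marker order is input, never inferred; the package does not build
  genetic maps or perform likelihood-based QTL interval mapping.
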