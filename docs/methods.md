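# Methods

## Scoring model

A case's Ki-67 proliferation index (IK) is estimated from click-annotated
×40 microscope fields.  Each field contributes
`IK_field = 100 · p / (p + n)` where `p` and `n` are the counts of positive
and negative nucleus markers; the case value is the **unweighted arithmetic
mean** of the per-field IKs.  This is the estimator used by the scoring
protocol the package implements; it weights every field equally regardless
of how many nuclei it contains.  The pooled ratio
`100 · Σp / Σ(p+n)` — the maximum-likelihood estimate under a common
Bernoulli rate — is always computed alongside as a diagnostic.  The two are
identical when field totals are equal and diverge otherwise (fields
(1 of 10) and (90 of 100) give 50 % vs 82.7 %); surfacing both makes the
divergence visible instead of hiding an arbitrary choice.

Scoring assumes at least 1,000 tumor nuclei per case.  Falling short raises
a warning and sets `meets_minimum=False` rather than failing, so partial
cases remain inspectable.  `images_needed(k, minimum)` is
`⌈minimum / k⌉`: 7 fields at the typical median yield of 151 nuclei/field,
2 fields for dense tumors above 500 nuclei/field.  At the *mean* yield of
173 the ceiling is 6, while observed practice is "about seven images per
case"; the planner therefore exposes both mean- and median-based estimates
and does not force agreement — the median-based plan is the conservative
one.

## Geometry and units

The reference acquisition field is 310.3 × 232.72 μm (0.072213 mm²).
Coordinates use the image convention (origin top-left, x rightward along
the width, y downward), are stored as floats, and are canonically in
micrometres; pixel-unit files convert through `um_per_px` on read, and
writing pixels without that calibration is an error.  A marker exactly on
the field border is in-bounds (closed interval): clicked nuclei may
straddle edges, and the original protocol does not state a policy, so the
inclusive choice loses no clicks.  Nuclear density is `count / area`
(nuclei/mm²), kept at full precision internally and rounded to integers
only for presentation.  Of the published per-field density summary, the
median and min/max are arithmetically consistent with the corresponding
counts over 0.072213 mm²; the published *mean* density (2451) is not
consistent with the mean count (173/0.072213 ≈ 2396), so only the
consistent cells are used as reference values.

Near-duplicate markers (suspected double clicks) are *flagged* via a k-d
tree pair query with a strict `< threshold` contract — a threshold of 0
flags nothing — and never merged: the human click is ground truth in this
method.

## Stratification rules

* **ER/PR**: positive strictly above 1 %; positive cases split at 50 %
  (low ≤ 50 < high).  Boundary values 1 % and 50 % fall in the lower band.
* **HER2**: 0 — absent staining or < 10 % of cells; 1+ — weak and
  discontinuous in > 10 %; 2+ — weak/moderate and continuous in > 10 %, or
  intense and continuous in ≤ 30 %; 3+ — intense and continuous in > 30 %.
  Only 3+ is positive; 2+ stays "questionable" (whether such cases get
  reflex FISH testing is outside this package's scope).  The rule table has
  genuine gaps (exactly 10 %, moderate or intense discontinuous staining);
  these raise an explicit unscorable error instead of defaulting, so the
  scorer is total over the printed domain and honest outside it.
* **Luminal typing**: luminal if ER and/or PR positive; the luminal-A
  candidate flag requires ER+ and PR+ and HER2 not 3+.  This is the
  subgroup whose chemotherapy decision hinges on the IK, so reports flag
  the luminal-A ∩ high-IK combination.
* **IK classes**: the printed bands "≤ 15 / 16–30 / > 30" leave (15, 16)
  undefined for continuous IK values; the package uses the half-open bands
  low ≤ 15 < moderate ≤ 30 < high anchored at the printed edges.  An
  alternative binary scheme splits luminal A/B at 14 %; the 15/30 scheme is
  the default because it is the one the cohort tables use.
* **NPI**: `0.2 · size_cm + node_score + grade` with node score 1 (none),
  2 (1–3 positive nodes), 3 (≥ 4 or positive apical node).  The moderate
  band 3.4–5.4 is closed on both ends; GPG strictly below, PPG strictly
  above.  Grade is an input (1–3); a helper maps a total SBR score by the
  standard Elston–Ellis convention (3–5 → 1, 6–7 → 2, 8–9 → 3) but mitosis
  and component scoring are out of scope.

Percentages in reports are recomputed from counts with half-up rounding to
1 decimal; counts are authoritative where historical roundings disagree.
Cross-tab columns always include every canonical class level (empty cells
print as `0.0 (0)`, as published tables do); rows show observed levels in
a fixed order so outputs are diffable.

## Synthetic data generator

`simulate_field` draws the nucleus count as Poisson with mean
`density × area` (default density 2396 /mm², matching a mean of ~173 nuclei
per 0.072213 mm² field and spanning the observed 83–585 per-field range
through per-case density variation), places nuclei uniformly over the
field, and labels each positive independently with probability
`p_positive`.  A fixed-count mode exists for exact tests.  Choices and
caveats:

* **Spatial pattern**: uniform placement — no clustering statistics are
  available for the source material, so none are modelled.  The optional
  hotspot gradient is a mean-preserving linear ramp of the positive
  probability along the field's long axis,
  `p(x) = p₀(1 + g(x/W − ½))` clipped to [0, 1]; it is a minimal stand-in
  for periphery-weighted hotspots, not a histological model.
* **Minimum separation**: enforced by simple sequential inhibition with a
  bounded proposal budget (200 proposals per nucleus, minimum 1,000);
  infeasible packings raise an error rather than looping.
* **Seeding**: one root seed; per-case streams are spawned through
  `numpy.random.SeedSequence`, so cohorts reproduce exactly and piecewise.
* **Cohort defaults** emulate an 81-case invasive-ductal-carcinoma series:
  true IK ~ Beta(1.2, 2.8) (mean 0.30); ~22 % of cases double
  receptor-negative; per-field mean counts lognormal around a median of
  151; tumor size lognormal (median 2.1 cm, mean ≈ 2.8 cm, clipped to
  0.3–12 cm); grade probabilities 9 : 45 : 27; nodal involvement in ~63 %
  of cases.  HER2 scores are drawn directly (0.55/0.20/0.15/0.10) rather
  than through synthetic staining observations.

What the generator does *not* emulate: staining intensity and its spatial
texture, non-tumor nuclei (lymphocytes, normal epithelium) that real
hotspot fields contain, inter-observer click variability, and section or
fixation artefacts.  Passing recovery tests therefore show that the
*arithmetic and aggregation* are unbiased under the stated sampling model,
not that the workflow is robust to those real-world error sources.

## Verification choices

Parameter recovery is checked over 200 seeded replicates at true p = 0.25
with 7 Poisson fields at 2396 nuclei/mm² (~1,200 nuclei per replicate):
the mean-of-fields IK must show |mean bias| < 0.5 percentage points, and at
least 90 % of replicates must fall inside the binomial 95 % confidence
interval computed at the true rate for each replicate's realized total
count (the nominal expectation is ~95 %; the 90 % floor keeps the check
stable at R = 200).  The until-minimum stopping rule is exercised 1,000
times and must always accumulate ≥ 1,000 nuclei — true by construction of
the loop, so the test guards regressions in the loop's accounting.  These
problem sizes keep the whole suite under half a minute while leaving the
binomial noise floor well below the tolerances checked.

## Numerical details

* Rounding of reported percentages: decimal half-up (not banker's).
* Even-length medians: mean of the central pair.
* IK and density carry full double precision internally; 1-decimal IK and
  integer density are presentation conventions.
* `aggregate_case` is permutation-invariant in field order; cross-tab
  outputs are deterministic given the input order of levels.

## Known limitations

* No pixel-level nucleus detection: inputs are point annotations, by
  design — the click is the measurement.
* One calibration per annotation file; mixed-magnification files are
  rejected.
* Group-level mean IKs of historical cohorts cannot be recomputed from
  published class counts alone and are treated as pass-through data, not
  reproducible targets.
* The HER2 engine accepts precomputed 0–3 scores for cohorts scored
  elsewhere; it does not model in-situ hybridisation reflex testing.
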