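# Methods

## The assessment model

A Vulnerable Marine Ecosystem (VME) is designated when an area meets at
least one of five FAO criteria: uniqueness or rarity, functional
significance, fragility, life-history traits that make recovery slow, or
structural complexity. `vmescan` operationalises this for a *single* image
as an ordered rule list over (a) per-taxon counts of VME indicator taxa and
(b) annotator-supplied boolean evidence flags:

0. *Element detection.* If no indicator taxon was counted and no evidence
   flag is raised, the image carries no evidence either way; the verdict is
   "evaluate more images", not "not a VME". Merely detecting an element is
   never sufficient on its own, so a positive here only unlocks the later
   steps.
1. *Reef present* (live or dead scleractinian or sponge reef) → VME, all
   five criteria.
2. *Chemosynthetic ecosystem taxa present* → VME (uniqueness/rarity,
   functional significance, fragility, life history).
3. *Large/old individual* — an individual or discrete colony large enough to
   be plausibly >100 years old → VME (uniqueness/rarity, functional
   significance, fragility).
4. *Visible functional role* — nursery, spawning, egg attachment → VME
   (functional significance).
5. *Threatened taxon present* → VME (uniqueness/rarity, functional
   significance).
6. *Richness*: number of distinct indicator taxa S ≥ τ_S → VME (structural
   complexity).
7. *Monotypic stand*: any taxon density d_t = n_t/A ≥ τ_d[t] → VME
   (structural complexity).
8. *Combined density*: D = Σ_t d_t ≥ τ_D → VME (structural complexity).

Otherwise the single image does not depict a VME, with the caveat (carried
in the result) that absence should be confirmed from more images. The
engine is stateless and short-circuiting; its tested contract is totality
(every valid input yields exactly one decision), monotonicity (raising a
count or a flag can never demote a VME decision), and irrelevance of inputs
downstream of the step that fired.

Steps 1–5 are expert visual judgments. They are deliberately carried as
booleans set by the annotator rather than inferred from the count table: a
reef, an individual's age, or a nursery role are not computable from counts,
and a reef image may contain no countable colonies at all (which is why a
raised flag satisfies step 0 by itself).

## Indicator registry

Which taxa count as indicators differs by management body. The packaged
registry encodes, for 22 taxon rows plus 2 habitat-feature rows × 8 bodies,
one of `indicator`, `not_indicator` or `qualified`. Qualified cells carry
either a machine-readable restricted-subtaxa list (e.g. Ceriantharia → only
Cerianthidae; Scleractinia under SPRFMO → six named genera) or, where the
original wording is ambiguous between restriction and synonymy, the verbatim
note (e.g. "stalked only", "as subclass Hydroidolina") — flagged, never
silently interpreted. The default membership policy is `qualified_counts`
(a qualified listing counts as membership), since cross-region consensus
statements treat "members considered indicators" as membership; `strict`
is available. Under `qualified_counts` the cross-body intersection is
exactly {Alcyonacea, Antipatharia, Scleractinia}.

Free-text annotation labels resolve to registry rows case-insensitively via
a synonym table (Gorgonacea → Alcyonacea — pre-2022 octocoral taxonomy is
retained because the management bodies have not adopted the revision; the
synonym table is the extension point) and an upward walk of a small packaged
taxonomic hierarchy (Hexasterophora → Hexactinellida → Porifera). Unknown
labels are a value (`None`), distinct from "not an indicator". Feature rows
("Seamounts as a whole", "Chemosynthetic taxa") answer registry queries but
never participate in count-based density work.

## Densities and the area filter

Counts convert to densities per image, d_t = n_t/A (individuals m⁻²), with
richness S the number of distinct indicator taxa present and richness
density S/A. Images with A < 1 m² are removed first (strictly-below rule:
in the 1,273-image reference layout exactly 38 images fall below 1 m²,
leaving 1,235) because densities extrapolated from tiny fields of view are
unreliable. Images with zero indicator counts are retained with D = 0. By
default richness/density are computed against the union of all bodies'
indicator lists under `qualified_counts`; a single body or the intersection
can be selected instead. The step-6 richness threshold uses the raw count S
by default, with S/A available by configuration, since the two readings are
both defensible and the calibration analyses are phrased per unit area.

## Calibration statistics

Given expert Yes/Maybe/No labels per image, for each metric (richness m⁻²,
Alcyonacea, Scleractinia, Porifera, each registry group, overall density):

- per-label n, mean, sample SD (n−1 denominator), min, max; unlabelled
  records are excluded and counted;
- one-way fixed-effects ANOVA (F from between/within mean squares, upper
  tail of F(k−1, N−k)); implemented via `scipy.stats.f_oneway` and verified
  in the tests against a direct sum-of-squares oracle to |ΔF| < 1e−9;
- Tukey HSD adjusted pairwise p-values from the studentized range with
  pooled within-group variance (Tukey–Kramer under unequal n), via
  `scipy.stats.tukey_hsd`, degenerate zero-variance inputs handled
  explicitly (p = 1 for identical means);
- OLS confounder regressions of overall density on depth and on percent
  soft substrate (taken as 100 − % hard, and noted as such in the report),
  two-sided slope t-test, missing covariates dropped and counted; densities
  are left untransformed by default (a log1p option exists).

Maybe-labelled images participate in summaries and ANOVA (three groups) but
are excluded from threshold derivation, which contrasts Yes against No:

- `midpoint_means`: (mean_Yes + mean_No)/2 — the packaged default
  thresholds come from this estimator (τ_d: Alcyonacea 0.88, Scleractinia
  2.035, Porifera 0.935; τ_D 4.16 individuals m⁻²; τ_S 3 taxa) and are
  shipped explicitly as calibration-derived placeholders to be overridden,
  since no settled thresholds exist;
- `no_quantile`: the q-th quantile of the No group (default q = 0.95, lower
  interpolation);
- `min_misclassification`: the cut minimising false-VME + missed-VME over
  observed values, ties resolved toward the lower cut.

No multiple-testing correction is applied across metrics (matching
per-metric reporting); the report records the number of tests run.

## Synthetic survey generator

The generator emulates the compiled multi-laboratory survey: 10
laboratories, 27 sites, 1,273 images in the study-like layout; areas
log-uniform on 1–50 m² with an exact count of sub-1 m² images (fraction
38/1273, drawn log-uniform on 0.25–1 m²) so the area filter's effect is
deterministic; depths uniform on 100–4,176 m; hard-substrate percentage
uniform on 0–100; labels i.i.d. with P(Yes, Maybe, No) = (0.30, 0.25,
0.45) — chosen as a realistic expert-label split, the reference tables do
not report group sizes.

Counts are negative-binomial per (label, taxon-group): mean = configured
group density × A, size k per (label, group). The Yes/No group means are
the reported values (Alcyonacea 1.47/0.29, Scleractinia 3.59/0.48, Porifera
1.29/0.58 individuals m⁻²; Porifera Maybe 1.48; other Maybe values are
Yes/No midpoints). A residual "Other" group (split equally across
Pennatulacea, Antipatharia and Actiniaria so that richness emerges from
which counts are nonzero) makes the overall Maybe/No means match the
reported 5.81/2.32. For Yes the three focal group means alone already sum
to 6.35 > 6.00 — the reported tables are internally inconsistent there —
so the Yes residual is instead a small co-occurring background (0.5 m⁻²)
chosen so the emergent richness-per-m² ordering across labels reproduces
the reported No < Yes < Maybe structure; the overall Yes mean is emergent
(≈6.6 m⁻²). Dispersions are solved from the reported mean ± SD pairs at
the median analysis area à = √50 m² (k = d²/(SD² − d/Ã)), e.g. k ≈ 0.15
for Scleractinia-Yes; where no SD is reported the Yes/No midpoint or a
global default k = 0.25 is used. Negative-binomial was chosen because every
reported SD greatly exceeds its mean; the distributional family itself is a
modelling choice, not an observed fact.

What the generator does **not** emulate: within-site spatial correlation
(a lognormal site-level density multiplier exists but defaults to off, the
correlation being real but unquantified), label–area or label–depth
dependence, correlated taxon co-occurrence beyond shared labels, percent
cover of reef framework, and any depth or substrate effect on density (so
the confounder regressions are true null tests on synthetic data). Passing
tests therefore demonstrate that the pipeline's arithmetic, filtering and
inference behave correctly under the study's marginal statistical
structure — not that real surveys satisfy these independence assumptions.

Evidence-flag probabilities default to zero for all labels: the calibration
survey records density evidence only, and flag-driven steps are exercised by
targeted fixtures instead.

## Numerical choices

- D = Σ d_t is pure arithmetic; the tested tolerance is 1e−9 absolute.
- Area filter boundary: remove strictly below the threshold (areas exactly
  1 m² are kept), consistent with a removed count of 38 from 1,273.
- Constant-response regression returns slope 0, p = 1 exactly rather than
  0/0; zero covariate variance is an error.
- ANOVA with zero variance everywhere returns F = 0, p = 1.
- Quantile thresholds use lower interpolation, so the estimator always
  returns an observed value.
- Tie-breaks in `min_misclassification` go to the lowest optimal cut,
  making the estimator deterministic.
- CSV output is byte-deterministic (fixed column order: metadata, then taxa
  alphabetically; `repr` float formatting), so identical config + seed
  yields identical files.

## Testing problem sizes

Property and calibration checks run at sizes chosen to make the statistics
sharp while keeping the default suite quick: oracle equivalence on 500
random small ANOVA/regression instances, type-I calibration over 1,000
null-label simulations of 240 images each (rejection rate within binomial
99% bounds of α = 0.05), parameter recovery at 20,000 images (within 3
standard errors for every configured label × group mean), and flow-chart
properties over 10,000 randomized annotations.

## Known limitations

- The registry is a snapshot; body lists change (e.g. NPFC began listing
  Porifera after the reference snapshot) and the packaged CSV is the single
  place to update.
- Single-image scope only: areal-extent aggregation across images,
  confidence indices, and percent-cover metrics for reef framework are out
  of scope.
- The calibration treats images as independent; site-level random effects
  are not modelled (matching the reference analysis).
- Expert labels are judgments; the pipeline reproduces the statistics of
  the calibration exercise, not the correctness of any individual judgment.
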