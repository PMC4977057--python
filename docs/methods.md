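# Methods

## Data model

A screening release is modelled as a sparse chemical × assay collection of
pair results. Each result carries one of four hit calls — `active`,
`inactive`, `single_conc_presumed_inactive` (tested at a single
concentration and presumed inactive), `untested` — plus, for active pairs
only, the AC50 in μM and the cytotoxicity *z*-score. Untested pairs are
represented by absence, so there is exactly one encoding of "no data"; CSV
rows labelled `untested` are dropped on load. Any reported potency
(AC50 or a lowest-effect concentration from LEC-style platforms) is treated
uniformly as the `ac50_uM` field, with an optional `platform_tag` preserving
provenance — the scoring transform makes no distinction between the two
readouts. The loader is permissive on non-active rows (a stray *z*-score is
ignored) and strict on active rows (missing or nonpositive potency is an
error naming the row).

## Input-value transform

For an active pair, `v = max(0, −log10(AC50·10⁻⁶) + z)`; 0 for everything
else, and 0 for active pairs with `z ≤ 2` (boundary excluded). The cutoff
targets the cytotoxic signal burst: near cytotoxic concentrations many
assays activate nonspecifically, and hits whose potency is not separated
from the chemical's cytotoxicity distribution are more likely artifacts.
Design points:

* **Untested = 0.** With sparse coverage, absence of evidence is scored as
  no evidence. This biases the analysis toward chemicals that were actually
  tested; the method finds candidate positives and can miss untested ones.
* **Flooring at 0.** A negative sum would need AC50 far above 1 M; input
  values represent nonnegative potency evidence, so the sum is floored.
  Values that large do not occur in realistic data, so the floor is
  effectively dormant.

## Slice scoring

Per model slice, input values are summed over the slice's assays (assays
absent from the panel contribute 0 — missing model assays are legal, not an
error), then range-normalized across the chemical population:
`(raw − min)/(max − min)`. A degenerate slice with equal raw sums for all
chemicals scores 0 for everyone: the normalization is undefined there and a
constant slice carries no ranking information. The normalized value times
the slice weight gives the component score; the overall score is the
component sum. With equal weights `1/n_slices`, scores lie in [0, 1] and the
component sum reproduces the overall score to 1e-12 (asserted by tests).

Because normalization is population-relative, the scorer is an estimator:
`ToxPiScorer.fit` learns per-slice min/range from a population and
`transform` applies them; transforming chemicals outside the fitted
population clips the normalized value into [0, 1] to preserve the bounds.
Scoring a population uses fit and transform on the same matrix.

## Ranking, bands, prioritization

Chemicals are sorted by overall score with competition ("minimum") ranking,
so tied chemicals share the best rank and "top N%" statements stay
conservative under ties. Bands: top5 if `rank/N ≤ 0.05`, top10 if `≤ 0.10`,
top15 if `≤ 0.15`, else none; a score of exactly 0 is `not_active` and is
never banded. The denominator `N` is configurable: `active_only` (chemicals
with score > 0; the default) or `full_library`. The published band tables
this scheme descends from cannot all be reconciled with a single
denominator, so neither policy is asserted as the historical choice; both
are implemented and the default is the one consistent with more of the
printed bands. A chemical is *prioritized* when it is banded top5 or top10
(i.e. top ~10%) in at least one model.

The RAR companion is a single-slice model run through identical math; its
score is order-isomorphic to the slice raw sums and is appended as a column
to the adipocyte report rather than mixed into the adipocyte score.

## Similarity profiling

Fingerprints bin the *z*-score into six categories (NA / 0 / 1–4, see
README). Note the scoring-stage `z ≤ 2` exclusion is deliberately *not*
applied: the binning itself assigns active `z ≤ 3` to category 1, so weakly
specific activity still shapes the profile. Pearson correlations are
computed on complete pairwise observations (pandas `corr(min_periods=...)`).
Two conventions where the upstream description is silent:

* **Minimum overlap** defaults to 10 shared tested assays (configurable down
  to 2): correlations over a handful of points are noise.
* **Constant restricted vectors** give an *undefined* correlation (`None`),
  not 0 — Pearson r does not exist there.

`top_similar` sorts defined correlations descending, breaking ties
lexicographically by candidate id for deterministic output, and accepts an
exclusion predicate (e.g. dropping pharmaceuticals via annotation tags).
The AC50 variant replaces bins with negative log molar potencies (0 for
tested-inactive, NA for untested); it responds to potency shifts that the
z-binned profile deliberately ignores, so the two rankings can differ.

## Clustering

PCA is run on the column-centered, unscaled slice-score matrix — slices
already share the [0, weight] scale, so rescaling would inflate
near-constant slices. Components explaining ≥ 5% of variance are retained
(exactly the threshold rule; if no component reaches it, that is an error
rather than a silent fallback). k-means uses Lloyd iterations with a 10,000
iteration cap. Two interpretation choices where the upstream wording is
ambiguous:

* the iteration count is read as the cap of a seeded run, and because a
  single run is initialization-sensitive, `restarts` seeded restarts
  (default 10) are run with the best within-cluster sum of squares kept;
* "k equal to the dimensions of the reduced matrix" is read as
  k = number of retained components (the default for `k="auto"`), with an
  explicit `k` available.

The whole fit is deterministic given `random_state`; there is no hidden
global randomness.

## Synthetic data

The generator emulates the structural features of a ToxCast-like release
that the pipeline is sensitive to: a panel built from the union of the
bundled models' assays plus distractor endpoints; archetype chemicals active
on mechanism-specific target sets; burst-like background activity; and
two-tier coverage (a dense, fully tested tier at 60% of the library, the
rest with each pair masked to untested at 60%, echoing the released data's
densely tested subset). Default generative parameters, chosen once as
realistic for nuclear-receptor-scale screening:

| parameter | default | rationale |
|---|---|---|
| p(active) on target assays | 0.8 | strong but imperfect on-mechanism hit rate |
| p(active) background | 0.02 (null chemicals 0.05) | sparse off-target activity |
| log10 AC50 (μM), target hits | mean 0, sd 0.5 | ~1 μM potency, "relatively low concentration" hits |
| background potency offset | +1.3 decades (~20 μM) | distractor hits weaker than on-target hits |
| target z | normal(4.5, 1.5) truncated ≥ 2.5 | specific signal that survives the z ≤ 2 filter by design, separating filter behavior from signal planting |
| background z | uniform[0, 2] | burst-like, removed by the filter by design |

The broad-cytotoxicant archetype is pure background at rate 0.9 — its every
hit carries z ≤ 2, so it must score exactly 0 after filtering; this is the
direct test of the specificity logic. Masking is pairwise-independent;
assay-family block missingness is not modelled. The generator does not
simulate dose–response curves, chemical structures, or specific real
chemicals' profiles — so passing recovery tests demonstrates the pipeline's
mechanics (filtering, normalization, ranking, similarity, clustering) on
data of realistic shape, not predictive validity on any real release.

The default recovery study (20 chemicals per archetype, 400 nulls,
480 × 101 matrix) is the end-to-end acceptance surface: each archetype's
median rank in its matched model must fall in the top decile of the library,
cytotoxicants must score 0, and a planted near-duplicate (same fingerprint,
one entry moved to a different bin) must rank first in its source's
similarity list. These sizes keep a full pipeline run under a few seconds
while leaving hundreds of null chemicals to compete against.

## Numerical choices and degenerate inputs

* Weight sums are validated to 1e-9 on user JSON (accumulated float error of
  hand-entered weights); bundled equal weights satisfy 1e-12.
* Scoring requires ≥ 2 chemicals (normalization is population-relative);
  PCA requires ≥ 2 chemicals, ≥ 2 slices, and nonzero variance.
* Score/rank ties break deterministically (minimum rank, then id).
* All tables are written with fixed float formats and a seed-carrying header
  line, making full-run manifests byte-reproducible from config + seed.

## Known limitations

* Bundled model assay ids are `<GENE>_<k>` placeholders derived from
  published per-gene assay counts, not real release endpoint names; real
  analyses supply model JSONs with release names.
* Upstream curve fitting, hit calling and z-score derivation are out of
  scope: AC50 and z are consumed as given.
* No chemotype/structural similarity, no toxicokinetics or exposure context,
  and no graphical output; the percentile-band star tables and TSVs are the
  reporting surface.
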