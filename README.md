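# toxscreen

Specificity-weighted prioritization of chemicals from high-throughput
screening (HTS) bioactivity data, aimed at researchers generating hypotheses
about environmental chemicals that may disrupt metabolic processes
(adipocyte differentiation, feeding behavior, insulin sensitivity, pancreatic
islet and β cell function).

Screening programs like EPA ToxCast report, for each chemical–assay pair, a
hit call, an AC50 (the concentration producing half-maximal response, μM) and
a cytotoxicity *z*-score — the distance of the hit from the chemical-specific
cytotoxicity distribution, with larger *z* meaning activity more specific
than generic cell stress. `toxscreen` turns such a sparse chemical × assay
matrix into ranked priority scores against curated biological-process models,
complements them with chemical–chemical similarity profiles, and clusters the
resulting activity profiles.

## The score

For each active pair, the scoring input value combines potency and
specificity:

```
v = max(0, −log10(AC50 · 10⁻⁶) + z)        if active and z > 2
v = 0                                       otherwise
```

so an active pair with AC50 = 1 μM and *z* = 5.4 has input value
6 + 5.4 = 11.4. The `z ≤ 2` exclusion removes the "cytotoxic signal burst" —
nonspecific assay activation near cytotoxic concentrations.

A *process model* groups assays into weighted slices. Per slice, input
values are summed across the slice's assays, range-normalized across
chemicals, `(x − min) / (max − min)`, and multiplied by the slice weight
(`1/n_slices` under the default equal weighting); the overall ToxPi score is
the sum of the slice components and lies in [0, 1] — a score of 1 means the
chemical is the most potent in every slice. Chemicals are ranked
(competition ranking) and banded into top ~5 / ~10 / ~15 percentiles;
a chemical in the top ~10% of at least one model is flagged for follow-up.

Six bundled models cover metabolic processes, with 5, 9, 12, 11, 11 and 14
slices; a single-slice companion model scores retinoic acid receptor (RAR)
agonism, reported next to the adipocyte model because RAR activation can
block adipogenic signalling.

Two complementary analyses:

* **Similarity** — each chemical's profile is binned
  (untested → NA; inactive → 0; active: z ≤ 3 → 1, 3 < z ≤ 6 → 2,
  6 < z ≤ 9 → 3, z > 9 → 4) and chemical–chemical Pearson correlations are
  computed on complete pairwise observations, giving ranked most-similar
  lists; an AC50-based variant tracks potency instead of specificity.
* **Clustering** — PCA of a model's slice-score matrix, retention of
  components explaining ≥ 5% of variance, seeded k-means (Lloyd, 10,000
  iteration cap) on the reduced coordinates, and cluster mean profiles.

Because real screening releases cannot be redistributed, a synthetic
generator plants mechanism archetypes (PPARγ agonist, GR agonist,
serotonin/dopamine binder, broad cytotoxicant) in a ToxCast-shaped matrix
with two-tier testing coverage, providing ground truth for end-to-end tests.

## Worked example

```python
import toxscreen as ts

dataset = ts.default_recovery_dataset(seed=7)        # 480 chemicals x 101 assays
iv = ts.build_input_matrix(dataset.matrix)
results = ts.toxpi_scores(iv, ts.bundled_model("adipocyte_differentiation"))
top = results[0]
print(top.chemical_id, round(top.overall_score, 3), top.rank, top.band.value)
```

prints

```
pparg_agonist_001 0.373 1 top5
```

— the top-ranked chemical is one of the planted PPARγ agonists, with an
overall score of 0.373 (it dominates the PPARγ and RXRA slices but not every
slice of the model), rank 1 and a top-5% band. The planted broad cytotoxicants all
score exactly 0: every one of their hits carries z ≤ 2 and is removed by the
burst filter.

The same pipeline is scriptable from the shell:

```sh
toxscreen simulate --seed 7 --out sim/
toxscreen score --hts sim/hts.csv --model adipocyte_differentiation --out scores.tsv --seed 7
toxscreen run-all --config run.json
```

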