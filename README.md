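# microsig

Tissue-specific microbial signature detection in low-biomass taxonomic
profiles.

In tissue RNA-seq, only a tiny fraction of reads is microbial, and at
that biomass contamination — from the collection site, nucleic-acid
isolation, or sequencing — can rival genuine signal. `microsig` is for
researchers who have taxon-by-sample count tables (from any taxonomic
quantifier) and want to know whether a tissue's microbial profile is
*distinctive*, *not explainable by contamination*, and *reproducible in
an independent cohort*. It implements that question as a pipeline:

1. **Core microbiome** — per tissue, keep species present (count > 0) in
   ≥ 10% of samples; the union over tissues is the feature universe.
2. **CSS normalization** — cumulative sum scaling: sample *j* is scaled
   by s_j = Σ{c_ij : 0 < c_ij ≤ q_j}, where q_j is the *l*-th quantile
   (default 0.5) of its nonzero counts, giving values c_ij·N/s_j
   (N = 1000). Fit separately within every train/test split.
3. **Signature models** — per tissue, iterated 1-vs-rest stochastic
   gradient boosting: stratified 70/30 split, minority up-sampling,
   2-fold CV grid over interaction depth 1–3 × trees 50–150 at learning
   rate 0.1 (min 3 obs/node). Reported per tissue: mean AUROC, mean
   AUPR, mean relative AUPR = AUPR / prevalence, with 1.96·sd/√I
   margins. Signature-positive ⇔ mean AUROC ≥ 0.70 and mean relative
   AUPR ≥ 1.4.
4. **In-silico contamination** — 12 pseudo-contaminants (high-volume:
   few samples within one linkage unit, strong; low-volume: many
   samples, weak; per route: collection site / isolation batch /
   sequencing batch) injected post-CSS, redrawn each iteration.
   A tissue is *contamination-driven* iff the contaminated arm wins
   significantly on AUROC **and** AUPR (rank-sum, p < 0.05) and the
   contaminants carry importance (≥ 5% total share or a top-10 rank);
   otherwise *resilient*.
5. **Transfer validation** — stored models scored on an independently
   normalized external cohort against a shuffled-label retrained null;
   *preserved* ⇔ beats the null on both metrics and clears the same
   0.70 / 1.4 thresholds externally.

A synthetic-cohort generator (zero-inflated negative-binomial counts,
~4.2×10⁴ reads/sample, shared core, planted per-tissue fold-change
signatures, tissue-linked collection sites and batch structure) makes
the whole pipeline testable without any data download, and doubles as a
power-analysis tool. See `docs/methods.md` for the models and defaults.

## Worked example

```python
import microsig as ms

config = ms.CohortConfig(n_tissues=4, samples_per_tissue=30, n_species=120,
                         signature_tissues=(0,), seed=42)
counts, meta = ms.generate_cohort(config)
cores = [ms.core_microbiome(counts, meta, t) for t in meta.tissues]
universe, _ = ms.core_union_and_intersections(cores)

spec = ms.ModelSpec(iterations=10, master_seed=0)
result = ms.TissueSignatureModel(counts, meta, "tissue_00", universe, spec).fit()
print(result.summary())
```

prints

```
Tissue signature model: tissue_00 (1 vs rest)
  iterations            10
  mean AUROC            0.769 +/- 0.0381
  mean AUPR             0.577 +/- 0.0590
  mean relative AUPR    2.309 +/- 0.2359
  signature verdict     POSITIVE (AUROC >= 0.7, rel. AUPR >= 1.4)
  top features (first-iteration importance share):
    sp_0057                  0.287
    sp_0038                  0.158
    sp_0099                  0.120
    sp_0102                  0.055
    sp_0069                  0.050
```

Tissue 0 carries a planted 10-species signature at a 4-fold abundance
shift; the model detects it (AUROC 0.77, relative AUPR 2.3 — i.e. 2.3×
better than a random classifier at this class balance), and planted
species such as `sp_0038` surface among the top importance shares.
`ms.signature_species(config)` lists the ground truth for comparison.

Downstream stages hang off the same objects:

```python
scenario = ms.build_default_scenario(meta, seed=0)
study = ms.ContaminationStudy(counts, meta, ["tissue_00"], universe,
                              scenario, spec)
print(study.fit().summary())          # resilient / contamination_driven

ext = ms.generate_external_cohort(config, n_samples_per_tissue=15)
trained = ms.TissueSignatureModel(counts, meta, "tissue_00", universe,
                                  spec, store_models=True).fit()
null = ms.random_label_null(counts, meta, "tissue_00", universe, spec)
print(ms.TransferStudy(trained, null, *ext, feature_universe=universe)
      .fit().summary())               # preserved or not
```

## Command line

Every stage is scriptable over plain TSV/JSON files:

```bash
microsig simulate --out cohort/
microsig core --counts cohort/counts.tsv --metadata cohort/metadata.tsv --out cores/
microsig normalize --counts cohort/counts.tsv --out normalized.tsv
microsig classify --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --universe cores/core_union.json --tissue tissue_00 --iterations 20 --out sig.json
microsig run-all --config run.yaml   # the whole pipeline, report.json out
```

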