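# lowbiome

Contamination-aware analysis of low-biomass 16S rRNA amplicon data.

Claims of a microbiome in tissues long assumed sterile — human fetal organs
being the canonical case — stand or fall on how the analysis treats
contamination. Extraction kits and reagents carry their own microbial DNA
(the "kitome"), and at sub-nanogram biomass that background can dominate the
sequencing output. `lowbiome` implements, as a tested and reusable library,
an analysis design built around matched negative controls: every fetus
contributes PBS buffer blanks processed identically to its tissues, and
reagent/environment/operator controls bracket every processing step. The
question the pipeline answers is not "what taxa are present?" but "is there
signal *above* that background, and which taxa carry it?"

## What it computes

Starting from an OTU count table (taxa × samples), sample metadata, and a
rooted phylogeny:

1. **Preprocessing** — dataset-wide singleton removal, a minimum-depth
   filter (default 500 reads), and repeated rarefaction: each sample is
   subsampled without replacement to a fixed depth (default 1,000 reads,
   10 independent replicates); metrics are computed per replicate and
   averaged.
2. **Alpha diversity** — Shannon entropy (base 2) and bias-corrected Chao1,
   and an **exceedance test**: the 95th percentile of the PBS controls'
   Shannon values defines a cutoff, and each sample class's above/below
   split is compared with PBS by Fisher's exact test.
3. **Beta diversity** — Bray-Curtis and weighted UniFrac (raw and
   normalized), PCoA by classical scaling, and one-way PERMANOVA with

   R² = 1 − SS_within/SS_total, pseudo-F = (SS_between/(k−1)) / (SS_within/(N−k))

   and a seeded label-permutation p value.
4. **Matched-control distances** — each tissue's mean distance to its
   fetus-matched PBS blanks, compared against the PBS-to-PBS reference
   distribution, and (per fetus with ≥ 2 tissues) normalized by the
   within-fetus mean so a surface-to-internal gradient can be tested by
   signed rank.
5. **Taxa screens** — a genus-level intensity screen (PBS ≥ fetal maximum ⇒
   potential contaminant; PBS well below fetal maximum ⇒ potential signal)
   and a differential enrichment rule per genus-level OTU *i*:

   log2FC_i = log2((A_i + pc)/(B_i + pc)),
   RPA_i = 100·S_target / (S_target + S_internal + S_PBS)

   with A_i/B_i mean normalized counts in the target organ vs an internal
   control (a low-signal organ such as spleen or thymus) or the external
   PBS control, S_* the reads-positive sample counts, and a taxon flagged
   enriched when both log2FC values are ≥ 2 and RPA ≥ 3%.
6. **qPCR support** — replicate-averaged Ct values compared per class
   (lower Ct = more amplifiable bacterial DNA).

A synthetic-data module generates datasets with this exact structure —
homogeneous kitome in every sample including controls, organ-restricted
signal taxa with a surface-to-internal abundance gradient, matched PBS per
fetus, Dirichlet-multinomial counts — with per-taxon truth labels, so every
stage is testable end to end without any external download.

## Worked example

```python
import lowbiome as lb

cfg = lb.SimConfig(seed=1)                       # 8 fetuses x 6 organs + controls
table, meta, taxonomy, tree, truth = lb.generate_dataset(cfg)
bundle = lb.run_pipeline(table, meta, tree=tree, taxonomy=taxonomy,
                         config=lb.PipelineConfig(seed=1))

print(bundle.exceedance.threshold)               # 3.268310508079232
print(bundle.permanova.r2, bundle.permanova.p_value)  # 0.4041036581553392 0.001
print(bundle.manifest["n_enriched_taxa"])        # 4
skin = [r.distance for r in bundle.matched_normalized.records if r.organ == "skin"]
print(sum(skin) / len(skin))                     # 1.6066612810848597
print(bundle.organ_tests_paired["skin"].p_value) # 0.0078125
```

Reading: the PBS Shannon cutoff for this dataset is ≈ 3.27; sample classes
separate strongly in weighted-UniFrac space (PERMANOVA R² ≈ 0.40,
p = 0.001); exactly the 4 planted gut-restricted signal taxa pass the
log2FC/RPA rule; and skin — the most surface-exposed organ — sits ≈ 1.6×
farther from its matched PBS than the within-fetus average (signed-rank
p ≈ 0.008), reproducing the planted exposure gradient.

The same analysis is available from the shell:

```sh
lowbiome simulate --seed 1 --out sim/
lowbiome run --table sim/otu_table.tsv --metadata sim/metadata.tsv \
             --tree sim/tree.nwk --taxonomy sim/taxonomy.tsv \
             --ct sim/ct.tsv --seed 1 --out report/
```

## Layout

- `src/lowbiome/core.py` — domain types (OTU table, sample metadata, tree,
  distance matrix, Ct records, truth labels) with validation
- `src/lowbiome/io.py` — TSV/newick readers and writers
- `src/lowbiome/preprocess.py` — filters and the rarefaction ensemble
- `src/lowbiome/alpha.py`, `beta.py` — diversity metrics, PCoA, PERMANOVA
- `src/lowbiome/stats.py` — exact small-sample tests
- `src/lowbiome/controls.py` — exceedance, matched distances, Ct summaries
- `src/lowbiome/enrichment.py` — intensity screen, log2FC + RPA, culture overlap
- `src/lowbiome/simulate.py` — the synthetic-data generator
- `src/lowbiome/pipeline.py`, `cli.py`, `evaluate.py` — orchestration,
  command line, recovery benchmarks

See `docs/methods.md` for the model, parameter choices, and limitations.
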