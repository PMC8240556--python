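# Methods

## The analytical problem

At the biomass of a fetal tissue biopsy, the DNA contributed by extraction
kits and reagents is comparable to — often larger than — any biological
signal. The analysis therefore never interprets a taxon's presence in
isolation; every statistic is a *contrast against negative controls*:
fetus-matched PBS blanks (the primary control, processed identically to
tissue from collection to sequencing), plus reagent, environment and
operator controls. The package implements that contrast at three levels —
whole-sample diversity, between-sample distance, and per-taxon abundance —
and ships a generator of synthetic datasets with known ground truth so the
full chain is testable.

## Preprocessing

Order is fixed and asserted by a test: (1) remove taxa whose *total* count
across the entire dataset is 1 (dataset-wide singletons; a taxon observed
once in each of two samples survives); (2) drop samples with fewer than
500 total reads (boundary retained); (3) rarefy each surviving sample to
1,000 reads, 10 independent times. Whether the depth filter should precede
singleton removal is not determined by the design being emulated; the order
above removes sequencing noise before judging sample depth and is our
documented choice.

Rarefaction draws a uniform subsample *without replacement*
(`numpy.random.Generator.multivariate_hypergeometric`), so each rarefied
column sums exactly to the depth and the marginal distribution of any taxon
is hypergeometric — both asserted by tests, the latter by a moment check
within 3 standard errors over 1,000 replicates. Per-replicate seeds are
spawned from the master seed via `numpy.random.SeedSequence`, making the
ensemble reproducible while keeping replicates independent. Diversity
metrics are computed per replicate and averaged (the metric is averaged,
not the tables); distance matrices are averaged element-wise across
replicates.

## Diversity metrics

*Shannon* uses log base 2 (the QIIME 1.x convention; the base is a keyword
because published cutoffs rarely state it). *Chao1* uses the bias-corrected
form S_obs + F1(F1−1)/(2(F2+1)); the classic form is behind a flag.
*Bray-Curtis* is the standard 1 − 2·Σmin/(Σ+Σ). *Weighted UniFrac* follows
the branch-weighted formulation: raw distance Σ_b ℓ_b·|p_A(b) − p_B(b)|
over branches, where p_X(b) is the fraction of sample X's reads descending
through branch b; the normalized variant divides by Σ_leaves
depth(leaf)·(p_A + p_B), bounding it by 1. The implementation is a single
incidence-matrix product per sample set; a recursive branch-enumeration
oracle and scikit-bio both serve as independent checks in the tests.

*PCoA* is classical scaling (eigendecomposition of the double-centered
−d²/2 matrix). Negative eigenvalues — expected for non-Euclidean
dissimilarities — are reported but carry no coordinates, and the
proportion of variance explained is taken over positive eigenvalues only.

*PERMANOVA* is the one-way distance-based test: SS_total = Σ_{i<j} d²_ij/N,
SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g, R² = 1 − SS_within/SS_total, pseudo-F
with (k−1, N−k) degrees of freedom, and p = (1 + #{F_perm ≥ F_obs}) /
(permutations + 1) under seeded label permutation (ties count as
exceedances, so p never underruns its support). The permutation batch is
evaluated with one quadratic-form einsum per group, which is what makes the
2,000-simulation calibration test cheap. Calibration is verified: under
random relabeling of a fixed matrix, p is uniform on its support.

## Small-sample tests

The group tests are deliberately exact where sample sizes allow, because
control groups here are small. Mann-Whitney U switches to exact enumeration
when n_x + n_y ≤ 12 with no ties (two-sided p = doubled smaller tail,
capped at 1); otherwise the normal approximation with tie and continuity
corrections. The paired analogue is the Wilcoxon signed-rank test (zeros
dropped, exact for n ≤ 15 without ties; the reported statistic is the
positive-rank sum T+). Fisher's exact test uses the probability-mass
two-sided rule. These are scipy-backed wrappers; the exact-path selection
rules are ours, and every exact p is reproduced in the tests by independent
enumeration (all 2×2 tables with grand total ≤ 10; every size split for the
rank tests). The percentile behind the exceedance cutoff is the
linear-interpolation (type-7) estimator, configurable since published
cutoff values rarely state the method.

## Control comparisons

*Exceedance*: the threshold is the 95th percentile of PBS Shannon values;
"above" is strict (boundary counts as below — a binary figure cannot
disambiguate, and strictness is the conservative choice). Each non-PBS
class is tested against PBS on the above/below 2×2 by Fisher's exact test.

*Matched distances*: each tissue's distance to its matched PBS is the mean
over that fetus's PBS blanks (plural blanks are averaged; tissues without a
matched blank are excluded with a warning, never imputed). The reference
distribution is all PBS-to-PBS pairwise distances. Within-fetus
normalization divides each record by the fetus's mean record and is
restricted to fetuses with ≥ 2 tissue records; it forces the per-fetus mean
to exactly 1, so the meaningful paired test is *per organ* against 1 —
surface-exposed organs should exceed 1 and internal organs fall below it if
an exposure gradient exists. The pooled normalized mean is 1 by
construction and is not a test statistic.

*Ct summaries*: technical replicates are averaged arithmetically; organ and
control classes are compared by Mann-Whitney U against PBS and against the
designated internal-control organ (default thymus). No amplification-
efficiency modeling is attempted.

## Taxa screens

The intensity screen aggregates OTUs to genus (lineages without a parseable
genus map to "unassigned" and are excluded), averages per-sample abundance
within each class (per-organ fetal classes by default, pooled optional),
drops genera that are zero everywhere, and labels each genus:
`control_enriched` if PBS intensity ≥ the fetal maximum; `fetal_enriched`
if PBS < θ·(fetal maximum) with positive fetal signal (θ defaults to 0.5);
`indeterminate` otherwise. The θ band exists because the boundary between
"low in PBS" and "comparable to PBS" is a judgment call in any curated
dot-plot; making it an explicit ratio keeps the screen reproducible, at the
cost of an indeterminate class.

Differential enrichment scores each genus-level OTU in a target organ
against an internal control (a low-signal fetal organ — spleen or thymus —
which controls for everything a buffer blank cannot: the tissue matrix,
host DNA load, per-fetus processing) *and* the external PBS control. The
pseudocount (default 1 normalized-count unit) makes log2FC defined when the
control count is zero — precisely the interesting case. "Reads exist" for
the RPA prevalence counts means strictly positive count after
preprocessing. A taxon is enriched when *both* log2FC values pass the
cutoff (an OR mode exists behind a flag) and RPA passes its cutoff.
Records are sorted by RPA, then log2FC.

Culture overlap harmonizes genus names (lowercase, strip strain suffixes,
optional synonym table) and reports the distinct-genus intersection
globally and per tissue.

## The synthetic generator

The generator encodes the two signatures that distinguish contamination
from signal in this design, as structural assumptions:

- **Kitome homogeneity**: contaminant taxa have the *same* expected
  relative composition in every sample — tissues, PBS, reagent and
  environment controls alike. Their shares are drawn once per dataset from
  a normalized log-normal (sd 0.5 → shares roughly 4–25% across 10 taxa).
- **Exposure gradient**: signal taxa are absent from all controls and
  restricted to target organs. Organs carry surface-exposure ranks
  (skin/placenta 1, gut/lung 2, liver/mLN 3, thymus/spleen 4); a signal
  taxon's compositional mass is `signal_scale · exposure_decay^(rank−1)`
  (defaults 0.16 and 0.6). Each taxon has a "reach" — the deepest rank it
  colonizes — with defaults of four surface-only, four surface+mid, and
  four all-organ taxa, so internal organs carry a small but real signal
  load and the target-organ screen has genuinely absent-from-internal taxa
  to find.

Counts are Dirichlet-multinomial (concentration 2000, i.e. mild
compositional overdispersion — the kitome of a single extraction batch is
compositionally reproducible, which is exactly why prevalence-based
decontamination works; heavier overdispersion is one knob away) at a
log-normal depth (median 10⁴, sd 0.15 dex). Each of 8 fetuses contributes
one sample per organ (6 organs by default: skin, placenta, gut, lung,
thymus, spleen) and 2 matched PBS blanks; 3 reagent and 3 environment
controls complete the frame. The UniFrac tree is a random bifurcating
topology with exponential branch lengths. qPCR Ct values follow
baseline − slope·log10(load) with load 1 + planted signal mass, duplicate
replicates, and Gaussian noise. A single master seed drives every substream
by name, so datasets are byte-identical across runs.

What the generator does *not* emulate: taxonomic misassignment,
cross-contamination between wells (a knob exists, default 0), PCR and
primer bias, batch-to-batch kitome drift, and the possibility of real
signal in PBS (e.g. carried over during collection). Passing recovery tests
therefore show the *pipeline logic* is sound — they do not show that real
fetal-tissue data would separate as cleanly, and on real data the
contaminant/signal boundary will be blurrier in exactly the ways listed.

## Recovery benchmarks and their scope

`evaluate.py` defines the recovery metrics: signal recall is measured over
taxa whose truth targets include the target organ and exclude the internal
control (taxa planted elsewhere cannot and should not pass a gut screen);
contaminant specificity is the fraction of planted contaminant genera
labeled `control_enriched`; the gradient check applies the per-organ signed
rank to the most surface-exposed organ. At the default conditions the
pipeline attains ≈100% recall, ≥99% specificity and 100% gradient
detection over 100 datasets, with a null exceedance rejection rate well
under the nominal 5% (Fisher is conservative at these group sizes). The
reproduction script (`scripts/acceptance.py`) recomputes all of these from
scratch at 50 + 50 datasets, sizes chosen to keep a laptop run under ten
seconds while leaving the Monte-Carlo error on each rate below ~2 points.

## Known limitations

- Rank tests fall back to normal approximations in the presence of ties;
  mid-p or exact-with-ties variants are not implemented.
- PERMANOVA is one-way only (no strata/blocking), matching its use here.
- The intensity screen's per-organ maximum makes `control_enriched` a
  strict call: a contaminant genus needs its PBS mean to exceed *six* noisy
  organ means, so specificity depends on class sizes and overdispersion.
- Genus aggregation trusts the input lineages; no synonym resolution is
  applied outside the culture-overlap accessor.
- BIOM/HDF5 and Excel inputs are out of scope; everything is delimited
  text and newick.
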