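# Methods

## The model

A target gene of the ARR1/10/12 family is modelled by a monotone Boolean
function *f* over TF **presence**: in a genotype whose present-TF set
satisfies *f* the gene sits at its baseline log2 expression; once *f* fails
the gene shifts by a fixed effect.  Genes whose expression *falls* when the
logic fails are *activated* targets (called D in the mutants); genes that
*rise* are targets of suppression (called U).  In canonical form *f* is the
antichain of its minimal sufficient TF subsets — its minimal disjunctive
normal form.  `1∨12` means ARR1 or ARR12 alone suffices; `1∧10∧12` means
all three are required.

Two structural facts drive the inference and are verified exhaustively in
the test suite:

- A deletion set S switches *f* off exactly when S intersects every
  minimal sufficient subset (hitting-set criterion), so each structure
  predicts a set of *changed* comparisons among the seven deletion
  genotypes.  For three TFs there are 18 non-constant monotone functions
  (Dedekind's 20 minus the two constants) with pairwise-distinct predicted
  changed sets.
- Predicted changed sets are upward closed (deleting a superset of a
  sufficient deletion also changes the gene), and the 18 changed sets
  biject with the nonempty up-sets of the 7-element deletion lattice.
  Hence, after superset closure, **every** uniform-direction pattern maps
  to exactly one structure; "unmapped" arises only from patterns mixing U
  and D, which no single monotone structure can generate.

## Differential-expression statistic

Per gene and comparison (test group vs untreated wild type, both n ≥ 2):

- T: pooled-variance two-sample Student's t (test − reference).  With two
  replicates per group a separate-variance correction has no degrees of
  freedom to estimate, so the pooled form is the natural choice.
- M: log2-median-ratio, median(test) − median(reference) on the log2
  scale.

Null distributions are built by relabeling the comparison's samples into
the two groups in every non-identity balanced way — C(4,2) − 1 = 5
assignments for a 2v2 design, enumerated exhaustively; larger designs fall
back to seeded sampling capped at `max_perms` — and pooling the recomputed
T and M across genes into one common null per statistic.  Pooling across
genes is what gives a 5-permutation design usable resolution (5 × n_genes
null values).

One-sided empirical p-values are taken in the observed direction with an
add-one pseudocount, p = (1 + #{null ≥ obs})/(1 + N) for positive
observations and mirrored for negative ones, so p ∈ [1/(N+1), 1].  The two
p-values are combined by Stouffer's method, z_c = (z_T + z_M)/√2 with
z = Φ⁻¹(1 − p) and inputs clamped to [1e−15, 1 − 1e−15].

A gene is called U or D when the combined p ≤ α (default 0.05) **and**
|M| ≥ the fold-change cutoff, defined per comparison as the 95th
percentile (linear interpolation) of the null |M| distribution.  The
cutoff is always data-derived — on typical synthetic studies it lands
around 0.5 log2 units, but it is a property of each comparison's noise,
never a constant.  A Benjamini–Hochberg column over the combined p is
emitted for transparency; it plays no role in the calls.

### Error properties, stated honestly

With two replicates the median equals the mean, so T and M are nearly
collinear and the two one-sided p-values are close to duplicates; combined
with the directional (favorable-side) convention, the Stouffer p alone is
anti-conservative under the null (P(p_c ≤ 0.01) ≈ 0.10 on pure noise).
Error control comes from the dual gate: the |M| cutoff caps the
per-comparison call rate at ≈ 5%, and measured rates on pure-noise
simulations are 4.5–5.0% at the default operating point (α = 0.05,
fc quantile 0.95).  Consequences:

- tightening α below 0.05 barely reduces the call rate (the fc gate
  binds), and
- ~5% false calls per comparison corrupt a noticeable fraction of 7-symbol
  patterns; end-to-end recovery of planted structures runs ≈ 89% under
  the default study conditions, with corrupted patterns mostly becoming
  unmapped or drifting to a neighbouring structure.

The test suite asserts the operating-point guarantee (call rate ≤ 0.05 on
pure noise, monotone in α) rather than a per-α nominal bound the
construction cannot provide.

## Pattern mapping and clusters

Calls over the seven comparisons (canonical order: arr1, arr10, arr12,
arr1/10, arr1/12, arr10/12, arr1/10/12) form each gene's U/D/N pattern.
All-N genes are not DEGs and leave the analysis; mixed-direction patterns
are unmapped.  Mapping modes:

- **strict** — the observed changed set must equal a predicted changed set
  verbatim;
- **closure** (default) — the observed set is first closed upward under
  superset, treating a missing call in an implied comparison as a false
  negative.  This is the principled reconstruction of merging many
  observed patterns into few structures, and with it every
  uniform-direction pattern maps.

The default reporting catalogue is the 15 structures the reference
knockout analysis exhibits (clusters C1–C15, numbered: singles 1–3, AND
pairs 4/6/8, OR pairs 5/7/9, AND triple 10, majority 11, x∨(y∧z) 12–14,
OR triple 15).  The three remaining forms x∧(y∨z) complete the monotone
family and are available with `n_catalogue=18` (pipeline flag
`report_18`); under the default catalogue a pattern implying one of them
is reported unmapped.  This default reflects the reporting convention of
the analysis the package reimplements; with ~5% per-comparison false
calls, rare multi-comparison false patterns would otherwise scatter into
the three extra structures and inflate the structure count.

Major clusters are selected independently for up- and down-regulated
genes: a cluster is selected when its size strictly exceeds the 50th
percentile (linear interpolation; absent clusters count as size 0) of the
15 cluster sizes for that direction.  Selected clusters take the fixed
group map G1 = {C1,C2,C3}, G2 = {C5,C7,C9}, G3 = {C10}, G4 = {C15},
G5 = {C11,C12}; everything else keeps its cluster with group `none`.

## Synthetic study design

The generator emulates the real study's design: ten conditions — WT and
the seven deletion genotypes untreated, plus mock- and CK-treated WT —
with 2 biological replicates each (configurable, minimum 2).  Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_background_genes` | 5000 | unregulated genes |
| `genes_per_structure` | 40 | planted genes per catalogue structure |
| `effect_delta` | 2.0 | log2 shift when the logic fails |
| `noise_sd` | 0.25 | replicate Gaussian SD, log2 scale |
| `baseline_mu`, `baseline_sd` | 8.0, 1.5 | baseline log2 intensity |
| `fraction_repressed` | 0.4 | planted genes that rise when logic fails |
| `ck_effect_delta` | 2.0 | CK shift for the responsive subset |
| `ck_fraction_planted`, `n_ck_background` | 0.3, 200 | CK-responsive designation |

Effect size 2 log2 units at noise 0.25 puts planted genes far above the
detection threshold (the interesting failure mode is pattern corruption by
false calls, not missed effects); baselines are typical mid-range
log-intensities.  The 0.4 repressed fraction mirrors a study in which both
up- and down-regulated targets occur with a down-regulated majority among
activator targets.  CK responsiveness is a purely additive shift applied
in CK-treated WT only, on a seeded subset of planted and background genes;
there is no mechanistic signaling model.  One probe per gene by default;
`probes_per_gene > 1` emits duplicated gene rows with fixed per-probe
offsets to exercise median probe collapsing.

What the generator does **not** emulate: hybridization artifacts, dye
bias, intensity-dependent variance, correlated probe noise, batch
effects, or any real microarray noise spectrum.  Passing recovery tests
therefore demonstrate the statistical machinery and the logic engine, not
robustness to platform-specific artifacts.

## Normalization and IO

Quantile normalization maps every column onto the reference distribution
given by row means of the column-sorted matrix; ties within a column
receive the mean of the reference quantiles they span (an all-constant
column maps to the reference mean rather than erroring).  On tie-free data
the operation is exactly idempotent and equalizes sorted columns; the test
suite asserts both to 1e-12.  Probe-to-gene collapsing is the per-gene
median across probes, applied after normalization; missing values are
rejected by default with an opt-in row-drop policy.  A minimal plain-text
GEO Series Matrix reader is provided for studies exported in that format.

## Network and enrichment statistics

Hub-likeness and high clustering coefficient are upper-tail empirical
p-values of a node statistic against the network-wide distribution:
exact mode (default) uses the ECDF over all nodes, p = #{stat ≥ obs}/n;
sampled mode draws `n_samples` (default 100,000) values with replacement,
p = (1 + #{draw ≥ obs})/(1 + n_samples), seeded.  Exact mode is the limit
the sampling approximates, so it is the default; flags are set at
p < 0.05.  The local clustering coefficient is 2e/(k(k−1)) with c = 0 for
k < 2.  Nodes absent from the network get no row (scoring them k = 0
would deflate the null).  Membership fractions of gene classes in target
sets (hormone-signaling layers, function classes) are count/|set| with
percents rounded to one decimal.

Over-representation is the one-tailed hypergeometric upper tail
P(X ≥ k); the EASE variant recomputes at k − 1 (floor 0) and is always ≥
the Fisher p.  The default universe is all genes on the platform, not the
DEG list; the pass flag uses the raw p at the 0.1 default threshold, with
a BH column attached for transparency.

## CK-response classification

CK DEGs (CK-treated vs mock-treated WT) are classified by their behaviour
in the mutants: the mutant direction of a mapped gene is its cluster's
direction; a mutant DEG that failed logic mapping uses its dominant call
direction across the seven comparisons (exact ties are excluded and
logged).  Classes are up_up, up_dw, dw_up, dw_dw and ck_only, with a group
suffix (G1–G5) when the gene sits in a selected, grouped cluster and
"Others" otherwise.  The up-in-CK/down-in-mutants view — the expected
direction for targets of positive regulators — is a flagged column, not a
filter.

## Pipeline mechanics

One top-level seed fans out via `numpy.random.SeedSequence` to per-stage
and per-comparison child seeds (all < 2³¹), so any stage reproduces in
isolation.  Stage order: simulate/load → normalize → DEG (7 mutant
comparisons + CK when present) → logic → network → enrichment → CK
overlap; every stage writes TSV/JSON outputs and the run report echoes
parameters, seeds, counts and the output manifest.  Configs are TOML;
all CLI flags override config keys.

## Problem sizes

Defaults are sized so a full synthetic run (5600 genes × 20 samples,
8 comparisons × 5 permutations each) completes in seconds on one core,
and the complete test suite — including exhaustive checks over all 3⁷
patterns and all 256 truth tables — in well under a minute.  Larger
designs engage seeded permutation sampling via `max_perms`.

## Known limitations

- Logic inference is exact-match (strict or closure); there is no
  probabilistic or noisy-logic model, and no best-match fallback for
  corrupted patterns.
- Enumeration is guarded at 4 regulators; the antichain space explodes
  beyond that.
- The Stouffer combination treats T and M as independent, which they are
  not in small designs; see the error-properties note above.
- The EASE/Fisher enrichment does not reproduce any specific annotation
  database, GO graph propagation, or term clustering.
- Directional category totals count a gene once per direction, matching
  the up + down = total reporting convention.
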