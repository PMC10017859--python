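# Methods

## Problem setting

Heterogeneous intake forms ask semantically equivalent questions with
different wordings under different section hierarchies. The pipeline groups
distinct question strings into semantic categories and quantifies (a) how
reproducible the grouping is on independent data and (b) how well the
discovered categories align with an external reference taxonomy. All
geometry is cosine/unit-sphere geometry: every embedding is L2-normalized
on ingestion, so cosine similarity equals the dot product downstream.

## Records and distinctness

A question record is a `(field_path, field_name)` pair plus provenance
(form id, optional date and site). `field_path` is the slash-terminated
trail of section titles; flattening a JSON-Schema form definition emits one
record per non-object leaf property, typed free-text/number/choice/
multi-answer (enumerated values become `allowed_values`).

Distinctness is counted under two keys: normalized path + text, or
normalized text only. Normalization is deliberately minimal — case-fold,
collapse internal whitespace, strip ends; no stemming or punctuation
removal — because anything stronger silently merges questions a reviewer
could not audit. Raw duplicates are retained in the canonical record store
and removed only at the analysis boundary, so the dedup report reconciles
against the source data.

## Encoders

The encoder contract is pluggable. The optional external backend wraps a
pretrained sentence transformer (768-d MPNet-class model), used as-is with
no fine-tuning. The default fallback is fully deterministic and
self-contained: hashed character n-grams (3–5, word-boundary padded,
2¹² hash buckets) → Gaussian random projection drawn once from the seed →
L2 normalization. It preserves the one property the downstream stages rely
on — near-duplicate strings embed close together — but it is a lexical
encoder: it does not capture synonymy between disjoint vocabularies
("Highest grade attained" vs. "Years of schooling"). Synthetic-corpus tests
therefore demonstrate pipeline correctness, not the semantic quality of any
particular encoder.

## Locally linear embedding

Standard LLE: K = 5 Euclidean nearest neighbors (ties broken by lowest
index via stable argsort); barycentric weights solve the local Gram system
G w = 1 with Σw = 1, where G is conditioned by adding r·trace(G)/K
(r = 1e-3, or r alone when the trace vanishes) to its diagonal; the
embedding is the bottom d+1 eigenvectors of M = (I−W)ᵀ(I−W) with the
constant direction removed. Because a K-NN graph can be disconnected — in
which case M's null space has multiplicity and the constant vector need not
appear as a single eigenvector — the implementation projects span{1} out of
the bottom (d+1)-dimensional eigenspace and re-orthonormalizes rather than
dropping column 0. The reconstruction error Φ(Y) = Σᵢ‖Yᵢ − Σⱼ Wᵢⱼ Yⱼ‖²
depends only on the retained subspace, so this choice is invariant-safe;
Φ is also invariant under global rotation and translation of Y (weight rows
sum to 1), which the tests assert. Column signs are fixed by making each
column's largest-magnitude entry positive. A dense symmetric eigensolver is
used up to n = 2,000 and shift-invert Lanczos above, matching the corpus
scale (a few thousand items).

The dimension sweep refits LLE on replicated random subsamples (without
replacement) for each candidate d and tabulates mean/min/max/median/IQR/SD
of Φ. Selection is manual by default — the reconstruction-error curve
typically *increases* with d at this scale, so no automatic rule is imposed
— with a knee option (maximum perpendicular distance to the endpoint
chord) for curves with a genuine corner.

## Spherical k-means

Rows are L2-normalized; assignment minimizes cosine distance with ties to
the lowest centroid index; updates renormalize cluster means; the objective
Σ(1 − cos) never increases across iterations (asserted per-iteration in
tests). Defaults: `max_iter = 10`, multiple restarts keeping the
lowest-inertia model. Initializations: `cosine_plus_plus` (k-means++
seeding under cosine distance, the default), `similar_cut_like` (a
farthest-first approximation of fast similarity-based seeding: repeatedly
take the point with the smallest maximum similarity to the chosen seeds),
and `random`. An emptied cluster is re-seeded with the point farthest from
its current centroid — a deterministic repair. A minimum-document-frequency
centroid projection (`minimum_df_factor`, e.g. 0.05 = drop centroid terms
supported by fewer than 5% of member documents) applies only to
non-negative sparse term-frequency inputs; on dense coordinates it is a
logged no-op, since zeroing dense low-support coordinates has no
document-frequency interpretation.

k is chosen from the elbow (knee) of the inertia curve, with the
Calinski–Harabasz index and mean cosine silhouette reported per k from the
same fitted model; manual override is supported. CH uses
[B/(k−1)]/[W/(n−k)] on the normalized rows and returns +inf when W = 0;
silhouette gives singleton-cluster points a score of 0.

## In-Group Proportion

IGP_j = the proportion of test items assigned (by nearest training
centroid) to cluster j whose nearest *test* neighbor is also assigned to j.
Distances default to cosine, consistent with the clustering geometry; a
`one_minus_pearson` option mirrors correlation-based implementations.
Clusters with fewer than two assigned test items have an undefined
proportion: they are recorded as NaN, excluded from summaries, and logged,
so totals reconcile. Replicated runs draw a fresh uniform partition
(default ratio 1,937:1,645 ≈ 0.54 at n = 3,582), refit the clustering on
the training half, and summarize the defined per-cluster values with
linear-interpolation quantiles and sample SD (ddof = 1). The pipeline
computes IGP on the post-reduction coordinates by default, with the raw
embedding space available by flag.

## Taxonomy mapping

Category strings are the non-empty fields (category, subcategory 1–3,
definition) joined with ", ". Both sides are embedded with the same
encoder; the match threshold is the upper fence Q3 + 1.5·IQR of *all*
pairwise cosine similarities (the boxplot-outlier reading: declared matches
are outliers of the similarity distribution, roughly 3 SD above the mean
under normality). Edges require strictly greater-than; equality is
excluded. Coverage = percentage of categories with ≥ 1 edge; one category
may map to several reference measures. Quartiles use linear interpolation
between order statistics (the mainstream numerical default) rather than
Tukey hinges; the convention is recorded in the run manifest. Category keys
include the subcategory path so rows sharing a top-level category remain
distinct nodes.

## Synthetic data

`sample_vmf_mixture` draws component means uniformly on the sphere subject
to a minimum pairwise angle (default 75°), then samples each component from
a von Mises–Fisher distribution (κ = 0 falls back to uniform). The 75°
default makes "well separated" quantitative: at the reference concentration
κ = 40 in d = 10 the vMF angular spread is ≈ 27°, so 75° keeps planted
clusters more than twice their spread apart, and placing 6 such means in 10
dimensions succeeds quickly by rejection (90° does not). The default stress
scale mirrors the study: n = 3,582 split 1,937/1,645, with k well below n.
What the generator does *not* emulate: real embedding manifolds are neither
isotropic within clusters nor balanced across them, and real category
structure is hierarchical — so passing recovery tests shows the estimators
are correct under their stated model, not that any real corpus is this easy.

`generate_question_corpus` fills ≥ 2 paraphrase templates per category,
randomizes section paths, and injects exact duplicate wordings under
different paths at a configurable rate, so text-only dedup is strictly
coarser than path+text dedup on generated corpora.
`make_reference_taxonomy` emits one reference name per planted category
plus optional unrelated distractor names for end-to-end mapping tests with
known ground truth.

## Reproducibility

A single master seed fans out to per-stage seeds through numpy
`SeedSequence` spawn keys, so each stage can be re-run in isolation. The
run manifest is a flat, append-only JSON record of per-stage parameters,
seeds, software version, timestamps and SHA-256 hashes of every input and
output file; determinism is tested by re-running the full pipeline and
comparing hashes. Problem sizes in the test suite and acceptance script
(200-point LLE fixtures, 600-point recovery instances, the 3,582-item IGP
replication) were chosen as the smallest scales at which each property is
cleanly exhibited.

## Known limitations

- The fallback encoder is lexical; semantic claims require the external
  pretrained backend.
- LLE has no out-of-sample extension here; IGP classification of test items
  uses centroids in whichever space the clustering ran.
- Alternative reducers and clusterers (kernel PCA, Isomap, MDS, UMAP;
  spectral, bisecting k-means, linkage methods, BIRCH) are deliberately not
  implemented; the plug-in seams are the `Encoder` protocol and the
  stage-skipping config.
- The `similar_cut_like` initialization approximates the fast-seeding idea
  and is not a port of any specific implementation.
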