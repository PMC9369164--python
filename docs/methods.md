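# Methods

## The association statistic

For two diseases A and B, let `n(Q)` be the number of indexed documents
matching a Boolean query Q. The association value is the Jaccard index of
the two document sets:

    a(A, B) = n(A AND B) / n(A OR B)

The raw co-citation count `n(A AND B)` is dominated by heavily studied
diseases; normalizing by the union count removes that volume bias, shrinking
the association of highly cited diseases and lifting that of rarely cited
ones. By construction `a` lies in [0, 1]; `a x 100` can be read as an
approximate percent comorbidity. The statistic assumes co-mention noise is
random, so its signal-to-noise ratio grows roughly with the square root of
the co-citation count; restricting queries to the title, abstract and
other-terms fields (rather than full text) further suppresses incidental
co-occurrence.

No significance test is attached to individual associations: the filtering
floor (below) plays that role as a crude noise cut, which is a known
limitation.

## Queries and backends

Each disease is queried as its quoted name plus any synonyms, OR-ed, each
phrase restricted to `[tiab]` and `[ot]` (or `[All Fields]` when the
unrestricted mode is chosen). Quoted phrases suppress PubMed automatic term
mapping by default; this is configurable in spirit by editing the synonym
list. Phrases containing diacritics are sent in both the original and
ASCII-folded form, OR-ed, because indexing of diacritics is inconsistent.
Pair queries order their operands lexicographically by id, so the query
string and every cache key are invariant to argument order.

Counts come from a `CountBackend`: the live E-utilities backend (rate
limited to 3 requests/s without an API key, exponential backoff, not
snapshot-consistent), a query->count table dumped from a previous run, or a
simulated corpus. On snapshot-consistent backends the identity
`n_or = n_a + n_b - n_and` is enforced as an error; on the live backend a
violation is only logged, since PubMed grows between requests. All four
counts per pair are cached in a tab-delimited file keyed by (backend, pair,
field setting), making a full C(n, 2) sweep resumable.

## Matrix assembly and filtering

The association matrix is symmetric with a diagonal fixed at 1 by
convention (the diagonal is ignored by clustering and validation, which is
why the convention is harmless). Filtering happens in two stages:

1. **Disease exclusion** — curated exclusion ids, plus any disease with
   fewer singleton citations than `min_citations` (default 100). The
   default exists because a disease with essentially no literature produces
   unions near zero and meaningless ratios; the cut-off is a package
   choice, stated here because no canonical value exists.
2. **Association floor** — surviving cells with `a < 1e-5` are set to 0 and
   masked `floored` rather than removed, keeping the matrix square and the
   clustering input well-defined. At PubMed scale (~3x10^7 documents) an
   association of 1e-5 corresponds to a handful of co-citations, i.e.
   indistinguishable from noise.

Both stages are reported row-by-row (item, reason, value); filtering never
increases a cell value.

## Classification

Diseases are clustered by agglomerative hierarchical clustering (average
linkage by default) on one of two distances:

- `correlation` (default): `d(i, j) = 1 - r(row_i, row_j)` with the two
  diseases' own columns excluded pairwise, so the conventional diagonal
  never contaminates the profile comparison. This matches the default
  behaviour of common heatmap-clustering web tools. A constant profile has
  no defined correlation; its distances are set to the maximum (2) with a
  warning.
- `one-minus-association`: `d = 1 - a`, the direct reading of "association
  distance".

Labels are sorted lexicographically before linkage so ties resolve
identically regardless of input order, and optimal leaf ordering is applied,
making the heatmap layout deterministic and permutation-invariant. The flat
partition cuts the dendrogram at `k` clusters (default k = 10, matching the
roughly ten affected systems the disease taxonomy distinguishes:
gastrointestinal, neuronal, eye, cutaneous, musculoskeletal, kidneys and
lungs, cardiovascular, hematopoietic, endocrine, multiple) or at a height.
Cluster annotation summarizes term metadata (majority system label, mean
female fraction, mean onset age, mean prevalence) per cluster, ordered by
leaf order for rendering.

## Validation

A predicted matrix is compared to an independent reference comorbidity
matrix by correlating the upper-triangle off-diagonal values over the
shared label set (aliases map reference labels onto term ids; at least 3
shared labels are required). The diagonal is excluded because
self-association is a convention, not an observation. Pearson is the
default reading of a reported "R"; Spearman is available as a sensitivity
check. Identical vectors short-circuit to exactly 1.0 rather than
accumulating rounding error through the normalization. Reference values
published only as figures must be supplied by the user as a delimited
matrix; the package ships no figure-read numbers.

## The synthetic corpus model

Real per-pair counts cannot be reproduced offline, so the test surface is a
generative stand-in with known truth. Each document independently:

1. activates one of `n_blocks` "system" topics uniformly at random (with
   probability `block_topic_prob`, default 1);
2. mentions each disease independently with probability
   `base_prob x within_block_boost` if the disease's block is active, else
   `base_prob x between_block_boost`.

Base probabilities are log-normal (`exp(N(log 0.01, 1))`, clipped to 1),
giving the heavy-tailed citation totals real literatures show. Defaults:
50 diseases, 5 blocks (round-robin assignment), 20,000 documents, boost
ratio 10:1, seed-deterministic bit for bit. Boosted probabilities above 1
are clipped with a warning; with the default tail this happens routinely
and corresponds to a saturated, always-mentioned "hot" disease. Setting
both boosts equal removes the block effect exactly, reducing the model to
independent mentions with a closed-form expected association
`p_a p_b / (p_a + p_b - p_a p_b)` — the calibration point used by the
generator's own tests. Gender skew is block-level metadata only; it shapes
annotations, never counts.

What the model does **not** emulate: MeSH indexing, synonym ambiguity in
real text, publication-date drift, inter-paper citation structure, and any
correlation between citation volume and block membership. Passing tests
therefore demonstrate the pipeline's correctness and statistical behaviour
under block-structured co-mention, not the fidelity of PubMed counts.

The synthetic reference matrix is the corpus's true empirical association
matrix plus independent symmetric Gaussian noise clipped at 0 — an
idealized external study measuring the same quantity with error.

## Calibrated quantities and problem sizes

- **Validation noise band.** On the calibration corpus (generator defaults,
  corpus seed 101), `noise_sd = 0.0127` was chosen from the analytic
  attenuation `sd_x * sqrt(1/0.9^2 - 1)` targeting R ~ 0.9; a 1000-replicate
  Monte-Carlo run gave R = 0.92485 +- 0.00354 (clipping at zero lifts R
  slightly above the analytic target). The frozen acceptance band is
  mean +- 6 sd = [0.9036, 0.9461].
- **Cluster recovery** is scored over 100 generator seeds at the default
  study conditions; the package's own acceptance bar is ARI >= 0.9 in at
  least 95% of seeds.
- **Oracle equivalence** uses corpora of <= 1,000 documents and <= 20
  diseases, where brute-force per-document set scanning is fast and exact
  agreement (not approximate) is asserted.

## Numerical choices

- Associations are computed once per unordered pair and mirrored, so the
  matrix is symmetric to exact equality, not to tolerance.
- The empirical-association oracle computes the intersection-count matrix
  via float64 BLAS matmul; counts are far below 2^53, so the result is
  exact after rounding.
- Matrix exports print floats with `np.format_float_positional(unique=True)`
  and are read back with round-trip float parsing, so write/read is
  lossless and exports are byte-stable.
- Chord-link rows sort by descending width, then lexicographic source and
  target; ranking for the "top co-cited" subset uses total singleton
  citation count with lexicographic tie-break.
- `1 - r` distances are clamped at 0 to absorb 1-ULP negative values.

## Known limitations

- The live backend's counts drift over time; downstream provenance records
  backend id and retrieval timestamps, but two live runs will not agree
  exactly.
- The association floor and citation minimum are heuristics, not tests; a
  cell just above the floor is not statistically distinguishable from one
  just below it.
- Correlation distance is undefined for diseases whose profile is constant
  (typically all-zero after flooring); such diseases receive maximal
  distance and end up as late-merging singletons, which is a rendering
  convention rather than evidence of dissimilarity.
- PCA-based classification is deliberately not implemented; hierarchical
  clustering is the classification surface.
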