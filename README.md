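# aidmap

Disease association networks from literature co-citation.

Many autoimmune diseases co-occur in the same patients, but systematic
comorbidity data are sparse and scattered. `aidmap` estimates the pairwise
association of diseases directly from the literature: for diseases A and B
it counts indexed documents mentioning each and both, and scores

    association(A, B) = n(A AND B) / n(A OR B)

— the Jaccard index of the two document sets, which normalizes away the
citation-volume bias of raw co-citation counts. Multiplied by 100, the
value reads as an approximate percent comorbidity. The package assembles
these values into a symmetric association matrix over a curated disease
list, filters out noise-level associations (< 1e-5) and under-cited
diseases, classifies diseases into affected-system clusters by
hierarchical clustering of association distances, validates predictions
against independent reference comorbidity matrices, and exports ordered
heatmap matrices and Circos-style chord-link tables.

It is written for researchers mining bibliographic databases for disease
co-occurrence (autoimmune diseases are the motivating case, but nothing is
specific to them) and for anyone needing a fully offline, testable
re-implementation of this kind of co-citation pipeline.

Counts come from pluggable backends: live NCBI E-utilities (rate-limited,
cached, resumable), a cached query-count table, or a simulated corpus. The
simulator plants known "affected system" blocks with boosted within-block
co-mention and heavy-tailed citation totals, so every pipeline stage can be
verified against ground truth without network access.

## Worked example

```python
import aidmap as am
from sklearn.metrics import adjusted_rand_score

# a simulated literature: 12 diseases in 3 "system" blocks, 5000 papers
spec = am.SyntheticCorpusSpec(n_diseases=12, n_blocks=3, n_documents=5000, seed=8)
corpus = am.generate_corpus(spec)
backend = am.corpus_backend(corpus)          # snapshot-consistent counts
terms = [am.DiseaseTerm(d, d) for d in corpus.disease_ids]

matrix, counts = am.matrix_from_backend(terms, backend)
pc = counts.pair_map()[am.pair_key("d07", "d10")]
print(pc.n_a, pc.n_b, pc.n_and, pc.n_or)     # 482 456 102 836
v = matrix.value("d07", "d10")
print(round(v, 4), round(am.to_percent_comorbidity(v), 2))  # 0.122 12.2

filtered, report = am.apply_filters(
    matrix, am.FilterPolicy(min_citations=50), counts.singletons
)
print(filtered.n, len(report))               # 10 6

result = am.classify(filtered, k=3)
truth = [corpus.truth[l] for l in result.labels]
pred = [result.flat_labels[l] for l in result.labels]
print(adjusted_rand_score(truth, pred))      # 1.0

ref = am.reference_from_truth(corpus, noise_sd=0.01, seed=4)
print(round(am.validate(filtered, ref).r, 3))  # 0.912
```

Reading the numbers: diseases d07 and d10 share 102 of 836 papers, an
association of 0.122 (&asymp; 12% comorbidity) — they sit in the same planted
block. Filtering drops 2 of the 12 diseases (fewer than 50 citations) and
records every action in the report. Clustering the filtered matrix at k = 3
recovers the planted blocks exactly (adjusted Rand index 1.0), and the
prediction correlates at R = 0.91 with a noisy synthetic reference matrix.

For real PubMed counts, replace the backend:

```python
backend = am.EntrezBackend(email="you@example.org")   # needs network
cache = am.CountCache("counts.tsv")                   # resumable
matrix, counts = am.matrix_from_backend(am.training_terms(), backend, cache)
```

`am.training_terms()` ships a small editable seven-disease list (systemic
lupus erythematosus, Sjögren's syndrome, type 1 diabetes, autoimmune
thyroid disease, rheumatoid arthritis, multiple sclerosis, systemic
sclerosis); `am.load_terms()` reads your own list with synonyms and
metadata.

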