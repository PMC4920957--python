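# Methods

## Model and assumptions

The pipeline treats a corpus of short messages as a weighted bag-of-words
matrix and summarizes it by a sequence of cardinality-constrained rank-1
components. Two modeling assumptions are load-bearing and inherited by
everything downstream:

1. **Bag of words.** Word order and syntax are discarded; all structure the
   method can see is co-occurrence of terms across messages. Terms with
   multiple senses are represented by their dominant usage pattern; minority
   senses are invisible unless they dominate a residual.
2. **One topic per message.** Each extracted component *consumes* its top
   associated documents (their rows are zeroed from the residual), which is a
   hard clustering: a message can illustrate at most one topic. For
   ~140-character messages this is usually adequate; for longer mixed-content
   text a mixed-membership model would be more appropriate and is explicitly
   out of scope.

## Normalization (preprocess)

Rules, in order, per whitespace chunk: a leading `RT` marker is stripped and
flagged; `@`-prefixed chunks are dropped (user names are not content); URL-
shaped chunks are dropped (`http(s)://`, `www.`, or a domain/path shape);
remaining text is lowercased and split on everything except `#` and
intra-word apostrophes; hashtags are kept verbatim with their `#` and are
exempt from stop-word removal (the tag itself is topical); single-character
tokens and stop-words are dropped. The 179-word English stop list (plus
contracted forms, plus the extra token `rt`) is frozen as a text file inside
the package so results do not drift with library versions. Normalization is
idempotent on its own output — property-tested under fuzzing.

Duplicate collapsing merges records that are linked by retweet ids
(transitively; a retweet whose original is missing stands alone) or that have
identical non-empty normalized token sequences. The earliest member donates
id, timestamp and tokens; the group size becomes the document multiplicity.
Empty token sequences are never merged by content: two messages that
normalize to nothing carry no evidence of being the same message.

## Weighting (term_matrix)

Entry (i, j) = √multiplicityᵢ × tf(term j in doc i). The square root makes a
message repeated c times contribute exactly c times the squared-Frobenius
mass of a singleton, which keeps the variance-explained accounting
interpretable as "fraction of message-weighted word mass". Raw counts are the
default tf (a log1p mode exists for robustness checks); no IDF is applied.
Document-frequency pruning defaults to min_df = 2 (hapax terms cannot form
co-occurrence patterns) and max_df = 0.95 of documents (near-ubiquitous
terms, typically the collection query phrases themselves, would otherwise
leak into every component). Both are configurable; an option to stop-list
the query phrases outright exists and is off by default.

## Sparse rank-1 extraction (spca)

Each topic solves max ‖Xv‖ s.t. ‖v‖=1, ‖v‖₀ ≤ k (default k = 5) by truncated
power iteration: u ← Xv/‖Xv‖, w ← Xᵀu, keep the k largest-|·| entries of w
(ties toward the lower column index), renormalize; stop when σ changes by
≤ tol (default 1e-9, cap 500 iterations). The support search is NP-hard and
truncated power iteration is a local heuristic, so the solver runs a
deterministic multi-start family and keeps the best σ:

- the 10 columns of largest norm (the classic max-column start);
- each such column's hard-thresholded Gram column XᵀXeⱼ — a one-step
  lookahead that starts from a column *plus its strongest partners*;
- a greedy forward-selected support (grow the support one column at a time
  by maximal leading eigenvalue of the restricted Gram block);
- the hard-thresholded dense leading right singular vector.

The Gram-based starts are gated to ≤ 2000 columns, where the Gram matrix is
cheap; above that the column starts carry the search. On 1000 random 6×10
non-negative integer matrices with k = 3 this family attained the
exhaustive-enumeration optimum (over all 120 supports) in every case; the
acceptance script re-measures that agreement on every run. There is no
randomness anywhere in the solver: given the same matrix and configuration
the fit is bitwise reproducible, and shuffling document rows permutes only
document ids, not topics.

Document association scores are |row·v| (a signed-score mode exists); the
top m rows with positive score (ties toward the earlier document) become the
topic's examples and are zeroed from the residual. When fewer than m rows
score positive — typical after heavy retweet collapsing — the topic simply
reports fewer examples. σ is recorded from the residual at extraction time,
so it measures the topic's prevalence in what remained of the corpus, and
extraction order can shuffle slightly relative to the σ ranking (a sparse
approximation, not an exact SVD ordering).

Stopping: residual ‖·‖²_F ≤ 5% of the original, or 200 topics, or no signal
left. An all-zero matrix yields an empty model rather than an error.

## Model selection (model_selection)

e_t = 1 − residual²_F(t)/‖X‖²_F, computed exactly from the norms stored
during fitting. Settings m ∈ {10, 15, 20} are fit independently from the
same matrix and compared by whole curves plus one scalar: topics needed to
reach 90% explained variance (threshold configurable). Winner: fewest topics
to threshold, ties toward higher coverage at that point, then smaller m —
matching the preference for the most parsimonious per-topic reading load.
On block-disjoint corpora the removal sequences for different m nest (a
larger m removes a superset of rows at every step), so the curves dominate
each other exactly; with cross-cutting background terms the dominance is
only a strong tendency.

## Synthetic corpora (synthetic)

The generator's defaults are the package's reference study conditions: 5
topics × 5 disjoint keywords × 40 documents; background vocabulary of 100
filler terms; 6–12 tokens per document, 80% drawn from the document's single
keyword set; 20% of base documents pure-background contamination; 5%
mislabeled non-English documents (scrambled tokens from a disjoint
pseudo-vocabulary, language-tagged "en", mirroring how imperfect platform
language tags leak foreign-language content into an "English" corpus);
retweet duplication with geometric duplicate counts of mean 1.5 (mean
multiplicity 2.5); and a two-period timeline split at 2012-03-14 with twice
the baseline volume afterwards. Contamination and non-English counts are
fractions of the *total* base-document count with deterministic rounding, so
80 on-topic documents at 20% contamination give exactly 100 base documents.
Off-topic and non-English documents carry a collection query phrase with
probability 0.5 (how irrelevant content enters a keyword-collected stream);
on-topic documents do not by default, so pipeline runs on synthetic corpora
skip the keyword filter (`use_query=False` / `--no-query`). Topics can be
restricted to the follow-up period to plant an event-driven topic.

What the generator does **not** emulate: real lexical diversity (Zipfian
vocabulary, misspellings, slang), hashtag virality, user networks,
correlated topic drift, or messages mixing topics. Passing the recovery
tests therefore shows the machinery is correct and well-conditioned under
the stated noise sources, not that real corpora are this easy: real topics
overlap in vocabulary and their keyword sets are not known, which is exactly
why the human coding stage exists.

## Numerical and reproducibility choices

- All tie-breaks (thresholding, document scoring, winner selection) resolve
  toward the lower index/smaller setting and are documented in docstrings.
- Residual norms are tracked from the sparse data directly; an independent
  dense replay of the removals agrees to 1e-12 relative (tested and
  re-measured by the acceptance script).
- Outputs are byte-deterministic: JSON is written sorted, the run log
  records stages and counts but no wall-clock times, and plots are rendered
  with the Agg backend and fixed metadata.
- Test and acceptance problem sizes (≈250–650 records per corpus, 20 seeds
  per experiment, 100 oracle matrices) were chosen so the whole suite
  exercises every stage end-to-end in well under a minute each while keeping
  the exhaustive oracles exact.

## Known limitations

- The solver is a heuristic for an NP-hard problem; optimality is verified
  exhaustively only at small scale.
- Hard clustering makes topic content depend on m (tweets per topic);
  the model-selection module exists precisely to expose that dependence.
- The singular-value scale depends on corpus size and weighting, so σ is
  comparable within one fitted model, not across corpora.
- Period boundaries are inclusive UTC calendar dates; sub-day event timing
  is not modeled.
- Language filtering trusts the corpus language tags; no language detection
  is performed (mislabeled content is surfaced as its own topics, to be
  discarded by the human coder).
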