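# Methods

## The normalization heuristic

Biomedical corpora prepared for embedding typically have their domain
concepts already collapsed: annotation pipelines replace multi-word terms
and their synonyms ("myocardial infarction", "heart attack") with a single
identifier token. `synnorm` applies the same idea to the *general*
vocabulary that surrounds those concepts.

Let f(w) be the corpus frequency of token w (every occurrence counts) and

    mu = total_tokens / vocab_size

the mean frequency per distinct token. The replacement threshold defaults
to tau = mu (a `multiplier` scales it; the sweep {0.5, 1, 2, 4}×mu covers
conservative through aggressive regimes). Note mu is a mean over *types*,
not occurrences — the occurrence-weighted mean would be orders of
magnitude larger and would mark nearly the whole vocabulary as
"infrequent".

The plan builder:

1. Candidates R = unprotected tokens with f(w) < tau. Frequent words are
   presumed meaningful and left alone.
2. For each candidate, its synonym pool is the union of lemma names over
   all of the word's synsets across all parts of speech, lowercased, with
   any lemma that cannot be a single corpus token (whitespace, underscore,
   apostrophe, hyphen) dropped. No word-sense disambiguation: the pool
   deliberately merges senses, because the replacement target is chosen by
   corpus frequency, not by sense.
3. s_max = argmax over the pool of f(s), with pool members absent from the
   corpus scoring 0 and ties broken lexicographically (determinism).
4. w is mapped to s_max only if f(s_max) >= tau and s_max != w. A rare
   word whose synonyms are all rare is presumed to carry specific,
   discriminative meaning and is retained; so are candidates with no pool.
5. The plan is applied in a single pass with frequencies held fixed.

Consequences used as invariants: sources are strictly below tau and
targets at or above it, so sources and targets are disjoint, chains cannot
form, application is idempotent, token counts are conserved and the
vocabulary never grows.

Protected tokens (default regex `^(mesh|ncbigene|omim|cid)_?[a-z0-9]*\d`)
are never candidates. Concept identifiers would not have synonym entries
anyway; the explicit predicate makes the guarantee independent of the
synonym resource. The default is belt-and-braces, and configurable for
other identifier conventions.

Numerals are not filtered: a corpus that still contains "13", "thirteen",
"xiii" will have the variants consolidated onto the dominant form, which
is the worked example shipped in `data/example_synonyms.tsv`. Upstream
pipelines that strip numerals simply never present such candidates.

## Synonym backends

The fixture TSV backend is authoritative for tests: lookup equals the
table row exactly, so results do not depend on a lexical-database version.
The WordNet backend (optional `nltk` extra) applies the identical
normalization to live synset lookups. Both return an empty pool for an
unknown word — absence is information, not an error.

## Embedding trainer

Skip-gram with negative sampling, implemented as a single-threaded numba
kernel. Defaults follow common practice for this evaluation setting:
dim 128, window 10 (effective window shrunk uniformly per position),
min_count 1 (identifier tokens are often rare and must stay in the
vocabulary), 5 negative samples from the unigram^0.75 distribution,
learning rate linear from 0.03 down to 0.0001, frequent-word downsampling
threshold 1e-3, 5 epochs. The downsampling threshold and epoch count are
the conventional defaults, exposed in `EmbeddingParams`; tests use smaller
dimensions for speed.

Single-threading is a deliberate trade: with a fixed seed the trainer is
run-to-run deterministic on one machine, which the null-control experiment
depends on (identical corpora must give bitwise-identical spaces).
Bitwise reproducibility across platforms is not promised. Vector I/O uses
the standard word2vec text format.

## Coherence evaluation

For a concept set with n members present in both spaces, coherence is the
mean of d(u,v) = 1 − cos(u,v) over all n(n−1)/2 unordered pairs; smaller
means tighter. Cosine *distance* (1 − similarity) is used throughout so
"smaller = more coherent" reads consistently; an angular metric would
order pairs identically.

Sets are filtered to those with ≥ 5 members present in **both**
vocabularies and restricted to that shared subset, so the two distance
lists are matched pair-for-pair. The per-set test is a paired two-sided
t-test on the matched lists — pairing is the natural choice since the
identical concept pairs exist in both spaces; Welch's unpaired test is
available via `paired=False`. Zero variance of the differences (e.g.
comparing a space to itself) is reported as p = 1 with a degenerate flag
rather than NaN. alpha = 0.05, with no multiple-testing correction; the
per-category summaries count wins among significant sets and among all
sets separately, which is the honest way to read a marginal effect.

The whole-space diagnostic samples distinct-token pairs uniformly with
replacement (10,000 by default; the same machinery scales to millions),
and reports ECDFs on a shared grid, matched Q-Q quantiles and the
two-sample Kolmogorov–Smirnov statistic. Each space is sampled by a
generator started from the same seed, so comparing a space to itself
yields KS = 0 exactly.

Statistics are computed from their formulas (scipy supplies only the t
distribution CDF); the test suite cross-checks t, Welch and KS values
against scipy's independent implementations to 1e-10.

## Synthetic benchmark

The generator emulates exactly the features the heuristic exploits:

* topic-linked **concept identifier** tokens (`cid_t<k>_c<i>`, protected
  by the default regex) at rate `concept_rate` per position — each
  topic's concepts form one evaluation set;
* topic-linked **synonym classes** whose member at each use is drawn from
  a Zipf law (rank^−s), so one member dominates and the rest are rare —
  this is what makes "most frequent synonym" well-defined; the generator
  emits the matching fixture resource;
* Zipf-distributed shared **filler** words as background. Half of
  non-concept positions are class words, half filler (a fixed generator
  constant, not a parameter under study).

Defaults: 10 topics × 200 documents × 50 tokens, concept_rate 0.3,
8 concepts/topic, 10 classes of 5 members with exponent 1.5, 100 fillers
(~100k tokens, vocabulary 230, mu ≈ 435). The filler count was sized so
that dominant class members stay above 4×mu while deep ranks fall below
0.5×mu — the threshold sweep then spans all regimes and the replaced
count grows monotonically (10 → 30 → 40 → 40 at 0.5/1/2/4 × mu, seed 0).

What the generator does **not** model: real English word order and
syntax, polysemy (class members are interchangeable by construction),
annotation noise, and document-length variation. Passing tests therefore
demonstrate the algorithm's correctness and the direction of its effect
under controlled conditions, not its effect size on real literature.

## End-to-end effect and its variance

`end_to_end_experiment` runs generate → count → plan → apply → train both
corpora (same embedding seed) → filter → compare → summarize. At the
default configuration (dim 32 for speed) and seed 0, the normalized space
is tighter in 6 of 10 concept sets; that value is pinned as a seeded
regression. Across other seeds the winner count ranges from 1 to 6 of 10:
at ~100k tokens the replacement effect is of the same order as the
stochastic training noise, so only its direction — not a stable
magnitude — is meaningful, and even at six orders of magnitude more data
this class of experiment reports per-category win rates of only roughly
50–60%. The null control (tau = 0) is exact: an empty plan leaves the
corpus untouched and the seeded trainer reproduces the identical space,
so every comparison is a tie.

## Numerical and degenerate-input choices

* Empty corpus: frequency table flagged `empty`, mean 0; deriving a
  threshold from it raises.
* Candidates with empty pools are retained and counted
  (`n_retained_no_pool`), separately from the all-infrequent retention.
* argmax ties: lexicographic, so plans are reproducible.
* Mean pairwise distance requires ≥ 2 present members and rejects zero
  vectors (undefined cosine).
* Distance computations are done in float64 regardless of stored vector
  precision.
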