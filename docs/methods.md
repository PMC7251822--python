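# Methods

This note documents the models and procedures implemented in `pxinsight`,
the defaults chosen where the method leaves room, and what the synthetic
experiments do and do not demonstrate.

## Text reduction chain

Raw answers pass through: lowercase cleaning (non-letters become spaces;
intra-word hyphens/apostrophes survive; abbreviations expanded from a
word→expansion map) → Norvig-style spell correction → Porter stemming →
stopword removal → corpus frequency floor → tf-idf.

* **Spell correction.** A token found in the frequency dictionary is kept;
  otherwise the highest-frequency dictionary word at edit distance 1 wins,
  then distance 2, then the token itself. Edits are insert / delete /
  substitute / transpose over `a–z'-`; frequency ties break
  lexicographically for determinism. The bundled dictionary is composed
  from the package's word lists with deterministic, banded synthetic
  frequencies (stopwords highest); `augment_dictionary` lifts corpus tokens
  occurring more than a threshold (default 100) into it, the mechanism for
  domain-specific vocabulary.
* **Stemming.** A from-scratch implementation of the original Porter
  algorithm (validated against classic input/output pairs). Note that
  suffix strippers are not idempotent on their own outputs (`nurse → nurs`,
  but `nurs → nur`), so the reduction chain as a whole is only exactly
  idempotent with the identity stemmer; this is a property of the
  algorithm, not an implementation defect. Stopword filtering compares both
  the surface token and its stem against the (stemmed) stopword list.
* **Frequency floor.** Terms with fewer than `min_word_count` (default 20)
  occurrences in a question's corpus are dropped. Corpora are built per
  question: Q1 and Q2 are modelled separately throughout.
* **tf-idf.** Several conventions exist; this package uses smoothed
  `idf = ln((1+N)/(1+df)) + 1` with L2 row normalization (computed by
  scikit-learn's `TfidfTransformer`). Documents left token-less keep an
  all-zero row — no response is ever dropped.

Tokenization is whitespace splitting after cleaning. Sentiment scoring
(below) deliberately runs on cleaned but **unstemmed** tokens, because
stemming destroys the adjectives a lexicon keys on.

## Topic model

NMF minimizes the Frobenius loss ‖V − W·H‖ with multiplicative updates
(denominator guard 1e-12), NNDSVDa initialization (nonnegative double SVD,
zeros filled with the matrix mean — deterministic; a seeded random init is
available), `max_iter` 500, and convergence when the per-iteration loss
decrease falls below `tol` (1e-4) × the initial loss. Multiplicative
updates guarantee a non-increasing loss, which the tests check directly.

**Model selection.** Models are fitted for every K in `[k_min, k_max]`
(defaults 4–100, stride configurable, K capped at min(n_docs, n_terms)) and
scored by mean topic coherence: the mean pairwise NPMI of each topic's
`top_n` = 10 descriptors, estimated from binary document co-occurrence.
Conventions: a pair that never co-occurs scores exactly −1; words appearing
in every document score +1; topics with fewer than `top_n` positive-weight
terms use what they have (warning logged). Highest mean coherence wins,
ties to the smaller K.

A caveat observed on planted synthetic corpora: coherence discriminates
sharply *above* the true K (split topics import never-co-occurring noise
descriptors, NPMI −1) but only weakly *below* it, because a merged NMF
topic's top descriptors can still come almost entirely from one planted
topic. Occasionally the scan therefore selects a K below the planted count
even though the K-true model recovers the planted structure perfectly.

**Assignment.** Each document gets its argmax-weight topic (ties to the
lowest index); all-zero rows — responses empty after preprocessing — are
UNASSIGNED. No additional minimum-weight cut-off is applied. Topic labels
are the argmax-H vocabulary terms.

## N-gram subtopics

Within each topic's assigned responses, all contiguous 2-, 3- and 4-grams
of the stemmed token stream are counted; n-grams without at least one noun
(bundled noun-list lookup on stems; any word→bool test can be plugged in)
are discarded; the top 20 by count (ties: longer n, then lexicographic)
become candidates. For display, each stem n-gram carries its most frequent
surface rendering. Every assigned response is matched to the candidate
maximizing the normalized Levenshtein similarity
`100·(1 − dist/max(len))` — computed with edlib — between the candidate and
any contiguous token window of the response (partial-ratio semantics);
below a floor of 60/100 the response keeps its topic but no n-gram. The
floor is a documented operationalization: the method's description does not
state whether every response was forced onto an n-gram.

## Sentiment

Each lexicon word in a response contributes its polarity (plus any override
adjustment, clamped to [−1, 1]); intensifiers among the 2 preceding tokens
multiply the contribution by their factor, and any negation in that window
flips it once by ×(−0.5) (pattern-library convention; window and factor
configurable). The response score is the mean contribution, clamped;
responses without lexicon words score 0.0. Categories: negative < 0.0,
neutral 0.0–0.1 inclusive, positive > 0.1 — boundary values are neutral so
the three intervals partition [−1, 1].

Domain adjustment: words occurring > 50 times with |polarity| > 0.5 are
flagged for review; the bundled override template adjusts eight words by
±0.3 (disease, ill, painful, nauseous up; help, remarkable, waiting,
complicated down), the canonical corrections for hospital-survey text where
a general lexicon misfires. The bundled lexicon is a ~100-adjective English
fixture; any language's resources can be supplied as TSV/plain-text files.

## Prioritization

Per n-gram: frequency = matched responses, mean sentiment = arithmetic mean
of their scores. With Q2 = median and Q3 = third quartile of the frequency
distribution (linear interpolation, computed per question):

* improve: freq > Q3 and sentiment < 0.0
* celebrate: freq > Q3 and sentiment > 0.1
* monitor: freq > Q3 with 0.0 ≤ sentiment ≤ 0.1, or Q2 < freq < Q3 with
  sentiment < 0.0
* none: everything else (inequalities are strict exactly as written)

Impact defaults to the risk-style product frequency × |mean sentiment|,
rescaled within each question to a maximum of 100, with a pluggable scorer
interface; ranking within category is impact-descending (ties by frequency,
then text), top 5 per category reported. Both questions are plotted in one
matrix with distinct markers; quartiles stay per-question.

## Transferability and validation

* **Assignment-rate test.** Expected assigned/unassigned counts for the new
  sample derive from the reference proportions; Pearson chi-square over the
  2 categories has df = 1.
* **Topic overlap.** Greedy one-to-one matching of topics by Jaccard
  similarity of top-10 descriptor sets (stems), floor 0.2. Shared fraction
  = 2·matches/(K_a+K_b); unique fractions are per model. This is a
  documented operationalization of "similar topics", not a claim about how
  any particular study judged similarity.
* **Fleiss' kappa.** Computed via statsmodels from the subject×category
  count table; an all-one-category table (chance correction degenerate but
  agreement perfect) is defined as κ = 1. The 95% CI is κ ± z·SE with the
  Fleiss–Nee–Landis large-sample SE; percent agreement is the share of
  subjects on which all raters coincide.

## Synthetic surveys

The generator emulates short inpatient-survey answers: alternating Q1/Q2
docs; per-doc length 1 + Poisson(mean − 1) with mean 12 words (such surveys
average roughly 8–25 words per answer); 6 planted topics of 10 nouns each,
drawn from the bundled noun list after de-duplicating by Porter stem so the
planted sets stay disjoint downstream; ~35% stopwords; one
polarity-consistent sentiment adjective per answer (Q1 mostly positive, Q2
mostly negative, occasional intensifier); 15% of answers empty or
stopword-only (these must end UNASSIGNED); 5% per-token single-character
typos, matching the reach of the edit-distance corrector. All randomness
flows from one seed; identical parameters and seed give byte-identical
output.

What passing synthetic tests shows: the machinery is correct — planted
structure is recovered, rules and statistics match independent oracles,
runs are deterministic. What it does not show: performance on real
free text, which has grammar, multi-topic responses, dialect and
orthographic noise far beyond single-character typos, and no disjoint topic
vocabulary. The generator is a test harness, not a simulation of patients.

## Numerical and degenerate-input choices

* NMF denominator guard 1e-12; loss monotonicity asserted to 1e-9 relative.
* NPMI: exact −1 for zero co-occurrence, +1 for ubiquitous pairs (avoids
  0/0), otherwise the plain estimator, clipped to [−1, 1].
* Quartiles by linear interpolation (numpy default); a single-record set
  makes Q2 = Q3 = its frequency, and the literal strict inequalities land
  it in "none".
* Spell-correction and fuzzy-match ties break by frequency/count then
  lexicographically, so every stage is deterministic.
* Empty documents: zero tf-idf rows, UNASSIGNED topics, sentiment 0.0
  (neutral); they stay in every table so accounting always closes.
* Problem sizes in tests and the acceptance script (1,000-response
  pipeline runs, K scans to 10–12, 500-doc recovery experiments, 1,000
  simulated rater panels) are chosen so the full suite completes in a few
  minutes on one CPU while still exercising every stage at realistic scale.

## Known limitations

* One topic and one sentiment score per response; multi-topic answers are
  assigned their best-fitting topic only.
* Coherence-based K selection is weakly discriminative below the true K
  (see above).
* The bundled English resources are fixtures: small lexicon, synthetic
  dictionary frequencies. Production use should supply a real
  word-frequency list and lexicon for the target language.
* Impact is a package default (frequency × |sentiment|, max-100 rescaling);
  alternative weightings plug in via the scorer interface.
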