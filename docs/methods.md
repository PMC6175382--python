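# Methods

This note records the models implemented in `screenprio`, the defaults and
why they were chosen, the numerical decisions taken where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Text processing

References are split into title and abstract documents, tokenised on
non-alphanumeric boundaries (hyphenated words split, lemmas lowercased).
Lemmatisation is pluggable; the shipped default is a deliberately minimal
rule-based English lemmatiser (plural stripping `-ies→-y`, sibilant `-es`,
trailing `-s`; verb suffix `-ised/-ized → -ise/-ize`). The rationale is
determinism and transparency: a biomedical tagger would lemmatise better,
but residual inflection mostly fragments rare vocabulary entries that fall
below the frequency cut-off anyway, and a deterministic lemmatiser makes
every downstream artefact reproducible byte for byte. Part-of-speech tags
are coarse suffix heuristics consumed only by the term extractor.

The vocabulary keeps lemmas whose **total collection frequency** is at least
`min_count` (default 5) and which are not on the stop list shipped in the
package data (hashable, versioned with the package). Pure-numeric and
single-character tokens are excluded by decision; this is flagged as a
sensitivity point, not a principled choice. Column order is lexicographic,
so the vocabulary is invariant to reference order.

## Feature representation

Three concatenated blocks per reference, in fixed order:

1. title TF-IDF, 2. abstract TF-IDF, 3. LDA topic proportions θ.

TF is the raw within-field count; IDF is the smoothed
`ln((1+N)/(1+df)) + 1`, which avoids a zero weight at `df = N` and division
problems at the margins. Both bag-of-words blocks are L2-normalised so each
non-empty row has unit sum of squares; the topic block is a probability
simplex and is left un-normalised — normalising a simplex vector would
discard its interpretation as proportions and the two conventions differ
only by a bounded row-scale factor.

## Topic model

LDA is fitted by collapsed Gibbs sampling with
`p(z=k) ∝ (n_dk+α_k)(n_kw+β)/(n_k+Vβ)` and
`θ_dk = (n_dk+α_k)/(L_d+Σα)`. Defaults: K = 300 topics, symmetric
α = 1/K, β = 0.01, with a symmetric-α Minka fixed-point update every 50
sweeps (`optimise_interval=0` disables it). K = 300 suits collections of a
few thousand references; tests and simulations use K between 2 and 15,
which is appropriate for corpora of a few hundred documents built from a
handful of themes. Asymmetric-prior optimisation is deliberately not
implemented: the symmetric update is deterministic, cheap and sufficient
for the feature-block role of θ. Each topic is summarised by its 5 most
frequent words and its 45 most associated references (association = θ[d,k],
ties broken by reference id). Inference for a new document Gibbs-samples its
token assignments with topic-word counts frozen and averages θ over the
second half of the sweeps; a document with no in-vocabulary tokens receives
the prior proportions. The Gibbs inner loop is numba-compiled and seeded,
so fits are bit-reproducible for a given seed.

## Relevancy classifier

An L2-regularised squared-hinge linear SVM solved in the dual by coordinate
descent (liblinear through scikit-learn), cost C = 1 and tolerance ε = 0.1 —
the standard defaults for this solver family, adequate because ranking, not
calibrated probability, is the consumed output. The intercept is included
via the augmented-feature formulation and is therefore (weakly) regularised,
which is the solver's native behaviour. Decision values map to inclusion
confidences through the logistic function; a user-chosen threshold (≥, so
the boundary includes) produces include/exclude predictions. Rankings sort
unscreened references by confidence with ties broken by reference id.
Class weighting is deliberately absent: under relevancy-based active
learning the training set self-balances as the highest-confidence
references are screened first.

A screening session refuses to train until both an inclusion and an
exclusion have been recorded (cold start) and exposes a random-sample
picker for the initial batch. Retraining is explicit; a reminder flag
raises after 25 decisions without an update. Feature blocks are computed
once at ingest and reused across retrains.

## Descriptive clustering

Spectral clustering follows the symmetric-normalisation convention: top-k
eigenvectors of `D^{-1/2} X Xᵀ D^{-1/2}` (cosine similarities of combined
title+abstract TF-IDF rows), rows normalised to the unit sphere before
k-means. The similarity matrix is never formed; the Lanczos eigensolver
applies `v ↦ D^{-1/2} X (Xᵀ (D^{-1/2} v))` with degrees computed as
`X (Xᵀ 1)`. The number of eigenvectors equals k (the standard choice; it is
configurable only through k itself). Documents with no in-vocabulary tokens
would produce zero degrees, so they are held out of the eigenproblem and
assigned afterwards to the nearest cluster TF-IDF centroid in cosine;
all-zero rows tie at similarity 0 and fall deterministically to the lowest
cluster index.

Spherical k-means maximises total cosine similarity to centroids, best of
10 replicates, at most 100 Lloyd iterations, initialised by the scalable
k-means++ (k-means‖) scheme with l = 2k candidates per round for 5 rounds
followed by weighted classic k-means++ reduction to k seeds. A centroid
left empty mid-iteration is re-seeded at the point farthest (in cosine)
from its own centroid. Everything is driven by one seeded generator, so
assignments are reproducible.

Cluster descriptions are selected from binary indicators over vocabulary
lemmas, surface words that differ from their lemma, and extracted multiword
terms (terms below the vocabulary frequency cut-off, or beyond the 200
highest C-values, are skipped as undescriptive; exact-duplicate indicator
columns are collapsed). The pipeline: (1) keep features positively
correlated with membership; (2) greedy CMIM — add the feature maximising
`min_s Î(f; membership | s)` over already-selected `s`, plug-in estimates
with add-half smoothing, stopping at 50 features or when no candidate
retains positive score; (3) choose the keyword count m minimising
`BIC = −2·llf + (m+1)·ln n` of an unpenalised logistic membership model on
the first m indicators; (4) sort the survivors by fitted coefficient. The
logistic fit caps its iterations because planted markers often separate the
cluster perfectly; the likelihood plateau reached by then is what BIC needs.

## Evaluation statistics

All metrics derive from the relevance-indicator sequence of a **complete**
trace. `WSS@95% = 0.95 − i_R95/N` with
`i_R95 = min{i : recall(i) ≥ 0.95}`; the 95% threshold is applied as the
integer ceiling `r = ⌈19R/20⌉` to dodge floating-point boundary artefacts.
The exact null pmf of `i_R95` under random ordering is a hypergeometric
draw of r−1 inclusions among the first i−1 positions times the probability
`(R−r+1)/(N−i+1)` that the r-th inclusion lands at position i, supported on
`r ≤ i ≤ N−(R−r)`; the support endpoints were verified by the normalisation
property and exhaustive enumeration. Binomials are evaluated in log-space
via log-gamma, so N ≈ 5000 poses no overflow risk. The p-value is the lower
tail, clipped into (0, 1]; the significance star threshold defaults to 0.01.
WSS and AUR refuse partial traces; only running recall accepts them.

`AUR = Σ recall(i) / (N − (R−1)/2)`. The normaliser is the unique choice
for which perfect prioritisation scores exactly 1, since the perfect
ordering has `Σ recall(i) = (R+1)/2 + (N−R) = N − (R−1)/2`. Two analytic
consequences used as test oracles: a uniformly random ordering has expected
AUR `(N+1)/2 / (N−(R−1)/2)` (≈ 0.528 at N = 200, R = 20, i.e. slightly above
one half), and the expected null `i_R95` is the order-statistic mean
`r(N+1)/(R+1)`, which makes the null **mean of WSS@95% slightly positive**
(+0.032 at N = 100, R = 10) — a discreteness effect of the ceiling in r, not
a bias in the implementation.

Running recall tracks, at each point where the trace has consumed w
baseline-relevant references, the fraction of the last 50 (default) of them
the screener marked include — a complacency diagnostic. Decision times are
smoothed by a centred sliding-window median over interdecision intervals
(window 51, odd, truncated at the edges).

## Synthetic collections and simulations

The generator emulates the statistical shape of real screening corpora:
collection sizes from tens to thousands, specificity anywhere in
(0, 1) — realistic values run from under 0.3% to about 30% — and a topical
vocabulary structure. Themes are word distributions mixing a boosted
disjoint block (weight 0.7) with a shared Zipfian background; irrelevant
documents draw Dirichlet mixtures of background themes while relevant
documents place `signal_strength` (default 0.9) on designated relevant
themes. Title and abstract lengths are Poisson (means 10 and 70 tokens).
Defaults for simulation studies are N = 1000 at 5% specificity: mid-range
size, low-but-workable specificity. The oracle screener is infallible;
reviewer error and complacency are modelled only as test fixtures for
running recall, so simulation results measure the engine, not reviewer
behaviour.

Strategies: `random`; `active_learning` (50 random references, random
until both classes are seen, then retrain every 25 decisions — the reminder
cadence — and screen top-confidence first); `topics_then_random` and
`topics_then_AL` (screen the designated topics' 45-reference lists first).
Real reviewers designate topics from a-priori keyword lists; the simulator
stands in with ground-truth overlap (`designate_topics_by_overlap`), which
is an optimistic proxy and is labelled as such.

What passing tests show — and what they do not: the simulations demonstrate
that the engine recovers planted topical signal and that the evaluation
statistics are exactly calibrated under the null. Real abstracts have
correlated vocabulary, near-duplicate records, metadata noise and fallible
reviewers; absolute WSS@95% values obtained here do not transfer to any
particular real collection, only the qualitative ordering of strategies and
the calibration of the significance test do.

## Problem sizes in the shipped test suite

Chosen so the full statistical battery stays comfortably desk-scale: null
calibration uses 10⁴ random-strategy simulations at N = 100, R = 10;
Monte-Carlo checks of the exact null use 10⁵ shuffles at N = 1000, R = 30;
active-learning efficacy uses ten seeds of N = 1000 collections at 5%
specificity; clustering recovery uses ten 150-document 5-theme collections.

## Known limitations

* The rule-based lemmatiser under-conflates irregular forms; swap in a
  stronger `Lemmatiser` implementation for production corpora.
* The C-value extractor's noun-phrase recogniser is a POS-suffix heuristic,
  not a parser; precision on real biomedical text will be lower than on the
  synthetic fixtures.
* Topic-based screening simulation designates topics from ground truth —
  an upper bound on what keyword-matched designation would achieve.
* No stopping criterion is provided: WSS@95% is an upper bound on
  realisable savings, computable only after complete screening.
* Search is a minimal in-memory Boolean filter over lemmas, phrases,
  topics and clusters; there is no web interface, persistence layer or
  multi-user state.
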