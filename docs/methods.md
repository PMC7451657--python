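# Methods

`soaptriage` reimplements, as a tested library, an end-to-end protocol for
predicting emergency-department (ED) disposition — admission to a ward bed
vs. discharge home — from the free text of the *first* SOAP note of a
visit, together with the statistical machinery used to compare the
machine's predictions with those of human graders. The original protocol
was developed on a private hospital EMR corpus; since those data cannot be
redistributed, this package ships a synthetic-corpus generator that
emulates the *structure* of such data, and every claim the test suite
makes should be read in that light (see "What the synthetic corpus does and
does not show" below).

## Record filtering

A raw corpus is cleaned by four exclusion rules applied per record in a
fixed precedence:

1. **duplicates** — a record whose four lowercased section texts are
   byte-identical to an earlier record's (whitespace is not collapsed; the
   first occurrence is kept);
2. **explicit final status** — the outcome leaks into the note itself,
   detected with a configurable phrase list ("HAA", "PD", "patient left",
   …). Phrases of ≤ 3 characters are matched on word boundaries so that
   "PD" does not fire inside "copd"; longer phrases match as
   case-insensitive substrings after whitespace normalization;
3. **empty** — all four sections blank after stripping;
4. **incomplete** — between one and three sections blank.

Each record is claimed by at most one rule (first match), so the counts
form an exact partition: `initial = removed + final` per class and in
total. Precedence is observable: an exact copy of an empty record counts
as a duplicate, not as empty. The published protocol does not state a
precedence for records matching several rules; the row order of its
selection table was adopted.

## Featurization

Text is normalized (whitespace tokenization, lowercasing, removal of
punctuation characters and digits, stopword removal, stemming), expanded
into all contiguous 1-, 2- and 3-grams, and scored by the F-value

    F(i) = [ (x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)² ] / [ s²ᵢ⁺ + s²ᵢ⁻ ]

where x̄ᵢ, x̄ᵢ⁺, x̄ᵢ⁻ are the means of feature *i*'s raw per-document
counts over all / admitted / discharged training documents, and s² are
the within-class sample variances (ddof 1). A zero denominator (feature
constant within both classes) defines F = 0. F-values are computed on raw
counts because selection happens *before* the conversion to the weighted
set-of-words matrix. Features strictly above the 65th percentile of the
F-value distribution are kept; the percentile uses NumPy's inclusive
linear-interpolation definition and the inequality is strict ("above the
percentile"), so a fully tied distribution selects nothing.

Matrix cells use augmented term frequency × inverse document frequency:

    TFIDF(t, d, D) = f(t,d) / max{f(t′,d) : t′ ∈ d} · log(|D| / df(t))

with the max over the document's *selected-vocabulary* terms (the matrix
is built after selection), df(t) the training document frequency, and no
smoothing (a selected term always occurs in training, so df ≥ 1). The log
is natural by default; the base is exposed as a parameter because it only
rescales columns uniformly and some toolkits print base-10 or base-2
weights. Documents with no in-vocabulary term receive an all-zero row —
they are legal and are classified by the sign of the bias. Test documents
are weighted with the frozen training idf and their own max counts;
vocabulary and idf never see test data.

Stemming is a named contract. The default is the identity map, which is
the right choice for pseudo-word synthetic corpora; a light
Portuguese-capable suffix-stripping stemmer (plural, feminine, adverbial
and diminutive reductions in the minimal RSLP style) is included for real
Portuguese notes. It is deliberately conservative: suffix rules with
minimum-stem lengths only, no exception dictionary.

## Classification

The classifier is a nu-SVC with linear kernel and nu = 0.5 ("default
parameters"), exposed as a scikit-learn estimator. The decision rule is
s(x) = w·x + b with *inpatient* as the positive class and the threshold at
0, so ROC orientation is unambiguous. nu is checked against the class-size
feasibility bound 2·min(n⁺, n⁻)/n before fitting. The quadratic program is
solved by libsvm through scikit-learn; the solver is an interchangeable
engine behind the training contract (the tests verify it against an
independent SLSQP solution of the nu-SVC dual on small instances:
hyperplane to 1e−6, identical support sets). The nu-property — fraction of
dual variables at the box bound (margin errors) ≤ nu ≤ fraction of support
vectors — is asserted on the dual solution; note the margin-error half of
the inequality presumes a positive margin ρ and is therefore checked on
the dual variables, not on misclassification counts, which can exceed nu
on heavily overlapping data where ρ ≤ 0.

## Evaluation statistics

* **Stratified split.** Per-class test counts may be given explicitly
  (the published 230-record test set, 120 discharged / 110 inpatient, is
  *not* exact proportional rounding, so explicit counts are accepted as
  input rather than derived) or as a fraction with round-half-away
  per-class counts. Sampling is without replacement and seeded.
* **Margin of error.** z·sqrt(0.25/n)·sqrt((N−n)/(N−1)) — worst-case
  proportion with finite-population correction; n = 230 of N = 9,030 at
  95% gives 6.4%.
* **ROC / AUROC.** The curve runs over all distinct thresholds (ties give
  diagonal segments); AUROC by the trapezoidal rule, which equals the
  Mann-Whitney concordance-probability estimator with half credit for
  ties — both are implemented and their equivalence is asserted to 1e−12.
  The AUROC CI is the normal approximation with DeLong's variance (the
  source protocol does not state its CI method).
* **DeLong's test.** Midrank placement values per case for each curve;
  their 2×2 empirical covariance gives
  z = (A₁ − A₂)/sqrt(v₁ + v₂ − 2c) and a two-sided normal p. No
  multiplicity correction, matching the raw pairwise p-values reported in
  the original comparison. Binary human ratings enter as {0, 1} score
  vectors, giving the two-segment ROC of a single operating point.
* **Youden cutoff.** Maximizes J = sens + spec − 1 over curve points; ties
  break toward higher sensitivity (the clinically conservative,
  admission-favoring direction), then toward the lower threshold.
* **Sensitivity/specificity CIs.** Wilson score intervals (method not
  stated in the source; Wilson behaves well at proportions near 1).
* **Cohen's kappa.** po, pe from marginals, κ = (po − pe)/(1 − pe), with
  Landis–Koch bands; the pooling gate for a rater pair is κ ≥ 0.61
  ("substantial" or better). Degenerate pe = 1 (both raters constant and
  identical) is defined as κ = 1.
* **Conservative aggregation.** A rater pair's disagreement on a case
  resolves to "inpatient".
* **Concordance accounting.** Five mutually exclusive categories per
  case: divergence between the two physician groups takes precedence;
  agreeing groups are then crossed with machine correctness. Counts are
  reported per truth class with percentages of all evaluated cases.

## Synthetic corpus: what it emulates, and what it does not

Records are assembled from banks of 1–3-token phrases — admission-
indicative (symptom phrases, e.g. "edema", "paroxysmal nocturnal
dyspnea"), discharge-indicative (normal-exam phrases, e.g. "well perfused
extrem", "no history dysuria") and neutral — padded with stopwords,
numerals and punctuation at configurable rates. Multiword phrases ensure
bigram/trigram features carry signal. Tokens are lowercase ASCII
pseudo-words (plus the few real anchor phrases); no attempt is made to
model Portuguese clinical language. Phrase banks are a deterministic
function of the bank sizes alone, so the informative features are stable
across corpus seeds.

Defaults mirror the study corpus shape: 9,030 records with 4,357
admissions (class balance 0.4825), four sections of 6 phrase slots each,
stopword/numeral/punctuation rates 0.3/0.1/0.2. `signal_strength` is the
per-slot probability of drawing from the class bank rather than the
neutral bank; the default 0.9 is the strong-signal recovery condition.
Class counts use round-half-away-from-zero of n × balance (deterministic
and symmetric). Contamination artifacts are injected with exact ground
truth: duplicates are byte-identical copies under fresh ids; status leaks
are copies with a leak phrase appended to one random section; empties are
whitespace-only records, each with a distinct amount of padding so that
two empties are not mutual duplicates; incomplete records have 1–3
uniformly chosen sections blanked.

Two structural caveats bound what passing tests show about real data.
First, per-record evidence accumulates over ~24 phrase slots, so even
modest per-slot signal makes records near-perfectly separable: held-out
AUROC is ≈ 1.0 at signal 0.9 and ≈ 0.5 at signal 0, and the published
intermediate operating point (AUROC ≈ 0.8) is not reproduced by any
generator setting with these defaults — reproducing it was never the goal,
since it is a property of the private corpus. Second, simulated raters
draw errors *independently* given the truth, whereas real physicians'
errors are correlated (shared case difficulty); consequently two simulated
raters at a realistic operating point show trial-subset kappa well below
what real physician pairs reach, and the kappa pooling gate is recorded in
the run manifest rather than enforced as a hard stop.

## Orchestration and reproducibility

`run_experiment` chains the stages and writes a bundle: selection-table
mirror, accuracy table (AUROC/sensitivity/specificity with CIs for
machine, novice and experienced groups), pairwise DeLong p-values,
concordance table, ROC point files, vocabulary and model TSVs, and a
manifest (config hash, derived seeds, per-stage counts, deterministic
manifest hash). Every stage seed derives from the master seed by stable
SHA-256 hashing of the stage name, so adding a stage never shifts another
stage's random stream; identical configs give byte-identical outputs
(timings excepted). Default problem sizes in the test and acceptance runs
(2,000-record corpora, 25% held out; 2,000 null replicates for the DeLong
calibration; 5,000 ratings for operating-point recovery) were chosen so
the Monte-Carlo error is comfortably inside each asserted tolerance.

## Known limitations

* Synthetic text has no discourse structure, negation, misspellings or
  section-specific register; distributional realism is out of scope.
* The leak-phrase list is configuration, not ground truth — only a handful
  of example phrases are published.
* The DeLong normal approximation is asserted at n = 230 with binary
  raters; at much smaller n its discreteness inflates the type-I error.
* `nu` is fixed at 0.5 by default; no hyperparameter search is provided by
  design.
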