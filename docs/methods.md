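# Methods

## Task and labeling rule

One clinical note section is one binary classification unit. A section is
positive when it documents any sign, symptom, diagnostic evaluation,
cognitive assessment, or treatment evidence of cognitive decline (the
spectrum from subjective cognitive decline through MCI to dementia).
Transient, reversible causes — memory loss attributable to medication,
post-anesthesia confusion, delirium from an acute infection — are
negative. This rule is enforced everywhere: the generator labels
transient-cause sections negative, the mock backend answers from that
label, and the error taxonomy contains a `transient-cause` category.

## Synthetic corpora

Real note sections cannot be distributed, so every stage runs on
generated corpora that reproduce the *statistical shape* of the study
data:

| corpus | n (default) | prevalence | length law (chars) |
|---|---|---|---|
| keyword-filtered development | 4,949 | 0.294 | log-normal, mean 850, bounds [26, 9323] |
| unfiltered test | 1,996 | 0.035 | log-normal, mean 464, bounds [26, 14740] |

Labels are i.i.d. Bernoulli(prevalence); lengths are drawn from a
log-normal (σ = 1, μ set so the untruncated mean matches the target) and
resampled into the hard bounds. Text is scaffolded from a fixed set of
sentence frames ("Patient reports {X} over the past six months.", …) whose
count per section follows the same law in both classes, so neither frame
words nor sentence counts carry class signal; keyword-free filler
sentences pad each section toward its drawn length.

* **Positives** embed 1–3 cue phrases drawn from a 20-phrase vocabulary
  (memory loss, forgetfulness, MoCA/MMSE scores, donepezil, …) with a
  skewed usage law (memory complaints dominate; drug names are rare), as
  in real notes. Cues are recorded in `meta["cues"]` and always occur
  verbatim in the text, so the learnable signal is recoverable by
  substring search.
* **Negatives** mix three distractor families: ~10% negated cues ("no
  memory loss"), ~10% transient-cause cues, and benign uses of screening
  keywords ("good sleep quality", "stable mood"). Benign mentions also
  appear in ~30% of positives' non-cue slots and in ~20% of random
  unfiltered sections — cue presence is deliberately the *only* consistent
  token-level class signal.
* In keyword-filtered mode every section (either class) contains at least
  one expert screening keyword, by construction: the first cue of a
  positive is keyword-bearing, and benign negatives carry one benign
  keyword phrase.

Generation is a pure function of the spec: one integer seed drives a
single numpy generator with fixed sampling order, so equal specs yield
byte-identical corpora.

What the generator does **not** emulate: real lexical diversity (the
scaffold vocabulary is a few hundred types), discourse structure,
misspellings, templated EHR boilerplate, or label noise. Consequently a
passing suite shows the machinery is correct and the pipeline's
comparative logic behaves as designed — not that any model would reach
these scores on real notes.

## Keyword screen

Expert keywords ship as a 36-entry list; entries ending in `-` are prefix
stems. Matching is case-insensitive and token-initial: a wildcard stem
matches any token beginning with it (`forget-` → "forgetfulness"), a plain
keyword matches a whole token only (`exam` does not fire in
"examination"). This mirrors the truncation-search convention of
literature databases. The screen is a pure filter: order-preserving,
idempotent, monotone in the pattern set.

## Local classifiers

**Boosted trees.** tf-idf over lower-cased word unigrams + bigrams
(minimum document frequency 2) into XGBoost (binary logistic, 200 rounds,
depth 4, η = 0.2, single-thread, `hist`). Per-feature *total gain* is
exported for interpretation. The feature construction is this package's
choice; only the model family is fixed by the design.

**Attention network.** Embedding (64) → 1-D convolution (64 filters,
width 5, ReLU, same-padding) → bidirectional LSTM (64 per direction) →
additive attention pooling → sigmoid, trained with Adam(W) on binary
cross-entropy, 10% validation split with early stopping (patience 2).
"Four layers" reads as conv / biLSTM / attention / dense; the embedding is
counted as input. All forward/backward passes are explicit numpy; a
finite-difference gradient check in the suite guards the backpropagation.
Regularization: dropout 0.3 on the pooled context, word-level dropout 0.15
(tokens replaced by UNK during training), decoupled weight decay 1e-4.
Every sequence is prefixed with a learned null token the attention can
park on when nothing is informative. Tokenization is the shared
`[a-z0-9]+` lower-case pattern, truncation at 512 tokens.

Desk-scale runs (tests, `small_config`, the acceptance script) use 1,200
training sections and a 16-dimensional network (word dropout 0.2, weight
decay 1e-3): at that corpus size the full-size network memorizes the
scaffold sentences and extrapolates erratically to the unfiltered corpus,
while the small regularized one tracks the boosted trees. These sizes are
the package's desk-scale study conditions, chosen once.

**Cutoff.** Probability ≥ 0.5 is positive; the boundary counts as
positive. Confusion counts computed from labels are identical to counts
from probabilities + cutoff (asserted in tests).

## Prompting subsystem

Prompts are rendered in fixed order: task description (required), task
guidance, error-analysis instructions, few-shot examples, the JSON
response directive, then the query section verbatim exactly once. Reply
triage is total: the first well-formed JSON object with keys
`cognitive_decline` and `keywords` → *effective & parseable*; otherwise a
documented fallback (negation-first affirmation lexicon + a
`keywords: …` line scan) must recover both answers → *effective but not
parseable*; otherwise *not effective* (no verdict is retained, even if one
was guessable). Because it is ambiguous whether the "effective response
rate" should count unparseable-but-complete replies, `effective_rate`
reports both conventions.

Example selection: `select_random` (seeded uniform), `select_targeted`
(from sections the model previously got wrong; an error if fewer than k
exist), `select_kmeans` (scikit-learn k-means, 10 restarts, 100
iterations, Euclidean; returned examples are *medoids* — the pool member
nearest each centroid — because a prompt example must be a real section),
and `select_dynamic` (top-k cosine similarity per query, ties broken by
section id). Embeddings go through a pluggable contract; the shipped
default is a deterministic feature-hashing embedder (blake2b, signed
buckets, dimension 256, L2-normalized, constant bias bucket) so everything
runs offline; an embedding-service adapter can be registered instead.

The mock backend answers from the gold label flipped independently with a
configured probability from one seeded stream, reports the planted cues
(or matched screening keywords) as its keywords, and can emit a configured
share of free-text or ineffective replies to exercise triage. Temperature
is pinned to 0 in replication configs. The manual template-tuning loop is
represented by a bookkeeping log that flags its stopping rule (perfect
effective rate, or three consecutive attempts without improvement); it
does not generate paraphrases.

Abstention (a not-effective reply) is resolved by policy: default
`negative` (abstention votes 0); alternative `defer` (the two local models
decide, the boosted trees breaking their ties).

## Evaluation and error profiles

Majority vote over exactly three binary votes. The ensemble-error
identity — a section is an ensemble error iff at least two individual
models err — is asserted at run time on every `ensemble_run`. Metrics are
precision, recall, F1 (harmonic mean), accuracy; zero denominators yield
0.0 with an explicit warning flag; report tables round to one decimal in
percent, raw values are retained. Error overlap is reported as all seven
Venn regions plus the union, with pairwise counts given under both
conventions (full intersections and exactly-two regions), and the union is
cross-checked against inclusion-exclusion.

## Interpretation

Selection rule: statistic strictly greater than mean + 2·SD of its
population (population SD, ddof configurable; zero-variance populations
select nothing). Populations: per-reply keyword frequency for LLM output
(normalized lower-case, whitespace-collapsed, phrases kept intact);
within-section attention weights (the rule runs inside each section; the
aggregate report counts flags, threshold 0); nonzero-gain tree features
(restricting the population avoids dilution by the untouched vocabulary —
`include_zero_gain=True` thresholds over the full export instead). The
merged table marks keyword × source membership against the shipped expert
list and highlights single-source keywords (in the worked examples only
the LLM surfaces multi-word phrases such as "memory loss").

## Pipeline and reproducibility

`run_study`: simulate → screen → split (pool / development holdout) →
train both locals on the filtered corpus → compare six prompting
strategies on the holdout by accuracy (mock error rates per strategy are
fixed study conditions: zero-shot 0.135, random 0.17, targeted 0.16,
k-means 0.16, dynamic 0.15, error-instructions 0.07, so the emulated
development accuracies track the reported comparison, with
error-analysis instructions winning) → run the winner plus both locals on
the unfiltered corpus → ensemble, interpretation reports, Venn regions →
manifest with config, per-stage seeds, and sha256 checksums of every
artifact. The master seed fans out to per-stage seeds via
`numpy.random.SeedSequence` children in a fixed order, so a stage can be
re-run in isolation; identical config + seed reproduce every artifact
bit for bit (single-thread XGBoost, pure-numpy network).

Strategies that are infeasible under a given condition (e.g. targeted
selection when an error-free probe leaves no prior errors) are recorded
as skipped rows rather than aborting the run.

## Known limitations

- The mock backend's errors are symmetric label flips; at 3.5% prevalence
  this yields far lower LLM precision than any plausible real model, so
  absolute mock-arm metrics on the unfiltered corpus are not meaningful —
  only the comparative machinery is.
- The attention network's out-of-domain precision (trained on screened,
  evaluated on unscreened text) varies substantially with the
  initialization seed at desk scale; its recall is stable. The
  ensemble's 2-of-3 vote, with the boosted trees' stable precision,
  absorbs this — which is the point of the design — but single-model
  numbers on the unfiltered corpus should be read with that caveat.
- The generator's closed vocabulary makes some in-domain tasks easier
  than reality (training F1 of 1.0 is expected, not impressive).
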