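# Methods

## Setting and model

The package targets the alignment recipe in which a strong, closed-
vocabulary multimodal classifier (the *upstream* model) teaches a
free-text LLM (the *downstream* model) its ranking behaviour. The
upstream model scores every label in a fixed vocabulary; those scores are
converted into preference pairs and the downstream model is trained to
prefer the upstream top of the list over its bottom. The package supplies
everything around the downstream model — dataset construction, the
objectives as functions of log-probabilities, and the evaluation chain —
plus synthetic stand-ins for the upstream classifier and a toy downstream
model, so the whole pipeline runs and is testable on one CPU in seconds.

### Preference pairs

For each sample the upstream scores are sorted descending (ties broken by
ascending stable label id, making the ranking canonical under any
iteration order of the score map). The chosen list is the top-*k* slice
with the ground truth forced into first position:

* truth already first → unchanged;
* truth elsewhere in the top-*k* → swapped with position 0 (the label
  *set* is preserved);
* truth outside the top-*k* → inserted at the front, former *k*-th label
  dropped.

The swap preserves the upstream's set judgement when the truth is already
deemed probable; the insert-and-truncate guarantees the truth's presence
at the top when it is not. The rejected list is the bottom-*q*, ordered
least-probable first so the most strongly rejected label is most
prominent (the ordering convention is otherwise unconstrained). If the
truth falls in the bottom-*q* it is removed there (it now leads the
chosen list) and the next-lowest unused label is backfilled — disjoint
chosen/rejected lists are required for a coherent preference pair.
Feasibility requires *k+q* ≤ vocabulary size; *k/q* is the
acceptance-over-rejection (AoR) ratio.

### Objectives

Both objectives act on `CompletionLogProb` values (total log-probability
in nats plus token count) and never on a model:

* ORPO: `L = L_SFT + β·L_OR` with
  `L_OR = −log σ(log odds(P_w) − log odds(P_l))`, `odds(p) = p/(1−p)`.
* DPO: `L = −log σ(β·[(log P_θ(y_w) − log P_ref(y_w)) − (log P_θ(y_l) −
  log P_ref(y_l))])`.

Numerical choices: all arithmetic in nats; `−log σ(x) = softplus(−x)`
via `log1p`; `log odds` is computed directly from the log-probability as
`z − log(−expm1(z))`, exact in the small-probability tail (a completion
with total log-probability −10⁴ keeps its full log-odds, ≈ −10⁴) and
clamped only on the `p → 1` side at `1 − 10⁻¹²`. `sequence_prob`, which
materializes a probability, clamps both sides to `(10⁻¹², 1 − 10⁻¹²)`.

Probabilities entering the odds default to the per-token geometric mean
`exp(logP/n)` (`normalize=True`), and the SFT term is correspondingly the
token-mean NLL. Joint sequence probabilities of realistic completions are
astronomically small, which collapses `odds(p) → p` and makes β
uninterpretable across completion lengths; length normalization keeps the
odds ratio on a comparable scale. Token-sum mode is available as a flag.
β defaults: 0.25 (ORPO), 0.1 (DPO) — conventional single-stage /
reference-anchored settings, exposed in every entry point.

### Evaluation chain

Responses are parsed from free text by extracting numbered or bulleted
lines; parsing never raises (failures surface as `parse_ok=False`, which
fails HFA). Grading follows a strict logical progression — Top-N and
Top-1 are graded only on HFA-passing samples and count as failures
otherwise, so `top1 ≤ topN ≤ HFA` holds on every run by construction.

Name comparison uses the Ratcliff/Obershelp ratio (difflib's
`SequenceMatcher`, `autojunk=False`) on a shared normal form: case-fold,
strip, collapse whitespace, strip trailing periods. Raw (un-normalized)
mode is a flag for bit-compatibility experiments. Abbreviations are
handled by comparing every candidate form (full string, any parenthesized
token, the string with parentheses stripped) against every entry form
(canonical name, abbreviation) and taking the best ratio — so "CdLS"
matches "Cornelia de Lange Syndrome" through the abbreviation path.
Thresholds: 0.6 for HFA (lenient plausibility screen), 0.8 for Top-N,
Top-1 and CAR (strict correctness).

The HFA pass rule defaults to *all* parsed names being
vocabulary-plausible — the strictest reading of "no fabricated labels" —
with `any` and `majority` available as config switches.

For CAR, the coverage and avoidance counts use a greedy best-similarity
one-to-one assignment between response names and list members (each side
countable once). Set intersection is only well-defined for exact strings;
the greedy rule extends it to fuzzy matching and reduces exactly to
multiset intersection at threshold 1.0, which the oracle tests exploit.
The coverage list T_k has the truth swapped into first position,
mirroring the chosen-list construction; B_q is the raw bottom-q. The
per-sample CAR term `(1+λ)CA/(λC+A)` is defined as 0 when the denominator
vanishes (conservative: a sample with no coverage and no avoidance
contributes nothing). λ defaults to 1 (plain harmonic mean), appropriate
for the balanced k=q settings used throughout; λ→0 recovers mean
coverage, λ→∞ mean avoidance, and CAR is invariant under
(C↔A, λ↔1/λ).

### Prompt construction

Phenotype-term ids are mapped through a term dictionary and joined with
`", "`, preserving order and casing, with no trailing punctuation
(sentence-final periods are neutral under the shared normal form).
Demographics lead the prompt; the default template is

    A {age} {sex} patient of {ethnicity} descent with the following
    clinical features: {phenotypes}

The exact sentence shape is not canonical, so the template is a single
configurable format string; the default follows the common clinical
presentation order age–sex–ethnicity. Records with entirely empty
demographics render the phenotype text alone.

## Synthetic data

The generators emulate the *statistical* structure of the real pipeline,
not its content:

* `make_label_space` — pseudo-disease names from syllable pairs, a
  configurable fraction carrying "FULL NAME (ABBR)"-style abbreviations.
  Default size 20 (the scale of the tissue-classification task; the
  disease task's ~520 labels are reachable by parameter).
* `simulate_upstream` — label logits i.i.d. standard normal, softmax at a
  temperature (default 1.0). A seeded Bernoulli(accuracy) draw decides
  per sample whether the truth's logit is swapped into (or out of) the
  argmax position before the softmax, so the empirical top-1 hit rate is
  exactly calibrated to the configured accuracy (default 0.8) rather than
  merely biased toward it. Default 2,000 samples for calibration checks.
* `simulate_responses` — with probability `quality` the truth-first
  top-N of the upstream prediction as a numbered block, otherwise a
  random label list; optional corruption replaces one entry with a
  fabricated string to exercise HFA.
* `make_learnable_prompts` — each label gets a distinct pseudo-word
  marker and prompts mention only the marker, giving a separable
  code-to-label task the toy LM can actually learn.

What the synthetic data does **not** emulate: clinical language and its
ambiguity, realistic phenotype-disease associations, correlated upstream
errors (confusable label pairs), multimodal inputs, and the scale and
class imbalance of real registries. Passing tests therefore demonstrate
the correctness of the machinery — construction rules, loss algebra,
grading semantics, calibration — not clinical performance of any aligned
model.

## Toy language model

`ToyCharLM` is a fixed-window character-level causal LM in numpy:
character embeddings (dim 8), the last 10 embeddings concatenated, one
tanh hidden layer (48 units), softmax over the character set. Gradients
of the full ORPO objective (token-mean SFT NLL plus the odds-ratio term)
are derived analytically and verified against central finite differences
in the test suite; optimization is per-record Adam (lr 0.01). Training on
100 separable preference records for 8 epochs takes about a second and
drives the mean chosen-vs-rejected log-odds-ratio margin from ≈0 to ≈7–8
nats. Completion scoring ranks label names by per-character
log-probability; responses are the top-N as a numbered block. A
non-finite loss aborts training with the offending sample identified.
The model is intentionally minimal — the smallest architecture that
overfits a ~20-label mapping — and exists to exercise the objective
end-to-end, not to model language.

## Problem sizes

Default problem sizes were chosen so the full test suite runs in seconds
and the acceptance script in under a minute on one CPU: simulator
calibration at n = 2,000 per accuracy level, grading pipeline at n = 400
with 20 labels, toy alignment at 10 labels × 100 training / 40 held-out
samples, oracle equivalence over 500 random instances and all 120
orderings of a 5-label space. These sizes are ample for the properties
being checked (binomial 3σ bands, exact oracle agreement); nothing in the
design prevents scaling them up.

## Known limitations

* The evaluation cannot distinguish two vocabulary entries whose
  normalized forms collide at the fuzzy threshold; very similar sibling
  labels ("… type 1" vs "… type 2") can cross the 0.8 ratio.
* The greedy assignment in CAR is not a maximum bipartite matching; in
  rare fuzzy-tie configurations it can undercount by one pair. At
  threshold 1.0 it is exact.
* The toy LM's fixed context window cannot represent long-range prompt
  dependencies; it is a smoke-test vehicle only.
* `RankedPrediction` renormalizes score vectors whose sum deviates from
  1 by more than 10⁻⁶ (warning) and rejects deviations beyond 10⁻³ —
  tolerant of float dumps, strict against malformed inputs.
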