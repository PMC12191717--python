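# Methods

This document describes what the package computes and why each protocol is
shaped the way it is. The worked example lives in the top-level README.

## Problem setting

A longitudinal health record is a sequence of visits; each visit is a set of
medical codes drawn from a fixed vocabulary partitioned into ordered regions
— diagnoses, then procedures, then medications — plus optional complex
payloads (notes, vectors) attached per visit. Records in practice are often
*deficient*: truncated after some visit (longitudinal deficiency) or missing
whole code regions (modality deficiency). The package trains a generative
model of complete records and uses it to simulate the missing parts, so that
downstream models can be trained on enriched data.

## Record representation

A record with `T` visits is encoded as a `(T+1) × V` binary matrix: one
multi-hot row per visit over the code vocabulary, followed by a sentinel row
whose only active bit is the reserved *stop code* (the last vocabulary
index). Generation and likelihood both treat the stop bit as an ordinary
code: a record ends when the stop bit is drawn.

## Model

The probability of a record factorizes at two granularities:

- **Across visits** — a causal transformer (`medisim.model.MediSim`)
  summarizes visits `1..t` into a history vector `h_t`. The input at each
  position is a linear embedding of the multi-hot row (plus positional
  embedding, plus any codec payload embedding); attention is masked so `h_t`
  never sees future visits. A dummy all-zero first input row makes `h_0` a
  well-defined empty-history summary.
- **Within a visit** — a masked autoregressive head predicts each code bit
  `c_i` of the next row from `concat(h_t, next_row)` through two square
  masked linear layers with ReLU between them. Degrees are assigned so the
  first layer is *strictly* autoregressive over the code block (bit `i`
  never reads bits `j ≥ i`), while the history block is fully visible to
  every output. An `inclusive` ablation mode exists and demonstrably leaks.

Both properties are enforced by tests that exhaustively flip every input bit
and assert invariance of the protected outputs.

All tensor work runs on a small reverse-mode autodiff engine over NumPy
(`medisim.autodiff`) that is gradient-checked against finite differences; no
deep-learning framework is required.

## Training

Binary cross-entropy over every position of every row (sentinel included),
with per-record masking so padded rows contribute zero gradient. Adam, with
`desk` (embedding 64, 2 blocks — minutes on a CPU) and `full` (768/12/12)
profiles. Validation perplexity is checkpointed each epoch and the best
parameters are restored at the end, so `fit` never returns a model worse
than its best epoch.

**Perplexity** is `exp(−log-likelihood / N_present)`: the likelihood runs
over *all* positions (present and absent bits, sentinel row included), but
is normalized by the number of *present* codes. The log-sum and
product-of-probabilities forms are tested to agree to 1e-9.

## Simulation engine

`complete_record` / `complete_batch` consume `DeficientRecord`s:

- `longitudinal`: the observed prefix is preserved bit-for-bit and new
  visits are sampled autoregressively until the stop bit fires or a visit
  cap is reached;
- `modality`: observed regions (which must form a region prefix, e.g.
  diagnoses) are clamped and the remaining regions of each visit are filled
  in within-visit autoregressive order;
- `dual`: both; `none`: passthrough.

`generate_from_scratch` is completion of an empty prefix.
`enrich_cohort` additionally returns per-record provenance (which visits and
codes are simulated). Sampling supports a temperature knob applied to
Bernoulli odds. Contracts (preservation, termination, closed-form length
and marginal statistics under a fixed-probability model) are tested at
n=5000.

## Policy-gradient refinement

A weak real-vs-synthetic RNN classifier (the reward model) scores sampled
records; REINFORCE ascends expected reward. Two details matter:

- The gradient uses the likelihood of the *raw sampled rows*
  (`simulate.sample_raw`), not of the canonicalized records — the raw-row
  likelihood is exactly the probability with which the sequence was
  sampled, making the score-function identity exact (verified by summing
  `exp(log P)` to 1 over an enumerated sequence space and by
  finite-difference checks of the enumerated expected reward). Rewards are
  still computed on canonical records, which is what a discriminator sees.
- `refine` evaluates validation perplexity on a schedule and keeps the best
  parameters seen anywhere in the loop (including the starting point), so
  refinement can never end worse than it began.

## Modality bridge (complex payloads)

Codecs map per-visit payloads to fixed-width embeddings concatenated to the
encoder input: a bag-of-tokens note codec, a linear vector codec, and a
zero codec. `attach_codec` widens the input embedding with fresh rows while
preserving all existing parameters, so attaching a zero codec is a *null
extension*: probabilities are bit-identical. Payload generators exist for
code-redundant template notes and for side-information vectors that reveal
the synthetic generator's latent state — only the latter carries
information beyond the codes, and only it can reduce perplexity.

## Synthetic cohort generator

A hidden-Markov cascade: a latent state follows a Markov chain; diagnoses
are state-conditional Bernoulli emissions; procedures and medications fire
from trigger rules on codes earlier in the same visit; record length is
geometric (continuation probability) with a cap. `GroundTruth` provides
closed forms used as test oracles: exact record likelihood, state
posteriors, next-row conditionals, the entropy-rate bound on achievable
perplexity, and exact continuation sampling. Generator defaults are fixed
study conditions, not tuning knobs.

## Evaluation protocols

- `temporal_eval`: teacher-forced next-visit prediction from visit 2 onward
  (plus the stop decision), micro-F1 and present-code-normalized perplexity.
- `modality_eval`: procedure/medication prediction with diagnoses clamped,
  teacher-forced or sequential (own samples carried forward).
- `enrichment_benchmark`: three *training* regimes for a bag-of-codes
  phenotype classifier — deficient, enriched (deficient completed by the
  model), full real — all scored on one common real test cohort with real
  labels, with a paired bootstrap (same test resamples for every regime).
  The enriched regime's training labels come from its own completed
  records, since the real continuation is precisely what enrichment lacks;
  a cheating oracle that samples the true continuation must (and does)
  match the full regime.

## Estimator surface

`MediSim` and `RewardModel` follow the sklearn estimator idiom
(`fit`/`score`/`get_params`/`set_params`, trailing-underscore fitted
attributes) because they are fit/predict-shaped; the rest of the package is
deliberately a tool-shaped library (record formats, completion engine, CLI)
where module-level functions fit the domain better.
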