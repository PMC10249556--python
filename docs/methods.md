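# Methods

This note documents the models and procedures implemented in `mlmga`,
the parameters that matter, the synthetic data the package runs on, and
the design choices made where the design was genuinely open.

## Tokenization

SMILES strings are pre-tokenized on punctuation: every non-alphanumeric
character (brackets, `=`, `#`, `+`, `-`, `/`, `\`, `@`, `%`, `.`, …)
becomes a single pre-token, and runs of letters/digits group. Subword
tokens are then learned by iterative pair merging *inside* alphanumeric
pre-tokens: at each step the most frequent adjacent symbol pair (ties
broken lexicographically) becomes a new token, until the target
vocabulary size is reached or no pair repeats. Consequences:

* multi-character tokens never straddle structural punctuation, so
  filled-in mutations cannot splice, say, half a ring-closure digit
  onto a branch parenthesis;
* every character seen in the corpus is itself a token, so encoding is
  lossless on in-corpus alphabets (`decode(encode(s)) == s`);
* the merge list is prefix-stable: a larger build only appends tokens.

Encoding is greedy longest-match; characters outside the vocabulary map
to `[UNK]`, and any sequence containing `[UNK]` is excluded from
training and never emitted as an offspring (an unknown cannot be decoded
back to chemistry). SMILES case is never altered — aromatic `c` and
aliphatic `C` are distinct chemistry. Specials are `[PAD]`, `[UNK]`,
`[MASK]`, stored first in the vocabulary file in that order.

Default vocabulary size is 512. This suits corpora of 10³–10⁴
molecules; the parameter is the knob to turn for larger corpora (a
vocabulary of 32,768 is the regime of billion-molecule pre-training,
not reachable or useful at desk scale).

## Mask-prediction backends

Both backends implement one contract: given a token sequence containing
`[MASK]` tokens, return a ranking (or sample) over non-special
vocabulary tokens per masked position; support multi-epoch pre-training
and one-epoch adaptation. Rankings break score ties by ascending token
ID, so all predictions are deterministic given model state; save/load
round-trips are bit-exact.

**Transformer.** A bidirectional pre-norm encoder written directly in
NumPy with hand-derived backprop and Adam: token + learned positional
embeddings, 2 layers, 2 heads, width 64, feed-forward 128, GELU,
sequence window 128 tokens (all configurable; the hand-written gradients
are verified against finite differences in the test suite). Training
masks each position independently at the masking rate (default 0.15 for
pre-training), with at least one mask per sequence, and always writes a
literal `[MASK]` — at mutation time inputs always carry literal masks,
so the pre-training distribution matches the use distribution. The
output projection is evaluated only at masked positions, which removes
the dominant vocabulary-sized matmul from both training and inference.
Sequences longer than the window are skipped with a warning rather than
truncated (truncation would corrupt ring/branch syntax).

**Positional n-gram.** For a mask at position *i* the context is the
ordered pair (token *i*−1, token *i*+1), with begin/end sentinels at the
boundaries; unseen or masked neighbours back off to unigram counts.
Distributions are add-one smoothed over the predictable vocabulary.
"One epoch of training" is exact counting of (left, centre, right)
triples, so the backend's predictions and fitted cross-entropy can be
checked against an independent brute-force counter — which the test
suite does. It is also fast enough to run whole GA batteries in
seconds.

**Sampling.** `predict_sample` draws `argmax(log p / T + Gumbel)` per
masked position — the hard Gumbel-softmax sample of the model's
categorical distribution at temperature `T`; at `T → 0` it reduces to
the rank-1 candidate.

## Adaptation (the one-epoch-per-generation strategy)

`adapt(population)` performs exactly one epoch of masked-prediction
training on the current population. Two optimizer choices matter, and
both were genuinely open:

* **Learning rate.** Adaptation uses `adapt_lr_factor ×` the
  pre-training rate, with factor default **1.0**. At desk scale a
  population of 200–500 molecules gives only 7–16 Adam steps per epoch;
  at a reduced rate (e.g. 1/10) those steps measurably do nothing — the
  fixed and adaptive schedules produce indistinguishable trajectories,
  and the strategy comparison the package exists for collapses. At the
  full rate, one epoch per generation visibly refits the proposal
  distribution, which is the regime the method describes (at production
  scale, where one epoch is thousands of steps, a smaller factor is the
  right setting — hence the knob).
* **Optimizer state.** Adam's moment estimates are reset at the
  pre-train → adapt boundary (a fresh optimizer for the fine-tuning
  phase, as is standard). Stale second moments accumulated over
  pre-training otherwise damp the adaptation steps enough to suppress
  the effect being studied. Consecutive `adapt` calls within a run
  share optimizer state, forming one continued-training process.

## Mutation operators

The number of masks is `max(1, Binomial(n, p))` for an *n*-token parent
at mutation rate *p* (default 0.3; the interesting sweep is 0.15–0.75).
One of three operators is chosen uniformly per parent:

* **replacement** — all sampled positions become masks (length
  unchanged);
* **insertion** — a mask is inserted before the first sampled position;
  remaining sampled positions become replacements (length +1);
* **deletion** — the designated site becomes a mask and the token after
  it is deleted; remaining sampled positions become replacements
  (length −1).

For deletion the designated site is drawn among positions that *have* a
following token, and replacement positions exclude the token slated for
deletion. This keeps the arithmetic exact — Δlength is always −1 and
the mask count always equals the plan's — where sampling the designated
site like the others would occasionally delete a mask or have nothing to
delete. A deletion on a one-token parent degrades to replacement; the
resulting mask-only sequence decodes to the empty string and is
discarded as invalid downstream.

In top-k mode (the GA default, k = 5) offspring *i* fills every masked
position with its rank-*i* candidate — a deliberate simple scheme; a
joint beam over positions is a possible alternative that was not
implemented. In sample mode, k independent Gumbel-softmax fills are
drawn.

## The genetic algorithm

(μ + 5μ) truncation selection with the current population always in the
survivor pool (elitism: best fitness never decreases — asserted
exactly, every generation, in the tests). Parents are drawn uniformly
with replacement; offspring are filtered for RDKit validity,
canonicalized, and deduplicated within the batch and against the
current population; novelty is counted against the initial dataset.
Survivor ties break by canonical SMILES, making n-gram runs bit-for-bit
reproducible. When a generation is adaptive, the model trains on the
selected population *before* proposing. Desk-scale defaults: μ = 200,
10 generations, 6 repeats with per-repeat seeds derived from one master
seed; each repeat restarts from the pre-trained weights. μ = 10⁵ is a
configuration, not a different code path.

The `switch` schedule is fixed through generation *g* and adaptive
after. `reinit_on_switch` optionally restores the pre-trained weights
at the switch point, mirroring multi-job runs that re-initialize on
restart; default off.

Fitness metrics: QED (RDKit), synthetic-accessibility score normalized
as (10 − SA)/9 — the standard affine map onto [0, 1] with higher =
easier; the raw score's own normalization is not published anywhere
authoritative, so the map is configurable in principle — and optionally
an affinity score `clip(prediction/10, 0, 1)` from an external scorer
(one callable: list of SMILES → one finite −log₁₀ affinity each). A
scorer failure flags the molecule and assigns fitness 0 instead of
aborting the run. The packaged `MockAffinityScorer` is synthetic: a
fixed function of ring count and heteroatom fraction spanning roughly
4–9, built so three-metric runs are reproducible without any external
model; it has no pharmacological meaning.

## Synthetic data

All experiments run from generated data:

* **Broad corpus** — random cap–linker–cap chains (1–4 fragments) from a
  hand-curated ~55-fragment attachment-point library of common
  lead-like substructures, sanitized with RDKit, deduplicated by
  canonical form, and screened for normalized synthesizability > 0.30
  (the customary screen for augmented corpora). ~0.6 QED / ~0.85
  SA-norm on average.
* **Low-fitness start** — the same generator over a small C/N/O/F
  fragment set, capped at 9 heavy atoms (QM9-style composition); mean
  two-metric fitness ≈ 0.55.
* **High-fitness start** — the top *n* of an `n × pool_factor` broad
  pool ranked by two-metric fitness; mean ≈ 0.85 at pool factor 4.

What the generator does *not* emulate: the scale (10⁵–10¹⁰ molecules),
the structural diversity of make-on-demand libraries (stereochemistry,
charged species and exotic ring systems are absent), and any real
hold-out distribution. Passing experiments therefore demonstrate the
*mechanisms* — mimicry under adaptation, the early advantage of the
fixed schedule from a poor start, the benefit of switching — not
absolute performance numbers on real libraries.

## Desk-scale study conditions

The test suite and `scripts/acceptance.py` use: 5,000-molecule corpus,
512-token vocabulary, 6 pre-training epochs, populations of 500,
μ = 200 for 10 generations at mutation rate 0.3, three seeds per
comparison with majority scoring. The distribution-mimicry experiment
(selection off, 5 generations) uses Gumbel-softmax sampling rather than
top-k fills, because deterministic rank fills blunt exactly the
distributional shift the experiment measures; closeness is the sum of
per-metric |Δmean| against the high-fitness reference set. These sizes
were chosen so the full battery runs on one CPU core in minutes while
still showing every qualitative effect; with them, the expected
orderings hold in 3/3 seeds in the committed configuration.

## Known limitations

* The n-gram backend sees only adjacent-token context; it is an oracle
  and smoke-test backend, not a competitive mutation model.
* One mutation operator per parent per generation (no operator
  stacking, no crossover, no fragment- or rule-based mutations).
* Validity rates of mutated SMILES are modest (roughly half of
  proposals at rate 0.3 with the desk-scale transformer); invalid
  proposals are counted and discarded, not repaired.
* Harmonic-mean fitness with the zero convention (any zero metric →
  fitness 0) is intentional but means a single failed metric removes a
  molecule from contention entirely.
* `compare_distributions` summarizes by mean/SD differences only; it is
  a deliberate, interpretable reduction, not a distribution test.
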