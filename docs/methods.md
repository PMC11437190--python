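# Methods

## Task and data model

The unit of analysis is a *gene record*: a nucleotide sequence over
{A, C, G, T} with NCBI-style identifiers.  Sequences are framed for
modeling as `< x_1 ... x_L >`: the start symbol `<` (repeated N-1 times for
an order-N model) is conditioning context only and is never predicted; the
end symbol `>` is a predicted token, because knowing *where genes end* is
part of the modeling task — it is also where unsmoothed high-order models
typically meet their first unseen event on held-out data.

Corpus preparation follows a fixed protocol:
records longer than 1000 nt are filtered out (inclusive bound, minimum 1),
and the remainder is split at random into 80% train+validation / 20% test,
with validation taking 25% of the training side.  Split sizes floor the
kept (training-side) portion at each stage and give the remainder to the
held-out side, so a 22,886-record corpus yields 18,308 train+validation and
4,578 test records; splits are driven entirely by a stored integer seed.
Records containing IUPAC ambiguity codes are dropped at load time (counted
and logged); a flag instead maps them to an `N` token for callers who want
to keep them with an extended alphabet.  No deduplication of identical
sequences is performed.

## Perplexity convention

All models are scored by pooled per-token perplexity

    PPL = exp( - (sum of log p over all predicted tokens) / (number of predicted tokens) ),

pooled over the whole corpus rather than averaged per record, so the value
is independent of batching; each record contributes `len + 1` predictions
(its nucleotides plus the end event).  Under maximum likelihood a single
zero-probability event makes the corpus perplexity infinite; this is
reported as `inf`, never clipped.  Laplace smoothing uses add-one counts
with V = 5 (four nucleotides plus `>`), so every conditional is strictly
positive and perplexity is always finite.  The n-gram parameter count is
the number of non-zero (context, token) entries in the sparse table.

## Markov simulator and its ground truth

`synthetic.MarkovSimSpec` holds an order-r chain: one probability vector
over (A, C, G, T, END) per context, contexts being the last r symbols of
the START-padded history — exactly the convention the n-gram fitter uses,
so fitted conditionals are directly comparable to the ground truth.
`random_sim_spec` draws each vector from a symmetric Dirichlet; contexts
that still contain START padding get zero END mass, which guarantees every
sequence has at least r nucleotides (matching the minimum length 2 of the
order-2 gene-like default) and keeps maximum-likelihood recovery unbiased
(no rejection sampling of empty sequences is needed; rejection would bias
boundary conditionals by up to the END mass).  An optional `end_prob` pins
the END probability of interior contexts, giving mean sequence length
≈ 1/end_prob.

Two length regimes:

- **chain-terminated** (`length_law=None`): symbols are sampled until the
  chain emits END or a hard cap (default 1000).  For this regime the exact
  per-emission entropy rate is computed by treating the context process as
  an absorbing Markov chain and solving the expected visit counts; its
  exponential is the large-sample lower bound on any model's perplexity.
  The cap is ignored in that computation — with the default settings the
  truncated mass is well under 1%.
- **length-law** (default for gene-like corpora): a target length is drawn
  from a log-normal law (mu = log 295, sigma = 0.6526, truncated to
  [2, 1000]) chosen to match the filtered human-gene catalogue's median
  ≈ 295 and mean ≈ 365; nucleotides are then sampled from the chain with
  END renormalized away.  Upper truncation pulls the realized median to
  ≈ 285 and the mean to ≈ 333, which we accept as gene-like.

What the simulator deliberately does **not** emulate: codon structure,
repeats, GC heterogeneity between genes, and any biological meaning of the
simulated sequences.  Tests passing on simulated corpora therefore
establish the correctness of the machinery (counting, smoothing,
optimization, evaluation) and the statistical behavior of the methods at
the stated sample sizes — not biological conclusions about real genes.

## Neural language models

Both neural architectures follow the same contract as the n-grams: predict
every token of `< seq >` from its prefix.  The vocabulary has 7 symbols
(PAD, `<`, A, C, G, T, `>`); the input layer is a token embedding plus a
learned positional embedding; the head is a linear layer with one unit per
vocabulary symbol under softmax.  PAD targets are masked from loss and
perplexity; START never occurs as a target.  The LSTM body is a stack of
standard LSTM layers (Glorot input weights, orthogonal recurrent weights,
forget-gate bias 1).  The transformer body is a stack of causally masked
multi-head attention blocks in the pre-norm residual arrangement with a
final layer norm; pre-norm was chosen after post-norm blocks repeatedly
stalled at unigram-level perplexity without a warmup schedule, a known
optimization pathology of warmup-free post-norm training.  The output head
is zero-initialized, so an untrained model is exactly uniform over the
vocabulary (perplexity = vocabulary size), a useful calibration point.

Everything runs on a small reverse-mode autodiff core over numpy arrays
(`genelm._autograd`), validated against finite differences in the test
suite; training is single-threaded and bit-reproducible for a given seed.
Batches are length-bucketed (sorted by length with shuffled ties, batch
order shuffled) to keep padding waste low; each batch pads to its own
maximum length, bounded by `context_length` (default 1024, enough for a
1000-nt gene plus boundary tokens; exceeding it is an error).

Training runs a fixed number of epochs (default 40) of Adam (default lr
1e-3, batch 32; optional linear lr decay, dropout and gradient clipping are
off by default), recording train and validation perplexity and a weight
checkpoint after every epoch.  The reported epoch is chosen *post hoc*: the
best validation perplexity among epochs with |train − val| < 0.02, falling
back, with a logged warning, to the smallest-gap epoch when none qualifies.
This agreement rule refuses to report overfit epochs even when their raw
validation score looks acceptable.  Exact parameter counts come from a
closed form (embeddings V·d + L·d; per LSTM layer 4(d_in·h + h² + h); per
transformer block 4(d² + d) + d·ff + ff + ff·d + d + 4d, plus 2d for the
final norm; head d_out·V + V) and are cross-checked against the
instantiated models.  A `config_grid` helper enumerates Cartesian
hyperparameter grids for searches whose best settings are not fixed a
priori.

### Scale used in tests and the acceptance script

The learning-signal check trains both architectures on an order-2 chain
(Dirichlet concentration 0.8, interior END probability 0.02, hard cap 100,
mean length ≈ 45, n = 2000 split 80/20) and requires the best validation
perplexity to beat the unigram and land within 5% of exp(entropy rate).
The chosen configurations — LSTM (embedding 24, hidden 48, 10 epochs, lr
1e-2 decayed to 0.2×) and transformer (embedding 16, 1 block, ff 32, 2
heads, 45 epochs, lr 3e-3 decayed to 0.2×) — reach ≈ 1.02× and ≈ 1.03–1.05×
the bound respectively.  The cap at 100 keeps every position of the learned
positional table well trained; with a heavy length tail the transformer's
absolute-position attention overfits rare tail positions and stalls near
1.09× the bound.  These sizes were picked so the whole suite runs in a few
minutes on one CPU; they are small, and the absolute perplexities they
reach say nothing about the real gene corpus.

## Mutation benchmark

A benchmark dataset is built from the test split: for each pair, the number
of edits is uniform on {1, …, max_changes}; each edit is, with equal
probability, an insertion (uniform base, uniform position among L+1 slots),
a deletion (uniform position), or a substitution (uniform position, uniform
among the 3 alternative bases, never the identity).  Edits apply
sequentially to the evolving sequence.  Real members are drawn without
replacement until the test corpus is exhausted, then by further permutation
passes.  Degenerate cases are handled conservatively: a delete (or
substitute) drawn on an emptied working sequence redraws the edit kind; a
mutated copy that coincidentally equals its original is kept (and logged) —
it can only score as a tie.  Positions are 0-based internally.

A scorer is any function mapping a record to a perplexity; the pair is
predicted correctly iff the real member's perplexity is *strictly* lower.
Ties — including both members scoring `inf` — count as incorrect, a
conservative choice.  Externally curated real mutation pairs (for example
from a clinical mutation database, which cannot be redistributed here) load
from CSV with columns `pair_id, real_sequence, mutated_sequence` plus an
optional ops/annotation column, into the same evaluator.

## Numerical and design notes

- Log-probabilities are accumulated in natural log; the base cancels in
  the perplexity exponential.
- MLE conditionals at unseen contexts are zero-probability events (never
  clipped), matching the infinite-perplexity behavior that motivates
  smoothing.
- `generate_sequence` may legitimately return an empty sequence when END
  is drawn immediately; corpus loaders, by contrast, reject empty records.
- The experiment runner serializes every seed (data, split, mutation,
  neural) into `manifest.json`; identical configs reproduce result tables
  byte for byte.
- Known limitations: no smoothing beyond add-one (no backoff/Kneser-Ney,
  by design); single-nucleotide tokenization only; the numpy training loop
  is CPU-bound and meant for corpora of thousands, not millions, of
  sequences; published perplexities on the real gene corpus depend on an
  unpublished split seed and supplementary hyperparameters, so they are
  reproducible only approximately (the corpus-count and n-gram checks in
  `tests/test_acceptance.py` state the tolerances used).
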