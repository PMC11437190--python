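"""Fit the n-gram family and evaluate held-out perplexity.

Fit orders 1..6 by maximum likelihood
and 6..8 with Laplace add-one smoothing on the training split, then report
pooled per-token perplexity (end-of-gene event included) on the test split.
Lower is better; a uniform model would score 5.  MLE at high orders can
print 'inf': a single held-out n-gram unseen in training (typically at a
gene boundary) zeroes the whole likelihood, which is exactly the pathology
Laplace smoothing repairs.

To run on a real gene table instead, replace the generator call with
``load_gene_table("genes.csv")``.
"""

from genelm import (
    SplitSpec,
    corpus_perplexity,
    default_length_law,
    fit_ngram,
    generate_corpus,
    ngram_param_count,
    random_sim_spec,
    split_corpus,
)
from genelm.data_io import Corpus

spec = random_sim_spec(2, seed=42, n_records=2000, length_law=default_length_law())
corpus = generate_corpus(spec)
train, validation, test = split_corpus(corpus, SplitSpec(seed=0))
trainval = Corpus(train.records + validation.records)

print(f"train+val {len(trainval)} / test {len(test)} records\n")
print("  N  smoothing  test perplexity   parameters")
for N in range(1, 7):
    model = fit_ngram(trainval, N, "mle")
    ppl = corpus_perplexity(model, test)
    print(f"  {N}  mle        {ppl:15.4f}   {ngram_param_count(model):10d}")
for N in (6, 7, 8):
    model = fit_ngram(trainval, N, "laplace")
    ppl = corpus_perplexity(model, test)
    print(f"  {N}  laplace    {ppl:15.4f}   {ngram_param_count(model):10d}")
print("\nperplexity = exp(mean negative log-likelihood per predicted token)")
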