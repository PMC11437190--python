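"""Generate new candidate sequences from a fitted autoregressive model.

A Laplace 4-gram fitted on the synthetic corpus samples nucleotides token
by token from its conditionals until it emits the end-of-gene symbol, so
sequence lengths are themselves model-driven.  Note the order matters for
this: at high orders most contexts are rare, and add-one smoothing inflates
their end-of-gene probability, which biases samples short — one reason the
end event needs care when judging generative quality.
"""

import numpy as np

from genelm import default_length_law, fit_ngram, generate_corpus, generate_sequence, random_sim_spec

corpus = generate_corpus(random_sim_spec(2, seed=42, n_records=2000, length_law=default_length_law()))
model = fit_ngram(corpus, N=4, smoothing="laplace")

rng = np.random.default_rng(7)
print("sampled sequences (Laplace 4-gram):")
lengths = []
for i in range(5):
    record = generate_sequence(model, rng, max_len=1000, gene_id=f"sample{i}")
    lengths.append(len(record))
    print(f"  >{record.gene_id} length={len(record)}")
    print(f"   {record.sequence[:60]}{'...' if len(record) > 60 else ''}")
print(f"\ntraining median length {int(np.median(corpus.lengths()))}, "
      f"sampled lengths {lengths}")
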