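"""Train a small LSTM language model and compare it to the entropy-rate bound.

The corpus is an order-2 Markov chain whose exact per-token entropy rate is
computable, so exp(entropy rate) is the best perplexity any model can reach
in the large-sample limit.  Training prints per-epoch train/validation
perplexities; the reported epoch is chosen by the |train - val| < 0.02
agreement rule, which rejects overfit epochs.  Swap ``architecture`` to
"transformer" for the attention-based variant (it needs more epochs).
"""

import math

from genelm import (
    NeuralLMConfig,
    SelectionRule,
    SplitSpec,
    build_model,
    count_parameters,
    entropy_rate,
    generate_corpus,
    random_sim_spec,
    select_checkpoint,
    split_corpus,
    train,
)
from genelm.data_io import Corpus

spec = random_sim_spec(2, concentration=0.8, seed=11, end_prob=0.02, n_records=2000, max_len=100)
corpus = generate_corpus(spec)
bound = math.exp(entropy_rate(spec))
tr, va, te = split_corpus(corpus, SplitSpec(seed=1))
train_c, val_c = Corpus(tr.records + va.records), te

config = NeuralLMConfig(
    architecture="lstm", embedding_dim=24, hidden_dim=48, context_length=104,
    epochs=10, learning_rate=1e-2, lr_decay=0.2, batch_size=32, seed=4,
)
model = build_model(config)
print(f"{config.architecture} with {count_parameters(config):,} parameters; "
      f"entropy-rate bound = {bound:.4f}\n")

history = train(model, train_c, val_c, config)
for epoch, (tr_ppl, va_ppl) in enumerate(history.epochs, 1):
    print(f"  epoch {epoch:2d}: train {tr_ppl:.4f}  val {va_ppl:.4f}")

best = select_checkpoint(history, SelectionRule(tolerance=0.02))
tr_ppl, va_ppl = history.epochs[best]
print(f"\nselected epoch {best + 1}: validation perplexity {va_ppl:.4f} "
      f"({va_ppl / bound:.3f}x the theoretical optimum)")
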