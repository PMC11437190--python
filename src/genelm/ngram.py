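"""Order-N autoregressive n-gram models over nucleotide tokens.

A model of order N predicts each token (the four nucleotides plus the
end-of-gene symbol ``>``) from the previous N-1 tokens, with sequences
left-padded by N-1 start symbols ``<``.  START is conditioning context
only and is never predicted, so the predictive vocabulary has V = 5
symbols by default.

Two estimators are supported: plain maximum likelihood (``mle``), under
which any unseen event has probability zero and corpus perplexity becomes
infinite, and add-one Laplace smoothing (``laplace``), under which every
conditional is (c + 1) / (n + V) and perplexity is always finite.

Perplexity is pooled over tokens: exp of total negative log-likelihood
divided by the total number of predicted tokens (sequence length + 1 per
record, the END event included), so the value does not depend on how
records are batched.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ALPHABET, Corpus, END, GeneRecord, START, tokenize

DEFAULT_VOCAB: tuple[str, ...] = tuple(ALPHABET) + (END,)


@dataclass
class NgramModel:
    """Sparse count table for an order-N model plus its smoothing mode."""

    order: int
    smoothing: str = "mle"  # "mle" | "laplace"
    predictive_vocab: tuple[str, ...] = DEFAULT_VOCAB
    counts: dict[tuple[str, ...], Counter] = field(default_factory=dict)
    context_totals: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.smoothing not in ("mle", "laplace"):
            raise ValueError(f"unknown smoothing: {self.smoothing!r}")
        if START in self.predictive_vocab:
            raise ValueError("START is never predicted and cannot be in the predictive vocabulary")

    # -- convenience wrappers used by benchmark scorers ---------------------
    def perplexity(self, corpus: Corpus) -> float:
        return corpus_perplexity(self, corpus)

    def score(self, record: GeneRecord) -> float:
        """Perplexity of a single record (the mutation benchmark's scorer)."""
        logp, n = sequence_logprob(self, record)
        return math.inf if logp == -math.inf else math.exp(-logp / n)


def fit_ngram(
    corpus: Corpus,
    N: int,
    smoothing: str = "mle",
    predictive_vocab: tuple[str, ...] = DEFAULT_VOCAB,
) -> NgramModel:
    """Accumulate n-gram counts over every record of ``corpus``.

    Deterministic and order-independent: permuting the records yields
    identical counts.
    """
    if N < 1:
        raise ValueError("order must be >= 1")
    if len(corpus) == 0:
        raise ValueError("cannot fit on an empty corpus")
    model = NgramModel(order=N, smoothing=smoothing, predictive_vocab=tuple(predictive_vocab))
    counts: dict[tuple[str, ...], Counter] = defaultdict(Counter)
    totals: dict[tuple[str, ...], int] = defaultdict(int)
    for record in corpus:
        tokens = tokenize(record, n_start=max(N - 1, 1))
        start = N - 1 if N > 1 else 1  # N=1: skip the single pad token
        for i in range(start, len(tokens)):
            ctx = tuple(tokens[i - N + 1 : i])
            counts[ctx][tokens[i]] += 1
            totals[ctx] += 1
    model.counts = dict(counts)
    model.context_totals = dict(totals)
    return model


def next_token_prob(model: NgramModel, context: tuple[str, ...], token: str) -> float:
    """P(token | context) under the model's smoothing mode.

    MLE: c(context, token) / c(context); an unseen context (0/0) is reported
    as a zero-probability event.  Laplace: (c + 1) / (n + V).
    """
    if token == START:
        raise ValueError("START is never predicted")
    if len(context) != model.order - 1:
        raise ValueError(f"context must have length N-1 = {model.order - 1}")
    context = tuple(context)
    c = model.counts.get(context, {}).get(token, 0)
    n = model.context_totals.get(context, 0)
    if model.smoothing == "laplace":
        V = len(model.predictive_vocab)
        return (c + 1) / (n + V)
    return c / n if n > 0 else 0.0


def sequence_logprob(model: NgramModel, record: GeneRecord | str) -> tuple[float, int]:
    """(total log-probability, number of predicted tokens) for one record.

    Every non-START position is predicted, END included, so the count is
    ``len(sequence) + 1``.  Any zero-probability event makes the total -inf.
    """
    N = model.order
    tokens = tokenize(record, n_start=max(N - 1, 1))
    start = N - 1 if N > 1 else 1
    total = 0.0
    n_pred = 0
    for i in range(start, len(tokens)):
        p = next_token_prob(model, tuple(tokens[i - N + 1 : i]), tokens[i])
        n_pred += 1
        if p <= 0.0:
            total = -math.inf
        elif total != -math.inf:
            total += math.log(p)
    return total, n_pred


def corpus_perplexity(model: NgramModel, corpus: Corpus) -> float:
    """Pooled perplexity: exp(-sum(logp) / sum(n_predicted)); inf on any zero."""
    if len(corpus) == 0:
        raise ValueError("cannot evaluate on an empty corpus")
    total = 0.0
    n_pred = 0
    for record in corpus:
        lp, n = sequence_logprob(model, record)
        if lp == -math.inf:
            return math.inf
        total += lp
        n_pred += n
    return math.exp(-total / n_pred)


def generate_sequence(
    model: NgramModel,
    rng: np.random.Generator,
    max_len: int = 1000,
    gene_id: str = "generated",
) -> GeneRecord:
    """Sample nucleotides autoregressively until END or ``max_len``.

    The returned record's sequence excludes boundary tokens and may be
    empty if END is drawn immediately.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    vocab = model.predictive_vocab
    ctx = (START,) * (model.order - 1) if model.order > 1 else ()
    chars: list[str] = []
    while len(chars) < max_len:
        probs = np.array([next_token_prob(model, ctx, t) for t in vocab])
        s = probs.sum()
        if s <= 0.0:
            raise ValueError(f"model assigns zero total probability at context {ctx}")
        tok = vocab[int(rng.choice(len(vocab), p=probs / s))]
        if tok == END:
            break
        chars.append(tok)
        if model.order > 1:
            ctx = (ctx + (tok,))[-(model.order - 1):]
    return GeneRecord(gene_id=gene_id, sequence="".join(chars), gene_type="generated")


def ngram_param_count(model: NgramModel) -> int:
    """Number of stored (context, token) entries with a non-zero count."""
    return sum(1 for ctr in model.counts.values() for c in ctr.values() if c > 0)


# ---------------------------------------------------------------------------
# Serialization (flat JSON: order, smoothing, vocab, counts keyed by the
# context symbols joined into a string)


def save_ngram(model: NgramModel, path: str | Path) -> None:
    payload = {
        "order": model.order,
        "smoothing": model.smoothing,
        "predictive_vocab": list(model.predictive_vocab),
        "counts": {"".join(ctx): dict(ctr) for ctx, ctr in model.counts.items()},
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_ngram(path: str | Path) -> NgramModel:
    payload = json.loads(Path(path).read_text())
    order = int(payload["order"])
    counts = {tuple(key): Counter(ctr) for key, ctr in payload["counts"].items()}
    # context length is order-1; "".join is unambiguous for 1-char symbols
    model = NgramModel(
        order=order,
        smoothing=payload["smoothing"],
        predictive_vocab=tuple(payload["predictive_vocab"]),
        counts=counts,
        context_totals={ctx: sum(ctr.values()) for ctx, ctr in counts.items()},
    )
    return model
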