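"""LSTM and transformer next-token language models for nucleotide sequences.

Both architectures share the shape of the n-gram models' task: predict each
token of ``< seq >`` from everything before it.  The input layer learns a
token embedding plus a positional embedding; the body is a stack of LSTM
layers or of causally-masked transformer blocks; the head is a linear layer
with one unit per vocabulary symbol followed by softmax.  The vocabulary has
7 symbols — PAD, ``<``, A, C, G, T, ``>`` — and the loss masks PAD targets
(START never occurs as a target, being the first token of every sequence).

Training uses Adam, runs a fixed number of epochs (default 40), records
train/validation perplexity after every epoch, and keeps per-epoch weight
checkpoints so a reported result can be the epoch whose train/validation
perplexities agree to within a tolerance (default 0.02) — overfit epochs
are thereby never reported.

Everything runs on numpy via the package's reverse-mode autodiff core
(:mod:`genelm._autograd`); runs are deterministic for a given seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from ._autograd import Tensor, dropout, embedding, layer_norm, masked_nll, stack
from .data_io import ALPHABET, Corpus, END, GeneRecord, PAD, START

logger = logging.getLogger(__name__)

#: Neural vocabulary; PAD must be index 0.
VOCAB: tuple[str, ...] = (PAD, START) + tuple(ALPHABET) + (END,)
TOKEN_TO_ID = {t: i for i, t in enumerate(VOCAB)}
PAD_ID = TOKEN_TO_ID[PAD]


@dataclass(frozen=True)
class NeuralLMConfig:
    """Architecture and training hyperparameters.

    ``hidden_dim`` is the LSTM state size; ``ff_dim``/``num_heads`` apply to
    the transformer.  ``context_length`` bounds tokenized sequence length
    (1000-nt genes plus two boundary tokens fit in the default 1024).
    """

    architecture: str = "lstm"  # "lstm" | "transformer"
    embedding_dim: int = 32
    num_layers: int = 1
    hidden_dim: int = 64
    ff_dim: int = 64
    num_heads: int = 2
    context_length: int = 1024
    epochs: int = 40
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # final-epoch lr as a fraction of learning_rate (1.0 = constant)
    dropout: float = 0.0
    batch_size: int = 32
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("lstm", "transformer"):
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        if self.architecture == "transformer" and self.embedding_dim % self.num_heads != 0:
            raise ValueError("num_heads must divide embedding_dim")


@dataclass(frozen=True)
class SelectionRule:
    """Report the best-validation epoch among those with |train-val| < tolerance."""

    tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch (train perplexity, validation perplexity) pairs + checkpoints."""

    epochs: list[tuple[float, float]] = field(default_factory=list)
    checkpoints: list[dict[str, np.ndarray]] = field(default_factory=list)


def encode(record: GeneRecord | str) -> np.ndarray:
    seq = record.sequence if isinstance(record, GeneRecord) else record
    return np.array([TOKEN_TO_ID[START]] + [TOKEN_TO_ID[c] for c in seq] + [TOKEN_TO_ID[END]], dtype=np.int64)


# ---------------------------------------------------------------------------
# Models


class _Model:
    """Shared parameter bookkeeping for both architectures."""

    def __init__(self, config: NeuralLMConfig, vocab_size: int):
        self.config = config
        self.vocab_size = vocab_size
        self.params: dict[str, Tensor] = {}

    def _add(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array)
        self.params[name] = t
        return t

    def num_params(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()

    def score(self, record: GeneRecord) -> float:
        """Perplexity of a single record (the mutation benchmark's scorer)."""
        return neural_perplexity(self, Corpus([record]), batch_size=1)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, *shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def _uniform_embedding(rng: np.random.Generator, *shape) -> np.ndarray:
    return rng.uniform(-0.05, 0.05, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, _ = np.linalg.qr(a)
    return q[:rows, :cols] if q.shape[0] >= rows else q.T[:rows, :cols]


class LSTMLM(_Model):
    def __init__(self, config: NeuralLMConfig, vocab_size: int):
        super().__init__(config, vocab_size)
        rng = np.random.default_rng(config.seed)
        d, h = config.embedding_dim, config.hidden_dim
        self.emb = self._add("emb", _uniform_embedding(rng, vocab_size, d))
        self.pos = self._add("pos", _uniform_embedding(rng, config.context_length, d))
        self.layers = []
        for l in range(config.num_layers):
            d_in = d if l == 0 else h
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            wh = np.concatenate([_orthogonal(rng, h, h) for _ in range(4)], axis=1)
            self.layers.append(
                (
                    self._add(f"l{l}.Wx", _glorot(rng, d_in, 4 * h)),
                    self._add(f"l{l}.Wh", wh),
                    self._add(f"l{l}.b", b),
                )
            )
        # zero head: an untrained model is exactly uniform over the vocabulary
        self.head_w = self._add("head.w", np.zeros((h, vocab_size)))
        self.head_b = self._add("head.b", np.zeros(vocab_size))

    def forward(self, ids: np.ndarray, drop_rng: np.random.Generator | None = None) -> Tensor:
        """ids (B, T) -> logits (B, T, V); ``drop_rng`` enables training-mode dropout."""
        B, T = ids.shape
        h_dim = self.config.hidden_dim
        rate = self.config.dropout
        x = dropout(embedding(self.emb, ids) + self.pos[:T], rate, drop_rng)
        for Wx, Wh, b in self.layers:
            h = Tensor(np.zeros((B, h_dim)))
            c = Tensor(np.zeros((B, h_dim)))
            outs = []
            for t in range(T):
                gates = x[:, t] @ Wx + h @ Wh + b
                i = gates[:, :h_dim].sigmoid()
                f = gates[:, h_dim : 2 * h_dim].sigmoid()
                g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
                o = gates[:, 3 * h_dim :].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outs.append(h)
            x = dropout(stack(outs, axis=1), rate, drop_rng)
        return x @ self.head_w + self.head_b


class TransformerLM(_Model):
    def __init__(self, config: NeuralLMConfig, vocab_size: int):
        super().__init__(config, vocab_size)
        rng = np.random.default_rng(config.seed)
        d, ff = config.embedding_dim, config.ff_dim
        self.emb = self._add("emb", _uniform_embedding(rng, vocab_size, d))
        self.pos = self._add("pos", _uniform_embedding(rng, config.context_length, d))
        self.blocks = []
        for l in range(config.num_layers):
            blk = {
                name: self._add(f"b{l}.{name}", arr)
                for name, arr in [
                    ("Wq", _glorot(rng, d, d)), ("bq", np.zeros(d)),
                    ("Wk", _glorot(rng, d, d)), ("bk", np.zeros(d)),
                    ("Wv", _glorot(rng, d, d)), ("bv", np.zeros(d)),
                    ("Wo", _glorot(rng, d, d)), ("bo", np.zeros(d)),
                    ("ln1g", np.ones(d)), ("ln1b", np.zeros(d)),
                    ("W1", _glorot(rng, d, ff)), ("b1", np.zeros(ff)),
                    ("W2", _glorot(rng, ff, d)), ("b2", np.zeros(d)),
                    ("ln2g", np.ones(d)), ("ln2b", np.zeros(d)),
                ]
            }
            self.blocks.append(blk)
        self.lnf_g = self._add("lnf.g", np.ones(d))
        self.lnf_b = self._add("lnf.b", np.zeros(d))
        self.head_w = self._add("head.w", np.zeros((d, vocab_size)))
        self.head_b = self._add("head.b", np.zeros(vocab_size))

    def forward(self, ids: np.ndarray, drop_rng: np.random.Generator | None = None) -> Tensor:
        B, T = ids.shape
        d, H = self.config.embedding_dim, self.config.num_heads
        dh = d // H
        rate = self.config.dropout
        x = dropout(embedding(self.emb, ids) + self.pos[:T], rate, drop_rng)
        causal = np.triu(np.full((T, T), -1e9), k=1)  # no attention to the future
        # pre-norm residual blocks: x + MHA(LN(x)), x + FF(LN(x))
        for blk in self.blocks:
            a = layer_norm(x, blk["ln1g"], blk["ln1b"])
            q = ((a @ blk["Wq"] + blk["bq"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3))
            k = ((a @ blk["Wk"] + blk["bk"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3))
            v = ((a @ blk["Wv"] + blk["bv"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3))
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh)) + causal
            attn = scores.softmax(axis=-1) @ v
            x = x + dropout(attn.transpose(0, 2, 1, 3).reshape(B, T, d) @ blk["Wo"] + blk["bo"], rate, drop_rng)
            f = layer_norm(x, blk["ln2g"], blk["ln2b"])
            x = x + dropout((f @ blk["W1"] + blk["b1"]).relu() @ blk["W2"] + blk["b2"], rate, drop_rng)
        x = layer_norm(x, self.lnf_g, self.lnf_b)
        return x @ self.head_w + self.head_b


def build_model(config: NeuralLMConfig, vocab_size: int = len(VOCAB)) -> _Model:
    """Instantiate the configured architecture with seeded initial weights."""
    cls = LSTMLM if config.architecture == "lstm" else TransformerLM
    return cls(config, vocab_size)


def count_parameters(config: NeuralLMConfig, vocab_size: int = len(VOCAB)) -> int:
    """Closed-form trainable-parameter count (equals ``build_model(...).num_params()``)."""
    d = config.embedding_dim
    total = _embedding_param_count(vocab_size, d, config.context_length)
    if config.architecture == "lstm":
        h = config.hidden_dim
        for l in range(config.num_layers):
            d_in = d if l == 0 else h
            total += 4 * (d_in * h + h * h + h)
        total += h * vocab_size + vocab_size
    else:
        ff = config.ff_dim
        per_block = 4 * (d * d + d) + (d * ff + ff) + (ff * d + d) + 4 * d
        total += config.num_layers * per_block
        total += 2 * d  # final layer norm
        total += d * vocab_size + vocab_size
    return total


def _embedding_param_count(vocab_size: int, embedding_dim: int, context_length: int) -> int:
    """Token plus learned positional embedding: V*d + L*d."""
    return vocab_size * embedding_dim + context_length * embedding_dim


# ---------------------------------------------------------------------------
# Training & evaluation


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bucketed_order(encoded: list[np.ndarray], rng: np.random.Generator | None) -> np.ndarray:
    """Length-sorted record order (ties shuffled when ``rng`` is given).

    Grouping near-equal lengths into the same batch keeps per-batch padding
    waste small; the batch *order* is shuffled separately during training.
    """
    perm = rng.permutation(len(encoded)) if rng is not None else np.arange(len(encoded))
    return perm[np.argsort([len(encoded[i]) for i in perm], kind="stable")]


def _batches(
    encoded: list[np.ndarray],
    batch_size: int,
    order: np.ndarray,
    rng: np.random.Generator | None = None,
) -> Iterable[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (inputs, targets, mask) with per-batch PAD-right padding."""
    starts = list(range(0, len(order), batch_size))
    if rng is not None:
        rng.shuffle(starts)
    for lo in starts:
        chunk = [encoded[i] for i in order[lo : lo + batch_size]]
        T = max(len(s) for s in chunk)
        ids = np.full((len(chunk), T), PAD_ID, dtype=np.int64)
        for r, s in enumerate(chunk):
            ids[r, : len(s)] = s
        inputs = ids[:, :-1]
        targets = ids[:, 1:]
        mask = targets != PAD_ID
        yield inputs, targets, mask


def _encode_corpus(corpus: Corpus, context_length: int) -> list[np.ndarray]:
    encoded = [encode(r) for r in corpus]
    too_long = max((len(e) for e in encoded), default=0)
    if too_long > context_length:
        raise ValueError(f"tokenized length {too_long} exceeds context_length {context_length}")
    return encoded


def neural_perplexity(model: _Model, corpus: Corpus, batch_size: int | None = None) -> float:
    """Pooled per-token perplexity (PAD masked), same convention as the n-grams."""
    encoded = _encode_corpus(corpus, model.config.context_length)
    bs = batch_size or model.config.batch_size
    total, count = 0.0, 0
    for inputs, targets, mask in _batches(encoded, bs, _bucketed_order(encoded, None)):
        logits = model.forward(inputs)
        nll, n = masked_nll(logits, targets, mask)
        total += float(nll.data)
        count += n
    return math.exp(total / count)


def train(
    model: _Model,
    train_corpus: Corpus,
    validation_corpus: Corpus,
    config: NeuralLMConfig | None = None,
    keep_checkpoints: bool = True,
) -> TrainingHistory:
    """Run exactly ``config.epochs`` epochs of Adam; record both perplexities.

    The per-epoch weight snapshots let :func:`select_checkpoint` pick the
    reported epoch after training.
    """
    config = config or model.config
    if len(train_corpus) == 0 or len(validation_corpus) == 0:
        raise ValueError("train and validation corpora must be non-empty")
    encoded = _encode_corpus(train_corpus, config.context_length)
    _encode_corpus(validation_corpus, config.context_length)
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.params, config.learning_rate)
    history = TrainingHistory()
    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        opt.lr = config.learning_rate * (1.0 - (1.0 - config.lr_decay) * frac)
        order = _bucketed_order(encoded, rng)
        for inputs, targets, mask in _batches(encoded, config.batch_size, order, rng=rng):
            logits = model.forward(inputs, drop_rng=rng)
            nll, n = masked_nll(logits, targets, mask)
            loss = nll * (1.0 / n)
            loss.backward()
            if config.grad_clip is not None:
                norm = math.sqrt(sum(float((t.grad**2).sum()) for t in model.params.values()))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    for t in model.params.values():
                        t.grad *= scale
            opt.step()
        train_ppl = neural_perplexity(model, train_corpus)
        val_ppl = neural_perplexity(model, validation_corpus)
        history.epochs.append((train_ppl, val_ppl))
        if keep_checkpoints:
            history.checkpoints.append(model.state_dict())
    return history


def select_checkpoint(history: TrainingHistory, rule: SelectionRule = SelectionRule()) -> int:
    """Index (0-based) of the best-validation epoch with |train-val| < tolerance.

    If no epoch qualifies, falls back to the epoch with the smallest
    |train-val| gap and logs a warning.
    """
    if not history.epochs:
        raise ValueError("empty training history")
    qualifying = [i for i, (tr, va) in enumerate(history.epochs) if abs(tr - va) < rule.tolerance]
    if qualifying:
        return min(qualifying, key=lambda i: history.epochs[i][1])
    best = min(range(len(history.epochs)), key=lambda i: abs(history.epochs[i][0] - history.epochs[i][1]))
    logger.warning(
        "no epoch satisfies |train-val| < %s; falling back to the closest-gap epoch %d",
        rule.tolerance,
        best + 1,
    )
    return best


def restore_checkpoint(model: _Model, history: TrainingHistory, epoch: int) -> None:
    model.load_state_dict(history.checkpoints[epoch])


def config_grid(architecture: str, **param_lists: list) -> list[NeuralLMConfig]:
    """Cartesian hyperparameter grid, e.g. ``config_grid("lstm", hidden_dim=[64, 128])``."""
    import itertools

    keys = list(param_lists)
    configs = []
    for values in itertools.product(*(param_lists[k] for k in keys)):
        configs.append(NeuralLMConfig(architecture=architecture, **dict(zip(keys, values))))
    return configs
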