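"""Synthetic gene-like corpora from Markov chains with known parameters.

The generator serves two purposes.  First, with the default log-normal
length law it emulates the filtered human-gene corpus (lengths in [2, 1000],
median ~295, mean ~365) so the whole pipeline runs offline.  Second, in
*chain-termination* mode (``length_law=None``) sequences are sampled purely
from the Markov conditionals, END included, so that fitted n-gram models can
be checked against the ground-truth transition probabilities (parameter
recovery) and against the chain's exact entropy rate.

Boundary contexts — contexts still containing START padding — are given
zero END probability by :func:`random_sim_spec`, so every sequence carries
at least ``order`` nucleotides and maximum-likelihood recovery of the
conditionals is unbiased (no rejection of empty sequences is needed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ALPHABET, Corpus, END, GeneRecord, START

#: Symbols a Markov conditional distributes mass over, in storage order.
EMISSIONS: tuple[str, ...] = tuple(ALPHABET) + (END,)

_PROB_ATOL = 1e-12


@dataclass(frozen=True)
class LengthLaw:
    """Target-length distribution used when END is not sampled from the chain.

    ``kind="lognormal"``: lengths are ``round(exp(Normal(mu, sigma)))``
    truncated to ``[min_len, max_len]``.  ``kind="fixed"``: every sequence
    has length ``fixed_len``.
    """

    kind: str = "lognormal"
    mu: float = math.log(295.0)
    sigma: float = 0.6526
    min_len: int = 2
    max_len: int = 1000
    fixed_len: int = 0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.fixed_len, dtype=np.int64)
        if self.kind != "lognormal":
            raise ValueError(f"unknown length law: {self.kind!r}")
        a = (math.log(self.min_len) - self.mu) / self.sigma
        b = (math.log(self.max_len) - self.mu) / self.sigma
        z = stats.truncnorm.rvs(a, b, loc=self.mu, scale=self.sigma, size=n, random_state=rng)
        return np.clip(np.rint(np.exp(z)).astype(np.int64), self.min_len, self.max_len)


def default_length_law() -> LengthLaw:
    """Log-normal law matching the filtered gene corpus (median 295, mean ~365)."""
    return LengthLaw()


@dataclass(frozen=True)
class MarkovSimSpec:
    """Ground truth for a synthetic corpus: chain order, conditionals, lengths.

    ``transition_probs`` maps each context (tuple of ``order`` symbols, with
    START padding at sequence boundaries) to a probability vector over
    :data:`EMISSIONS` = (A, C, G, T, END).  ``length_law=None`` means lengths
    come from the chain's own END emissions (capped at ``max_len``).
    """

    order: int
    transition_probs: dict[tuple[str, ...], np.ndarray]
    n_records: int = 100
    seed: int = 0
    length_law: LengthLaw | None = None
    max_len: int = 1000

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        all_end = True
        for ctx, p in self.transition_probs.items():
            p = np.asarray(p, dtype=float)
            if len(ctx) != self.order:
                raise ValueError(f"context {ctx} has length != order {self.order}")
            if p.shape != (len(EMISSIONS),) or (p < 0).any():
                raise ValueError(f"invalid probability vector for context {ctx}")
            if abs(p.sum() - 1.0) > _PROB_ATOL:
                raise ValueError(f"probabilities for context {ctx} sum to {p.sum()!r}, not 1")
            if p[-1] < 1.0:
                all_end = False
        if all_end and self.transition_probs:
            raise ValueError("every context has P(END)=1: all sequences would be empty")


def markov_contexts(order: int) -> list[tuple[str, ...]]:
    """All contexts of a START-padded order-``order`` chain.

    Position ``i`` of a sequence is predicted from the last ``order`` symbols
    of ``'<' * order + seq[:i]``, so contexts are ``('<',)*k + w`` with ``w``
    a nucleotide word of length ``order - k``: (4**(order+1) - 1) / 3 in all.
    """
    out: list[tuple[str, ...]] = []
    for k in range(order, -1, -1):
        for w in itertools.product(ALPHABET, repeat=order - k):
            out.append((START,) * k + w)
    return out


def _is_boundary(ctx: tuple[str, ...]) -> bool:
    return START in ctx


def random_sim_spec(
    order: int,
    concentration: float = 1.0,
    seed: int = 0,
    end_prob: float | None = None,
    n_records: int = 100,
    length_law: LengthLaw | None = None,
    max_len: int = 1000,
) -> MarkovSimSpec:
    """Draw a random chain: one symmetric-Dirichlet conditional per context.

    Interior contexts get a Dirichlet(concentration) vector over the five
    emissions (or, when ``end_prob`` is given, that fixed END mass with the
    nucleotide part Dirichlet over four — handy for controlling the mean
    sequence length, ~1/end_prob).  Boundary contexts always get zero END
    mass so sequences are never shorter than ``order``.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    probs: dict[tuple[str, ...], np.ndarray] = {}
    for ctx in markov_contexts(order):
        if _is_boundary(ctx) or end_prob is not None:
            nuc = rng.dirichlet([concentration] * 4)
            pe = 0.0 if _is_boundary(ctx) else float(end_prob)
            p = np.concatenate([nuc * (1.0 - pe), [pe]])
        else:
            p = rng.dirichlet([concentration] * 5)
        probs[ctx] = p
    return MarkovSimSpec(
        order=order,
        transition_probs=probs,
        n_records=n_records,
        seed=seed,
        length_law=length_law,
        max_len=max_len,
    )


def true_conditional(spec: MarkovSimSpec, context: tuple[str, ...], symbol: str) -> float:
    """Ground-truth P(symbol | context) used by the generator."""
    context = tuple(context)
    if context not in spec.transition_probs:
        raise KeyError(f"unknown context: {context}")
    return float(spec.transition_probs[context][EMISSIONS.index(symbol)])


def generate_corpus(spec: MarkovSimSpec, provenance: str = "synthetic") -> Corpus:
    """Sample ``spec.n_records`` sequences; byte-identical for a given seed."""
    rng = np.random.default_rng(spec.seed)
    cum = {ctx: np.cumsum(p) for ctx, p in spec.transition_probs.items()}
    order = spec.order

    if spec.length_law is not None:
        # Target lengths from the law; END never sampled, nucleotide part
        # renormalized.
        cum_nuc = {}
        for ctx, p in spec.transition_probs.items():
            nuc = p[:4]
            tot = nuc.sum()
            if tot <= 0:
                raise ValueError(f"context {ctx} has no nucleotide mass; cannot use a length law")
            cum_nuc[ctx] = np.cumsum(nuc / tot)
        lengths = spec.length_law.sample(spec.n_records, rng)
    else:
        lengths = None

    records = []
    for i in range(spec.n_records):
        while True:
            chars: list[str] = []
            ctx = (START,) * order
            if lengths is not None:
                u = rng.random(int(lengths[i]))
                for t in range(int(lengths[i])):
                    j = int(np.searchsorted(cum_nuc[ctx], u[t], side="right"))
                    chars.append(ALPHABET[j])
                    ctx = (ctx + (ALPHABET[j],))[-order:] if order else ctx
            else:
                while len(chars) < spec.max_len:
                    j = int(np.searchsorted(cum[ctx], rng.random(), side="right"))
                    j = min(j, 4)
                    if EMISSIONS[j] == END:
                        break
                    chars.append(EMISSIONS[j])
                    ctx = (ctx + (EMISSIONS[j],))[-order:] if order else ctx
            if chars:
                break
            # order-0 chains may emit END immediately; resample (documented
            # length-distribution bias, conditionals elsewhere unaffected).
        records.append(GeneRecord(gene_id=f"SYN{i:06d}", sequence="".join(chars), gene_type="synthetic"))
    return Corpus(records, provenance=provenance)


def entropy_rate(spec: MarkovSimSpec) -> float:
    """Exact per-emission entropy rate (nats) of a chain-terminated spec.

    Treats the context process as an absorbing Markov chain (absorption on
    END), solves the expected visit counts nu(s) from the all-START state,
    and returns sum_s nu(s) H(s) / sum_s nu(s) — the pooled per-token
    entropy, END event included, matching the perplexity convention.
    exp(entropy_rate) is the large-sample bound for any model's perplexity
    on corpora drawn from the spec.  The ``max_len`` cap is ignored (its
    probability mass is negligible for any reasonable END mass).
    """
    if spec.length_law is not None:
        raise ValueError("entropy_rate is defined for chain-terminated specs (length_law=None)")
    contexts = list(spec.transition_probs)
    idx = {c: i for i, c in enumerate(contexts)}
    n = len(contexts)
    T = np.zeros((n, n))  # T[i, j] = P(next context j | context i), END excluded
    H = np.zeros(n)
    for c, i in idx.items():
        p = spec.transition_probs[c]
        nz = p[p > 0]
        H[i] = float(-(nz * np.log(nz)).sum())
        for j, sym in enumerate(ALPHABET):
            if p[j] > 0:
                nxt = (c + (sym,))[-spec.order:] if spec.order else c
                T[i, idx[nxt]] += p[j]
    start = np.zeros(n)
    start[idx[(START,) * spec.order]] = 1.0
    # nu = start + T' nu  =>  nu = (I - T')^-1 start
    nu = np.linalg.solve(np.eye(n) - T.T, start)
    return float((nu * H).sum() / nu.sum())
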