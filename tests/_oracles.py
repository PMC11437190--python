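"""Independent brute-force reference implementations used only by tests.

Deliberately written with plain nested loops and no shared code with the
package, so they can serve as oracles for the n-gram machinery.
"""

import math

PRED_VOCAB = ["A", "C", "G", "T", ">"]


def _pad(seq: str, N: int) -> list[str]:
    n_start = N - 1 if N > 1 else 1
    return ["<"] * n_start + list(seq) + [">"]


def brute_force_perplexity(train_seqs, eval_seqs, N, smoothing) -> float:
    """Pooled perplexity computed by explicit enumeration of all n-grams."""
    # collect every training n-gram as a tuple
    grams = []
    for s in train_seqs:
        toks = _pad(s, N)
        first = N - 1 if N > 1 else 1
        for i in range(first, len(toks)):
            grams.append(tuple(toks[i - N + 1 : i + 1]))

    total_logp = 0.0
    n_events = 0
    for s in eval_seqs:
        toks = _pad(s, N)
        first = N - 1 if N > 1 else 1
        for i in range(first, len(toks)):
            ctx = tuple(toks[i - N + 1 : i])
            tok = toks[i]
            num = 0
            den = 0
            for gram in grams:
                if gram[:-1] == ctx:
                    den += 1
                    if gram[-1] == tok:
                        num += 1
            if smoothing == "laplace":
                p = (num + 1) / (den + len(PRED_VOCAB))
            else:
                p = num / den if den else 0.0
            n_events += 1
            if p == 0.0:
                return math.inf
            total_logp += math.log(p)
    return math.exp(-total_logp / n_events)
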