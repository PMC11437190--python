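"""Real-vs-mutated discrimination benchmark for sequence language models.

A benchmark dataset is a set of pairs (real gene sequence, mutated copy).
The mutated copy is produced by a randomized procedure: draw the number of
edits uniformly between 1 and ``max_changes`` (inclusive), then apply that
many edits, each chosen uniformly among inserting a random nucleotide at a
random position, deleting a random position, and substituting a random
position with a *different* nucleotide.  A language model discriminates by
scoring both members: the lower-perplexity member is predicted to be the
real gene, and accuracy is the fraction of pairs predicted correctly.
Exact perplexity ties (including both-infinite) count as incorrect.

An externally supplied CSV of real mutation pairs (e.g. curated from a
clinical mutation database) can be loaded into the same evaluator.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data_io import ALPHABET, Corpus, GeneRecord

logger = logging.getLogger(__name__)

#: Scorer interface: perplexity of a single record (lower = more gene-like).
Scorer = Callable[[GeneRecord], float]

KINDS = ("insert", "delete", "substitute")


@dataclass(frozen=True)
class MutationConfig:
    n_pairs: int = 1000
    max_changes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.max_changes < 1:
            raise ValueError("n_pairs and max_changes must be >= 1")


@dataclass(frozen=True)
class MutationOp:
    """One edit; ``position`` is a 0-based index, ``base`` applies to insert/substitute."""

    kind: str
    position: int
    base: str = ""


@dataclass(frozen=True)
class MutationPair:
    real: GeneRecord
    mutated: str
    ops: tuple[MutationOp, ...] = ()


def sample_num_changes(max_changes: int, rng: np.random.Generator) -> int:
    """Uniform integer in [1, max_changes], both ends inclusive."""
    if max_changes < 1:
        raise ValueError("max_changes must be >= 1")
    return int(rng.integers(1, max_changes + 1))


def apply_mutation(sequence: str, op: MutationOp) -> str:
    if op.kind == "insert":
        if not (0 <= op.position <= len(sequence)):
            raise ValueError(f"insert position {op.position} out of range")
        return sequence[: op.position] + op.base + sequence[op.position :]
    if not (0 <= op.position < len(sequence)):
        raise ValueError(f"{op.kind} position {op.position} out of range (length {len(sequence)})")
    if op.kind == "delete":
        return sequence[: op.position] + sequence[op.position + 1 :]
    if op.kind == "substitute":
        if op.base == sequence[op.position]:
            raise ValueError("substitution must change the nucleotide")
        return sequence[: op.position] + op.base + sequence[op.position + 1 :]
    raise ValueError(f"unknown op kind: {op.kind!r}")


def mutate_sequence(
    sequence: str, num_changes: int, rng: np.random.Generator
) -> tuple[str, tuple[MutationOp, ...]]:
    """Apply ``num_changes`` sequential random edits.

    Edit kinds are equiprobable; insert positions span the L+1 slots,
    delete/substitute positions the current length, insert bases are uniform
    over {A,C,G,T} and substitute bases uniform over the 3 alternatives.  If
    the working sequence is empty and a delete (or substitute) is drawn, the
    kind is redrawn so the procedure is total.
    """
    if num_changes < 1:
        raise ValueError("num_changes must be >= 1")
    if not sequence:
        raise ValueError("cannot mutate an empty sequence")
    ops: list[MutationOp] = []
    current = sequence
    for _ in range(num_changes):
        while True:
            kind = KINDS[int(rng.integers(0, 3))]
            if current or kind == "insert":
                break
        if kind == "insert":
            pos = int(rng.integers(0, len(current) + 1))
            base = ALPHABET[int(rng.integers(0, 4))]
            op = MutationOp("insert", pos, base)
        elif kind == "delete":
            op = MutationOp("delete", int(rng.integers(0, len(current))))
        else:
            pos = int(rng.integers(0, len(current)))
            alternatives = [b for b in ALPHABET if b != current[pos]]
            op = MutationOp("substitute", pos, alternatives[int(rng.integers(0, 3))])
        current = apply_mutation(current, op)
        ops.append(op)
    return current, tuple(ops)


def build_mutation_dataset(test_corpus: Corpus, config: MutationConfig) -> list[MutationPair]:
    """``n_pairs`` (real, mutated) pairs, reproducible from ``config.seed``.

    Real members are drawn without replacement until the corpus is
    exhausted, then further permutation passes are made.  Pairs whose
    mutated copy coincidentally equals the original (possible from two
    cancelling edits) are kept and logged; they can only be scored as ties.
    """
    n = len(test_corpus)
    if n == 0:
        raise ValueError("test corpus is empty")
    rng = np.random.default_rng(config.seed)
    indices: list[int] = []
    while len(indices) < config.n_pairs:
        indices.extend(rng.permutation(n)[: config.n_pairs - len(indices)])
    pairs = []
    n_identity = 0
    for idx in indices:
        real = test_corpus[int(idx)]
        k = sample_num_changes(config.max_changes, rng)
        mutated, ops = mutate_sequence(real.sequence, k, rng)
        if mutated == real.sequence:
            n_identity += 1
        pairs.append(MutationPair(real=real, mutated=mutated, ops=ops))
    if n_identity:
        logger.info("%d/%d pairs have a mutated copy identical to the original", n_identity, len(pairs))
    return pairs


def discriminate(scorer: Scorer, pair: MutationPair) -> bool:
    """True iff the scorer assigns strictly lower perplexity to the real member.

    Ties — including both members scoring infinity — are conservatively
    counted as incorrect.
    """
    ppl_real = scorer(pair.real)
    ppl_mut = scorer(GeneRecord(gene_id=f"{pair.real.gene_id}:mut", sequence=pair.mutated))
    return ppl_real < ppl_mut


def evaluate_accuracy(scorer: Scorer, pairs: Sequence[MutationPair]) -> float:
    """Fraction of pairs whose real member gets the lower perplexity."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    return sum(discriminate(scorer, p) for p in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# CSV exchange format


def write_pairs(pairs: Sequence[MutationPair], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id", "real_sequence", "mutated_sequence", "ops_json"])
        for i, p in enumerate(pairs):
            ops = [{"kind": o.kind, "position": o.position, "base": o.base} for o in p.ops]
            writer.writerow([p.real.gene_id or f"pair{i}", p.real.sequence, p.mutated, json.dumps(ops)])


def load_real_pairs(path: str | Path) -> list[MutationPair]:
    """Read (pair_id, real_sequence, mutated_sequence[, mutation_info/ops_json]).

    Rows lacking either sequence are rejected with a logged count; the
    ``ops`` field of loaded pairs is left empty unless an ``ops_json``
    column is present.
    """
    pairs: list[MutationPair] = []
    n_rejected = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        required = {"pair_id", "real_sequence", "mutated_sequence"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader):
            real = (row.get("real_sequence") or "").strip().upper()
            mut = (row.get("mutated_sequence") or "").strip().upper()
            if not real or not mut or not set(real) <= set(ALPHABET) or not set(mut) <= set(ALPHABET):
                n_rejected += 1
                continue
            ops: tuple[MutationOp, ...] = ()
            if row.get("ops_json"):
                try:
                    ops = tuple(MutationOp(**d) for d in json.loads(row["ops_json"]))
                except (json.JSONDecodeError, TypeError):
                    logger.warning("%s row %d: unparseable ops_json; leaving ops empty", path, i)
            pairs.append(
                MutationPair(
                    real=GeneRecord(gene_id=row.get("pair_id") or f"pair{i}", sequence=real),
                    mutated=mut,
                    ops=ops,
                )
            )
    if n_rejected:
        logger.info("%s: rejected %d malformed row(s)", path, n_rejected)
    if not pairs:
        raise ValueError(f"{path}: no usable pairs")
    return pairs
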