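"""Gene-sequence corpus I/O, tokenization, length filtering and splitting.

A *corpus* is an ordered collection of gene records, each carrying a
nucleotide sequence over {A, C, G, T}.  Sequences are framed with a start
symbol ``<`` and an end symbol ``>`` at tokenization time; the raw stored
sequence never contains them.  Corpora are read from a CSV gene table
(NCBI-style columns: gene id, symbol, description, gene type, nucleotide
sequence) or from FASTA.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Nucleotide alphabet; the token vocabulary of every model in this package.
ALPHABET = "ACGT"
#: Start-of-gene boundary symbol (conditioning context only, never predicted).
START = "<"
#: End-of-gene boundary symbol (a predicted token).
END = ">"
#: Padding symbol used by the neural models.
PAD = "_"

#: IUPAC ambiguity codes (anything that is not a concrete A/C/G/T).
IUPAC_AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass(frozen=True)
class GeneRecord:
    """One gene: a nucleotide sequence plus NCBI-style identifiers."""

    gene_id: str
    sequence: str
    symbol: str = ""
    description: str = ""
    gene_type: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Corpus:
    """Ordered collection of :class:`GeneRecord` with unique identifiers."""

    records: list[GeneRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record identifiers must be unique within a corpus")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> GeneRecord:
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.records], dtype=np.int64)


@dataclass(frozen=True)
class FilterSpec:
    """Length filter; bounds are inclusive."""

    max_length: int = 1000
    min_length: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("require 1 <= min_length <= max_length")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split proportions.

    ``test_fraction`` is taken from the whole corpus, then
    ``validation_fraction_of_train`` from the remaining training portion.
    The kept (training-side) portion is floored at each stage, so e.g.
    n=22,886 with the defaults yields 18,308 train+validation and 4,578 test.
    """

    test_fraction: float = 0.20
    validation_fraction_of_train: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.validation_fraction_of_train):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# Loading


_SEQ_ALIASES = ("sequence", "nucleotide sequence", "nucleotide_sequence", "seq")
_ID_ALIASES = ("geneid", "gene_id", "gene id", "ncbi gene id", "ncbigeneid", "id")
_SYMBOL_ALIASES = ("symbol", "gene symbol", "gene_symbol", "name")
_DESC_ALIASES = ("description", "desc")
_TYPE_ALIASES = ("gene_type", "gene type", "genetype", "type")


def _find_column(header: Sequence[str], aliases: Sequence[str]) -> str | None:
    lowered = {h.strip().lower(): h for h in header}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    return None


def _clean_sequence(raw: str) -> str:
    """Upper-case and strip the surrounding ``<``/``>`` boundary markers."""
    s = raw.strip().upper()
    if s.startswith(START):
        s = s[1:]
    if s.endswith(END):
        s = s[:-1]
    return s


def load_gene_table(
    path: str | Path,
    format: str | None = None,
    sequence_column: str | None = None,
    drop_ambiguous: bool = True,
    provenance: str | None = None,
) -> Corpus:
    """Read a corpus from a CSV gene table or a FASTA file.

    CSV needs a header row and a nucleotide-sequence column (found among
    common aliases unless ``sequence_column`` names it).  Sequences are
    upper-cased and surrounding ``<``/``>`` markers stripped.  Records whose
    sequence is empty or contains characters outside {A,C,G,T} are dropped
    and counted (``drop_ambiguous=False`` instead maps every IUPAC ambiguity
    code to ``N`` and keeps the record; models must then be fitted with an
    extended alphabet).
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "csv"
    if format == "csv":
        records = _load_csv(path, sequence_column)
    elif format == "fasta":
        records = _load_fasta(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if not records:
        raise ValueError(f"{path}: no records found (empty corpus)")

    kept: list[GeneRecord] = []
    n_rejected = 0
    accepted = set(ALPHABET)
    for rec in records:
        seq = rec.sequence
        if not seq:
            n_rejected += 1
            continue
        if set(seq) <= accepted:
            kept.append(rec)
        elif drop_ambiguous:
            n_rejected += 1
        else:
            mapped = "".join(c if c in accepted else "N" for c in seq)
            kept.append(GeneRecord(rec.gene_id, mapped, rec.symbol, rec.description, rec.gene_type))
    if n_rejected:
        logger.info("%s: rejected %d record(s) with empty or non-ACGT sequences", path, n_rejected)
    if not kept:
        raise ValueError(f"{path}: every record was rejected")
    return Corpus(kept, provenance=provenance or str(path))


def _load_csv(path: Path, sequence_column: str | None) -> list[GeneRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        header = reader.fieldnames
        seq_col = sequence_column or _find_column(header, _SEQ_ALIASES)
        if seq_col is None or seq_col not in header:
            raise ValueError(f"{path}: no nucleotide-sequence column found in header {header}")
        id_col = _find_column(header, _ID_ALIASES)
        sym_col = _find_column(header, _SYMBOL_ALIASES)
        desc_col = _find_column(header, _DESC_ALIASES)
        type_col = _find_column(header, _TYPE_ALIASES)
        records = []
        for i, row in enumerate(reader):
            gene_id = (row.get(id_col) or "").strip() if id_col else ""
            records.append(
                GeneRecord(
                    gene_id=gene_id or f"row{i}",
                    sequence=_clean_sequence(row.get(seq_col) or ""),
                    symbol=(row.get(sym_col) or "").strip() if sym_col else "",
                    description=(row.get(desc_col) or "").strip() if desc_col else "",
                    gene_type=(row.get(type_col) or "").strip() if type_col else "",
                )
            )
    return records


def _load_fasta(path: Path) -> list[GeneRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        records.append(
            GeneRecord(
                gene_id=rec.id,
                sequence=_clean_sequence(str(rec.seq)),
                symbol=parts[1].split()[0] if len(parts) > 1 else "",
                description=parts[1] if len(parts) > 1 else "",
            )
        )
    return records


def write_gene_table(corpus: Corpus, path: str | Path) -> None:
    """Write the CSV gene-table dialect read by :func:`load_gene_table`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["GeneID", "Symbol", "Description", "Gene_Type", "Sequence"])
        for r in corpus:
            writer.writerow([r.gene_id, r.symbol, r.description, r.gene_type, r.sequence])


def write_fasta(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in corpus:
            desc = f" {r.symbol}" if r.symbol else ""
            fh.write(f">{r.gene_id}{desc}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Filtering, splitting, tokenization, statistics


def filter_by_length(corpus: Corpus, spec: FilterSpec = FilterSpec()) -> Corpus:
    """Keep records with ``min_length <= len <= max_length`` (order preserved)."""
    kept = [r for r in corpus if spec.min_length <= len(r) <= spec.max_length]
    return Corpus(kept, provenance=corpus.provenance)


def split_corpus(corpus: Corpus, spec: SplitSpec = SplitSpec()) -> tuple[Corpus, Corpus, Corpus]:
    """Random, seed-reproducible (train, validation, test) partition.

    Sizes: ``n_trainval = floor(n * (1 - test_fraction))``, test takes the
    remainder; validation is carved from the training portion the same way.
    Record order inside each partition follows the input corpus.
    """
    n = len(corpus)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    n_trainval = math.floor(n * (1.0 - spec.test_fraction))
    n_test = n - n_trainval
    n_train = math.floor(n_trainval * (1.0 - spec.validation_fraction_of_train))
    n_val = n_trainval - n_train
    if min(n_train, n_val, n_test) == 0:
        raise ValueError(
            f"split of n={n} with {spec} yields an empty partition "
            f"(train={n_train}, val={n_val}, test={n_test})"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    idx_train = sorted(perm[:n_train])
    idx_val = sorted(perm[n_train:n_trainval])
    idx_test = sorted(perm[n_trainval:])
    make = lambda idx, name: Corpus([corpus[i] for i in idx], provenance=f"{corpus.provenance}:{name}")
    return make(idx_train, "train"), make(idx_val, "validation"), make(idx_test, "test")


def tokenize(record: GeneRecord | str, n_start: int = 1) -> list[str]:
    """``n_start`` start symbols, one token per nucleotide, one end symbol.

    An order-N n-gram model conditions on N-1 tokens, so it consumes
    sequences tokenized with ``n_start = N - 1`` (minimum 1).
    """
    if n_start < 1:
        raise ValueError("n_start must be >= 1")
    seq = record.sequence if isinstance(record, GeneRecord) else record
    return [START] * n_start + list(seq) + [END]


def detokenize(tokens: Iterable[str]) -> str:
    """Strip boundary tokens; inverse of :func:`tokenize`."""
    return "".join(t for t in tokens if t not in (START, END, PAD))


def corpus_stats(corpus: Corpus) -> dict[str, float]:
    """Count/min/max/mean/median of raw sequence lengths (no boundary tokens)."""
    if len(corpus) == 0:
        raise ValueError("corpus_stats requires a non-empty corpus")
    lengths = corpus.lengths()
    return {
        "count": int(lengths.size),
        "min": int(lengths.min()),
        "max": int(lengths.max()),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
    }


def write_stats(stats: dict[str, float], path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats, indent=2) + "\n")


def write_split_manifest(
    splits: dict[str, Corpus], path: str | Path
) -> None:
    """CSV manifest mapping each record id to its partition name."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene_id", "partition"])
        for name, part in splits.items():
            for r in part:
                writer.writerow([r.gene_id, name])
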