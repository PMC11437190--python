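import numpy as np
import pytest

from genelm import Corpus, GeneRecord


def make_corpus(seqs, prefix="g"):
    return Corpus([GeneRecord(gene_id=f"{prefix}{i}", sequence=s) for i, s in enumerate(seqs)])


def random_corpus(rng, n_records, min_len=1, max_len=6):
    """Small random ACGT corpus for oracle comparisons."""
    seqs = []
    for _ in range(n_records):
        L = int(rng.integers(min_len, max_len + 1))
        seqs.append("".join(rng.choice(list("ACGT"), size=L)))
    return make_corpus(seqs)


@pytest.fixture
def acg_corpus():
    """The single-record corpus used throughout the hand-worked examples."""
    return make_corpus(["ACG"])


@pytest.fixture
def gene_table_csv(tmp_path):
    path = tmp_path / "genes.csv"
    path.write_text(
        "GeneID,Symbol,Description,Gene_Type,Sequence\n"
        "1,AAA,first gene,protein-coding,<ACGT>\n"
        "2,BBB,second gene,ncRNA,ggcc\n"
        "3,CCC,third gene,protein-coding,<TTTTAAAA>\n"
    )
    return path
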