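"""Fixed-length integer encoding of protein sequences.

Targets enter the model as amino-acid label vectors: each residue maps
to an integer, sequences are truncated or zero-padded to ``max_len``,
and index 0 is reserved for padding so an embedding layer can treat it
separately.  The vocabulary is the 20 standard amino acids plus a single
"unknown" index that absorbs the non-standard letters (B, J, O, U, X, Z)
found in real UniProt records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

__all__ = ["AMINO_ACIDS", "DEFAULT_VOCAB", "ProteinEncoding",
           "SequenceError", "encode_sequence", "read_fasta"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residue -> index; 0 = padding, 1..20 = standard residues, 21 = unknown.
DEFAULT_VOCAB = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
UNKNOWN_INDEX = len(AMINO_ACIDS) + 1

#: number of embedding rows needed (padding + residues + unknown)
VOCAB_SIZE = UNKNOWN_INDEX + 1


class SequenceError(ValueError):
    pass


@dataclass
class ProteinEncoding:
    labels: np.ndarray          # [max_len] int
    vocab: dict
    original_length: int


def encode_sequence(seq: str, vocab: dict | None = None,
                    max_len: int = 1000) -> ProteinEncoding:
    """Map a sequence to a length-``max_len`` integer label vector.

    Characters are looked up case-insensitively; anything outside the
    vocabulary maps to the unknown index.  Longer sequences truncate at
    ``max_len``, shorter ones are zero-padded on the right.
    """
    if max_len < 1:
        raise SequenceError("max_len must be >= 1")
    if not seq:
        raise SequenceError("empty protein sequence")
    if vocab is None:
        vocab = DEFAULT_VOCAB
    labels = np.zeros(max_len, dtype=np.intp)
    for i, ch in enumerate(seq[:max_len]):
        labels[i] = vocab.get(ch.upper(), UNKNOWN_INDEX)
    return ProteinEncoding(labels, vocab, len(seq))


def read_fasta(path) -> list[str]:
    """Sequences of a FASTA file in record order; headers discarded."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
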