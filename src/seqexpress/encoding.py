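"""Fractional one-hot encoding of IUPAC nucleotide sequences.

Each sequence position becomes a 4-vector over the channels (A, C, G, T).
Unambiguous bases put probability 1 on their channel; ambiguity codes spread
unit mass uniformly over the compatible bases (R -> 0.5 A + 0.5 G, N -> 0.25
each, ...), so every column sums to 1 and the matrix can be read as a
per-position base distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fixed channel order; serialized with model checkpoints.
CHANNELS = ("A", "C", "G", "T")

_IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


class EncodingError(ValueError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""


def _build_lookup() -> np.ndarray:
    table = np.full((128, 4), np.nan, dtype=np.float32)
    for code, bases in _IUPAC_BASES.items():
        col = np.zeros(4, dtype=np.float32)
        for b in bases:
            col[CHANNELS.index(b)] = 1.0 / len(bases)
        table[ord(code)] = col
        table[ord(code.lower())] = col
    return table


_LOOKUP = _build_lookup()


@dataclass
class OneHotMatrix:
    """4 x L fractional one-hot matrix for one gene's sequence window."""

    values: np.ndarray  # shape (4, L), float32, columns sum to 1
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2 or self.values.shape[0] != 4:
            raise ValueError(f"expected a 4 x L matrix, got shape {self.values.shape}")

    @property
    def length(self) -> int:
        return self.values.shape[1]


def one_hot(seq: str, gene_id: str = "") -> OneHotMatrix:
    """Encode an IUPAC nucleotide string as a 4 x L fractional one-hot matrix.

    Raises
    ------
    EncodingError
        If ``seq`` contains a character outside the IUPAC alphabet; the
        message names the offending character and its 0-based position.
    """
    codes = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    if codes.size and codes.max() >= 128:
        bad = int(np.argmax(codes >= 128))
        raise EncodingError(f"non-IUPAC character {seq[bad]!r} at position {bad}")
    mat = _LOOKUP[codes].T  # (4, L)
    if np.isnan(mat).any():
        bad = int(np.argmax(np.isnan(mat[0])))
        raise EncodingError(f"non-IUPAC character {seq[bad]!r} at position {bad}")
    return OneHotMatrix(values=mat, gene_id=gene_id)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence, mapping IUPAC codes to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_batch(seqs: list[str], gene_ids: list[str] | None = None) -> np.ndarray:
    """Stack one-hot encodings of equal-length sequences into (N, 4, L)."""
    if gene_ids is None:
        gene_ids = [""] * len(seqs)
    mats = [one_hot(s, g).values for s, g in zip(seqs, gene_ids)]
    lengths = {m.shape[1] for m in mats}
    if len(lengths) > 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    return np.stack(mats)


def save_encoded_batch(prefix, batch: np.ndarray, gene_ids: list[str]) -> None:
    """Store an encoded (N, 4, L) batch as ``<prefix>.npy`` plus a gene-order
    manifest ``<prefix>.genes.tsv``."""
    from pathlib import Path

    prefix = Path(prefix)
    if batch.shape[0] != len(gene_ids):
        raise ValueError("batch size and gene-id count differ")
    np.save(str(prefix) + ".npy", batch.astype(np.float32))
    Path(str(prefix) + ".genes.tsv").write_text("\n".join(gene_ids) + "\n")


def load_encoded_batch(prefix) -> tuple[np.ndarray, list[str]]:
    """Inverse of :func:`save_encoded_batch`."""
    from pathlib import Path

    batch = np.load(str(prefix) + ".npy")
    gene_ids = Path(str(prefix) + ".genes.tsv").read_text().splitlines()
    return batch, gene_ids
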