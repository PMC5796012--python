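"""DNA alignment reading/writing and site-pattern compression.

Alignments are assumed pre-aligned (equal-length rows).  Characters are
mapped to nucleotide *state sets* encoded as 4-bit masks over (A, C, G, T);
IUPAC ambiguity codes keep their standard meaning, while gaps ('-', '.')
and 'N'/'?' become full ambiguity {A,C,G,T} -- the usual missing-data
convention for both parsimony and likelihood scoring.

Distinct alignment columns are collapsed into weighted *site patterns* so
each scorer evaluates every pattern once and multiplies by its multiplicity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "Alignment",
    "SitePatterns",
    "NUCLEOTIDES",
    "CHAR_TO_MASK",
    "read_alignment",
    "read_fasta",
    "read_phylip",
    "write_fasta",
    "compress_patterns",
]

NUCLEOTIDES = "ACGT"

# 4-bit state-set masks: bit 0 = A, 1 = C, 2 = G, 3 = T.
CHAR_TO_MASK: Dict[str, int] = {
    "A": 0b0001,
    "C": 0b0010,
    "G": 0b0100,
    "T": 0b1000,
    "U": 0b1000,
    "R": 0b0101,  # A/G
    "Y": 0b1010,  # C/T
    "S": 0b0110,  # C/G
    "W": 0b1001,  # A/T
    "K": 0b1100,  # G/T
    "M": 0b0011,  # A/C
    "B": 0b1110,  # C/G/T
    "D": 0b1101,  # A/G/T
    "H": 0b1011,  # A/C/T
    "V": 0b0111,  # A/C/G
    "N": 0b1111,
    "X": 0b1111,
    "?": 0b1111,
    "-": 0b1111,
    ".": 0b1111,
}


class AlignmentError(ValueError):
    """Raised for unreadable or inconsistent alignment input."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length DNA sequences with unique taxon labels."""

    labels: Tuple[str, ...]
    sequences: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise AlignmentError("empty alignment")
        if len(self.labels) != len(set(self.labels)):
            raise AlignmentError("duplicate taxon labels in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        for lab, seq in zip(self.labels, self.sequences):
            for ch in seq:
                if ch not in CHAR_TO_MASK:
                    raise AlignmentError(f"invalid character {ch!r} in sequence {lab!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.labels)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: os.PathLike | str) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(
        labels=tuple(r.id for r in records),
        sequences=tuple(_normalize(str(r.seq)) for r in records),
    )


def read_phylip(path: os.PathLike | str) -> Alignment:
    """Relaxed PHYLIP reader (sequential or single-block interleaved).

    The header gives taxon and site counts; names are whitespace-delimited
    (no 10-character limit) and sequence data may continue over several
    tokens/lines until each row reaches the stated length.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 2:
        raise AlignmentError(f"missing PHYLIP header in {path}")
    try:
        n_taxa, n_sites = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise AlignmentError(f"bad PHYLIP header {tokens[:2]} in {path}") from exc
    pos = 2
    labels: List[str] = []
    seqs: List[str] = []
    for _ in range(n_taxa):
        if pos >= len(tokens):
            raise AlignmentError(f"truncated PHYLIP file {path}")
        labels.append(tokens[pos])
        pos += 1
        chunks: List[str] = []
        got = 0
        while got < n_sites:
            if pos >= len(tokens):
                raise AlignmentError(
                    f"sequence for {labels[-1]!r} shorter than header length {n_sites}"
                )
            chunks.append(tokens[pos])
            got += len(tokens[pos])
            pos += 1
        seq = "".join(chunks)
        if len(seq) != n_sites:
            raise AlignmentError(
                f"sequence for {labels[-1]!r} has {len(seq)} sites, header says {n_sites}"
            )
        seqs.append(_normalize(seq))
    return Alignment(labels=tuple(labels), sequences=tuple(seqs))


def read_alignment(path: os.PathLike | str, format: str = "fasta") -> Alignment:
    """Read a DNA alignment; `format` is ``fasta`` or ``phylip``."""
    if format == "fasta":
        return read_fasta(path)
    if format == "phylip":
        return read_phylip(path)
    raise AlignmentError(f"unknown alignment format {format!r}")


def write_fasta(aln: Alignment, path: os.PathLike | str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for lab, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{lab}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class SitePatterns:
    """Column-compressed alignment: distinct columns with multiplicities.

    `masks[i, j]` is the 4-bit state-set of taxon i at pattern j; patterns
    appear in order of first occurrence and `weights` sums to the original
    alignment length.
    """

    taxa: Tuple[str, ...]
    masks: np.ndarray  # (n_taxa, n_patterns) uint8
    weights: np.ndarray  # (n_patterns,) int64

    @property
    def n_patterns(self) -> int:
        return int(self.masks.shape[1])

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    def row_of(self, taxon: str) -> int:
        return self.taxa.index(taxon)


def compress_patterns(aln: Alignment) -> SitePatterns:
    """Collapse identical columns; first-occurrence order, integer weights."""
    mat = np.empty((aln.n_taxa, aln.length), dtype=np.uint8)
    for i, seq in enumerate(aln.sequences):
        mat[i] = [CHAR_TO_MASK[ch] for ch in seq]
    seen: Dict[bytes, int] = {}
    cols: List[np.ndarray] = []
    weights: List[int] = []
    for j in range(aln.length):
        key = mat[:, j].tobytes()
        idx = seen.get(key)
        if idx is None:
            seen[key] = len(cols)
            cols.append(mat[:, j])
            weights.append(1)
        else:
            weights[idx] += 1
    masks = np.stack(cols, axis=1) if cols else np.empty((aln.n_taxa, 0), dtype=np.uint8)
    return SitePatterns(
        taxa=tuple(aln.labels),
        masks=masks,
        weights=np.asarray(weights, dtype=np.int64),
    )
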