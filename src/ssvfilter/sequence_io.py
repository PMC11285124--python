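"""FASTA input, 2-bit nucleotide encoding, and the concatenated target space.

Targets are packed into one global coordinate vector in file order, padded
at the end with random residues so the total length is a multiple of the
engine's segment width. IUPAC ambiguity letters are replaced, at encode time,
by a letter drawn from the code's expansion using a seeded generator; the
substituted positions are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
LETTER_OF = "ACGT"

#: IUPAC ambiguity expansions, as tuples of 2-bit codes.
IUPAC_EXPANSION = {
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3),
}

_VALID_LETTERS = frozenset(CODE_OF) | frozenset(IUPAC_EXPANSION)


class FastaError(ValueError):
    pass


@dataclass
class EncodedSequence:
    """A 2-bit encoded nucleotide sequence (A=0, C=1, G=2, T=3)."""

    name: str
    codes: np.ndarray
    ambiguity_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 3):
            raise ValueError("codes must lie in {0,1,2,3}")

    @property
    def length(self) -> int:
        return int(self.codes.size)


@dataclass
class SequenceDB:
    """Concatenated, padded target collection in global coordinates."""

    sequences: list[EncodedSequence]
    segment_width: int
    rng_seed: int
    offsets: np.ndarray = field(init=False)
    padding_start: int = field(init=False)
    padded_length: int = field(init=False)
    concatenated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("SequenceDB requires at least one sequence")
        if self.segment_width < 1:
            raise ValueError("segment width must be >= 1")
        lengths = [s.length for s in self.sequences]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
        self.padding_start = int(sum(lengths))
        n = self.segment_width
        self.padded_length = ((self.padding_start + n - 1) // n) * n
        if self.padded_length == 0:
            self.padded_length = n
        pad = self.padded_length - self.padding_start
        rng = np.random.default_rng(self.rng_seed)
        padding = rng.integers(0, 4, size=pad, dtype=np.uint8)
        self.concatenated = np.concatenate(
            [s.codes for s in self.sequences] + [padding]
        ).astype(np.uint8)

    def locate(self, seq_pos: int) -> tuple[int, int]:
        """Map a global sequence position to (sequence index, local 0-based position).

        Positions at or beyond ``padding_start`` raise IndexError; they fall
        in the random padding.
        """
        if not 0 <= seq_pos < self.padding_start:
            raise IndexError(f"sequence position {seq_pos} outside [0, {self.padding_start})")
        idx = int(np.searchsorted(self.offsets, seq_pos, side="right")) - 1
        return idx, seq_pos - int(self.offsets[idx])


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (name, residues) in file order.

    The name is the description up to the first whitespace. Residues must be
    IUPAC nucleotide letters (case-insensitive; U accepted).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - _VALID_LETTERS
        if bad:
            raise FastaError(
                f"record {rec.id!r} contains non-IUPAC letters: {sorted(bad)}"
            )
        records.append((rec.id, residues))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (name, residues) records, wrapping at ``width`` columns."""
    with open(path, "w") as out:
        for name, residues in records:
            out.write(f">{name}\n")
            for start in range(0, len(residues), width):
                out.write(residues[start : start + width] + "\n")


def encode_2bit(
    residues: str,
    seed: int,
    name: str = "",
    expansion_aware: bool = True,
) -> EncodedSequence:
    """2-bit encode residues, replacing ambiguity codes with random letters.

    Replacement draws uniformly from the IUPAC expansion of the ambiguous
    letter (``expansion_aware=True``, the default) or from all four
    nucleotides. Identical (residues, seed) always yields identical output.
    """
    if not residues:
        raise ValueError("residues must be non-empty")
    residues = residues.upper()
    rng = np.random.default_rng(seed)
    codes = np.empty(len(residues), dtype=np.uint8)
    ambiguity_positions: list[int] = []
    for i, letter in enumerate(residues):
        code = CODE_OF.get(letter)
        if code is not None:
            codes[i] = code
            continue
        expansion = IUPAC_EXPANSION.get(letter)
        if expansion is None:
            raise ValueError(f"non-IUPAC letter {letter!r} at position {i}")
        pool = expansion if expansion_aware else (0, 1, 2, 3)
        codes[i] = pool[rng.integers(0, len(pool))]
        ambiguity_positions.append(i)
    return EncodedSequence(name=name, codes=codes, ambiguity_positions=ambiguity_positions)


def build_sequence_db(
    seqs: Sequence[EncodedSequence], n: int, seed: int
) -> SequenceDB:
    """Concatenate encoded sequences and pad to a multiple of the segment width."""
    return SequenceDB(sequences=list(seqs), segment_width=n, rng_seed=seed)


def reverse_complement(residues: str) -> str:
    table = str.maketrans("ACGTUacgtuRYSWKMBDHVNryswkmbdhvn",
                          "TGCAAtgcaaYRSWMKVHDBNyrswmkvhdbn")
    return residues.translate(table)[::-1]
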