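"""Shared sequence containers and small nucleotide utilities.

Coordinates are 0-based half-open everywhere inside the package; GFF's
1-based inclusive convention is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"

# byte -> 2-bit code; anything outside ACGT (case-insensitive) maps to 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[codes == i] = ord(b)
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGT/acgt; N passes through)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases only; raises on a sequence with no ACGT."""
    codes = encode(seq)
    n_acgt = int((codes < 4).sum())
    if n_acgt == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    n_gc = int(((codes == 1) | (codes == 2)).sum())
    return n_gc / n_acgt


@dataclass(frozen=True)
class Contig:
    """A contig with optional provenance back to its source genome."""

    id: str
    sequence: str
    sample: str | None = None
    source_genome: str | None = None
    source_start: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    source_genome: str | None = None
    source_start: int | None = None
    n_substitutions: int = 0


@dataclass(frozen=True)
class Bin:
    """A set of contigs treated as one draft genome (MAG candidate)."""

    id: str
    contigs: tuple[Contig, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"bin {self.id!r} has duplicate contig ids")

    @property
    def size(self) -> int:
        """Total assembly length in bases."""
        return sum(c.length for c in self.contigs)

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.contigs)

    def sequences(self) -> dict[str, str]:
        return {c.id: c.sequence for c in self.contigs}

    @classmethod
    def from_sequences(cls, bin_id: str, seqs: Mapping[str, str] | Iterable[tuple[str, str]]) -> "Bin":
        items = seqs.items() if isinstance(seqs, Mapping) else seqs
        return cls(bin_id, tuple(Contig(cid, s) for cid, s in items))


def as_bin(obj, bin_id: str = "bin") -> Bin:
    """Coerce a Bin, a mapping id->sequence, or an iterable of sequences to a Bin."""
    if isinstance(obj, Bin):
        return obj
    if isinstance(obj, Mapping):
        return Bin.from_sequences(bin_id, obj)
    if isinstance(obj, str):
        return Bin.from_sequences(bin_id, {f"{bin_id}_c0": obj})
    if isinstance(obj, Sequence):
        return Bin.from_sequences(bin_id, {f"{bin_id}_c{i}": s for i, s in enumerate(obj)})
    raise TypeError(f"cannot interpret {type(obj)!r} as a Bin")
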