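"""Shared sequence primitives: genomes, short reads, k-mer utilities.

Coordinates are 0-based and half-open on the top strand throughout the
package, except where a 3'-end is explicitly reported as the (closed)
coordinate of the last base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "ALPHABET",
    "Genome",
    "ReadRecord",
    "ReadSet",
    "kmer_set",
    "random_dna",
    "revcomp",
]

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Valid provenance labels for a read (where the molecule was sampled from).
PROVENANCE_LABELS = frozenset({"cellular", "secretome", "synthetic", "control"})


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random sequence over {A,C,G,T} (no Ns)."""
    letters = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    return bytes(rng.choice(letters, size=length)).decode()


def kmer_set(seq: str, k: int, both_strands: bool = False) -> set[str]:
    """All k-mers of `seq` (top strand; optionally union of both strands)."""
    out = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    if both_strands:
        rc = revcomp(seq)
        out |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return out


def encode_read(seq: str) -> np.ndarray:
    """uint8 encoding of a read for Hamming comparisons.

    'N' in a read is remapped to a byte that equals nothing a genome can
    contain, so N-vs-anything (including N-vs-N) counts as a mismatch.
    """
    return np.frombuffer(seq.upper().replace("N", "n").encode(), dtype=np.uint8)


@dataclass
class Genome:
    """A named nucleotide sequence (one replicon; no concatenation)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @cached_property
    def arr(self) -> np.ndarray:
        """uint8 view of the top strand."""
        return np.frombuffer(self.seq.encode(), dtype=np.uint8)

    @cached_property
    def rc_seq(self) -> str:
        return revcomp(self.seq)


@dataclass
class ReadRecord:
    """One short read: id, sequence, optional Phred qualities, provenance.

    Ground-truth annotations from the simulator travel in the id after a
    '|' separator (e.g. ``mix_000017|alien``) so they survive FASTA/FASTQ
    round trips.
    """

    id: str
    sequence: str
    qualities: list[int] | None = None
    provenance: str = "cellular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.provenance not in PROVENANCE_LABELS:
            raise ValueError(f"read {self.id!r}: unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def origin(self) -> str | None:
        """Truth label encoded in the id (text after the last '|'), if any."""
        if "|" in self.id:
            return self.id.rsplit("|", 1)[1]
        return None


ReadSet = list[ReadRecord]
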