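"""Aligned SD haplotype container and FASTA round-trip.

All coordinates throughout the package are 0-based, half-open, on the fixed
alignment frame. Sequences are upper-case text over ``{A, C, G, T, -, N}``;
gap and N columns are treated as non-comparable by every downstream
operation. FASTA headers follow the ``species|role|haplotypeID`` convention
with role one of ``SD1``, ``SD2`` (reference paralogs) or ``fusedSD``
(chimeric haplotype carrying the deletion).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ROLES = ("SD1", "SD2", "fusedSD")

# nucleotide -> integer code; anything >= 4 is non-comparable (gap, N, ...)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGT", dtype="S1")


def encode(sequence: str) -> np.ndarray:
    """Encode nucleotide text to uint8 codes (A,C,G,T -> 0..3; other -> 255)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.full(codes.shape, b"-", dtype="S1")
    ok = codes < 4
    out[ok] = _DECODE[codes[ok]]
    return out.tobytes().decode("ascii")


@dataclass(frozen=True)
class SDRecord:
    """One aligned haplotype: a reference paralog or a fused SD."""

    species: str
    role: str
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def label(self) -> str:
        return f"{self.species}|{self.role}|{self.id}"

    def codes(self) -> np.ndarray:
        return encode(self.sequence)


class SDAlignment:
    """A gap-aware multiple alignment of SD haplotypes, all the same length."""

    def __init__(self, records: Sequence[SDRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment needs at least one record")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        labels = [r.label for r in records]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate record labels in alignment")
        self.records = records
        self._by_label = {r.label: r for r in records}

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.species not in seen:
                seen.append(r.species)
        return seen

    def get(self, label: str) -> SDRecord:
        return self._by_label[label]

    def select(self, species: str | None = None, role: str | None = None) -> list[SDRecord]:
        return [
            r
            for r in self.records
            if (species is None or r.species == species) and (role is None or r.role == role)
        ]

    def reference(self, species: str, role: str) -> SDRecord:
        """The single SD1 or SD2 reference haplotype of a species."""
        hits = self.select(species=species, role=role)
        if len(hits) != 1:
            raise ValueError(f"expected exactly one {species}|{role} record, found {len(hits)}")
        return hits[0]

    def code_matrix(self) -> np.ndarray:
        """(n_records, length) uint8 matrix of nucleotide codes."""
        return np.stack([r.codes() for r in self.records])

    # ---- FASTA I/O -------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(r.sequence), id=r.label, description="")
            for r in self.records
        ]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SDAlignment":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"FASTA header {rec.id!r} does not follow species|role|id"
                )
            species, role, hap_id = parts
            records.append(SDRecord(species, role, hap_id, str(rec.seq).upper()))
        return cls(records)

    @classmethod
    def from_sequences(cls, items: Iterable[tuple[str, str, str, str]]) -> "SDAlignment":
        """Build from (species, role, id, sequence) tuples."""
        return cls([SDRecord(*item) for item in items])
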