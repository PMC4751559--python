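"""Core record types shared across the pipeline.

Positions are 0-based half-open internally; every user-facing report of a
histone-code residue is 1-based on the mature reference protein.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Completeness(str, enum.Enum):
    """Assembly completeness of the open reading frame behind a protein.

    ``complete`` requires both an ATG-derived initial Met and an in-frame
    stop codon; transcripts missing one or both ends are classed by which
    terminus is absent.
    """

    COMPLETE = "complete"
    INCOMPLETE_5PRIME = "incomplete_5prime"
    INCOMPLETE_3PRIME = "incomplete_3prime"
    FRAGMENT = "fragment"
    UNKNOWN = "unknown"


def classify_completeness(has_start: bool, has_stop: bool) -> Completeness:
    """Map start/stop codon presence to a completeness category."""
    if has_start and has_stop:
        return Completeness.COMPLETE
    if has_stop:
        return Completeness.INCOMPLETE_5PRIME
    if has_start:
        return Completeness.INCOMPLETE_3PRIME
    return Completeness.FRAGMENT


@dataclass
class TranscriptRecord:
    """An assembled (nucleotide) transcript."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        # IUPAC ambiguity codes other than N are collapsed to N.
        seq = self.sequence.upper()
        self.sequence = "".join(c if c in "ACGTN" else "N" for c in seq)


@dataclass
class ProteinRecord:
    """A translated protein with provenance and completeness flags."""

    id: str
    sequence: str
    species: str = ""
    completeness: Completeness = Completeness.UNKNOWN
    source_frame: int | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        self.sequence = self.sequence.upper()
        if "*" in self.sequence:
            raise ValueError(f"protein {self.id!r}: internal stop symbol")

    @property
    def is_complete(self) -> bool:
        return self.completeness is Completeness.COMPLETE
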