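"""FASTA input/output, six-frame ORF extraction, and record-level filters.

The filters formalize two manual curation steps applied to assembled
transcriptomes: removal of spurious residues in front of an otherwise
conventional histone tail (most parsimoniously explained by an upstream
in-frame start codon in the assembly), and removal of misassemblies such
as concatenated copies of a histone within a single transcript.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .records import Completeness, ProteinRecord, TranscriptRecord, classify_completeness

__all__ = [
    "read_fasta",
    "write_fasta",
    "find_orfs",
    "classify_completeness",
    "trim_nterminal_overhang",
    "flag_misassembly",
]


class FastaParseError(ValueError):
    pass


def _parse_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Return (id, description, sequence) triples; errors carry line numbers."""
    entries: list[tuple[str, str, str]] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        tokens = header.split(None, 1)
        desc = tokens[1] if len(tokens) > 1 else ""
        entries.append((tokens[0], desc, "".join(chunks).upper()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any FASTA header at line {lineno}"
                    )
                chunks.append(line)
        flush()
    return entries


def read_fasta(
    path: str | Path, kind: str = "protein", species: str = ""
) -> list[ProteinRecord] | list[TranscriptRecord]:
    """Read a FASTA file into protein or transcript records.

    The header token before the first whitespace becomes the record id and
    sequences are uppercased.  For ``kind="protein"`` a
    ``completeness=<value>`` token in the description (as written by
    :func:`write_fasta` / the ``extract-orfs`` subcommand) is honoured.
    """
    entries = _parse_fasta(path)
    ids = [e[0] for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaParseError(f"{path}: duplicate record ids {dupes}")
    if kind == "transcript":
        return [TranscriptRecord(id=i, sequence=s, species=species) for i, _, s in entries]
    records = []
    for rid, desc, seq in entries:
        completeness = Completeness.UNKNOWN
        rec_species = species
        for token in desc.split():
            if token.startswith("completeness="):
                completeness = Completeness(token.split("=", 1)[1])
            elif token.startswith("species="):
                rec_species = token.split("=", 1)[1]
        records.append(
            ProteinRecord(
                id=rid, sequence=seq, species=rec_species, completeness=completeness
            )
        )
    return records


def write_fasta(
    records: Iterable[ProteinRecord | TranscriptRecord],
    path: str | Path,
    width: int = 60,
    with_completeness: bool = False,
) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            desc = ""
            if with_completeness and isinstance(rec, ProteinRecord):
                desc = f" completeness={rec.completeness.value}"
                if rec.species:
                    desc += f" species={rec.species}"
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# --- ORF extraction ---------------------------------------------------------

_FRAMES = (1, 2, 3, -1, -2, -3)


def _translate(codons: str) -> str:
    return str(Seq(codons).translate())


def find_orfs(
    transcript: TranscriptRecord, min_aa: int = 60
) -> list[tuple[ProteinRecord, tuple[int, int]]]:
    """Extract maximal ORFs from all six reading frames.

    A maximal ORF is a stop-free codon run bounded by stop codons or the
    transcript ends.  It counts as having a start codon only when its first
    codon is ATG; internal ATGs are deliberately not used to re-anchor the
    ORF so that upstream residues of 5'-incomplete assemblies are preserved
    for downstream trimming.  Coordinates are 0-based half-open on the input
    strand orientation; translations consisting solely of X are dropped.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.sequence
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    results: list[tuple[ProteinRecord, tuple[int, int]]] = []
    counter = 0
    for frame in _FRAMES:
        src = seq if frame > 0 else rc
        offset = abs(frame) - 1
        usable = src[offset : offset + ((n - offset) // 3) * 3]
        if not usable:
            continue
        aa = _translate(usable)
        # split translation on stops; segment i covers aa residues [a, b)
        start = 0
        segments: list[tuple[int, int, bool]] = []  # (aa_start, aa_end, has_stop)
        for idx, res in enumerate(aa):
            if res == "*":
                if idx > start:
                    segments.append((start, idx, True))
                start = idx + 1
        if start < len(aa):
            segments.append((start, len(aa), False))
        for aa_start, aa_end, has_stop in segments:
            protein = aa[aa_start:aa_end]
            if len(protein) < min_aa or set(protein) == {"X"}:
                continue
            nt_start = offset + 3 * aa_start
            nt_end = offset + 3 * aa_end + (3 if has_stop else 0)
            has_start = usable[3 * aa_start : 3 * aa_start + 3] == "ATG"
            if frame > 0:
                coords = (nt_start, min(nt_end, n))
            else:  # map back onto the input strand
                coords = (n - min(nt_end, n), n - nt_start)
            counter += 1
            rec = ProteinRecord(
                id=f"{transcript.id}|orf{counter}",
                sequence=protein,
                species=transcript.species,
                completeness=classify_completeness(has_start, has_stop),
                source_frame=frame,
            )
            results.append((rec, coords))
    return results


# --- record-level filters ---------------------------------------------------


def trim_nterminal_overhang(protein: ProteinRecord, alignment) -> ProteinRecord:
    """Remove assembly-derived residues in front of a conventional tail.

    ``alignment`` is a global :class:`~histone_profiler.alignment.AlignmentResult`
    of ``protein`` against a histone reference.  The overhang is removed only
    when (a) the query has unaligned residues before the query position
    matched to reference position 1, (b) reference position 1 is aligned to a
    query residue, and (c) identity over the first 20 aligned reference
    positions is at least 80% — i.e. the trailing tail is clearly the
    conventional one.  The returned record carries the ``trimmed_nterm`` flag
    when trimming fired; otherwise the input is returned unchanged.
    """
    ref_to_query = alignment.ref_to_query()
    q1 = ref_to_query.get(1)
    if q1 is None or q1 <= 1:
        return protein
    ref = alignment.reference_sequence
    query = protein.sequence
    window = min(20, len(ref))
    matches = 0
    for pos in range(1, window + 1):
        q = ref_to_query.get(pos)
        if q is not None and query[q - 1] == ref[pos - 1]:
            matches += 1
    if matches / window < 0.80:
        return protein
    trimmed = dataclasses.replace(
        protein, sequence=query[q1 - 1 :], flags=set(protein.flags) | {"trimmed_nterm"}
    )
    return trimmed


def flag_misassembly(
    protein: ProteinRecord,
    reference: ProteinRecord | str,
    min_coverage: float = 0.80,
    min_identity: float = 0.40,
) -> tuple[bool, list[tuple[int, int]]]:
    """Detect concatenated copies of a reference histone in one protein.

    Flags the record when two or more mutually non-overlapping local
    alignments to the reference each cover >= ``min_coverage`` of the
    reference length at >= ``min_identity`` identity.  Returns the flag and
    the supporting query intervals (0-based half-open).
    """
    from .alignment import local_hits  # deferred: alignment imports this module's types

    ref_seq = reference.sequence if isinstance(reference, ProteinRecord) else reference
    hits = local_hits(protein.sequence, ref_seq, min_coverage, min_identity)
    return (len(hits) >= 2, hits)
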