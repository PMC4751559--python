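"""Parse homology evidence tables and call histone / DVNP candidates.

The pipeline consumes externally produced search results — BLASTP tabular
output (the 12-column outfmt-6 dialect) and HMMER3 per-domain tables
(domtblout, as written by hmmscan) — rather than re-running the search
engines.  A protein passing either evidence channel at its e-value cutoff
(1e-10 for BLASTP, 1e-8 for profile scans) is assigned the class of its
best passing hit; ties are broken by score, then class name, so the call
is deterministic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import Completeness, ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "DomainHit",
    "CandidateCall",
    "parse_blast_tab",
    "parse_hmmer_domtbl",
    "classify_histone_candidates",
    "tally_completeness",
    "BLAST_EVALUE_CUTOFF",
    "HMM_EVALUE_CUTOFF",
]

BLAST_EVALUE_CUTOFF = 1e-10
HMM_EVALUE_CUTOFF = 1e-8

CLASSES = ("H2A", "H2B", "H3", "H4", "H1", "DVNP")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_name: str
    domain_accession: str
    i_evalue: float
    env_start: int
    env_end: int
    score: float


@dataclass
class CandidateCall:
    protein_id: str
    assigned_class: str  # one of CLASSES or "none"
    evidence: list[tuple[str, object]] = field(default_factory=list)
    best_evalue: float = float("inf")


class TableParseError(ValueError):
    pass


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Read 12-column BLAST outfmt-6 (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TableParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise TableParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def parse_hmmer_domtbl(path: str | Path) -> list[DomainHit]:
    """Read a HMMER3 domtblout table in hmmscan orientation (the target is
    the profile, the query is the protein).  The independent (i-Evalue)
    column and the envelope coordinates are retained per domain row."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise TableParseError(
                    f"{path}: line {lineno}: expected >= 22 whitespace-separated "
                    f"fields of a domtblout row, got {len(fields)}"
                )
            try:
                hits.append(
                    DomainHit(
                        protein_id=fields[3],
                        domain_name=fields[0],
                        domain_accession=fields[1],
                        i_evalue=float(fields[12]),
                        env_start=int(fields[19]),
                        env_end=int(fields[20]),
                        score=float(fields[13]),
                    )
                )
            except ValueError as exc:
                raise TableParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def classify_histone_candidates(
    blast_hits: list[BlastHit],
    domain_hits: list[DomainHit],
    query_class_map: dict[str, str],
    blast_cutoff: float = BLAST_EVALUE_CUTOFF,
    hmm_cutoff: float = HMM_EVALUE_CUTOFF,
) -> list[CandidateCall]:
    """Assign each evidenced protein to a class, or to ``none``.

    Both evidence channels compete: among hits passing their channel cutoff,
    the lowest e-value wins; ties are broken by higher bitscore/score, then
    by lexicographic class name.  Hits to subjects/domains absent from
    ``query_class_map`` are ignored with a warning.  Proteins whose evidence
    all fails the cutoffs are still reported, with class ``none``.
    """
    # (protein, class, evalue, score, source, hit)
    rows: list[tuple[str, str, float, float, str, object]] = []
    seen: set[str] = set()
    warned: set[str] = set()
    for hit in blast_hits:
        seen.add(hit.query_id)
        cls = query_class_map.get(hit.subject_id)
        if cls is None:
            if hit.subject_id not in warned:
                warned.add(hit.subject_id)
                logger.info("BLAST subject %r not in class map; hits ignored", hit.subject_id)
            continue
        if hit.evalue <= blast_cutoff:
            rows.append((hit.query_id, cls, hit.evalue, hit.bitscore, "blast", hit))
    for dhit in domain_hits:
        seen.add(dhit.protein_id)
        cls = query_class_map.get(dhit.domain_name)
        if cls is None:
            if dhit.domain_name not in warned:
                warned.add(dhit.domain_name)
                logger.info("HMM domain %r not in class map; hits ignored", dhit.domain_name)
            continue
        if dhit.i_evalue <= hmm_cutoff:
            rows.append((dhit.protein_id, cls, dhit.i_evalue, dhit.score, "hmm", dhit))

    calls: dict[str, CandidateCall] = {
        pid: CandidateCall(protein_id=pid, assigned_class="none") for pid in sorted(seen)
    }
    by_protein: dict[str, list[tuple[str, float, float, str, object]]] = {}
    for pid, cls, evalue, score, source, hit in rows:
        by_protein.setdefault(pid, []).append((cls, evalue, score, source, hit))
    for pid, items in by_protein.items():
        items.sort(key=lambda t: (t[1], -t[2], t[0]))
        best_cls, best_e, _, _, _ = items[0]
        call = calls[pid]
        call.assigned_class = best_cls
        call.best_evalue = best_e
        call.evidence = [(source, hit) for _, _, _, source, hit in items]
    return list(calls.values())


def tally_completeness(
    calls: list[CandidateCall], proteins: list[ProteinRecord]
) -> pd.DataFrame:
    """Per-species, per-class totals of unique detected proteins and the
    complete subset; misassembly-flagged proteins are excluded from both.

    Returns a tidy frame with columns species, assigned_class, total,
    complete.
    """
    by_id = {p.id: p for p in proteins}
    missing = sorted({c.protein_id for c in calls} - set(by_id))
    if missing:
        raise KeyError(f"calls reference unknown protein ids: {missing}")
    counts: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        if call.assigned_class == "none":
            continue
        protein = by_id[call.protein_id]
        if "misassembly" in protein.flags:
            continue
        key = (protein.species, call.assigned_class)
        cell = counts.setdefault(key, [0, 0])
        cell[0] += 1
        if protein.completeness is Completeness.COMPLETE:
            cell[1] += 1
    records = [
        {"species": sp, "assigned_class": cls, "total": tot, "complete": comp}
        for (sp, cls), (tot, comp) in sorted(counts.items())
    ]
    return pd.DataFrame(records, columns=["species", "assigned_class", "total", "complete"])
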