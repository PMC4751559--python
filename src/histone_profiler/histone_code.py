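"""Histone-code conservation scoring and variant motif annotation.

The central statistic: a histone-code site at 1-based reference position i
is *conserved* in a variant, at radius r, when the whole reference window
[i-r, i+r] (clipped to the reference ends) corresponds gap-free,
contiguously and identically to the variant.  The rationale is that marks
are written and read in their local sequence context, so conservation of
the context — not just the residue — is what supports conservation of the
mark.  A variant is *assessable* at a site only when no window position
falls in a region the assembly failed to cover (see
:func:`histone_profiler.alignment.map_reference_positions`); C/N is the
conserved count over the assessable count.

"Precise match" is read strictly: an insertion inside the window breaks
conservation at r >= 1 even when the flanking residues themselves match.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .alignment import UNASSESSED, AlignmentResult, map_reference_positions
from .records import Completeness, ProteinRecord

__all__ = [
    "PanelSite",
    "ResiduePanel",
    "load_panels",
    "load_references",
    "score_residue_conservation",
    "conservation_report",
    "MotifHit",
    "scan_h2ax_motif",
    "VariantPair",
    "detect_h31_h33_pairs",
    "length_distribution",
    "HYDROPHOBIC",
]

RADII = (0, 1, 2)
HYDROPHOBIC = frozenset("AVLIMFWY")  # the Φ of the SQ(E/D)Φ motif


@dataclass(frozen=True)
class PanelSite:
    name: str
    pos: int  # 1-based on the mature reference
    residue: str


@dataclass
class ResiduePanel:
    histone_class: str
    sites: list[PanelSite]

    def validate(self, reference: str) -> None:
        for site in self.sites:
            if not 1 <= site.pos <= len(reference):
                raise ValueError(
                    f"{self.histone_class} panel: {site.name} position {site.pos} "
                    f"outside reference (length {len(reference)})"
                )
            actual = reference[site.pos - 1]
            if actual != site.residue:
                raise ValueError(
                    f"{self.histone_class} panel: {site.name} expects {site.residue} "
                    f"at position {site.pos} but reference has {actual}"
                )


def load_references(path: str | Path | None = None) -> dict[str, str]:
    """Mature human core histone references keyed by class (H2A/H2B/H3/H4)."""
    from .sequence_io import read_fasta

    if path is None:
        with resources.as_file(
            resources.files("histone_profiler.data") / "references.faa"
        ) as p:
            records = read_fasta(p)
    else:
        records = read_fasta(path)
    refs = {}
    for rec in records:
        cls = rec.id.split("_")[0]
        refs[cls] = rec.sequence
    return refs


def load_panels(
    path: str | Path | None = None, references: dict[str, str] | None = None
) -> dict[str, ResiduePanel]:
    """Load residue panels from YAML and validate them against the references."""
    if path is None:
        with resources.as_file(
            resources.files("histone_profiler.data") / "panels.yaml"
        ) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if references is None:
        references = load_references()
    panels: dict[str, ResiduePanel] = {}
    for cls, sites in raw.items():
        panel = ResiduePanel(
            histone_class=cls,
            sites=[PanelSite(s["name"], int(s["pos"]), s["residue"]) for s in sites],
        )
        if cls in references:
            panel.validate(references[cls])
        panels[cls] = panel
    return panels


def score_residue_conservation(
    variants: list[tuple[ProteinRecord, AlignmentResult]],
    panel: ResiduePanel,
    reference: str,
    r: int,
) -> dict[str, tuple[int, int]]:
    """C/N counts per panel site over a set of aligned variants.

    For each site at reference position i the window is
    [max(1, i-r), min(L, i+r)].  A variant is conserved at the site iff
    every window position maps to a query residue, the mapped query
    positions are contiguous, and the query residues equal the reference
    residues across the whole window.  A variant enters the N denominator
    iff no window position is unassessed (missing terminus of an
    incomplete assembly).
    """
    if r not in RADII:
        raise ValueError(f"radius must be one of {RADII}, got {r}")
    panel.validate(reference)
    L = len(reference)
    counts: dict[str, tuple[int, int]] = {}
    maps = [
        (rec, aln, map_reference_positions(aln, rec.completeness))
        for rec, aln in variants
    ]
    for site in panel.sites:
        lo, hi = max(1, site.pos - r), min(L, site.pos + r)
        window = range(lo, hi + 1)
        conserved = assessable = 0
        for rec, aln, posmap in maps:
            states = [posmap[p] for p in window]
            if any(s is UNASSESSED for s in states):
                continue
            assessable += 1
            if any(s is None for s in states):
                continue
            qpositions = [s for s in states]
            if any(
                b != a + 1 for a, b in zip(qpositions, qpositions[1:])
            ):  # insertion inside the window
                continue
            query = aln.query_sequence
            if all(
                query[q - 1] == reference[p - 1] for p, q in zip(window, qpositions)
            ):
                conserved += 1
        counts[site.name] = (conserved, assessable)
    return counts


def conservation_report(
    variants: list[tuple[ProteinRecord, AlignmentResult]],
    panel: ResiduePanel,
    reference: str,
    species: str = "",
    radii: tuple[int, ...] = RADII,
) -> pd.DataFrame:
    """Long-format C/N report over several radii (the per-species grid row)."""
    rows = []
    for r in radii:
        for name, (c, n) in score_residue_conservation(
            variants, panel, reference, r
        ).items():
            rows.append(
                {
                    "species": species,
                    "histone_class": panel.histone_class,
                    "site": name,
                    "radius": r,
                    "C": c,
                    "N": n,
                    "fraction": (c / n) if n else float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "histone_class", "site", "radius", "C", "N", "fraction"]
    )


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_sequence: str
    start: int  # 1-based query position of the S
    distance_from_cterm: int  # residues after the motif's last position


def scan_h2ax_motif(
    protein: ProteinRecord, mode: str = "strict", cterm_window: int = 10
) -> MotifHit | None:
    """Scan the C-terminus for the H2A.X phosphorylation motif SQ(E/D)Φ.

    Strict mode requires S-Q-(E/D)-Φ with Φ a hydrophobic residue
    ({A,V,L,I,M,F,W,Y}); relaxed mode drops the constraint on the third
    position so that naturally occurring near-motifs such as SQQY are
    captured.  Only the final ``cterm_window`` residues are scanned and the
    match closest to the C-terminus is returned.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")
    seq = protein.sequence
    scan_from = max(0, len(seq) - cterm_window)
    best: MotifHit | None = None
    for i in range(scan_from, len(seq) - 3):
        quad = seq[i : i + 4]
        if quad[0] != "S" or quad[1] != "Q":
            continue
        if mode == "strict" and quad[2] not in "ED":
            continue
        if quad[3] not in HYDROPHOBIC:
            continue
        best = MotifHit(
            protein_id=protein.id,
            motif_sequence=quad,
            start=i + 1,
            distance_from_cterm=len(seq) - (i + 4),
        )
    return best


@dataclass(frozen=True)
class VariantPair:
    id_a: str
    id_b: str
    diagnostic_positions: tuple[int, ...]
    identity_elsewhere: float


def detect_h31_h33_pairs(
    h3_variants: list[tuple[ProteinRecord, AlignmentResult]],
    identity_threshold: float = 0.95,
    diagnostic_position: int = 31,
) -> list[VariantPair]:
    """Find replication-variant pairs distinguished at the diagnostic position.

    The classical H3.1/H3.3 distinction is an Ala versus a phosphorylatable
    Ser/Thr at reference position 31 in two otherwise nearly identical
    proteins.  Variants are projected onto reference coordinates; a pair is
    reported when the two agree at >= ``identity_threshold`` of mutually
    assessable positions (excluding the diagnostic one), one carries S or T
    at the diagnostic position and the other A.  All differing positions are
    listed.
    """
    if len(h3_variants) < 2:
        return []
    projections = []
    for rec, aln in h3_variants:
        posmap = map_reference_positions(aln, rec.completeness)
        query = aln.query_sequence
        proj = {
            p: (query[q - 1] if isinstance(q, int) else q) for p, q in posmap.items()
        }
        projections.append((rec, proj))
    pairs: list[VariantPair] = []
    for i in range(len(projections)):
        for j in range(i + 1, len(projections)):
            rec_a, proj_a = projections[i]
            rec_b, proj_b = projections[j]
            shared = [
                p
                for p in proj_a
                if isinstance(proj_a[p], str) and isinstance(proj_b.get(p), str)
            ]
            if diagnostic_position not in shared:
                continue
            ra, rb = proj_a[diagnostic_position], proj_b[diagnostic_position]
            phospho_vs_ala = {ra, rb} in ({"S", "A"}, {"T", "A"})
            if not phospho_vs_ala:
                continue
            others = [p for p in shared if p != diagnostic_position]
            if not others:
                continue
            same = sum(1 for p in others if proj_a[p] == proj_b[p])
            identity = same / len(others)
            if identity < identity_threshold:
                continue
            differing = tuple(
                sorted([p for p in others if proj_a[p] != proj_b[p]] + [diagnostic_position])
            )
            pairs.append(
                VariantPair(
                    id_a=rec_a.id,
                    id_b=rec_b.id,
                    diagnostic_positions=differing,
                    identity_elsewhere=identity,
                )
            )
    return pairs


def length_distribution(
    proteins: list[ProteinRecord],
    classes: dict[str, str],
    reference_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Length summary of complete proteins per species and class.

    ``classes`` maps protein id → assigned class.  Incomplete proteins are
    excluded; reference lengths, when given, are appended as comparison rows
    with species ``reference``.
    """
    grouped: dict[tuple[str, str], list[int]] = {}
    for protein in proteins:
        cls = classes.get(protein.id)
        if cls is None or cls == "none":
            continue
        if protein.completeness is not Completeness.COMPLETE:
            continue
        grouped.setdefault((protein.species, cls), []).append(len(protein.sequence))
    rows = []
    for (sp, cls), lengths in sorted(grouped.items()):
        series = pd.Series(lengths)
        rows.append(
            {
                "species": sp,
                "histone_class": cls,
                "n": len(lengths),
                "min": int(series.min()),
                "median": float(series.median()),
                "max": int(series.max()),
            }
        )
    if reference_lengths:
        for cls, length in sorted(reference_lengths.items()):
            rows.append(
                {
                    "species": "reference",
                    "histone_class": cls,
                    "n": 1,
                    "min": length,
                    "median": float(length),
                    "max": length,
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "histone_class", "n", "min", "median", "max"]
    )
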