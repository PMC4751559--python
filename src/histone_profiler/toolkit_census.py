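"""Chromatin-toolkit census from domain architectures, and CTD annotation.

Writers, erasers, readers, remodelers, chaperones and the FACT complex are
called from accepted profile hits (independent e-value <= 1e-8) combined
under data-driven rules: each category is a required-domain multiset, e.g.
a CHD-family remodeler ATPase needs all three of Chromo, SWI2_N and
Helicase_C, and an HP1 homolog needs a pair of chromodomains plus a chromo
shadow domain.  The RNA polymerase II largest subunit is annotated
separately for its C-terminal heptad repeats (consensus YSPTSPS).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .homology_screen import DomainHit
from .records import ProteinRecord

__all__ = [
    "DomainArchitecture",
    "build_architectures",
    "load_rules",
    "classify_architecture",
    "census",
    "CtdAnnotation",
    "detect_ctd_repeats",
    "annotate_heptad",
    "CTD_CONSENSUS",
]

DOMAIN_EVALUE_CUTOFF = 1e-8
CTD_CONSENSUS = "YSPTSPS"


@dataclass
class DomainArchitecture:
    protein_id: str
    # (domain_name, env_start, env_end, i_evalue), 1-based inclusive, by start
    accepted_domains: list[tuple[str, int, int, float]] = field(default_factory=list)

    def domain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name, *_ in self.accepted_domains:
            counts[name] = counts.get(name, 0) + 1
        return counts


def build_architectures(
    hits: list[DomainHit], threshold: float = DOMAIN_EVALUE_CUTOFF
) -> dict[str, DomainArchitecture]:
    """Accepted domain architecture per protein.

    Hits above the e-value threshold are dropped; overlapping hits of the
    same domain are merged to their union interval keeping the best
    e-value; results are sorted by envelope start.
    """
    per_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.i_evalue <= threshold:
            per_protein.setdefault(hit.protein_id, []).append(hit)
    out: dict[str, DomainArchitecture] = {}
    for pid, phits in per_protein.items():
        merged: list[tuple[str, int, int, float]] = []
        by_name: dict[str, list[DomainHit]] = {}
        for hit in phits:
            by_name.setdefault(hit.domain_name, []).append(hit)
        for name, group in by_name.items():
            group.sort(key=lambda h: (h.env_start, h.env_end))
            current = [name, group[0].env_start, group[0].env_end, group[0].i_evalue]
            for hit in group[1:]:
                if hit.env_start <= current[2]:  # overlap (1-based inclusive)
                    current[2] = max(current[2], hit.env_end)
                    current[3] = min(current[3], hit.i_evalue)
                else:
                    merged.append(tuple(current))
                    current = [name, hit.env_start, hit.env_end, hit.i_evalue]
            merged.append(tuple(current))
        merged.sort(key=lambda t: (t[1], t[2], t[0]))
        out[pid] = DomainArchitecture(protein_id=pid, accepted_domains=merged)
    return out


def load_rules(path: str | Path | None = None, known_domains: set[str] | None = None):
    """Category → required-domain multiset rules (bundled defaults mirror the
    census figure conventions).  ``known_domains``, when given, is used to
    reject rule files naming domains outside the expected vocabulary."""
    if path is None:
        with resources.as_file(
            resources.files("histone_profiler.data") / "toolkit_rules.yaml"
        ) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    rules: dict[str, dict[str, int]] = {}
    for category, requirement in raw.items():
        if not isinstance(requirement, dict) or not requirement:
            raise ValueError(f"rule {category!r}: requirement must be a non-empty mapping")
        if known_domains is not None:
            unknown = set(requirement) - known_domains
            if unknown:
                raise ValueError(f"rule {category!r}: unknown domain names {sorted(unknown)}")
        rules[category] = {str(d): int(c) for d, c in requirement.items()}
    return rules


def classify_architecture(
    arch: DomainArchitecture, rules: dict[str, dict[str, int]]
) -> set[str]:
    """All category labels whose required-domain multiset the protein carries."""
    counts = arch.domain_counts()
    labels = set()
    for category, requirement in rules.items():
        if all(counts.get(domain, 0) >= k for domain, k in requirement.items()):
            labels.add(category)
    return labels


def census(
    architectures_by_species: dict[str, dict[str, DomainArchitecture]],
    rules: dict[str, dict[str, int]] | None = None,
    ctd_by_species: dict[str, list["CtdAnnotation"]] | None = None,
) -> pd.DataFrame:
    """Species × category matrix of distinct protein counts.

    Cells hold integers; pandas NA marks categories with no detected
    protein (rendered "–" on output, matching the presence/absence figure
    convention).  When CTD annotations are supplied, an ``Rpb1-CTD`` column
    reports the maximum repeat count among Rpb1 homologs — 0 means a homolog
    was found but no repeats are apparent, NA means no homolog at all.
    """
    if rules is None:
        rules = load_rules()
    categories = list(rules)
    rows = {}
    for species, archs in sorted(architectures_by_species.items()):
        counts = {cat: 0 for cat in categories}
        for arch in archs.values():
            for label in classify_architecture(arch, rules):
                counts[label] += 1
        row = {cat: (n if n > 0 else pd.NA) for cat, n in counts.items()}
        if ctd_by_species is not None:
            anns = ctd_by_species.get(species, [])
            row["Rpb1-CTD"] = max((a.repeat_count for a in anns), default=pd.NA)
        rows[species] = row
    columns = categories + (["Rpb1-CTD"] if ctd_by_species is not None else [])
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def render_census_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the census matrix with "–" marking absence."""
    matrix.fillna("–").to_csv(path, sep="\t", index_label="species")


@dataclass
class CtdAnnotation:
    protein_id: str
    repeat_count: int
    # (1-based start, 7-mer, identities to consensus)
    repeats: list[tuple[int, str, int]] = field(default_factory=list)
    # per consensus position: count of repeats matching it
    position_profile: list[int] = field(default_factory=lambda: [0] * 7)


def detect_ctd_repeats(
    protein: ProteinRecord,
    consensus: str = CTD_CONSENSUS,
    min_matches: int = 4,
    search_region: float = 0.30,
) -> CtdAnnotation:
    """Annotate divergent heptad repeats in the C-terminal domain.

    The C-terminal ``search_region`` fraction of the protein is tiled
    greedily left to right with non-overlapping 7-mers scoring at least
    ``min_matches`` identities to the consensus.  Because genuine CTDs are
    repeat arrays, isolated tiles (no other tile within 7 residues) are
    suppressed.  The permissive 4-of-7 floor plus chaining reflects repeats
    that are recognizable but highly divergent from YSPTSPS.
    """
    if len(consensus) != 7:
        raise ValueError("consensus must be a 7-mer")
    seq = protein.sequence
    annotation = CtdAnnotation(protein_id=protein.id, repeat_count=0)
    if len(seq) < 7:
        return annotation
    start = max(0, int(len(seq) * (1.0 - search_region)))
    tiles: list[tuple[int, str, int]] = []
    i = start
    while i <= len(seq) - 7:
        window = seq[i : i + 7]
        matches = sum(1 for a, b in zip(window, consensus) if a == b)
        if matches >= min_matches:
            tiles.append((i + 1, window, matches))
            i += 7
        else:
            i += 1
    kept = []
    for idx, (pos, window, matches) in enumerate(tiles):
        adjacent = False
        if idx > 0:
            prev_end = tiles[idx - 1][0] + 6
            adjacent |= pos - prev_end - 1 <= 7
        if idx + 1 < len(tiles):
            next_start = tiles[idx + 1][0]
            adjacent |= next_start - (pos + 6) - 1 <= 7
        if adjacent:
            kept.append((pos, window, matches))
    annotation.repeats = kept
    annotation.repeat_count = len(kept)
    profile = [0] * 7
    for _, window, _ in kept:
        for k in range(7):
            if window[k] == consensus[k]:
                profile[k] += 1
    annotation.position_profile = profile
    return annotation


def annotate_heptad(heptad: str) -> tuple[int, int, list[str]]:
    """Count phosphorylatable (S/T/Y) and proline-isomerizable positions.

    The consensus heptad YSPTSPS carries five phosphorylation sites and two
    proline isomerization sites.  Returns (phospho_sites, proline_sites,
    per-position annotation).
    """
    if len(heptad) != 7:
        raise ValueError(f"heptad must have length 7, got {len(heptad)}")
    heptad = heptad.upper()
    annotation = []
    phospho = proline = 0
    for residue in heptad:
        if residue in "STY":
            phospho += 1
            annotation.append("phospho")
        elif residue == "P":
            proline += 1
            annotation.append("proline-iso")
        else:
            annotation.append("other")
    return phospho, proline, annotation
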