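"""Synthetic transcriptomes with full ground-truth manifests.

The generator emulates the statistical structure of a translated
dinoflagellate transcriptome as the analysis assumes it: several variants
per histone family diverged from the mature human reference at a controlled
per-residue substitution rate, with selected histone-code sites protected
together with their ±2 context; elongated variants; transcripts missing
start and/or stop codons; concatenated-copy misassemblies; shuffled decoy
proteins; evidence tables (BLAST tabular / HMMER domtblout) consistent with
the true classes; toolkit proteins with configured domain architectures; an
Rpb1-like protein carrying heptad repeats; and a TPM table in which DVNPs
are far more highly expressed than histones.

Evidence tables are synthesized, not produced by running the search
engines, so the whole pipeline is testable with zero external-tool
dependencies.  H1 and DVNP "references" are synthetic stand-in sequences
(no curated query is bundled for them); classification of these classes is
purely evidence-driven, so their composition is irrelevant beyond being
fixed.  Same seed, same bytes: every output is a pure function of
(config, seed).
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .histone_code import load_panels, load_references
from .records import Completeness, ProteinRecord, TranscriptRecord
from .sequence_io import write_fasta

__all__ = [
    "ClassConfig",
    "GeneratorConfig",
    "default_config",
    "mutate_reference",
    "generate_transcriptome",
    "SyntheticDataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _codon_map() -> dict[str, list[str]]:
    mapping: dict[str, list[str]] = {}
    for codon, aa in sorted(_STANDARD_TABLE.forward_table.items()):
        mapping.setdefault(aa, []).append(codon)
    return mapping


CODONS = _codon_map()
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))


def _synthetic_sequence(length: int, tag: int) -> str:
    """A fixed pseudo-random protein sequence (internal constant seed, so it
    is a stable synthetic reference independent of the user's seed)."""
    rng = np.random.default_rng(20151208 + tag)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# Synthetic stand-ins for classes without a bundled curated reference.
SYNTHETIC_H1 = _synthetic_sequence(180, tag=1)
SYNTHETIC_DVNP = _synthetic_sequence(120, tag=2)


@dataclass
class ClassConfig:
    n_variants: int = 3
    mutation_rate: float = 0.15
    preserved_sites: tuple[str, ...] = ()
    elongation_prob: float = 0.3
    elongation_range: tuple[int, int] = (20, 60)
    fraction_incomplete_5p: float = 0.2
    fraction_incomplete_3p: float = 0.2


@dataclass
class GeneratorConfig:
    n_species: int = 3
    classes: dict[str, ClassConfig] = field(
        default_factory=lambda: {
            "H3": ClassConfig(
                n_variants=5, preserved_sites=("H3K4", "H3K36", "H3K56", "H3K64")
            ),
            "H4": ClassConfig(
                n_variants=3, preserved_sites=("H4K12", "H4K59", "H4K79", "H4K91")
            ),
            "H2A": ClassConfig(n_variants=3, preserved_sites=("H2AY57", "H2AK119")),
            "H2B": ClassConfig(n_variants=3, preserved_sites=("H2BK120",)),
            "H1": ClassConfig(n_variants=1, elongation_prob=0.0),
            "DVNP": ClassConfig(n_variants=3, mutation_rate=0.10, elongation_prob=0.0),
        }
    )
    n_misassemblies: int = 1
    n_decoys: int = 5
    n_h2ax: int = 1  # H2A variants per species given a C-terminal SQEF motif
    # (architecture multiset, number of proteins carrying it)
    toolkit_scenarios: tuple[tuple[tuple[tuple[str, int], ...], int], ...] = (
        ((("SWI2_N", 1), ("Helicase_C", 1)), 1),
        ((("Chromo", 1), ("SWI2_N", 1), ("Helicase_C", 1)), 1),
        ((("Chromo", 2), ("Chromo_shadow", 1)), 1),
        ((("SET", 1),), 3),
        ((("Hist_deacetyl", 1),), 2),
        ((("SIR2", 1),), 2),
        ((("SPT16", 1),), 1),
        ((("SSrecog", 1),), 1),
        ((("NAP", 1),), 2),
        ((("ASF1_hist_chap", 1),), 1),
    )
    ctd_repeats: int = 8
    # log-space (mu, sigma) of per-transcript TPM; DVNP >> histones mirrors
    # the observed expression hierarchy
    expression: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "H3": (2.5, 0.8),
            "H4": (2.5, 0.8),
            "H2A": (2.5, 0.8),
            "H2B": (2.5, 0.8),
            "H1": (2.5, 0.8),
            "DVNP": (6.0, 0.5),
        }
    )


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


def _toolkit_rules() -> dict[str, dict[str, int]]:
    from .toolkit_census import load_rules  # deferred to avoid an import cycle

    return load_rules()


def _protected_positions(class_name: str, preserved: tuple[str, ...], ref_len: int):
    if not preserved:
        return set(), {}
    panels = load_panels()
    panel = panels.get(class_name)
    windows: dict[str, set[int]] = {}
    protected: set[int] = set()
    if panel is None:
        raise ValueError(f"no panel for class {class_name!r}")
    by_name = {s.name: s for s in panel.sites}
    for name in preserved:
        if name not in by_name:
            raise ValueError(f"preserved site {name!r} not in {class_name} panel")
        pos = by_name[name].pos
        window = set(range(max(1, pos - 2), min(ref_len, pos + 2) + 1))
        windows[name] = window
        protected |= window
    return protected, windows


def mutate_reference(
    reference: str,
    mutation_rate: float,
    protected: set[int],
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Substitute residues outside protected 1-based positions.

    Each unprotected position is replaced, with probability
    ``mutation_rate``, by a uniformly chosen different residue.  Returns the
    variant and the list of substituted positions.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    if mutation_rate > 0 and len(protected) >= len(reference):
        import warnings

        warnings.warn("protected windows cover the whole sequence; nothing to mutate")
    out = list(reference)
    changed: list[int] = []
    for pos in range(1, len(reference) + 1):
        if pos in protected:
            continue
        if rng.random() < mutation_rate:
            current = out[pos - 1]
            choices = [a for a in AMINO_ACIDS if a != current]
            out[pos - 1] = choices[rng.integers(len(choices))]
            changed.append(pos)
    return "".join(out), changed


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = CODONS.get(aa)
        if options is None:  # X or other: emit NNN
            codons.append("NNN")
        else:
            codons.append(options[rng.integers(len(options))])
    return "".join(codons)


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    transcripts: list[TranscriptRecord]
    blast_rows: list[str]
    domtbl_rows: list[str]
    tpm: dict[str, float]
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.faa",
            "transcripts": outdir / "transcripts.fna",
            "blast": outdir / "blast.tsv",
            "domtbl": outdir / "scan.domtbl",
            "tpm": outdir / "tpm.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(self.proteins, paths["proteins"], with_completeness=True)
        write_fasta(self.transcripts, paths["transcripts"])
        paths["blast"].write_text("".join(self.blast_rows))
        header = (
            "# --- full sequence --- -------------- this domain -------------"
            " hmm coord ali coord env coord\n"
        )
        paths["domtbl"].write_text(header + "".join(self.domtbl_rows))
        with open(paths["tpm"], "w") as fh:
            fh.write("transcript_id\ttpm\n")
            for tid in sorted(self.tpm):
                fh.write(f"{tid}\t{self.tpm[tid]:.4f}\n")
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return paths


def _blast_row(qid: str, subject: str, qlen: int, evalue: float, identity: float) -> str:
    aln_len = qlen
    mism = int(round(aln_len * (1 - identity / 100.0)))
    bitscore = max(50.0, 2.0 * aln_len * identity / 100.0)
    return (
        f"{qid}\t{subject}\t{identity:.1f}\t{aln_len}\t{mism}\t0\t1\t{aln_len}\t1\t"
        f"{aln_len}\t{evalue:.2e}\t{bitscore:.1f}\n"
    )


def _domtbl_row(
    pid: str, domain: str, acc: str, i_evalue: float, start: int, end: int, score: float
) -> str:
    # hmmscan orientation: target = profile, query = protein
    fields = [
        domain, acc, "100", pid, "-", "500",
        f"{i_evalue:.2e}", f"{score:.1f}", "0.1", "1", "1",
        f"{i_evalue:.2e}", f"{i_evalue:.2e}", f"{score:.1f}", "0.1",
        "1", "100", str(start), str(end), str(start), str(end), "0.95", "-",
    ]
    return " ".join(fields) + "\n"


def generate_transcriptome(
    config: GeneratorConfig | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate a full synthetic dataset plus its ground-truth manifest."""
    if config is None:
        config = default_config()
    rng = np.random.default_rng(seed)
    references = dict(load_references())
    references["H1"] = SYNTHETIC_H1
    references["DVNP"] = SYNTHETIC_DVNP

    proteins: list[ProteinRecord] = []
    transcripts: list[TranscriptRecord] = []
    blast_rows: list[str] = []
    domtbl_rows: list[str] = []
    tpm: dict[str, float] = {}
    manifest_records: dict[str, dict] = {}
    census_expected: dict[str, dict[str, int]] = {}

    def emit_transcript(pid: str, species: str, protein_seq: str, completeness: Completeness):
        if completeness in (Completeness.COMPLETE, Completeness.INCOMPLETE_3PRIME):
            coding = "ATG" + _back_translate(protein_seq[1:], rng)  # seq starts with M
        else:
            coding = _back_translate(protein_seq, rng)
        if completeness in (Completeness.COMPLETE, Completeness.INCOMPLETE_5PRIME):
            coding += STOP_CODONS[rng.integers(len(STOP_CODONS))]
        transcripts.append(TranscriptRecord(id=pid, sequence=coding, species=species))

    def draw_tpm(cls: str) -> float:
        mu, sigma = config.expression[cls]
        return float(rng.lognormal(mean=mu, sigma=sigma))

    for s in range(config.n_species):
        species = f"synthspecies_{s + 1:02d}"
        for cls in sorted(config.classes):
            cc = config.classes[cls]
            reference = references[cls]
            protected, windows = _protected_positions(
                cls, cc.preserved_sites, len(reference)
            )
            for v in range(cc.n_variants):
                pid = f"{species}.{cls}.v{v + 1}"
                mature, changed = mutate_reference(
                    reference, cc.mutation_rate, protected, rng
                )
                extension = 0
                if rng.random() < cc.elongation_prob:
                    lo, hi = cc.elongation_range
                    extension = int(rng.integers(lo, hi + 1))
                    mature += "".join(rng.choice(list(AMINO_ACIDS), size=extension))
                motif = None
                if cls == "H2A" and v < config.n_h2ax:
                    mature += "SQEF"
                    motif = "SQEF"
                # a motif-bearing variant keeps its C-terminus intact
                u = 1.0 if motif else rng.random()
                if u < cc.fraction_incomplete_5p:
                    completeness = Completeness.INCOMPLETE_5PRIME
                    t = int(rng.integers(1, 11))
                    truncated = mature[t:]
                    while truncated and truncated[0] == "M":
                        t += 1
                        truncated = mature[t:]
                    sequence = truncated
                    n_missing = t
                elif u < cc.fraction_incomplete_5p + cc.fraction_incomplete_3p:
                    completeness = Completeness.INCOMPLETE_3PRIME
                    t = int(rng.integers(1, 11))
                    sequence = "M" + mature[:-t]
                    n_missing = t
                else:
                    completeness = Completeness.COMPLETE
                    sequence = "M" + mature
                    n_missing = 0
                rec = ProteinRecord(
                    id=pid, sequence=sequence, species=species, completeness=completeness
                )
                proteins.append(rec)
                emit_transcript(pid, species, sequence, completeness)
                identity = 100.0 * (1.0 - len(changed) / len(reference))
                evalue = 10.0 ** -float(rng.uniform(25, 60))
                if cls == "H1":
                    domtbl_rows.append(
                        _domtbl_row(
                            pid, "Linker_histone", "PF00538.1", evalue, 5,
                            min(80, len(sequence)), 120.0,
                        )
                    )
                else:
                    subject = "DVNP_SYNTH" if cls == "DVNP" else f"{cls}_HUMAN"
                    blast_rows.append(
                        _blast_row(pid, subject, len(sequence), evalue, identity)
                    )
                tpm[pid] = draw_tpm(cls)
                disrupted = sorted(
                    {
                        name
                        for name, window in windows.items()
                        if any(p in window for p in changed)
                    }
                )
                manifest_records[pid] = {
                    "species": species,
                    "true_class": cls,
                    "completeness": completeness.value,
                    "preserved_sites": sorted(cc.preserved_sites),
                    "disrupted_sites": disrupted,
                    "substituted_positions": changed,
                    "extension_length": extension,
                    "n_missing_terminal": n_missing,
                    "h2ax_motif": motif,
                    "misassembly": False,
                    "decoy": False,
                    "tpm": tpm[pid],
                }

        # concatenated-copy misassemblies (doubled H4 reference)
        for m in range(config.n_misassemblies):
            pid = f"{species}.H4.mis{m + 1}"
            doubled = references["H4"] * 2
            sequence = "M" + doubled
            rec = ProteinRecord(
                id=pid, sequence=sequence, species=species,
                completeness=Completeness.COMPLETE,
            )
            proteins.append(rec)
            emit_transcript(pid, species, sequence, Completeness.COMPLETE)
            blast_rows.append(_blast_row(pid, "H4_HUMAN", len(sequence), 1e-50, 100.0))
            tpm[pid] = draw_tpm("H4")
            manifest_records[pid] = {
                "species": species,
                "true_class": "H4",
                "completeness": "complete",
                "preserved_sites": [],
                "disrupted_sites": [],
                "substituted_positions": [],
                "extension_length": 0,
                "n_missing_terminal": 0,
                "h2ax_motif": None,
                "misassembly": True,
                "decoy": False,
                "tpm": tpm[pid],
            }

        # decoys: shuffled reference sequences whose evidence fails the cutoffs
        for d in range(config.n_decoys):
            pid = f"{species}.decoy{d + 1}"
            source = references[sorted(references)[d % len(references)]]
            shuffled = "".join(rng.permutation(list(source)))
            sequence = "M" + shuffled
            rec = ProteinRecord(
                id=pid, sequence=sequence, species=species,
                completeness=Completeness.COMPLETE,
            )
            proteins.append(rec)
            emit_transcript(pid, species, sequence, Completeness.COMPLETE)
            blast_rows.append(
                _blast_row(pid, "H3_HUMAN", len(sequence), 10.0 ** -float(rng.uniform(2, 5)), 22.0)
            )
            manifest_records[pid] = {
                "species": species,
                "true_class": "none",
                "completeness": "complete",
                "preserved_sites": [],
                "disrupted_sites": [],
                "substituted_positions": [],
                "extension_length": 0,
                "n_missing_terminal": 0,
                "h2ax_motif": None,
                "misassembly": False,
                "decoy": True,
                "tpm": None,
            }

        # chromatin-toolkit proteins with configured architectures
        expected: dict[str, int] = {}
        counter = 0
        for arch_spec, count in config.toolkit_scenarios:
            for _ in range(count):
                counter += 1
                pid = f"{species}.toolkit{counter}"
                body = "".join(rng.choice(list(AMINO_ACIDS), size=400))
                proteins.append(
                    ProteinRecord(
                        id=pid, sequence="M" + body, species=species,
                        completeness=Completeness.COMPLETE,
                    )
                )
                pos = 10
                for domain, copies in arch_spec:
                    for _ in range(copies):
                        domtbl_rows.append(
                            _domtbl_row(
                                pid, domain, f"PF{zlib.crc32(domain.encode()) % 99999:05d}.1",
                                1e-20, pos, pos + 60, 150.0,
                            )
                        )
                        pos += 100
                manifest_records[pid] = {
                    "species": species,
                    "true_class": "toolkit",
                    "completeness": "complete",
                    "architecture": {d: c for d, c in arch_spec},
                    "misassembly": False,
                    "decoy": False,
                }
        census_expected[species] = expected  # filled by manifest logic below

        # Rpb1 homolog with heptad repeats in its C-terminal tail
        pid = f"{species}.rpb1"
        body = "".join(rng.choice(list(AMINO_ACIDS.replace("Y", "").replace("S", "")), size=300))
        tail = "YSPTSPS" * config.ctd_repeats
        rpb1 = ProteinRecord(
            id=pid, sequence=body + tail, species=species,
            completeness=Completeness.COMPLETE,
        )
        proteins.append(rpb1)
        domtbl_rows.append(_domtbl_row(pid, "RNA_pol_Rpb1_5", "PF04997.1", 1e-40, 10, 290, 400.0))
        manifest_records[pid] = {
            "species": species,
            "true_class": "toolkit",
            "completeness": "complete",
            "ctd_repeats": config.ctd_repeats,
            "misassembly": False,
            "decoy": False,
        }

    # expected census matrix, evaluated directly from the scenario definitions
    for species in census_expected:
        counts: dict[str, int] = {}
        for arch_spec, count in config.toolkit_scenarios:
            have = {d: c for d, c in arch_spec}
            for category, requirement in _toolkit_rules().items():
                if all(have.get(dom, 0) >= k for dom, k in requirement.items()):
                    counts[category] = counts.get(category, 0) + count
        counts["Rpb1"] = counts.get("Rpb1", 0) + 1  # the Rpb1 homolog
        census_expected[species] = counts

    manifest = {
        "seed": seed,
        "n_species": config.n_species,
        "records": manifest_records,
        "census_expected": census_expected,
        "ctd_repeats": config.ctd_repeats,
    }
    return SyntheticDataset(
        proteins=proteins,
        transcripts=transcripts,
        blast_rows=blast_rows,
        domtbl_rows=domtbl_rows,
        tpm=tpm,
        manifest=manifest,
    )
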