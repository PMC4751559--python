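"""Pipeline driver and summary artifacts.

``run_pipeline`` chains every stage — evidence screening, misassembly
flagging, N-terminal trimming, reference alignment, conservation scoring at
r = 0/1/2, variant motif and pair annotation, the toolkit census, CTD
annotation, and expression summaries — and writes a TSV/JSON bundle plus a
run log.  The bundle is a pure function of inputs + configuration: the log
records versions, thresholds and seeds but no timestamps, so reruns are
byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .alignment import AlignmentResult, blosum62, global_align
from .histone_code import (
    conservation_report,
    detect_h31_h33_pairs,
    length_distribution,
    load_panels,
    load_references,
    scan_h2ax_motif,
)
from .homology_screen import (
    BLAST_EVALUE_CUTOFF,
    HMM_EVALUE_CUTOFF,
    CandidateCall,
    classify_histone_candidates,
    parse_blast_tab,
    parse_hmmer_domtbl,
    tally_completeness,
)
from .records import ProteinRecord
from .sequence_io import flag_misassembly, read_fasta, trim_nterminal_overhang
from .toolkit_census import (
    build_architectures,
    census,
    classify_architecture,
    detect_ctd_repeats,
    load_rules,
    render_census_tsv,
)

__all__ = ["summarize_expression_by_class", "run_pipeline", "PipelineError"]

CORE_CLASSES = ("H2A", "H2B", "H3", "H4")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record/path."""


def read_tpm_table(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t")
    id_col, tpm_col = frame.columns[0], frame.columns[1]
    return dict(zip(frame[id_col].astype(str), frame[tpm_col].astype(float)))


def summarize_expression_by_class(
    tpm_table: dict[str, float],
    calls: list[CandidateCall],
    proteins: list[ProteinRecord] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Order statistics of TPM per species and class, plus the per-species
    comparison "median DVNP TPM > median core-histone TPM".

    A one-sided Mann–Whitney U p-value accompanies the median comparison as
    a supplementary formalization of "more highly expressed".  Ids absent
    from the TPM table are skipped.
    """
    species_of = {p.id: p.species for p in (proteins or [])}
    grouped: dict[tuple[str, str], list[float]] = {}
    for call in calls:
        if call.assigned_class == "none":
            continue
        value = tpm_table.get(call.protein_id)
        if value is None:
            continue
        if value < 0:
            raise ValueError(f"negative TPM for {call.protein_id}")
        key = (species_of.get(call.protein_id, ""), call.assigned_class)
        grouped.setdefault(key, []).append(value)
    rows = []
    for (sp, cls), values in sorted(grouped.items()):
        series = pd.Series(values)
        rows.append(
            {
                "species": sp,
                "assigned_class": cls,
                "n": len(values),
                "min": series.min(),
                "q1": series.quantile(0.25),
                "median": series.median(),
                "q3": series.quantile(0.75),
                "max": series.max(),
            }
        )
    table = pd.DataFrame(
        rows, columns=["species", "assigned_class", "n", "min", "q1", "median", "q3", "max"]
    )
    comparisons: dict[str, dict] = {}
    for sp in sorted({k[0] for k in grouped}):
        dvnp = grouped.get((sp, "DVNP"), [])
        core: list[float] = []
        for cls in CORE_CLASSES:
            core.extend(grouped.get((sp, cls), []))
        if dvnp and core:
            flag = bool(pd.Series(dvnp).median() > pd.Series(core).median())
            u = stats.mannwhitneyu(dvnp, core, alternative="greater")
            comparisons[sp] = {
                "dvnp_gt_histone_median": flag,
                "mannwhitney_p": float(u.pvalue),
            }
        else:
            comparisons[sp] = {"dvnp_gt_histone_median": None, "mannwhitney_p": None}
    return table, comparisons


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the full analysis described by ``config`` and write the bundle.

    ``config`` maps stage inputs to paths: ``proteins`` (translated FASTA
    with optional completeness/species metadata), ``blast``, ``domtbl``,
    optional ``class_map``, ``panels``, ``references``, ``rules``, ``tpm``,
    and ``outdir``; cutoffs default to 1e-10 (BLAST) and 1e-8 (profiles).
    Returns a dict of output paths plus in-memory results.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir or config.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)

    for key in ("proteins", "blast", "domtbl"):
        if key not in config:
            raise PipelineError(f"config: missing required input {key!r}")
        if not Path(config[key]).exists():
            raise PipelineError(f"config: {key} path does not exist: {config[key]}")

    def stage(name: str, func, *args, **kwargs):
        try:
            return func(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    blast_cutoff = float(config.get("blast_cutoff", BLAST_EVALUE_CUTOFF))
    hmm_cutoff = float(config.get("hmm_cutoff", HMM_EVALUE_CUTOFF))

    proteins: list[ProteinRecord] = stage("read-proteins", read_fasta, config["proteins"])
    by_id = {p.id: p for p in proteins}
    blast_hits = stage("parse-blast", parse_blast_tab, config["blast"])
    domain_hits = stage("parse-domtbl", parse_hmmer_domtbl, config["domtbl"])

    if "class_map" in config:
        class_map = yaml.safe_load(Path(config["class_map"]).read_text())
    else:
        from importlib import resources

        with resources.as_file(
            resources.files("histone_profiler.data") / "class_map.yaml"
        ) as p:
            class_map = yaml.safe_load(p.read_text())

    calls = stage(
        "screen",
        classify_histone_candidates,
        blast_hits,
        domain_hits,
        class_map,
        blast_cutoff,
        hmm_cutoff,
    )
    unknown = [c.protein_id for c in calls if c.protein_id not in by_id]
    if unknown:
        raise PipelineError(f"stage 'screen': evidence for unknown protein ids {unknown[:5]}")

    references = load_references(config.get("references"))
    panels = load_panels(config.get("panels"), references)
    matrix = blosum62()

    # misassembly flagging + N-terminal trimming for core-histone calls
    class_of = {c.protein_id: c.assigned_class for c in calls}
    aligned: dict[str, AlignmentResult] = {}
    for call in calls:
        cls = call.assigned_class
        if cls not in CORE_CLASSES:
            continue
        protein = by_id[call.protein_id]
        flagged, _ = stage(
            "flag-misassembly", flag_misassembly, protein, references[cls]
        )
        if flagged:
            protein.flags.add("misassembly")
            continue
        aln = stage("align", global_align, protein, references[cls], matrix)
        trimmed = stage("trim", trim_nterminal_overhang, protein, aln)
        if "trimmed_nterm" in trimmed.flags:
            by_id[call.protein_id] = trimmed
            idx = proteins.index(protein)
            proteins[idx] = trimmed
            aln = stage("align", global_align, trimmed, references[cls], matrix)
        aligned[call.protein_id] = aln

    tallies = stage("tally", tally_completeness, calls, proteins)
    tallies.to_csv(outdir / "tallies.tsv", sep="\t", index=False)

    lengths = stage(
        "lengths",
        length_distribution,
        proteins,
        class_of,
        {cls: len(seq) for cls, seq in references.items()},
    )
    lengths.to_csv(outdir / "lengths.tsv", sep="\t", index=False)

    # conservation grids per species and class
    species_names = sorted({p.species for p in proteins})
    frames = []
    for sp in species_names:
        for cls in CORE_CLASSES:
            variants = [
                (by_id[pid], aligned[pid])
                for pid, c in sorted(class_of.items())
                if c == cls
                and pid in aligned
                and by_id[pid].species == sp
                and "misassembly" not in by_id[pid].flags
            ]
            if not variants:
                continue
            frames.append(
                conservation_report(variants, panels[cls], references[cls], species=sp)
            )
    conservation = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["species", "histone_class", "site", "radius", "C", "N", "fraction"]
        )
    )
    conservation.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    conservation.to_json(outdir / "conservation.json", orient="records", indent=2)

    # H2A.X motifs
    motif_rows = []
    for pid, cls in sorted(class_of.items()):
        if cls != "H2A" or "misassembly" in by_id[pid].flags:
            continue
        for mode in ("strict", "relaxed"):
            hit = scan_h2ax_motif(by_id[pid], mode=mode)
            if hit:
                motif_rows.append(
                    {
                        "protein_id": pid,
                        "species": by_id[pid].species,
                        "mode": mode,
                        "motif": hit.motif_sequence,
                        "start": hit.start,
                        "distance_from_cterm": hit.distance_from_cterm,
                    }
                )
    pd.DataFrame(
        motif_rows,
        columns=["protein_id", "species", "mode", "motif", "start", "distance_from_cterm"],
    ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)

    # H3.1/H3.3-style pairs
    pair_rows = []
    for sp in species_names:
        variants = [
            (by_id[pid], aligned[pid])
            for pid, c in sorted(class_of.items())
            if c == "H3" and pid in aligned and by_id[pid].species == sp
        ]
        for pair in detect_h31_h33_pairs(variants):
            pair_rows.append(
                {
                    "species": sp,
                    "id_a": pair.id_a,
                    "id_b": pair.id_b,
                    "diagnostic_positions": ",".join(map(str, pair.diagnostic_positions)),
                    "identity_elsewhere": round(pair.identity_elsewhere, 4),
                }
            )
    pd.DataFrame(
        pair_rows,
        columns=["species", "id_a", "id_b", "diagnostic_positions", "identity_elsewhere"],
    ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)

    # toolkit census + CTD
    rules = load_rules(config.get("rules"))
    archs = stage("architectures", build_architectures, domain_hits, hmm_cutoff)
    archs_by_species: dict[str, dict] = {}
    for pid, arch in archs.items():
        protein = by_id.get(pid)
        if protein is None:
            continue
        archs_by_species.setdefault(protein.species, {})[pid] = arch
    ctd_by_species: dict[str, list] = {}
    ctd_json = {}
    for sp, sp_archs in sorted(archs_by_species.items()):
        for pid, arch in sorted(sp_archs.items()):
            if "Rpb1" in classify_architecture(arch, rules):
                ann = detect_ctd_repeats(by_id[pid])
                ctd_by_species.setdefault(sp, []).append(ann)
                ctd_json[pid] = {
                    "species": sp,
                    "repeat_count": ann.repeat_count,
                    "repeats": [
                        {"start": s, "heptad": h, "matches": m} for s, h, m in ann.repeats
                    ],
                    "position_profile": ann.position_profile,
                }
    matrix_df = stage("census", census, archs_by_species, rules, ctd_by_species)
    render_census_tsv(matrix_df, outdir / "census.tsv")
    (outdir / "ctd.json").write_text(json.dumps(ctd_json, indent=2, sort_keys=True))

    # expression
    expression_comparisons: dict[str, dict] = {}
    if "tpm" in config:
        tpm = stage("read-tpm", read_tpm_table, config["tpm"])
        expr, expression_comparisons = stage(
            "expression", summarize_expression_by_class, tpm, calls, proteins
        )
        expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        (outdir / "expression_comparisons.json").write_text(
            json.dumps(expression_comparisons, indent=2, sort_keys=True)
        )

    log = {
        "histone_profiler_version": __version__,
        "blast_cutoff": blast_cutoff,
        "hmm_cutoff": hmm_cutoff,
        "inputs": {k: str(config[k]) for k in sorted(config) if k != "outdir"},
        "n_proteins": len(proteins),
        "n_calls": sum(1 for c in calls if c.assigned_class != "none"),
    }
    (outdir / "run.log").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    return {
        "outdir": outdir,
        "calls": calls,
        "tallies": tallies,
        "lengths": lengths,
        "conservation": conservation,
        "census": matrix_df,
        "ctd": ctd_json,
        "expression_comparisons": expression_comparisons,
        "proteins": proteins,
    }
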