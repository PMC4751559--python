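# Methods

## Scope and data model

The pipeline profiles histone proteins and the chromatin-protein toolkit in
*translated transcriptome assemblies*. Its primary input is a protein FASTA
(one record per assembled transcript translation, optionally carrying
`completeness=` / `species=` tokens in the description) together with two
externally produced homology-evidence tables: BLASTP tabular output
(12-column outfmt-6) from searches with reference histone queries, and a
HMMER3 per-domain table (domtblout, hmmscan orientation) from profile scans.
The package does not run the search engines itself: the scientific content
here is everything downstream of the search — thresholding, filtering,
alignment, scoring, and census rules. A nucleotide front end
(`extract-orfs`) derives translations and completeness calls from raw
transcript FASTA.

## ORFs and completeness

Completeness is a property of the assembly, not the protein: a translation
is *complete* only when its ORF begins with an ATG-derived Met and ends at
an in-frame stop; otherwise it is 5′-incomplete (no start), 3′-incomplete
(no stop), or a fragment (neither). `find_orfs` scans all six frames with
the standard genetic code and reports maximal stop-to-stop segments. A
segment counts as having a start only when its *first* codon is ATG;
internal ATGs deliberately do not re-anchor the ORF. This keeps spurious
upstream residues (the product of an earlier in-frame start codon in the
assembly) attached to the translation, where the N-terminal trimming filter
can deal with them explicitly rather than silently. Translations consisting
solely of X are dropped; ambiguity codes other than N are mapped to N on
input, and X never counts as a match anywhere downstream.

Two record-level filters formalize what was historically manual curation:

- **N-terminal overhang trimming.** If a histone candidate has unaligned
  residues in front of the query position matched to reference position 1,
  and identity over the first 20 aligned reference positions is ≥ 80%, the
  leading residues are removed (`trimmed_nterm` flag). The threshold is
  deliberately strict so the rule fires only on near-reference tails —
  a conventional tail behind a spurious extension — and never rewrites
  genuinely divergent N-termini.
- **Misassembly flagging.** A candidate is a putative concatenation
  artifact when two or more mutually non-overlapping local alignments
  (Smith–Waterman, BLOSUM62, −11/−1) each cover ≥ 80% of the reference at
  ≥ 40% identity. The 40% identity floor tolerates deep divergence while
  excluding chance repeats; the coverage bound makes the flag provably
  impossible below 1.6× the reference length. Flagged records are excluded
  from all counts.

## Candidate classification

Both evidence channels compete per protein: BLAST hits at e ≤ 1e-10 and
domain hits at i-Evalue ≤ 1e-8 are mapped to classes (H2A/H2B/H3/H4, linker
histone H1 via the linker-histone domain, DVNP via user-supplied queries)
through an editable class map; the lowest e-value wins, ties broken by
higher bit score, then lexicographic class name — the assignment is fully
deterministic. Each hit line is thresholded independently (per-HSP).
Proteins whose evidence all fails the cutoffs are reported as class `none`.

## Reference alignment and the position map

Each classified variant is aligned globally to the mature human reference
of its class (H2A type 1, H2B type 1, H3.1, H4; initiator Met removed, so
mark numbering such as H3K4 is literal). The aligner is an affine-gap
Needleman–Wunsch (Gotoh) with BLOSUM62 and gap open −11 / extend −1 (gap of
length k costs open + (k−1)·extend), and a fixed traceback preference
(substitution, then query-consuming gap, then reference-consuming gap), so
the same inputs always give the same alignment. Pairwise alignment to the
reference replaces a multiple sequence alignment on purpose: the
conservation statistic needs only each variant's correspondence to the
reference, and the pairwise procedure is deterministic, dependency-free and
testable against an independent dynamic program.

The alignment yields a reference→query position map. Reference positions
opposite a gap count as *not conserved* — with one exception. When the
query's terminus is missing from the assembly (5′-incomplete for the
leading end, 3′-incomplete or fragment for the trailing end), terminal gap
runs are marked *unassessed* and excluded from the N denominator: absence
of evidence, not evidence of absence. One numerical subtlety: global
alignment of a truncated query occasionally "jump-matches" one or two of
its terminal residues to a distant reference residue instead of leaving a
clean end gap (the two placements can tie, and the diagonal-first
tie-break then picks the jump). Such isolated matches are artifacts of
end-gap placement, so the terminal unassessed run extends inward until the
first run of ≥ 3 consecutively aligned reference positions, absorbing
shorter islands. The cost is a slight undercount of N for genuinely
divergent incomplete termini; the benefit is that truncation never
masquerades as loss.

## Conservation scoring

For a panel site at reference position *i* and radius *r* ∈ {0, 1, 2}, the
window is [max(1, i−r), min(L, i+r)] (clipped at the reference ends). A
variant is conserved iff every window position maps to a query residue, the
mapped positions are contiguous, and the residues are identical — the
strictest reading of "precise contextual match": an insertion inside the
window breaks conservation at r ≥ 1 even when the flanking residues match.
C/N fractions are reported per species, site and radius (long-format TSV
and JSON). Radius monotonicity (C at r=2 ≤ r=1 ≤ r=0, with identical N when
nothing is unassessed) is a structural invariant and is asserted in tests.

The residue panels are data (`data/panels.yaml`), validated at load against
the references: every site's expected residue must equal the reference
residue at its position. The bundled panels cover the classic marks —
H3: R2, T3, K4, T6, K9, S10, T11, K14, K18, K23, K27, S28, P30, K36, P38,
K56, K64, K79; H4: S1, R3, K5, K8, K12, K16, K20, K59, K79, K91; H2A: S1,
the N-tail acetyl-lysines K5/K9/K13/K15, Y57, K119, T120, S122; H2B: the
N-tail acetyl-lysines K5/K12/K16/K20 and K120. (Mature-protein numbering
throughout; the H2A N-tail acetyl-lysines of human H2A type 1 sit at
5/9/13/15.) Because figure-panel membership conventions vary, panels are
user-editable.

## Variant annotation

- **H2A.X motif.** The final 10 residues of an H2A candidate are scanned
  for S-Q-x₃-x₄ with x₄ hydrophobic (Φ = {A,V,L,I,M,F,W,Y}, wide enough to
  cover observed F/Y/I/M variants). Strict mode additionally requires
  x₃ ∈ {E, D}; relaxed mode drops that constraint to capture natural
  near-motifs such as SQQY. The match closest to the C-terminus wins;
  strict hits are a subset of relaxed hits by construction.
- **H3.1/H3.3-style pairs.** Two H3 variants form a replication-variant
  pair when their reference-projected sequences agree at ≥ 95% of mutually
  assessable positions and differ at position 31 with one member carrying a
  phosphorylatable S/T and the other A. The 0.95 threshold formalizes
  "very similar"; all differing positions are reported.

## Toolkit census and CTD

Domain hits at i-Evalue ≤ 1e-8 are reduced to per-protein architectures
(overlapping same-domain hits merged to their union interval, best e-value
kept). Census categories are required-domain multisets in
`data/toolkit_rules.yaml`, mirroring the standard combinations: remodeler
ATPase core = SWI2_N + Helicase_C; CHD-type adds Chromo; ISWI-type adds
SLIDE; INO80-type adds DBINO; HP1 = 2× Chromo + chromo shadow; FACT =
Spt16 and SSrecog (SSRP1); single-domain categories (SET, SIR2, HDAC,
JmjC, Bromo, Chromo, PHD, Tudor, PWWP, WD40, NAP1, ASF1, …) require one
copy. GNAT acetyltransferase domains occur in many enzymes unrelated to
chromatin, so GNAT counts are reported as such rather than inferred to be
HAT complexes (adapter-domain searches are the user's recourse, via the
same rule mechanism). Complexes without a single canonical profile (CAF-1,
HIRA, Dot1, PRMT5, Spt16, Rpb1) ship with documented default domain names,
all editable. Classification is monotone in evidence: adding a domain never
removes a label. The census matrix counts distinct proteins per category
and species, with "–" marking absence.

Rpb1 candidates (by domain hit) are annotated for CTD heptads: the
C-terminal 30% of the protein is tiled greedily left-to-right with
non-overlapping 7-mers scoring ≥ 4/7 identities to YSPTSPS, and isolated
tiles (no neighbor within 7 residues) are suppressed. The permissive floor
plus chaining is tuned to repeats that are recognizable yet highly
divergent from the consensus; in the census, 0 repeats in a detected Rpb1
homolog is distinct from no homolog at all. `annotate_heptad` counts
phosphorylatable (S/T/Y) and isomerizable (P) positions per heptad —
5 and 2 for the consensus.

## Expression summaries

TPM computation is out of scope (the table is an input). Per species and
class the pipeline reports order statistics and the comparison "median DVNP
TPM > median core-histone TPM", accompanied by a one-sided Mann–Whitney U
p-value as our explicit formalization of "more highly expressed".

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
3 species by default, with 5 H3 / 3 H4 / 3 H2A / 3 H2B variants, one linker
histone and 3 DVNPs per species. Variants diverge from the references by
per-residue substitution at rate 0.15 (uniform over the 19 alternatives —
the analysis consumes identity, not evolutionary distance), with selected
sites protected together with their ±2 context (defaults mirror the
well-conserved sites: H3 K4/K36/K56/K64, H4 K12/K59/K79/K91, H2A Y57/K119,
H2B K120). 30% of variants get C-terminal extensions of 20–60 random
residues (elongation without new domains); 20% each are 5′- or 3′-truncated
(1–10 residues plus the start or stop codon); one H2A per species carries
an appended SQEF motif; one doubled-H4 misassembly and five shuffled decoys
(with deliberately failing evidence rows) are added per species. Toolkit
proteins carry configured architectures; an Rpb1-like protein carries 8
consensus heptads. TPMs are log-normal with log-means 2.5 (histones) and
6.0 (DVNP), σ = 0.8/0.5, reproducing the DVNP ≫ histone hierarchy.
Transcripts are uniform-synonymous-codon back-translations. Evidence
tables are synthesized rather than produced by live searches, so tests
need no external tools. All outputs are byte-deterministic functions of
(config, seed). H1 and DVNP use fixed synthetic stand-in sequences
(there is no curated reference for them here); their classification is
purely evidence-driven, so only fixedness matters.

What the generator does *not* emulate — real codon usage and GC content,
trans-splicing leaders, sequencing error, assembly chimerism beyond exact
concatenation, genuinely novel domains — bounds what passing tests show:
they validate the *procedure* (thresholds, filters, scoring, bookkeeping)
exactly, not the biological sensitivity of homology search on real
dinoflagellate data.

## Verification and problem sizes

- The global aligner is checked score-exact against an independent affine
  dynamic program (Biopython's PairwiseAligner) on 200 seeded random pairs
  of length ≤ 12, and the bundled BLOSUM62 file against the canonical
  matrix entry-by-entry.
- The conservation scorer is checked against a direct string-slice oracle
  on 100 seeded substitution-only mutants (gap-free alignments) at every
  panel site and radius.
- Parameter recovery: protecting {H3K4, H3K36, H3K64} at substitution rate
  0.3 in 20 variants yields C/N = 1.0 exactly at the protected sites and
  < 1.0 at ≥ 90% of unprotected sites at r = 2. Twenty variants (rather
  than fewer) keep the chance of an unprotected site surviving intact in
  every variant below 1e-3 — relevant for H3R2/H3T3, whose r=2 windows
  overlap the protected H3K4 context everywhere except position 1.
- End-to-end: on the default synthetic dataset the pipeline recovers class
  labels, completeness tallies, misassembly flags, the census matrix and
  CTD repeat counts exactly as manifested, and decoys are class `none`.
- `scripts/acceptance.py --seed N --out results.json` recomputes all of the
  above from scratch in a few seconds on one CPU; the full test suite runs
  in well under a minute.

## Known limitations

Conservation of a residue and its context does not show the mark is
deposited in vivo (mass-spectrometry evidence is out of scope), and absence
in a transcriptome assembly is weak evidence of genomic absence. The
pairwise-to-reference convention scores each variant independently; it
cannot represent variant-specific contexts that an MSA column might. The
island-absorbing unassessed rule slightly under-counts N for divergent
incomplete termini. Phylogenetics, multiple alignment, read mapping and
abundance estimation are intentionally external to this package.
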