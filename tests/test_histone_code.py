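"""Windowed conservation scoring, motif scanning, and variant pairs."""
import random

import pytest

from histone_profiler.alignment import blosum62, global_align
from histone_profiler.histone_code import (
    detect_h31_h33_pairs,
    length_distribution,
    scan_h2ax_motif,
    score_residue_conservation,
)
from histone_profiler.records import Completeness, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _variant(ref, seq, vid="v", completeness=Completeness.COMPLETE, matrix=None):
    rec = ProteinRecord(id=vid, sequence=seq, completeness=completeness)
    return rec, global_align(rec, ref, matrix or blosum62())


@pytest.fixture(scope="module")
def matrix():
    return blosum62()


class TestConservation:
    def test_identical_variant_conserved_everywhere(self, references, panels, matrix):
        ref = references["H3"]
        variants = [_variant(ref, ref, matrix=matrix)]
        for r in (0, 1, 2):
            counts = score_residue_conservation(variants, panels["H3"], ref, r)
            assert all(cn == (1, 1) for cn in counts.values())

    def test_k9_methionine_substitution(self, references, panels, matrix):
        # an otherwise conventional H3 tail with K9 replaced by methionine
        ref = references["H3"]
        seq = ref[:8] + "M" + ref[9:]
        counts = score_residue_conservation(
            [_variant(ref, seq, matrix=matrix)], panels["H3"], ref, 0
        )
        assert counts["H3K9"] == (0, 1)
        assert counts["H3K4"] == (1, 1)

    def test_insertion_breaks_context_but_not_residue(self, references, panels, matrix):
        # 2-residue insertion between reference positions 3 and 4
        ref = references["H3"]
        seq = ref[:3] + "GG" + ref[3:]
        variants = [_variant(ref, seq, matrix=matrix)]
        r0 = score_residue_conservation(variants, panels["H3"], ref, 0)
        r1 = score_residue_conservation(variants, panels["H3"], ref, 1)
        assert r0["H3K4"] == (1, 1)
        assert r1["H3K4"] == (0, 1)

    def test_invalid_radius_rejected(self, references, panels):
        with pytest.raises(ValueError):
            score_residue_conservation([], panels["H3"], references["H3"], 3)

    def test_empty_variant_list_gives_zero_n(self, references, panels):
        counts = score_residue_conservation([], panels["H3"], references["H3"], 0)
        assert all(cn == (0, 0) for cn in counts.values())

    def test_matches_string_slice_oracle_on_gapfree_mutants(
        self, references, panels, matrix
    ):
        """Substitution-only mutants align gap-free; windowed conservation
        must equal a direct string-slice comparison at every site and radius."""
        ref = references["H3"]
        rng = random.Random(2024)
        variants = []
        for _ in range(100):
            seq = list(ref)
            for i in range(len(seq)):
                if rng.random() < 0.2:
                    seq[i] = rng.choice([a for a in AA if a != seq[i]])
            variants.append("".join(seq))
        aligned = [_variant(ref, v, vid=f"m{i}", matrix=matrix) for i, v in enumerate(variants)]
        for _, aln in aligned:
            assert "-" not in aln.aligned_query and "-" not in aln.aligned_reference
        for r in (0, 1, 2):
            counts = score_residue_conservation(aligned, panels["H3"], ref, r)
            for site in panels["H3"].sites:
                lo, hi = max(1, site.pos - r), min(len(ref), site.pos + r)
                expected = sum(
                    1 for v in variants if v[lo - 1 : hi] == ref[lo - 1 : hi]
                )
                assert counts[site.name] == (expected, len(variants)), (site.name, r)

    def test_radius_monotone_with_constant_n(self, references, panels, matrix):
        ref = references["H4"]
        rng = random.Random(5)
        variants = []
        for i in range(30):
            seq = list(ref)
            for j in range(len(seq)):
                if rng.random() < 0.15:
                    seq[j] = rng.choice([a for a in AA if a != seq[j]])
            variants.append(_variant(ref, "".join(seq), vid=f"v{i}", matrix=matrix))
        by_radius = {
            r: score_residue_conservation(variants, panels["H4"], ref, r)
            for r in (0, 1, 2)
        }
        for site in panels["H4"].sites:
            c0, n0 = by_radius[0][site.name]
            c1, n1 = by_radius[1][site.name]
            c2, n2 = by_radius[2][site.name]
            assert c2 <= c1 <= c0
            assert n0 == n1 == n2 == 30


class TestH2axMotif:
    def _protein(self, tail):
        return ProteinRecord(id="p", sequence="MSGRGKQGGKARAKAK" + tail)

    @pytest.mark.parametrize("tail", ["GKSQEF", "GKSQEY", "GKSQDF", "GKSQEI", "GKSQEM"])
    def test_strict_accepts_canonical_motifs(self, tail):
        hit = scan_h2ax_motif(self._protein(tail), mode="strict")
        assert hit is not None and hit.motif_sequence == tail[-4:]
        assert hit.distance_from_cterm == 0

    def test_sqqy_rejected_strict_accepted_relaxed(self):
        protein = self._protein("GKSQQY")
        assert scan_h2ax_motif(protein, mode="strict") is None
        relaxed = scan_h2ax_motif(protein, mode="relaxed")
        assert relaxed is not None and relaxed.motif_sequence == "SQQY"

    def test_no_motif(self):
        assert scan_h2ax_motif(self._protein("GKGKGK"), mode="relaxed") is None

    def test_match_closest_to_cterm_wins(self):
        protein = self._protein("SQEFSQEY")
        hit = scan_h2ax_motif(protein, mode="strict")
        assert hit.motif_sequence == "SQEY"

    def test_outside_cterm_window_ignored(self):
        protein = ProteinRecord(id="p", sequence="MSQEF" + "G" * 20)
        assert scan_h2ax_motif(protein, mode="strict") is None

    def test_strict_hits_subset_of_relaxed(self):
        rng = random.Random(31)
        for _ in range(200):
            seq = "".join(rng.choice(AA) for _ in range(rng.randint(8, 40)))
            protein = ProteinRecord(id="p", sequence=seq)
            strict = scan_h2ax_motif(protein, mode="strict")
            if strict is not None:
                relaxed = scan_h2ax_motif(protein, mode="relaxed")
                assert relaxed is not None


class TestH31H33Pairs:
    def test_position31_s_vs_a_pair(self, references, matrix):
        ref = references["H3"]
        a = _variant(ref, ref, vid="h31", matrix=matrix)  # position 31 is A
        b = _variant(ref, ref[:30] + "S" + ref[31:], vid="h33", matrix=matrix)
        pairs = detect_h31_h33_pairs([a, b])
        assert len(pairs) == 1
        assert pairs[0].diagnostic_positions == (31,)

    def test_identical_variants_no_pair(self, references, matrix):
        ref = references["H3"]
        a = _variant(ref, ref, vid="x", matrix=matrix)
        b = _variant(ref, ref, vid="y", matrix=matrix)
        assert detect_h31_h33_pairs([a, b]) == []

    def test_divergent_variants_below_threshold_no_pair(self, references, matrix):
        ref = references["H3"]
        rng = random.Random(8)
        seq = list(ref[:30] + "S" + ref[31:])
        for i in range(0, len(seq), 3):  # ~33% divergence everywhere else
            if i != 30:
                seq[i] = rng.choice([x for x in AA if x != seq[i]])
        a = _variant(ref, ref, vid="x", matrix=matrix)
        b = _variant(ref, "".join(seq), vid="y", matrix=matrix)
        assert detect_h31_h33_pairs([a, b]) == []

    def test_fewer_than_two_variants(self, references, matrix):
        ref = references["H3"]
        assert detect_h31_h33_pairs([_variant(ref, ref, matrix=matrix)]) == []


class TestLengthDistribution:
    def test_order_statistics(self):
        proteins = [
            ProteinRecord(id=f"p{i}", sequence="A" * n, species="sp",
                          completeness=Completeness.COMPLETE)
            for i, n in enumerate([135, 135, 167])
        ]
        classes = {p.id: "H3" for p in proteins}
        table = length_distribution(proteins, classes)
        row = table.iloc[0]
        assert (row["n"], row["min"], row["median"], row["max"]) == (3, 135, 135.0, 167)

    def test_incomplete_proteins_excluded(self):
        proteins = [
            ProteinRecord(id="a", sequence="A" * 100, species="sp",
                          completeness=Completeness.COMPLETE),
            ProteinRecord(id="b", sequence="A" * 50, species="sp",
                          completeness=Completeness.INCOMPLETE_5PRIME),
        ]
        table = length_distribution(proteins, {"a": "H4", "b": "H4"})
        assert table.iloc[0]["n"] == 1 and table.iloc[0]["min"] == 100

    def test_reference_lengths_appended(self):
        table = length_distribution([], {}, reference_lengths={"H4": 102})
        ref_row = table[table["species"] == "reference"].iloc[0]
        assert ref_row["min"] == ref_row["max"] == 102
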