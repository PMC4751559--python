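"""Domain-architecture rules, census counting, and CTD heptad annotation."""
import random

import pytest

from histone_profiler.homology_screen import DomainHit
from histone_profiler.records import ProteinRecord
from histone_profiler.toolkit_census import (
    DomainArchitecture,
    annotate_heptad,
    build_architectures,
    census,
    classify_architecture,
    detect_ctd_repeats,
    load_rules,
)


def _hit(pid, domain, evalue=1e-20, start=1, end=60):
    return DomainHit(pid, domain, "PF00000.1", evalue, start, end, 100.0)


@pytest.fixture(scope="module")
def rules():
    return load_rules()


class TestBuildArchitectures:
    def test_threshold_applied(self):
        archs = build_architectures([_hit("p", "SET", 1e-9), _hit("p", "PHD", 1e-6)])
        assert [d[0] for d in archs["p"].accepted_domains] == ["SET"]

    def test_no_hits_no_architectures(self):
        assert build_architectures([]) == {}

    def test_overlapping_same_domain_merged(self):
        archs = build_architectures(
            [_hit("p", "Chromo", 1e-12, 10, 60), _hit("p", "Chromo", 1e-15, 50, 100)]
        )
        domains = archs["p"].accepted_domains
        assert domains == [("Chromo", 10, 100, 1e-15)]

    def test_non_overlapping_same_domain_kept_separate(self):
        archs = build_architectures(
            [_hit("p", "Chromo", 1e-12, 10, 60), _hit("p", "Chromo", 1e-15, 80, 140)]
        )
        assert len(archs["p"].accepted_domains) == 2


class TestClassifyArchitecture:
    def test_chd_architecture(self, rules):
        archs = build_architectures(
            [_hit("p", "Chromo", start=1, end=60),
             _hit("p", "SWI2_N", start=100, end=200),
             _hit("p", "Helicase_C", start=250, end=350)]
        )
        labels = classify_architecture(archs["p"], rules)
        assert {"remodeler-core", "CHD-type", "Chromo-reader"} <= labels

    def test_hp1_architecture(self, rules):
        archs = build_architectures(
            [_hit("p", "Chromo", start=1, end=50),
             _hit("p", "Chromo", start=70, end=120),
             _hit("p", "Chromo_shadow", start=150, end=200)]
        )
        labels = classify_architecture(archs["p"], rules)
        assert {"HP1", "Chromo-reader"} <= labels

    def test_single_chromodomain_is_not_hp1(self, rules):
        archs = build_architectures([_hit("p", "Chromo")])
        labels = classify_architecture(archs["p"], rules)
        assert "HP1" not in labels and "Chromo-reader" in labels

    def test_empty_architecture_no_labels(self, rules):
        assert classify_architecture(DomainArchitecture("p"), rules) == set()

    def test_adding_domains_never_removes_labels(self, rules):
        rng = random.Random(17)
        domains = ["Chromo", "SWI2_N", "Helicase_C", "SET", "Bromodomain",
                   "Chromo_shadow", "SLIDE", "SSrecog", "NAP"]
        for _ in range(30):
            chosen = [d for d in domains if rng.random() < 0.5]
            hits = [_hit("p", d, start=1 + 100 * i, end=60 + 100 * i)
                    for i, d in enumerate(chosen)]
            arch = build_architectures(hits).get("p", DomainArchitecture("p"))
            base = classify_architecture(arch, rules)
            extra = rng.choice(domains)
            hits.append(_hit("p", extra, start=2000, end=2060))
            grown = classify_architecture(build_architectures(hits)["p"], rules)
            assert base <= grown

    def test_chd_implies_remodeler_core(self, rules):
        # rule-subset relation must hold for arbitrary architectures
        rng = random.Random(23)
        domains = ["Chromo", "SWI2_N", "Helicase_C", "SLIDE", "DBINO", "SET"]
        for _ in range(40):
            chosen = [d for d in domains if rng.random() < 0.6]
            hits = [_hit("p", d, start=1 + 100 * i, end=60 + 100 * i)
                    for i, d in enumerate(chosen)]
            archs = build_architectures(hits)
            if "p" not in archs:
                continue
            labels = classify_architecture(archs["p"], rules)
            if "CHD-type" in labels:
                assert "remodeler-core" in labels

    def test_unknown_domain_in_rules_rejected(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text("weird: {NotADomain: 1}\n")
        with pytest.raises(ValueError, match="NotADomain"):
            load_rules(p, known_domains={"SET", "Chromo"})


class TestCensus:
    def test_counts_distinct_proteins(self, rules):
        hits = [_hit(f"set{i}", "SET") for i in range(3)]
        archs = build_architectures(hits)
        matrix = census({"spX": archs}, rules)
        assert matrix.loc["spX", "SET"] == 3

    def test_fact_columns(self, rules):
        archs = build_architectures([_hit("a", "SPT16"), _hit("b", "SSrecog")])
        matrix = census({"spX": archs}, rules)
        assert matrix.loc["spX", "Spt16"] == 1 and matrix.loc["spX", "SSRP1"] == 1

    def test_absence_is_na(self, rules):
        import pandas as pd

        matrix = census({"spX": build_architectures([_hit("a", "SET")])}, rules)
        assert pd.isna(matrix.loc["spX", "HP1"])

    def test_synthetic_census_equals_manifest(self, rules, dataset):
        from histone_profiler.homology_screen import parse_hmmer_domtbl

        ds, paths = dataset
        hits = parse_hmmer_domtbl(paths["domtbl"])
        by_species: dict[str, dict] = {}
        for pid, arch in build_architectures(hits).items():
            species = pid.split(".")[0]
            by_species.setdefault(species, {})[pid] = arch
        matrix = census(by_species, rules)
        for species, expected in ds.manifest["census_expected"].items():
            for category, count in expected.items():
                assert matrix.loc[species, category] == count, (species, category)
            # all other categories absent
            for category in matrix.columns:
                if category not in expected:
                    import pandas as pd

                    assert pd.isna(matrix.loc[species, category]), (species, category)


class TestCtd:
    def _protein(self, tail, body_len=100):
        rng = random.Random(3)
        body = "".join(rng.choice("ACDEFGHIKLMNPQR") for _ in range(body_len))
        return ProteinRecord(id="rpb1", sequence=body + tail)

    def test_two_perfect_repeats(self):
        ann = detect_ctd_repeats(self._protein("YSPTSPS" * 2))
        assert ann.repeat_count == 2
        assert all(m == 7 for _, _, m in ann.repeats)

    def test_divergent_repeats_scored(self):
        ann = detect_ctd_repeats(self._protein("YSPTSPAYSPSSPS"))
        assert ann.repeat_count == 2
        assert [m for _, _, m in ann.repeats] == [6, 6]

    def test_random_sequence_has_no_repeats(self):
        rng = random.Random(404)
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200))
        ann = detect_ctd_repeats(ProteinRecord(id="r", sequence=seq))
        assert ann.repeat_count == 0

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_k_tandem_copies_detected_exactly(self, k):
        # body long enough that the full array lies in the C-terminal 30%
        ann = detect_ctd_repeats(self._protein("YSPTSPS" * k, body_len=20 * k))
        assert ann.repeat_count == k
        assert all(m == 7 for _, _, m in ann.repeats)
        assert ann.position_profile == [k] * 7

    def test_short_protein(self):
        ann = detect_ctd_repeats(ProteinRecord(id="r", sequence="YSP"))
        assert ann.repeat_count == 0

    def test_isolated_tile_suppressed(self):
        ann = detect_ctd_repeats(self._protein("YSPTSPS", body_len=200))
        assert ann.repeat_count == 0


class TestAnnotateHeptad:
    def test_consensus_heptad(self):
        phospho, proline, labels = annotate_heptad("YSPTSPS")
        assert (phospho, proline) == (5, 2)
        assert labels == [
            "phospho", "phospho", "proline-iso", "phospho",
            "phospho", "proline-iso", "phospho",
        ]

    @pytest.mark.parametrize(
        "heptad,expected", [("AAAAAAA", (0, 0)), ("SSSSSSS", (7, 0))]
    )
    def test_counting_definition(self, heptad, expected):
        phospho, proline, _ = annotate_heptad(heptad)
        assert (phospho, proline) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            annotate_heptad("YSPTSP")
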