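import numpy as np
import pytest

from endoshrink.census import (
    CategoryMap,
    CensusEntry,
    CladeCutoff,
    alignment_identity_coverage,
    categorize,
    compare_categories,
    derive_cutoff,
    extract_large,
    find_oie_ortholog,
    max_lengths,
)
from endoshrink.io_formats import BlastHit, ProteinRecord, SpeciesMeta

from oracles import exact_mann_whitney_p

META = [
    SpeciesMeta("o1", "F", "OIE", 0.3),
    SpeciesMeta("o2", "F", "OIE", 0.5),
    SpeciesMeta("n1", "F", "nonOIE", 3.0),
]


def prots(sid, lengths):
    return [ProteinRecord(f"{sid}p{i}", sid, "A" * ln) for i, ln in enumerate(lengths)]


class TestMaxLengthsAndCutoff:
    def test_max_per_species(self):
        proteomes = {"o1": prots("o1", [10, 20, 15]), "o2": prots("o2", [8]),
                     "n1": prots("n1", [30, 12])}
        table = max_lengths(proteomes, META)
        by_sid = {r["species_id"]: r for r in table}
        assert by_sid["o1"]["max_length"] == 20
        assert by_sid["o2"]["max_length"] == 8  # single-protein proteome
        assert by_sid["n1"]["max_length"] == 30

    def test_tie_reports_lexicographically_smallest_id(self):
        proteomes = {"o1": [ProteinRecord("zz", "o1", "A" * 9),
                            ProteinRecord("aa", "o1", "C" * 9)]}
        (row,) = max_lengths(proteomes, META[:1])
        assert row["protein_id"] == "aa"

    def test_cutoff_is_max_over_oie_maxima(self):
        table = [
            {"species_id": "o1", "lifestyle": "OIE", "max_length": 1507},
            {"species_id": "o2", "lifestyle": "OIE", "max_length": 1200},
            {"species_id": "n1", "lifestyle": "nonOIE", "max_length": 9000},
        ]
        assert derive_cutoff(META, table, "Bacteroidetes").cutoff_aa == 1507

    def test_no_oie_species_rejected(self):
        table = [{"species_id": "n1", "lifestyle": "nonOIE", "max_length": 100}]
        with pytest.raises(ValueError):
            derive_cutoff(META, table, "clade")


class TestExtractLarge:
    CUTOFF = CladeCutoff("clade", 100)

    def test_strictly_greater_filter_on_nonoie_only(self):
        proteomes = {
            "o1": prots("o1", [150]),   # OIE never included
            "o2": prots("o2", [80]),
            "n1": prots("n1", [100, 101, 99]),  # at cutoff excluded, above included
        }
        entries = extract_large(proteomes, META, self.CUTOFF)
        assert [(e.protein_id, e.length) for e in entries] == [("n1p1", 101)]
        assert all(e.category == "unassigned" for e in entries)

    def test_empty_when_cutoff_at_global_maximum(self):
        proteomes = {"o1": prots("o1", [50]), "o2": prots("o2", [60]),
                     "n1": prots("n1", [90, 100])}
        assert extract_large(proteomes, META, self.CUTOFF) == []


class TestCategorize:
    def test_id_map_keyword_rules_and_unassigned(self):
        entries = [
            CensusEntry("pA", "n1", 2000),
            CensusEntry("pB", "n1", 1800),
            CensusEntry("pC", "n1", 1700),
        ]
        cmap = CategoryMap(
            {"pA": "core"}, (("polyketide", "secondary_or_unknown"),)
        )
        out, unassigned = categorize(
            entries, cmap, descriptions={"pB": "Polyketide synthase", "pC": "none"}
        )
        assert out[0].category == "core"
        assert out[1].category == "secondary_or_unknown"
        assert out[2].category == "unassigned" and unassigned == ["pC"]


class TestCompareCategories:
    def test_disjoint_distributions_reach_enumeration_minimum(self):
        entries = [CensusEntry(f"c{i}", "n1", 1500, "core") for i in range(5)] + [
            CensusEntry(f"s{i}", "n1", 8000 + i, "secondary_or_unknown")
            for i in range(5)
        ]
        res = compare_categories(entries)
        # lengths {1500}×5 are tied; the corrected normal approximation applies
        assert res["p"] < 0.02
        assert res["chi2"] == pytest.approx(res["z"] ** 2)
        assert res["core_median"] == 1500 and res["secondary_n"] == 5

    def test_exactly_matches_enumeration_for_tiefree_lengths(self):
        core = [1450, 1480, 1510, 1540]
        sec = [1700, 1800, 1900, 2000]
        entries = [CensusEntry(f"c{i}", "n1", v, "core") for i, v in enumerate(core)]
        entries += [
            CensusEntry(f"s{i}", "n1", v, "secondary_or_unknown")
            for i, v in enumerate(sec)
        ]
        assert compare_categories(entries)["p"] == pytest.approx(
            exact_mann_whitney_p(core, sec), abs=1e-12
        )

    def test_empty_category_rejected(self):
        entries = [CensusEntry("c0", "n1", 1500, "core"),
                   CensusEntry("c1", "n1", 1500, "core")]
        with pytest.raises(ValueError):
            compare_categories(entries)


class TestFindOieOrtholog:
    def test_identical_sequences_found(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        large = ProteinRecord("big", "n1", seq)
        oie = {"o1": [ProteinRecord("small", "o1", seq)]}
        found, best = find_oie_ortholog(large, oie_proteomes=oie)
        assert found and best == "small"

    def test_shortened_counterpart_passes_thresholds(self):
        rng = np.random.default_rng(2)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        big_seq = "".join(rng.choice(aa, 1500))
        small = list(big_seq[:1200])
        for i in rng.choice(1200, size=24, replace=False):  # 2% substitutions
            small[i] = next(c for c in aa if c != small[i])
        large = ProteinRecord("big", "n1", big_seq)
        oie = {"o1": [ProteinRecord("small", "o1", "".join(small))]}
        found, _ = find_oie_ortholog(large, oie_proteomes=oie)
        assert found

    def test_low_coverage_fails_despite_high_identity(self):
        rng = np.random.default_rng(3)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        oie_seq = "".join(rng.choice(aa, 400))
        # the large protein contains only 150 of the OIE protein's 400 aa
        big_seq = "".join(rng.choice(aa, 1000)) + oie_seq[:150] + "".join(
            rng.choice(aa, 400)
        )
        found, _ = find_oie_ortholog(
            ProteinRecord("big", "n1", big_seq),
            oie_proteomes={"o1": [ProteinRecord("small", "o1", oie_seq)]},
        )
        assert not found

    def test_blast_hit_route_applies_both_thresholds(self):
        large = ProteinRecord("big", "n1", "A" * 2000)
        lengths = {"small": 1000}

        def hit(ident, sstart, send):
            return BlastHit("big", "small", ident, send - sstart + 1, 0, 0,
                            1, send - sstart + 1, sstart, send, 1e-50, 500.0)

        ok = [hit(70.0, 1, 900)]        # 70% identity over 90% coverage
        low_cov = [hit(70.0, 1, 500)]   # 70% identity over 50% coverage
        low_id = [hit(60.0, 1, 900)]
        assert find_oie_ortholog(large, blast_hits=ok, subject_lengths=lengths)[0]
        assert not find_oie_ortholog(
            large, blast_hits=low_cov, subject_lengths=lengths
        )[0]
        assert not find_oie_ortholog(
            large, blast_hits=low_id, subject_lengths=lengths
        )[0]

    def test_neither_input_supplied_rejected(self):
        with pytest.raises(ValueError):
            find_oie_ortholog(ProteinRecord("big", "n1", "A" * 20))

    def test_identity_denominator_includes_gap_columns(self):
        # one 5-aa deletion inside an otherwise identical 60-aa region:
        # 55 matches over 60 columns ≈ 91.7%, not 55/55
        rng = np.random.default_rng(4)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(aa, 60))
        gapped = seq[:30] + seq[35:]
        identity, coverage = alignment_identity_coverage(seq, gapped)
        assert identity == pytest.approx(100 * 55 / 60, abs=1.0)
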