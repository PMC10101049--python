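from __future__ import annotations

import numpy as np
import pytest

from rdrpscout import annotate as ann
from rdrpscout import classify as cls
from rdrpscout import profilehmm as phmm
from rdrpscout.classify import ClassificationRecord, CoreSequence


def _core(seq, orf_ref="core1", seq_from=1):
    return CoreSequence(
        orf_ref=orf_ref,
        profile_name="fam",
        aa_seq=seq,
        seq_from=seq_from,
        seq_to=seq_from + len(seq) - 1,
    )


class TestLocateMotifC:
    def test_anchored_lookup_via_hit_map(self, small_family, small_profile):
        """The planted triplet is read off the anchored profile column."""
        from rdrpscout.orfs import Orf

        member = small_family.heldout_members[0][1]
        orf = Orf("c", 1, "+", 0, 0, 3 * len(member), member)
        hit = phmm.score_sequence(small_profile, member, orf_ref=orf.id)
        core = cls.trim_to_core(orf, hit)
        motif = ann.locate_motif_c(
            core, family_anchor=small_profile.motif_anchor_col, hit=hit
        )
        assert motif is not None
        assert motif.triplet == small_family.triplet
        # position maps back to the planted anchor column of the member
        assert core.seq_from - 1 + motif.position - 1 == small_family.anchor_col

    def test_fallback_prefers_position_near_70_percent(self):
        # two candidates: GDD at 20% and SDD at ~70% of the core
        seq = "L" * 20 + "GDD" + "L" * 47 + "SDD" + "L" * 28
        motif = ann.locate_motif_c(_core(seq))
        assert motif.triplet == "SDD"
        assert motif.window == "LLLLLSDDLLLLL"

    def test_no_candidate_returns_absent(self):
        assert ann.locate_motif_c(_core("L" * 50)) is None

    def test_window_padding_at_core_edges(self):
        motif = ann.locate_motif_c(_core("GDDLLLLLL"))
        assert motif.position == 1
        assert motif.window == "-----GDDLLLLL"


class TestTripletCensus:
    def test_counts_exact(self):
        motifs = [
            ann.MotifC("a", 1, "GDD", "-----GDDAAAAA"),
            ann.MotifC("b", 1, "GDD", "-----GDDAAAAA"),
            ann.MotifC("c", 1, "SDD", "-----SDDAAAAA"),
        ]
        census, table = ann.triplet_census(motifs)
        assert census.to_dict() == {"GDD": 2, "SDD": 1}
        assert census.sum() == len(motifs)  # conservation of counts
        # padding excluded: column 1 saw nothing, column 6 saw G,G,S
        assert table[1].sum() == 0
        assert table[6]["G"] == 2 and table[6]["S"] == 1

    def test_empty_input(self):
        census, table = ann.triplet_census([])
        assert len(census) == 0

    def test_planted_mixture_recovered_exactly(self, rng):
        weights = {"GDD": 500, "SDD": 300, "GDN": 120, "IDD": 50, "ADN": 20, "ADD": 10}
        motifs = []
        i = 0
        for trip, n in weights.items():
            for _ in range(n):
                motifs.append(ann.MotifC(f"m{i}", 6, trip, f"XXXXX{trip}XXXXX"))
                i += 1
        order = rng.permutation(len(motifs))
        census, _ = ann.triplet_census([motifs[j] for j in order])
        assert census.to_dict() == weights
        assert list(census.index) == list(weights)  # descending frequency


class TestCooccurrence:
    def _rec(self, best, second, status=cls.CLASSIFIED):
        return ClassificationRecord(
            orf_ref=f"{best}-{second}",
            status=status,
            best_profile=best,
            best_idscore=0.5,
            second_profile=second,
            second_idscore=0.3 if second else None,
        )

    def test_row_normalisation_by_max(self):
        mat = ann.cooccurrence_matrix(
            [self._rec("A", "B"), self._rec("A", "B"), self._rec("A", "C")]
        )
        df = mat.to_frame()
        assert df.loc["A", "B"] == 2 and df.loc["A", "C"] == 1
        norm = mat.to_frame(normalized=True)
        assert norm.loc["A", "B"] == 1.0 and norm.loc["A", "C"] == 0.5

    def test_single_record(self):
        mat = ann.cooccurrence_matrix([self._rec("A", "B")])
        assert mat.to_frame(normalized=True).loc["A", "B"] == 1.0

    def test_records_without_second_hit_are_skipped(self):
        mat = ann.cooccurrence_matrix([self._rec("A", None)])
        assert mat.counts.size == 0

    def test_non_classified_records_excluded_and_counts_conserved(self):
        recs = [
            self._rec("A", "B"),
            self._rec("A", "C", status=cls.AMBIGUOUS),
            self._rec("B", "A"),
        ]
        mat = ann.cooccurrence_matrix(recs)
        assert mat.counts.sum() == 2
        assert np.all(np.diag(mat.counts) == 0)
        norm_max = mat.normalized.max(axis=1)
        assert np.all(norm_max[mat.counts.sum(axis=1) > 0] == 1.0)


HOST_CASES = [
    # metagenomic: no Eukaryota token
    ("gut metagenome", "metagenomic"),
    ("", "metagenomic"),
    ("cellular organisms; Bacteria; Proteobacteria", "metagenomic"),
    ("marine metagenome; environmental samples", "metagenomic"),
    ("cellular organisms; Archaea", "metagenomic"),
    # fungi
    ("cellular organisms; Eukaryota; Opisthokonta; Fungi; Ascomycota", "fungi"),
    ("cellular organisms; Eukaryota; Fungi", "fungi"),
    ("cellular organisms; Eukaryota; Opisthokonta; Fungi; Basidiomycota; Ustilago", "fungi"),
    # plants
    ("cellular organisms; Eukaryota; Viridiplantae; Streptophyta", "plants"),
    ("cellular organisms; Eukaryota; Viridiplantae; Chlorophyta", "plants"),
    ("cellular organisms; Eukaryota; Viridiplantae", "plants"),
    # arthropods (checked before vertebrates)
    ("cellular organisms; Eukaryota; Metazoa; Arthropoda; Insecta", "arthropods"),
    ("cellular organisms; Eukaryota; Opisthokonta; Metazoa; Arthropoda; Crustacea", "arthropods"),
    ("cellular organisms; Eukaryota; Metazoa; Arthropoda", "arthropods"),
    # vertebrates
    ("cellular organisms; Eukaryota; Metazoa; Chordata; Vertebrata; Mammalia", "vertebrates"),
    ("cellular organisms; Eukaryota; Metazoa; Chordata; Vertebrata; Amphibia", "vertebrates"),
    ("cellular organisms; Eukaryota; Opisthokonta; Metazoa; Chordata; Vertebrata", "vertebrates"),
    # invertebrates: Metazoa without Arthropoda/Vertebrata
    ("cellular organisms; Eukaryota; Metazoa; Mollusca; Gastropoda", "invertebrates"),
    ("cellular organisms; Eukaryota; Metazoa; Annelida", "invertebrates"),
    ("cellular organisms; Eukaryota; Metazoa; Ctenophora", "invertebrates"),
    ("cellular organisms; Eukaryota; Metazoa; Chordata; Tunicata", "invertebrates"),
    # protists: Eukaryota without Metazoa/Fungi/Viridiplantae
    ("cellular organisms; Eukaryota; Sar; Alveolata", "protists"),
    ("cellular organisms; Eukaryota; Discoba; Euglenozoa", "protists"),
    ("cellular organisms; Eukaryota; Amoebozoa", "protists"),
    ("cellular organisms; Eukaryota", "protists"),
    # keyword matching is exact on tokens, not substrings
    ("cellular organisms; Eukaryota; Fungivora", "protists"),
    ("cellular organisms; Eukaryota; Pseudofungi; Oomycota", "protists"),
    ("Eukaryota; Metazoa; Arthropodalike", "invertebrates"),
    ("Eukaryotal organisms; metagenome", "metagenomic"),
    ("cellular organisms; Eukaryota; Haptista; Haptophyta", "protists"),
    ("cellular organisms; Eukaryota; Metazoa; Echinodermata", "invertebrates"),
]


class TestAssignHost:
    @pytest.mark.parametrize("lineage,expected", HOST_CASES)
    def test_keyword_rules(self, lineage, expected):
        assert ann.assign_host("c", lineage).category == expected

    def test_priority_plants_before_metazoa(self):
        # contrived dual-kingdom line: Viridiplantae outranks Metazoa
        a = ann.assign_host("c", "cellular organisms; Eukaryota; Viridiplantae; Metazoa")
        assert a.category == "plants"

    def test_total_and_deterministic_partition(self, rng):
        tokens = ["Eukaryota", "Fungi", "Metazoa", "Arthropoda", "Vertebrata",
                  "Viridiplantae", "Sar", "Bacteria", "metagenome"]
        for _ in range(200):
            k = int(rng.integers(0, 5))
            lineage = "; ".join(rng.choice(tokens, size=k, replace=False)) if k else ""
            cat = ann.assign_host("c", lineage).category
            assert cat in ann.HOST_CATEGORIES
            assert ann.assign_host("c", lineage).category == cat


class TestHostSummary:
    def test_counts_and_mean(self):
        rows = [
            {"family": "F", "core_seq": f"SEQ{i}", "category": "plants",
             "dataset_id": f"DS{i % 2}", "species": "Saccharum hybrid"}
            for i in range(4)
        ]
        per_cat, per_fam = ann.host_summary(rows)
        assert per_cat.loc["plants", "rdrp_count"] == 4
        assert per_cat.loc["plants", "dataset_count"] == 2
        assert per_cat.loc["plants", "species_count"] == 1
        assert per_cat.loc["plants", "mean_rdrps_per_species"] == pytest.approx(4.0)
        assert per_fam.loc[("F", "plants"), "rdrp_count"] == 4

    def test_identical_cores_in_one_family_counted_once(self):
        rows = [
            {"family": "F", "core_seq": "SAME", "category": "fungi",
             "dataset_id": "DS1", "species": "sp1"},
            {"family": "F", "core_seq": "SAME", "category": "fungi",
             "dataset_id": "DS2", "species": "sp1"},
            {"family": "G", "core_seq": "SAME", "category": "fungi",
             "dataset_id": "DS1", "species": "sp1"},
        ]
        per_cat, _ = ann.host_summary(rows)
        assert per_cat.loc["fungi", "rdrp_count"] == 2  # per-family dedup only

    def test_missing_assignment_goes_to_unknown_bucket(self):
        rows = [{"family": "F", "core_seq": "S1", "category": None,
                 "dataset_id": None, "species": None}]
        per_cat, _ = ann.host_summary(rows)
        assert per_cat.loc["unknown", "rdrp_count"] == 1

    def test_empty_input_gives_empty_tables(self):
        per_cat, per_fam = ann.host_summary([])
        assert per_cat.empty and per_fam.empty
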