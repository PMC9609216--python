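import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nkaminer import (
    ProteinRecord,
    SiteDef,
    global_align,
    group_similarity,
    map_site,
    motif_prevalence,
    percent_identity,
    scan_assembly_motif,
    site_state_table,
)
from nkaminer.motif import blosum_score

from oracles import biopython_global_score

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestMotifScan:
    def test_exact_sygq(self):
        (hit,) = scan_assembly_motif("ASYGQL")
        assert (hit.position, hit.template, hit.mismatches) == (2, "SYGQ", 0)

    def test_glu_variant_is_consensus(self):
        (hit,) = scan_assembly_motif("ASYGEL")
        assert hit.mismatches == 0 and hit.template == "SYGE"

    def test_similar_single_mismatch_hits(self):
        (hit,) = scan_assembly_motif("ASFGQL")
        assert hit.mismatches == 1
        pos, tmpl_res, obs, score = hit.mismatch_detail
        assert (pos, tmpl_res, obs) == (2, "Y", "F")
        assert score == blosum_score("F", "Y") and score > 0

    def test_dissimilar_single_mismatch_misses(self):
        # P at template position 2 scores -3 against Y: not similar
        assert scan_assembly_motif("ASPGQL") == []

    def test_double_mismatch_misses(self):
        assert scan_assembly_motif("ASAGAL") == []

    def test_no_reverse_semantics(self):
        seq = "MMSYGQMM"
        hits = scan_assembly_motif(seq)
        assert [h.position for h in hits] == [3]
        assert scan_assembly_motif(seq[::-1]) == []

    def test_overlapping_windows_all_reported(self):
        # SYGE directly followed by SYGQ: two separate window hits
        hits = scan_assembly_motif("SYGESYGQ")
        assert [h.position for h in hits] == [1, 5]


class TestPrevalence:
    def make(self, group, n, carriers):
        base = "MKTAYIAKQRLPDEHH" * 4
        out = []
        for i in range(n):
            seq = base[: 40 + i] + ("SYGQ" if i < carriers else "LLLL") + base[:10]
            out.append(ProteinRecord(id=f"{group}{i}", sequence=seq, group=group))
        return out

    def test_two_of_nine_is_22_22(self):
        recs = self.make("fungi", 9, 2)
        assert motif_prevalence(recs)["fungi"] == 22.22

    def test_boundaries(self):
        recs = self.make("fungi", 5, 0) + self.make("vertebrate", 4, 4)
        out = motif_prevalence(recs)
        assert out["fungi"] == 0.0 and out["vertebrate"] == 100.0

    def test_half_up_rounding(self):
        # 1/16 = 6.25 exactly; 5/16 = 31.25 -> both round half-up at 2 dp
        recs = self.make("fungi", 16, 1)
        assert motif_prevalence(recs)["fungi"] == 6.25

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            motif_prevalence([ProteinRecord(id="x", sequence="SYGQ")])


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("MKTAYIAKQR", "MKTAYIAKQR")
        assert aln.query_aligned == aln.reference_aligned == "MKTAYIAKQR"
        assert list(aln.column_map) == list(range(1, 11))

    def test_deletion_maps_reference_columns_to_gap(self):
        ref = "MKTAYIAKQRW"
        query = ref[:4] + ref[7:]  # delete residues 5-7
        aln = global_align(query, ref)
        assert (aln.column_map == 0).sum() == 3
        assert "".join(aln.reference_aligned).replace("-", "") == ref
        assert "".join(aln.query_aligned).replace("-", "") == query

    def test_score_symmetry(self):
        a, b = "MKTAYIAKQR", "MKTAYWAKR"
        assert global_align(a, b).score == global_align(b, a).score

    def test_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            a = "".join(rng.choice(list(AA20), size=rng.integers(3, 13)))
            b = "".join(rng.choice(list(AA20), size=rng.integers(3, 13)))
            assert global_align(a, b).score == pytest.approx(
                biopython_global_score(a, b)
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MKT")


class TestMapSite:
    REF = "MKTAYIAKQRGCWDEFGHIKLMNPQRSTVWYAD"  # GC at positions 11-12

    def test_identity_site(self):
        aln = global_align(self.REF, self.REF)
        assert map_site(aln, 11) == "GC"

    def test_upstream_insertion_absorbed(self):
        query = self.REF[:5] + "WWWWW" + self.REF[5:]
        aln = global_align(query, self.REF)
        assert map_site(aln, 11) == "GC"

    def test_deletion_at_site_reports_gap(self):
        query = self.REF[:10] + self.REF[12:]  # remove the GC
        aln = global_align(query, self.REF)
        assert map_site(aln, 11) == "gap"

    def test_out_of_range_rejected(self):
        aln = global_align(self.REF, self.REF)
        with pytest.raises(ValueError):
            map_site(aln, len(self.REF))

    @given(offset=st.integers(min_value=0, max_value=6), width=st.just(2))
    @settings(max_examples=20, deadline=None)
    def test_insertions_away_from_site_never_move_state(self, offset, width):
        aln = global_align(self.REF[:offset] + "AAAA" + self.REF[offset:], self.REF)
        assert map_site(aln, 15, width) == self.REF[14:16]


class TestSiteTable:
    def test_constructed_groups(self):
        ref = ProteinRecord(id="ref", sequence="MKTAYIAKQRGCWDEFGHIKLMNPQRSTVWYAD")
        vert = ProteinRecord(id="v1", sequence=ref.sequence, group="vertebrate",
                             isoform="a1")
        # replace the GC at 11-12 by GA
        other = ProteinRecord(
            id="f1", sequence=ref.sequence[:11] + "A" + ref.sequence[12:], group="fungi"
        )
        rep = site_state_table([vert, other], ref, [SiteDef(11, ("GC",))])
        assert rep.per_sequence.loc["v1", "site_11"] == "GC"
        assert rep.per_sequence.loc["f1", "site_11"] == "GA"
        assert rep.group_percent[11].loc["vertebrate", "GC"] == 100.0
        assert rep.group_percent[11].loc["fungi", "GA"] == 100.0

    def test_empty_site_list(self):
        ref = ProteinRecord(id="ref", sequence="MKTAYIAKQR")
        rep = site_state_table([ref], ref, [])
        assert rep.group_percent == {} and rep.isoform_percent == {}


class TestSimilarity:
    def test_identical_pair(self):
        assert percent_identity("AAAA", "AAAA") == 100.0

    def test_three_quarters(self):
        assert percent_identity("AAAA", "AAAT") == 75.0

    def test_symmetric(self):
        a, b = "MKTAYIAKQR", "MKTAWIAKR"
        assert percent_identity(a, b) == percent_identity(b, a)

    def test_group_mean_equals_bruteforce_average(self):
        seqs = ["MKTAYIAKQR", "MKTAYIAKQW", "MKTAFIAKQR"]
        recs = [ProteinRecord(id=f"g{i}", sequence=s, group="fungi")
                for i, s in enumerate(seqs)]
        expect = np.mean([
            percent_identity(seqs[0], seqs[1]),
            percent_identity(seqs[0], seqs[2]),
            percent_identity(seqs[1], seqs[2]),
        ])
        sim = group_similarity(recs)
        assert sim.loc["fungi", "fungi"] == pytest.approx(expect)

    def test_singleton_group_within_missing(self):
        recs = [
            ProteinRecord(id="a", sequence="MKTAYIAKQR", group="fungi"),
            ProteinRecord(id="b", sequence="MKTAYIAKQR", group="Protista"),
            ProteinRecord(id="c", sequence="MKTAFIAKQR", group="Protista"),
        ]
        sim = group_similarity(recs)
        assert np.isnan(sim.loc["fungi", "fungi"])
        assert sim.loc["fungi", "Protista"] > 0
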