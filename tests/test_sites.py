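"""Reference-numbered site mapping and the three classifiers."""

import pytest

from opsinsites.errors import SchemeError
from opsinsites.sites import (
    BISTABLE,
    INDETERMINATE,
    MONOSTABLE,
    PAIR_BROKEN,
    PAIR_INTACT,
    ReferenceScheme,
    classify_counterion,
    load_scheme,
    map_sites,
    parse_scheme,
    profile_sequence,
    score_rlbp1,
)
from opsinsites.align import nw_align


def mutate(seq: str, pos: int, res: str) -> str:
    """Replace the residue at 1-based *pos*."""
    return seq[: pos - 1] + res + seq[pos:]


class TestMapSites:
    def test_identity_maps_every_site_in_place(self, opsin_scheme):
        p = profile_sequence("self", opsin_scheme.reference_seq, opsin_scheme)
        assert len(p.site_calls) == len(opsin_scheme.sites)
        for call in p.site_calls:
            assert call.status == "match"
            assert call.query_position == opsin_scheme.site(call.site_label).ref_position

    def test_deletion_spanning_counterion_yields_unaligned(self, opsin_scheme):
        ref = opsin_scheme.reference_seq
        query = ref[:109] + ref[116:]  # residues 110-116 removed
        p = profile_sequence("del", query, opsin_scheme)
        call = next(c for c in p.site_calls if c.site_label == "E113")
        assert call.status == "unaligned"
        assert call.query_position is None

    def test_nterminal_insertion_shifts_query_positions(self, opsin_scheme):
        query = "GGGGG" + opsin_scheme.reference_seq
        p = profile_sequence("ins", query, opsin_scheme)
        for call in p.site_calls:
            assert call.status == "match"
            assert call.query_position == opsin_scheme.site(call.site_label).ref_position + 5

    def test_reference_mismatch_names_scheme(self, opsin_scheme):
        aln = nw_align("ACDEF", "ACDEY", query_id="q", ref_id="bovine_rhodopsin")
        with pytest.raises(SchemeError, match="bovine_rhodopsin"):
            map_sites(aln, opsin_scheme)


class TestCounterion:
    def test_reference_is_charged_monostable(self, opsin_scheme):
        p = profile_sequence("self", opsin_scheme.reference_seq, opsin_scheme)
        assert (p.counterion_state, p.stability_prediction) == ("charged", MONOSTABLE)

    def test_aspartate_also_counts_as_charged(self, opsin_scheme):
        q = mutate(opsin_scheme.reference_seq, 113, "D")
        p = profile_sequence("e113d", q, opsin_scheme)
        assert (p.counterion_state, p.stability_prediction) == ("charged", MONOSTABLE)

    def test_uncharged_residue_predicts_bistable(self, opsin_scheme):
        # the retinochrome-like signature: uncharged residue mapped to 113
        q = mutate(opsin_scheme.reference_seq, 113, "F")
        p = profile_sequence("retinochrome_like", q, opsin_scheme)
        assert (p.counterion_state, p.stability_prediction) == ("uncharged", BISTABLE)

    def test_gap_at_counterion_is_indeterminate(self, opsin_scheme):
        ref = opsin_scheme.reference_seq
        q = ref[:109] + ref[116:]
        p = profile_sequence("gapped", q, opsin_scheme)
        assert (p.counterion_state, p.stability_prediction) == (
            INDETERMINATE,
            INDETERMINATE,
        )

    def test_scheme_without_counterion_site_rejected(self, rlbp1_scheme):
        calls = map_sites(
            nw_align(
                rlbp1_scheme.reference_seq,
                rlbp1_scheme.reference_seq,
                ref_id=rlbp1_scheme.scheme_id,
            ),
            rlbp1_scheme,
        )
        with pytest.raises(SchemeError, match="counterion"):
            classify_counterion(calls, rlbp1_scheme)


class TestGProtein:
    def test_reference_has_all_five_features_intact(self, opsin_scheme):
        p = profile_sequence("self", opsin_scheme.reference_seq, opsin_scheme)
        assert all(s == PAIR_INTACT for s in p.pair_status.values())
        assert p.motif_status == PAIR_INTACT
        assert p.signaling_intact_count == 5
        assert p.deviations == []

    def test_p303s_breaks_motif_only(self, opsin_scheme):
        q = mutate(opsin_scheme.reference_seq, 303, "S")
        p = profile_sequence("p303s", q, opsin_scheme)
        assert p.motif_status == PAIR_BROKEN
        assert all(s == PAIR_INTACT for s in p.pair_status.values())
        assert p.signaling_intact_count == 4
        assert p.deviations == ["P303:S"]

    def test_missing_e247_breaks_pair_with_absent_deviation(self, opsin_scheme):
        ref = opsin_scheme.reference_seq
        q = ref[:243] + ref[250:]  # residues 244-250 deleted, E247 lost
        p = profile_sequence("rgr_like", q, opsin_scheme)
        assert p.pair_status["K231/E247"] == PAIR_BROKEN
        assert "E247:absent" in p.deviations


class TestRLBP1Score:
    def test_reference_scores_ten(self, rlbp1_scheme):
        p = profile_sequence("self", rlbp1_scheme.reference_seq, rlbp1_scheme)
        assert p.rlbp1_score == 10

    def test_each_single_mutation_costs_exactly_one(self, rlbp1_scheme):
        ref = rlbp1_scheme.reference_seq
        for site in rlbp1_scheme.sites:
            q = mutate(ref, site.ref_position, "A")
            p = profile_sequence("mut", q, rlbp1_scheme)
            assert p.rlbp1_score == 9
            back = profile_sequence("rev", ref, rlbp1_scheme)
            assert back.rlbp1_score == 10

    def test_cumulative_mutations_reach_every_score(self, rlbp1_scheme):
        ref = rlbp1_scheme.reference_seq
        q = ref
        for k, site in enumerate(rlbp1_scheme.sites, start=1):
            q = mutate(q, site.ref_position, "A")
            assert profile_sequence("m", q, rlbp1_scheme).rlbp1_score == 10 - k

    def test_wrong_number_of_critical_sites_rejected(self, rlbp1_scheme):
        partial = ReferenceScheme(
            scheme_id="partial",
            reference_seq=rlbp1_scheme.reference_seq,
            sites=tuple(rlbp1_scheme.sites[:3]),
        )
        calls = map_sites(
            nw_align(
                partial.reference_seq, partial.reference_seq, ref_id="partial"
            ),
            partial,
        )
        with pytest.raises(SchemeError, match="exactly 10"):
            score_rlbp1(calls, partial)


class TestSchemeConfig:
    def test_packaged_schemes_load_and_validate(self, opsin_scheme, rlbp1_scheme):
        assert opsin_scheme.scheme_id == "bovine_rhodopsin"
        assert len(opsin_scheme.reference_seq) == 348
        assert len(opsin_scheme.pairs) == 4
        assert rlbp1_scheme.scheme_id == "human_RLBP1"
        assert len(rlbp1_scheme.sites_by_role("rlbp1_critical")) == 10

    def test_unknown_scheme_name_rejected(self):
        with pytest.raises(SchemeError, match="unknown scheme"):
            load_scheme("no_such_scheme")

    def test_reference_must_carry_expected_residue(self):
        text = "scheme_id = s\nreference = AAAA\nsite = X1=2:C:counterion\n"
        with pytest.raises(SchemeError, match="expected"):
            parse_scheme(text)

    def test_pair_members_must_exist(self):
        text = (
            "scheme_id = s\nreference = AAAA\n"
            "site = A1=1:A:gprotein\npair = P=A1,Z9\n"
        )
        with pytest.raises(SchemeError, match="unknown member"):
            parse_scheme(text)

    def test_profiles_are_deterministic(self, opsin_scheme):
        q = mutate(opsin_scheme.reference_seq, 113, "F")
        p1 = profile_sequence("q", q, opsin_scheme)
        p2 = profile_sequence("q", q, opsin_scheme)
        assert p1 == p2
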