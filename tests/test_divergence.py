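"""Codon-pair divergence statistics: examples, invariants, oracle checks."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_pair
from olfdiverge.divergence import (
    SENSE_CODONS,
    DayhoffPartition,
    RegionAnnotation,
    analyze_pair,
    estimate_dn_ds,
    estimate_dr_dc,
    prepare_pair,
    protein_distance,
    region_and_charge_profile,
)

codon = st.sampled_from(SENSE_CODONS)
codon_pair_lists = st.integers(1, 6).flatmap(
    lambda n: st.tuples(
        st.lists(codon, min_size=n, max_size=n),
        st.lists(codon, min_size=n, max_size=n),
    )
)


class TestPreparePair:
    def test_identity_single_codon(self):
        pair = prepare_pair("ATG", "ATG")
        assert pair.n_codons == 1
        assert pair.codons_a == ("ATG",)

    def test_gap_column_dropped_pairwise(self):
        pair = prepare_pair("ATG---AAA", "ATGCCCAAA")
        assert pair.n_codons == 2
        assert pair.dropped_gap_columns == 1
        # ungapped codon indices track each sequence separately
        assert pair.positions_a == (0, 1)
        assert pair.positions_b == (0, 2)

    def test_terminal_stop_dropped(self):
        pair = prepare_pair("ATGTAA", "ATGTAA")
        assert pair.n_codons == 1
        assert pair.dropped_stop_columns == 1

    @pytest.mark.parametrize(
        "a, b",
        [
            ("ATGC", "ATGC"),       # not a multiple of 3
            ("ATG", "ATGAAA"),      # length mismatch
            ("ATN", "ATG"),         # invalid character
            ("A-G", "ATG"),         # gap straddling a codon
        ],
    )
    def test_invalid_inputs_rejected(self, a, b):
        with pytest.raises(ValueError):
            prepare_pair(a, b)


class TestProteinDistance:
    def test_identity_is_zero(self):
        pair = prepare_pair("ATGGCC", "ATGGCC")
        assert protein_distance(pair) == (0.0, 0.0)

    def test_poisson_correction_half_different(self):
        # 2 of 4 residues differ: p = 0.5, d = -ln(0.5)
        pair = make_pair(["ATG", "GCA", "AAA", "TTT"], ["ATG", "GCA", "CGA", "GGG"])
        p, d = protein_distance(pair, "poisson")
        assert p == 0.5
        assert d == pytest.approx(-math.log(0.5), abs=1e-12)

    def test_saturation_flagged(self):
        pair = make_pair(["ATG"], ["TGG"])
        p, d = protein_distance(pair)
        assert p == 1.0 and d is None

    def test_no_correction_returns_p(self):
        pair = make_pair(["ATG"], ["TGG"])
        assert protein_distance(pair, "none") == (1.0, 1.0)

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            protein_distance(make_pair([], []))


class TestDnDs:
    def test_identical_pair(self):
        dn, ds, omega, N, S = estimate_dn_ds(make_pair(["ATG", "GGA"], ["ATG", "GGA"]))
        assert dn == 0.0 and ds == 0.0 and omega is None
        assert N + S == pytest.approx(6.0, abs=1e-9)

    def test_single_synonymous_difference(self):
        # GGG vs GGA is Gly/Gly: all divergence synonymous, omega -> 0.
        # pS saturates on one codon, so dS itself is flagged undefined.
        dn, ds, omega, N, S = estimate_dn_ds(make_pair(["GGG"], ["GGA"]))
        assert dn == 0.0
        assert ds is None
        assert omega == 0.0

    def test_matches_oracle_on_random_pairs(self):
        rnd = random.Random(1234)
        for _ in range(60):
            n = rnd.randint(1, 10)
            ca = [rnd.choice(SENSE_CODONS) for _ in range(n)]
            cb = [rnd.choice(SENSE_CODONS) for _ in range(n)]
            expected = oracles.ng86(ca, cb)
            dn, ds, omega, N, S = estimate_dn_ds(make_pair(ca, cb))
            for got, want in [
                (dn, expected["dN"]), (ds, expected["dS"]), (omega, expected["omega"]),
                (N, expected["N_sites"]), (S, expected["S_sites"]),
            ]:
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-12)


class TestDrDc:
    def test_dayhoff_classification(self, dayhoff):
        assert not dayhoff.is_radical("A", "G")  # both AGPST
        assert dayhoff.is_radical("A", "D")      # AGPST vs DENQ

    def test_identical_pair(self):
        dr, dc, ratio, *_ = estimate_dr_dc(make_pair(["GCA"], ["GCA"]))
        assert dr == 0.0 and dc == 0.0 and ratio is None

    def test_single_radical_step(self):
        # GCA (Ala) -> GAA (Glu): one step across Dayhoff classes
        _, _, _, N_R, N_C, O_R, O_C = estimate_dr_dc(make_pair(["GCA"], ["GAA"]))
        assert O_R == pytest.approx(1.0, abs=1e-12)
        assert O_C == pytest.approx(0.0, abs=1e-12)

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            DayhoffPartition(("AGPST", "DENQA", "HKR", "ILMV", "FWY", "C"))  # overlap
        with pytest.raises(ValueError):
            DayhoffPartition(("AGPST", "DENQ"))  # residues uncovered


class TestRegionProfile:
    def test_no_tm_labels_gives_zero_tm_tally(self, dayhoff):
        pair = make_pair(["GAA", "AAA"], ["GAT", "AAA"])
        regions = RegionAnnotation("a", ("inside", "outside"))
        tallies, *_ = region_and_charge_profile(pair, regions, dayhoff)
        assert tallies["TM"] == {"radical": 0, "conservative": 0}

    def test_tm_conservative_and_charged_substitution(self, dayhoff):
        # 10 residues, TM at positions 4-9 (0-based 3..8), E->D at position 5 (index 4)
        codons_a = ["ATG"] * 4 + ["GAA"] + ["ATG"] * 5
        codons_b = ["ATG"] * 4 + ["GAT"] + ["ATG"] * 5
        labels = ("inside",) * 3 + ("TM",) * 6 + ("outside",)
        tallies, charged, charged_tm = region_and_charge_profile(
            make_pair(codons_a, codons_b), RegionAnnotation("a", labels), dayhoff
        )
        assert tallies["TM"] == {"radical": 0, "conservative": 1}  # E,D both DENQ
        assert charged == 1 and charged_tm == 1

    def test_asn_substitution_counts_as_charged(self, dayhoff):
        # N -> K touches the default {E, N, Y} set
        pair = make_pair(["AAT"], ["AAA"])
        _, charged, _ = region_and_charge_profile(
            pair, RegionAnnotation("a", ("outside",)), dayhoff
        )
        assert charged == 1

    def test_annotation_length_mismatch(self, dayhoff):
        pair = make_pair(["GAA", "AAA"], ["GAT", "AAA"])
        with pytest.raises(ValueError):
            region_and_charge_profile(pair, RegionAnnotation("a", ("TM",)), dayhoff)


class TestInvariants:
    @given(codon_pair_lists)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_symmetry_and_conservation(self, pair_lists):
        ca, cb = pair_lists
        pair = make_pair(ca, cb)
        swapped = pair.swapped()
        dn, ds, _, N, S = estimate_dn_ds(pair)
        dn2, ds2, _, N2, S2 = estimate_dn_ds(swapped)
        assert (dn, ds) == (dn2, ds2)
        assert N == pytest.approx(N2, abs=1e-9) and S == pytest.approx(S2, abs=1e-9)
        dr, dc, _, N_R, N_C, O_R, O_C = estimate_dr_dc(pair)
        dr2, dc2, *_ = estimate_dr_dc(swapped)
        assert (dr, dc) == (dr2, dc2)
        # conservation: radical + conservative partitions the nonsynonymous total
        assert N_R + N_C == pytest.approx(N, abs=1e-9)
        est = analyze_pair(pair)
        assert O_R + O_C == pytest.approx(est.N_diff, abs=1e-9)

    @given(st.lists(codon, min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_self_pair_all_zero(self, codons):
        est = analyze_pair(make_pair(codons, codons))
        assert est.p_dist == 0.0 and est.d_prot == 0.0
        assert est.dN == 0.0 and est.dS == 0.0
        assert est.O_R == 0.0 and est.O_C == 0.0 and est.S_diff == 0.0

    def test_analyze_pair_row_is_serializable(self):
        est = analyze_pair(make_pair(["GCA", "AAA"], ["GAA", "AAA"]))
        row = est.to_row()
        assert row["O_R"] == pytest.approx(1.0)
        assert "TM_radical" in row
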