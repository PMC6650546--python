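import math

import numpy as np
import pytest

from codonaudit.genetic_code import (
    SENSE_CODONS,
    dna_to_rna,
    reverse_complement_rna,
)
from codonaudit.io import CodingSequence, TRNAPool
from codonaudit.trna_adaptation import (
    PairingRule,
    absolute_adaptiveness,
    access_curve,
    access_equality_test,
    build_network,
    tai,
)

RULE = PairingRule.default()


def _wc_anticodon(codon: str) -> str:
    return reverse_complement_rna(dna_to_rna(codon))


def _full_pool(copies: int = 1) -> TRNAPool:
    return TRNAPool({_wc_anticodon(c): copies for c in SENSE_CODONS})


class TestPairingRule:
    def test_watson_crick_anticodon_pairs_its_codon(self):
        assert RULE.pairable("AAA", "UUU")
        assert RULE.class_of("AAA", "UUU") == "watson_crick"

    def test_wobble_gu(self):
        # codon ending U read by anticodon starting G
        assert RULE.pairable("TTT", "GAA")
        assert RULE.class_of("TTT", "GAA") == "wobble"
        assert RULE.s_of("TTT", "GAA") == pytest.approx(0.41)

    def test_interior_mismatch_forbidden(self):
        assert not RULE.pairable("AAA", "UUC")  # middle base mismatch

    def test_watson_crick_has_smallest_s(self):
        wc = [s for k, s in RULE.constraints.items() if RULE.classes[k] == "watson_crick"]
        wobble = [s for k, s in RULE.constraints.items() if RULE.classes[k] == "wobble"]
        assert max(wc) < min(wobble)

    def test_inosine_toggle_removes_a_starting_wobble(self):
        no_inosine = PairingRule.default(inosine=False)
        assert RULE.pairable("TTC", "AAA")  # I:C wobble
        assert not no_inosine.pairable("TTC", "AAA")


class TestAbsoluteAdaptiveness:
    def test_equal_exact_pools_give_equal_w(self):
        W, unreadable = absolute_adaptiveness(_full_pool(2), RULE)
        assert unreadable == []
        # every codon readable by its own anticodon (s=0) plus possibly
        # wobble contributions; Watson-Crick part alone is equal
        assert min(W.values()) > 0

    def test_doubling_pool_doubles_w_keeps_tai(self):
        pool1 = _full_pool(1)
        pool2 = _full_pool(2)
        W1, _ = absolute_adaptiveness(pool1, RULE)
        W2, _ = absolute_adaptiveness(pool2, RULE)
        for c in SENSE_CODONS:
            assert W2[c] == pytest.approx(2 * W1[c])
        cds = CodingSequence("g", "ATGAAAGGCCTG")
        assert tai(cds, W1).tai == pytest.approx(tai(cds, W2).tai)

    def test_exact_plus_wobble_sum(self):
        # codon TTT (Phe, ends U): exact anticodon AAA (s=0) tGCN=2,
        # wobble anticodon GAA (s=0.41) tGCN=1 -> W = 2 + 0.59
        pool = TRNAPool({"AAA": 2, "GAA": 1})
        W, _ = absolute_adaptiveness(pool, RULE)
        assert W["TTT"] == pytest.approx(2 * 1.0 + 1 * 0.59)

    def test_unreadable_codons_reported(self):
        pool = TRNAPool({"UUU": 1})  # reads Lys codons only
        W, unreadable = absolute_adaptiveness(pool, RULE)
        assert W["GGG"] == 0.0
        assert "GGG" in unreadable


class TestTAI:
    def test_max_w_codons_give_one(self):
        W = {c: 1.0 for c in SENSE_CODONS}
        cds = CodingSequence("g", "AAAGGG")
        assert tai(cds, W).tai == pytest.approx(1.0)

    def test_geometric_mean_of_two(self):
        W = {c: 1.0 for c in SENSE_CODONS}
        W["GGG"] = 0.5
        cds = CodingSequence("g", "AAAGGG")
        assert tai(cds, W).tai == pytest.approx(math.sqrt(0.5))

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        W = {c: float(rng.uniform(0.1, 1.0)) for c in SENSE_CODONS}
        a = tai(CodingSequence("g", "AAAGGCCTG"), W)
        b = tai(CodingSequence("g", "CTGAAAGGC"), W)
        assert a.tai == pytest.approx(b.tai)

    def test_never_exceeds_one_and_zero_w_skipped(self):
        W = {c: 0.0 for c in SENSE_CODONS}
        W["AAA"] = 2.0
        W["GGG"] = 1.0
        record = tai(CodingSequence("g", "AAAGGGTTT"), W)
        assert record.tai <= 1.0
        assert record.skipped_codons == 1  # TTT has W = 0
        with pytest.raises(ValueError):
            tai(CodingSequence("g", "TTTTTC"), W)


class TestNetwork:
    def test_two_edges_distinct_classes_for_twofold_family(self):
        # anticodon GAA reads TTC (exact) and TTT (wobble G:U)
        pool = TRNAPool({"GAA": 1})
        profile = {c: 1.0 for c in SENSE_CODONS}
        edges = build_network({"genome": profile}, pool, RULE)
        assert set(edges["codon"]) == {"UUU", "UUC"}
        assert set(edges["pairing_class"]) == {"watson_crick", "wobble"}

    def test_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(4)
        anticodons = [
            "".join(rng.choice(list("ACGU"), 3)) for _ in range(10)
        ]
        pool = TRNAPool({ac: 1 for ac in anticodons})
        profile = {c: 1.0 for c in SENSE_CODONS}
        edges = build_network({"genome": profile}, pool, RULE)
        expected = sum(
            RULE.pairable(c, ac)
            for c in SENSE_CODONS
            for ac in set(pool.copies)
        )
        assert len(edges) == expected

    def test_missing_profiles_rejected(self):
        with pytest.raises(ValueError):
            build_network({}, _full_pool(), RULE)


class TestAccessCurve:
    def test_zero_cutoff_counts_every_pairable_anticodon(self):
        pool = _full_pool(2)
        profile = {c: 1.0 for c in SENSE_CODONS}
        curve = access_curve(profile, pool, RULE)
        assert curve["accessible_copies"].iloc[0] == pool.total

    def test_cutoff_above_max_rscu_gives_zero(self):
        pool = _full_pool(1)
        profile = {c: 0.8 for c in SENSE_CODONS}
        curve = access_curve(profile, pool, RULE)
        assert curve["accessible_copies"].iloc[-1] == 0

    def test_monotone_and_matches_brute_force(self):
        rng = np.random.default_rng(9)
        anticodons = ["".join(rng.choice(list("ACGU"), 3)) for _ in range(10)]
        pool = TRNAPool({ac: int(rng.integers(1, 5)) for ac in anticodons})
        profile = {c: float(rng.uniform(0, 2)) for c in SENSE_CODONS}
        curve = access_curve(profile, pool, RULE)
        copies = curve["accessible_copies"].to_numpy()
        assert np.all(np.diff(copies) <= 0)
        for _, row in curve.iloc[::25].iterrows():
            t = row["cutoff"]
            expected = sum(
                n
                for ac, n in pool.copies.items()
                if any(
                    RULE.pairable(c, ac) and profile[c] >= t
                    for c in SENSE_CODONS
                )
            )
            assert row["accessible_copies"] == expected

    def test_matched_supply_curves_coincide_at_zero_cutoff(self):
        """When supply matches demand, no set has privileged access."""
        pool = _full_pool(1)
        profile_a = {c: 1.2 for c in SENSE_CODONS}
        profile_b = {c: 0.7 for c in SENSE_CODONS}
        a0 = access_curve(profile_a, pool, RULE)["accessible_copies"].iloc[0]
        b0 = access_curve(profile_b, pool, RULE)["accessible_copies"].iloc[0]
        assert a0 == b0 == pool.total

    def test_missing_preferred_anticodons_lower_the_curve(self):
        """A set whose favored codons lack tRNAs accesses fewer copies."""
        # pool supplies anticodons for codons ending G/C only
        pool = TRNAPool(
            {_wc_anticodon(c): 1 for c in SENSE_CODONS if c[2] in "GC"}
        )
        pref_missing = {
            c: (1.8 if c[2] in "AT" else 0.2) for c in SENSE_CODONS
        }
        pref_present = {
            c: (1.8 if c[2] in "GC" else 0.2) for c in SENSE_CODONS
        }
        low = access_curve(pref_missing, pool, RULE)
        high = access_curve(pref_present, pool, RULE)
        at = 150  # cutoff 1.5, above the non-preferred RSCU
        assert (
            low["accessible_copies"].iloc[at]
            < high["accessible_copies"].iloc[at]
        )


class TestAccessEquality:
    def test_identical_proportions(self):
        res = access_equality_test(40, 40, 100)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_difference(self):
        res = access_equality_test(1000, 0, 1000)
        assert res.p_value < 1e-10

    def test_matches_plain_proportions_test(self):
        from codonaudit.stats import chi_square_proportions

        res = access_equality_test(50, 40, 100)
        direct = chi_square_proportions(50, 100, 40, 100)
        assert res.statistic == pytest.approx(direct.statistic)
        assert res.p_value == pytest.approx(direct.p_value)
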