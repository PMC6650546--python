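import math
from collections import Counter

import numpy as np
import pytest

from codonaudit.codon_metrics import (
    accuracy_regression_inputs,
    cai,
    codon_counts,
    enc,
    median_rscu_profile,
    percentile_ranks,
    relative_adaptiveness,
    rscu,
)
from codonaudit.genetic_code import (
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
)
from codonaudit.io import CodingSequence
from codonaudit.simulate import make_profile
from codonaudit.stats import linear_fit


def _cds_from_codons(codons, gene_id="g"):
    return CodingSequence(gene_id, "".join(codons))


class TestRSCU:
    def test_lysine_three_to_one(self):
        values = rscu(Counter({"AAA": 3, "AAG": 1}))
        assert values["AAA"] == pytest.approx(1.5)
        assert values["AAG"] == pytest.approx(0.5)

    def test_uniform_usage_is_neutral(self):
        counts = Counter({c: 5 for c in SENSE_CODONS})
        values = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_single_codon_of_fourfold_family(self):
        values = rscu(Counter({"GGG": 7}))
        assert values["GGG"] == pytest.approx(4.0)
        assert values["GGA"] == values["GGC"] == values["GGT"] == 0.0

    def test_absent_family_is_nan_not_zero(self):
        values = rscu(Counter({"AAA": 2}))
        assert math.isnan(values["GGG"])

    def test_family_sums_equal_family_size(self):
        counts = Counter({"CTT": 4, "CTA": 1, "TTG": 2, "AAA": 3})
        values = rscu(counts)
        leu = sum(values[c] for c in SYNONYMOUS_FAMILIES["L"])
        assert leu == pytest.approx(6.0)


class TestRelativeAdaptiveness:
    def test_three_to_one_family(self):
        w = relative_adaptiveness(Counter({"AAA": 3, "AAG": 1}), pseudocount=0)
        assert w["AAA"] == pytest.approx(1.0)
        assert w["AAG"] == pytest.approx(1 / 3)

    def test_equal_counts_all_one(self):
        w = relative_adaptiveness(Counter({c: 4 for c in SENSE_CODONS}), pseudocount=0.5)
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_pseudocount_rescues_zero_count_codon(self):
        w = relative_adaptiveness(Counter({"AAA": 99.5}), pseudocount=0.5)
        assert w["AAG"] == pytest.approx(0.5 / 100.0)
        assert w["AAG"] > 0


class TestCAI:
    def test_optimal_codons_give_one(self):
        w = relative_adaptiveness(Counter({"AAA": 3, "AAG": 1}), pseudocount=0.5)
        assert cai(_cds_from_codons(["AAA", "AAA"]), w) == pytest.approx(1.0)

    def test_geometric_mean(self):
        w = {c: 1.0 for c in SENSE_CODONS}
        w["AAG"] = 0.2
        value = cai(_cds_from_codons(["AAA", "AAG"]), w)
        assert value == pytest.approx(math.sqrt(0.2))

    def test_single_codon_families_excluded(self):
        w = {c: 1.0 for c in SENSE_CODONS}
        w["AAG"] = 0.2
        base = cai(_cds_from_codons(["AAA", "AAG"]), w)
        with_met = cai(_cds_from_codons(["ATG", "AAA", "AAG"]), w)
        assert with_met == pytest.approx(base)

    def test_swapping_to_optimal_codon_increases_cai(self):
        w = relative_adaptiveness(
            Counter({"AAA": 10, "AAG": 2, "GGG": 8, "GGA": 1}), pseudocount=0.5
        )
        worse = cai(_cds_from_codons(["AAG", "GGA"]), w)
        better = cai(_cds_from_codons(["AAA", "GGA"]), w)
        assert better > worse

    def test_codon_order_invariant(self):
        w = relative_adaptiveness(Counter({c: i + 1 for i, c in enumerate(SENSE_CODONS)}))
        a = cai(_cds_from_codons(["AAA", "GGA", "CTT"]), w)
        b = cai(_cds_from_codons(["CTT", "AAA", "GGA"]), w)
        assert a == pytest.approx(b)


class TestENC:
    def test_uniform_61_codons_clips_to_61(self):
        codons = [c for c in SENSE_CODONS for _ in range(100)]
        record = enc(_cds_from_codons(codons))
        assert record.enc == 61.0
        assert record.clipped

    def test_one_codon_per_amino_acid_is_20(self):
        one_each = sorted(
            {aa: fam[0] for aa, fam in SYNONYMOUS_FAMILIES.items()}.values()
        )
        record = enc(_cds_from_codons([c for c in one_each for _ in range(10)]))
        assert record.enc == pytest.approx(20.0)

    def test_wright_homozygosity_three_one(self):
        # Lys counts (3,1): n=4, sum p^2 = 10/16, F = (40/16 - 1)/3 = 0.5
        record = enc(_cds_from_codons(["AAA"] * 3 + ["AAG"]))
        assert record.f_bar[2] == pytest.approx(0.5)

    def test_uniform_long_sequence_lands_near_61(self):
        rng = np.random.default_rng(11)
        codons = list(rng.choice(SENSE_CODONS, size=10_000))
        assert 60.0 <= enc(_cds_from_codons(codons)).enc <= 61.0

    def test_too_short_to_estimate(self):
        with pytest.raises(ValueError):
            enc(_cds_from_codons(["ATG"]))

    def test_order_invariant(self):
        rng = np.random.default_rng(5)
        codons = list(rng.choice(SENSE_CODONS, size=300))
        a = enc(_cds_from_codons(codons)).enc
        rng.shuffle(codons)
        b = enc(_cds_from_codons(codons)).enc
        assert a == pytest.approx(b)

    def test_enc_gc3_scan_is_monotone_and_detectable(self):
        """Profiles varying only in GC3 trace a falling ENC trend."""
        rng = np.random.default_rng(3)
        xs, ys = [], []
        for gc3 in np.linspace(0.5, 0.95, 10):
            profile = make_profile(gc3, bias_strength=1.5)
            codons = []
            for aa, fam in SYNONYMOUS_FAMILIES.items():
                codons_fam, probs = profile.family(aa)
                draws = rng.choice(len(codons_fam), size=60, p=probs)
                codons.extend(codons_fam[i] for i in draws)
            cds = _cds_from_codons(codons)
            from codonaudit.composition import gc3_content

            xs.append(gc3_content(cds))
            ys.append(enc(cds).enc)
        fit = linear_fit(xs, ys)
        assert fit.slope < 0
        assert fit.p_value < 0.01
        # realized ENC falls monotonically with the planted GC3 tilt
        assert ys == sorted(ys, reverse=True)


class TestPercentileRanks:
    def test_max_is_100(self):
        assert percentile_ranks([1, 5, 3])[1] == pytest.approx(100.0)

    def test_counting_definition(self):
        ranks = percentile_ranks([4, 1, 3, 2])
        assert ranks[1] == pytest.approx(25.0)

    def test_ties_share_rank(self):
        assert list(percentile_ranks([2.0, 2.0, 2.0])) == [100.0, 100.0, 100.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_ranks([])


class TestAccuracyRegressionInputs:
    def test_identical_genes_reproduce_single_gene_values(self):
        codons = ["AAA"] * 6 + ["AAG"] * 2 + ["GGG"] * 4
        genes = [_cds_from_codons(codons, f"g{i}") for i in range(3)]
        pairs, dropped = accuracy_regression_inputs(genes)
        max_rscu, usage = pairs["K"]
        assert max_rscu == pytest.approx(1.5)  # RSCU of AAA at (6,2)
        assert usage == pytest.approx(8 / 12)

    def test_single_codon_fourfold_family_limit(self):
        # Gly used at 10% with one codon only: pair (4.0, 0.10)
        codons = ["GGG"] * 2 + ["AAA"] * 9 + ["AAG"] * 9
        genes = [_cds_from_codons(codons, f"g{i}") for i in range(2)]
        pairs, _ = accuracy_regression_inputs(genes)
        assert pairs["G"] == (pytest.approx(4.0), pytest.approx(0.10))

    def test_single_codon_families_never_reported(self):
        codons = ["ATG", "TGG", "AAA", "AAA"]
        genes = [_cds_from_codons(codons, f"g{i}") for i in range(2)]
        pairs, _ = accuracy_regression_inputs(genes)
        assert "M" not in pairs and "W" not in pairs

    def test_absent_amino_acids_dropped_and_reported(self):
        genes = [_cds_from_codons(["AAA", "AAG"], f"g{i}") for i in range(2)]
        pairs, dropped = accuracy_regression_inputs(genes)
        assert set(pairs) == {"K"}
        assert "G" in dropped


class TestMedianRSCUProfile:
    def test_median_across_genes(self):
        g1 = _cds_from_codons(["AAA"] * 3 + ["AAG"])  # RSCU(AAA)=1.5
        g2 = _cds_from_codons(["AAA", "AAG"])  # RSCU(AAA)=1.0
        g3 = _cds_from_codons(["AAA"] * 4)  # RSCU(AAA)=2.0
        profile = median_rscu_profile([g1, g2, g3])
        assert profile["AAA"] == pytest.approx(1.5)

    def test_absent_everywhere_stays_nan(self):
        profile = median_rscu_profile([_cds_from_codons(["AAA", "AAG"])])
        assert math.isnan(profile["GGG"])
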