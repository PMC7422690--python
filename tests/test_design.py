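import itertools
import random
import re

import pytest

import amplitag as at
from amplitag.primers import S615F_CER, S947R_CER

import oracles


def loose_constraints(**kw):
    """Constraints with all screens effectively disabled unless overridden."""
    defaults = dict(
        barcode_length=8, min_pairwise_distance=1, max_homopolymer_run=8,
        base_count_min=0, base_count_max=8, gc_min=0.0, gc_max=1.0,
    )
    defaults.update(kw)
    return at.DesignConstraints(**defaults)


class TestEnumerateCandidates:
    def test_single_base_words(self):
        c = loose_constraints(barcode_length=1, max_homopolymer_run=1,
                              base_count_max=1, min_pairwise_distance=1)
        assert at.enumerate_candidates(c) == ["A", "C", "G", "T"]

    def test_dinucleotides_without_repeats(self):
        c = loose_constraints(barcode_length=2, max_homopolymer_run=1, base_count_max=2)
        words = at.enumerate_candidates(c)
        assert len(words) == 12
        assert all(w[0] != w[1] for w in words)

    def test_default_8mer_count_matches_naive_enumeration(self, constraints):
        got = at.enumerate_candidates(constraints)
        expected = []
        for word in map("".join, itertools.product("ACGT", repeat=8)):
            counts = {b: word.count(b) for b in "ACGT"}
            gc = (counts["G"] + counts["C"]) / 8
            if min(counts.values()) < 1 or max(counts.values()) > 3:
                continue
            if not 0.375 <= gc <= 0.625:
                continue
            if re.search(r"(.)\1\1", word):
                continue
            expected.append(word)
        assert got == expected

    def test_refuses_combinatorial_explosion(self):
        with pytest.raises(ValueError):
            at.enumerate_candidates(loose_constraints(barcode_length=13))


class TestScreenAgainstPrimer:
    def test_revcomp_of_primer_prefix_always_fails(self, constraints):
        primer = str(S615F_CER)
        # concrete realization of the degenerate prefix; still pairs fully
        b = str(at.revcomp(primer[:8].replace("R", "A")))
        ok, audit = at.screen_against_primer(b, primer, constraints)
        assert not ok
        assert audit["heteroduplex_max_run"] >= 8

    def test_matches_brute_force_on_printed_primer(self, constraints):
        primer = str(S615F_CER)
        rng = random.Random(11)
        for _ in range(30):
            b = "".join(rng.choice("ACGT") for _ in range(8))
            ok, _ = at.screen_against_primer(b, primer, constraints)
            expect = (
                not oracles.has_hairpin(b + primer, 4, 3)
                and oracles.duplex_max_run(b, primer) < 6
                and oracles.duplex_three_prime_run(b, primer) < 4
                and oracles.duplex_max_run(b, b) < 6
                and oracles.duplex_three_prime_run(b, b) < 4
            )
            assert ok == expect, b

    def test_at_only_pairs_cannot_reach_default_thresholds(self, constraints):
        # A/T-only barcode vs C/G-free primer: longest A.T run < thresholds
        ok, _ = at.screen_against_primer("ATTATAAT", "TTATTATAATTAA", constraints)
        assert ok == (
            not oracles.has_hairpin("ATTATAAT" + "TTATTATAATTAA", 4, 3)
            and oracles.duplex_max_run("ATTATAAT", "TTATTATAATTAA") < 6
            and oracles.duplex_three_prime_run("ATTATAAT", "TTATTATAATTAA") < 4
            and oracles.duplex_max_run("ATTATAAT", "ATTATAAT") < 6
            and oracles.duplex_three_prime_run("ATTATAAT", "ATTATAAT") < 4
        )

    def test_degenerate_barcode_rejected(self, constraints):
        with pytest.raises(ValueError):
            at.screen_against_primer("ACGTACGN", str(S615F_CER), constraints)


class TestScreenAgainstFlank:
    def test_exact_substring_fails(self, constraints):
        flank = "ACGTAACCGGTTACGT"
        b = flank[3:11]
        c = at.DesignConstraints(flank_match_max=7)
        assert at.screen_against_flank(b, flank, c) is False

    def test_zero_matches_pass(self, constraints):
        assert at.screen_against_flank("AAAAAAAA", "CCCCCCCCCCCC", constraints) is True

    def test_matches_sliding_window_brute_force(self, constraints):
        rng = random.Random(3)
        for _ in range(50):
            b = "".join(rng.choice("ACGT") for _ in range(8))
            flank = "".join(rng.choice("ACGTRY") for _ in range(20))
            got = at.screen_against_flank(b, flank, constraints)
            assert got == (oracles.sliding_flank_matches(b, flank) <= 5)

    def test_short_flank_rejected(self, constraints):
        with pytest.raises(ValueError):
            at.screen_against_flank("AAAAAAAA", "ACGT", constraints)


class TestSelectSet:
    def test_small_pool_exact_choice(self):
        s = at.select_set(["AAAAAAAA", "AAAAAAAT", "CCCCCCCC"], min_distance=3, target_size=5)
        assert set(s.barcodes) == {"AAAAAAAA", "CCCCCCCC"}
        assert s.warning is not None

    def test_distance_one_keeps_everything(self):
        cands = ["AAAAAAAA", "AAAAAAAT", "CCCCCCCC"]
        s = at.select_set(cands, min_distance=1, target_size=10)
        assert sorted(s.barcodes) == sorted(cands)

    def test_equals_exhaustive_maximum_on_small_pools(self):
        rng = random.Random(19)
        for trial in range(15):
            n = rng.randint(4, 12)
            pool = set()
            while len(pool) < n:
                pool.add("".join(rng.choice("ACGT") for _ in range(6)))
            pool = sorted(pool)
            d = rng.randint(2, 4)
            s = at.select_set(pool, min_distance=d, target_size=len(pool),
                              constraints=at.DesignConstraints(barcode_length=6,
                                                               min_pairwise_distance=d))
            assert len(s.barcodes) == oracles.max_compatible_subset_size(pool, d), (
                pool, d,
            )

    def test_monotone_in_min_distance(self):
        rng = random.Random(23)
        pool = list({"".join(rng.choice("ACGT") for _ in range(8)) for _ in range(60)})
        sizes = {}
        for d in (3, 4):
            c = at.DesignConstraints(barcode_length=8, min_pairwise_distance=d)
            sizes[d] = len(at.select_set(pool, d, target_size=100, seed=9, constraints=c).barcodes)
        assert sizes[4] <= sizes[3]

    def test_seeded_selection_reproducible(self):
        rng = random.Random(31)
        pool = list({"".join(rng.choice("ACGT") for _ in range(8)) for _ in range(50)})
        a = at.select_set(pool, 3, 10, seed=7,
                          constraints=at.DesignConstraints(min_pairwise_distance=3))
        b = at.select_set(pool, 3, 10, seed=7,
                          constraints=at.DesignConstraints(min_pairwise_distance=3))
        assert a.barcodes == b.barcodes


class TestDesignPipeline:
    def test_forward_primer_reaches_target_with_flank(self, constraints):
        recs = at.make_reference_alignment(primer=str(S615F_CER), seed=7)
        cons = at.consensus([seq for _, seq in recs])
        flank = at.extract_flank(cons, str(S615F_CER), constraints.flank_window)
        bset = at.design_barcodes(S615F_CER, constraints, target_size=18, seed=1,
                                  flank_consensus=flank)
        assert len(bset) >= 18
        assert bset.min_pairwise_distance() >= 3
        assert at.validate_set(bset, flank).passed

    def test_reverse_primer_reaches_target(self, rv_set):
        assert len(rv_set) >= 18
        assert at.validate_set(rv_set).passed

    def test_any_seed_passes_validation(self, constraints):
        for seed in (0, 17):
            s = at.design_barcodes(S615F_CER, constraints, target_size=12, seed=seed)
            assert at.validate_set(s).passed


class TestValidateSet:
    def test_duplicate_detected(self, constraints):
        s = at.BarcodeSet(["ACGTACTG", "ACGTACTG"], str(S615F_CER), "forward", constraints)
        report = at.validate_set(s)
        assert not report.passed
        assert not report.checks["distinct"]

    def test_close_pair_named_as_offender(self, constraints):
        s = at.BarcodeSet(["ACGTACTG", "ACGTACTT", "TGCATGAC"],
                          str(S615F_CER), "forward", constraints)
        report = at.validate_set(s)
        assert not report.checks["min_pairwise_distance"]
        assert "ACGTACTG" in report.offenders["min_pairwise_distance"]

    def test_designed_set_passes(self, fw_set):
        assert at.validate_set(fw_set).passed


class TestCrossCombinationScreen:
    def test_non_complementary_alphabets_pass(self, constraints):
        # everything over {A,C}: reverse complements live in {G,T}, no pairing
        fw = at.BarcodeSet(["ACACACAC", "CCAACCAA"], "AACCAACCAA", "forward", constraints)
        rv = at.BarcodeSet(["CACACACA", "AACCAACC"], "CCAACCAACC", "reverse", constraints)
        assert at.cross_combination_screen(fw, rv) == []

    def test_injected_reverse_complement_pair_reported(self, constraints):
        fw_tag, fw_primer = "ACGTTGCA", "AAAACCCCGGGGTTTT"
        rc = str(at.revcomp(fw_tag + fw_primer))
        fw = at.BarcodeSet([fw_tag], fw_primer, "forward", constraints)
        rv = at.BarcodeSet([rc[:8]], rc[8:], "reverse", constraints)
        failing = at.cross_combination_screen(fw, rv)
        names = {(a, b) for a, b, _ in failing}
        assert ("bcF01", "bcR01") in names

    def test_pair_count_bound_at_study_scale(self, fw_set, rv_set):
        n = len(fw_set) + len(rv_set)
        assert n * (n + 1) // 2 == 666  # 18+18 tagged oligos, self-pairs included
        failing = at.cross_combination_screen(fw_set, rv_set)
        assert len(failing) <= 666
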