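import random

import pytest

from mirqpcr import (
    DesignConfig,
    PrimerCandidate,
    ScoredPrimer,
    design_target,
    end_scores,
    enumerate_pairs,
    longest_internal_anneal,
    longest_three_prime_anneal,
    parse_targets,
    rank_pairs,
    reverse_complement,
    score_primer,
    weak_count,
)
from mirqpcr.scoring import (
    PrimerPair,
    internal_anneal_factor,
    template_overlap,
    three_prime_anneal_factor,
)

# ---------------------------------------------------------------------------
# Brute-force annealing oracles (exhaustive enumeration, independent of the
# substring / dynamic-programming search used by the implementation).
# ---------------------------------------------------------------------------

def brute_three_prime(a, b):
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        suffix_rc = reverse_complement(a[-k:])
        for off in range(len(b) - k + 1):
            if b[off:off + k] == suffix_rc:
                best = k
                break
    return best


def brute_internal(a, b):
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        amers = {a[i:i + k] for i in range(len(a) - k + 1)}
        bmers = {reverse_complement(b[i:i + k]) for i in range(len(b) - k + 1)}
        if amers & bmers:
            best = k
    return best


def fwd_candidate(seq, specific_length=None, five_prime_score=10):
    n = specific_length if specific_length is not None else len(seq)
    return PrimerCandidate(
        orientation="forward", sequence=seq.upper(),
        specific_part=seq.upper()[-n:], tail=seq.upper()[:-n] if n < len(seq) else "",
        footprint=(0, n), tm=59.0, five_prime_score=five_prime_score,
    )


# expected Table-style reference rows for the eight ssc-let-7a forwards:
# (name, seq, specific_length, total, two, three, five, self3, internal)
LET7A_ROWS = [
    ("F_1", "gcagtgaggtagtaggttgt", 16, "0.64", "1.0", "1.0", "1.0", "1.0", "1.0"),
    ("F_2", "gcagtgaggtagtaggttg", 15, "0.56", "1.0", "1.0", "1.0", "1.0", "1.0"),
    ("F_3", "cgcagtgaggtagtaggt", 13, "0.42", "1.0", "1.0", "1.0", "1.0", "1.0"),
    ("F_4", "cgcagtgaggtagtaggtt", 14, "0.34", "0.7", "1.0", "1.0", "1.0", "1.0"),
    ("F_5", "gcagtgaggtagtaggttgta", 17, "0.25", "0.7", "1.0", "0.5", "1.0", "1.0"),
    ("F_6", "cgcagtgaggtagtagg", 12, "0.25", "0.7", "1.0", "1.0", "1.0", "1.0"),
    ("F_7", "gcagtgaggtagtaggttgtat", 18, "0.09", "0.7", "0.3", "0.5", "1.0", "1.0"),
    ("F_8", "gcagtgaggtagtaggttgtata", 19, "0.02", "0.7", "0.3", "0.5", "0.2", "1.0"),
]


class TestWeakCount:
    @pytest.mark.parametrize("seq,n", [("GT", 1), ("TAT", 3), ("GCGCG", 0),
                                       ("at", 2)])
    def test_counts_a_and_t(self, seq, n):
        assert weak_count(seq) == n


class TestEndScores:
    @pytest.mark.parametrize("seq,expected", [
        ("GCAGTGAGGTAGTAGGTTGT", (1.0, 1.0, 1.0)),
        ("GCAGTGAGGTAGTAGGTTGTAT", (0.7, 0.3, 0.5)),
        ("GGTCCAGTTTTTTTTTTTTTTTAACTATAC", (1.0, 1.0, 0.5)),
    ])
    def test_reference_windows(self, seq, expected):
        assert end_scores(seq) == expected

    def test_short_sequence_skips_missing_windows(self):
        # 4-nt sequence: the 5-nt window does not fit and is neutral
        assert end_scores("GCGT")[2] == 1.0


class TestAnnealDetectors:
    def test_self_annealing_tata_suffix(self):
        a = "GCAGTGAGGTAGTAGGTTGTATA"
        assert longest_three_prime_anneal(a, a) == 4

    def test_full_palindrome(self):
        assert longest_three_prime_anneal("ATATATAT", "ATATATAT") == 8

    def test_internal_below_penalty_threshold(self):
        a = "GCAGTGAGGTAGTAGGTTGT"
        assert longest_internal_anneal(a, a) < 6

    def test_internal_engineered_six_mer(self):
        assert longest_internal_anneal("AAAAAACCCCCC", "GGGGGGTTTTTT") >= 6

    def test_matches_exhaustive_oracles_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(300):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 35)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 35)))
            assert longest_three_prime_anneal(a, b) == brute_three_prime(a, b)
            assert longest_internal_anneal(a, b) == brute_internal(a, b)

    @pytest.mark.parametrize("k,factor", [(0, 1.0), (3, 1.0), (4, 0.2),
                                          (5, 0.1), (6, 0.1), (12, 0.1)])
    def test_three_prime_factor_clamped(self, k, factor):
        assert three_prime_anneal_factor(k) == factor

    @pytest.mark.parametrize("k,factor", [(0, 1.0), (5, 1.0), (6, 0.8),
                                          (7, 0.3), (8, 0.1), (11, 0.1)])
    def test_internal_factor_clamped(self, k, factor):
        assert internal_anneal_factor(k) == factor


class TestScorePrimer:
    @pytest.mark.parametrize("row", LET7A_ROWS, ids=[r[0] for r in LET7A_ROWS])
    def test_reference_forward_breakdowns(self, row, let7a_result):
        from mirqpcr import format_score
        name, seq, n, total, two, three, five, self3, internal = row
        primer = {p.name: p for p in let7a_result.forwards}[name]
        assert primer.candidate.sequence.lower() == seq
        assert primer.candidate.specific_length == n
        s = primer.score
        assert (format_score(s.total), format_score(s.two_last_score),
                format_score(s.three_last_score), format_score(s.five_last_score),
                format_score(s.three_self_anneal),
                format_score(s.internal_self_anneal)) == (
            total, two, three, five, self3, internal)

    def test_reverse_has_no_length_factor(self, let7a_result):
        r1 = let7a_result.reverses[0]
        assert r1.candidate.sequence.lower() == "ggtccagtttttttttttttttaactatac"
        assert r1.score.length_score == 1.0
        assert r1.score.total == pytest.approx(0.5)

    def test_total_is_product_of_factors(self, let7a_result):
        for p in let7a_result.forwards + let7a_result.reverses:
            s = p.score
            assert s.total == pytest.approx(
                s.two_last_score * s.three_last_score * s.five_last_score
                * s.three_self_anneal * s.internal_self_anneal * s.length_score
            )
            assert 0 < s.total <= 1.0

    def test_five_prime_score_never_enters_score(self, config):
        a = fwd_candidate("GCAGTGAGGTAGTAGGTTGT", 16, five_prime_score=10)
        b = fwd_candidate("GCAGTGAGGTAGTAGGTTGT", 16, five_prime_score=5)
        assert score_primer(a, config).total == score_primer(b, config).total

    def test_case_and_ut_spelling_invariance(self, let7a_result, config):
        rna = parse_targets(">ssc-let-7a\nugagguaguagguuguauaguu")[0]
        alt = design_target(rna, config)
        assert [(p.name, p.candidate.sequence, p.score.total)
                for p in alt.forwards] == [
            (p.name, p.candidate.sequence, p.score.total)
            for p in let7a_result.forwards]


class TestPairs:
    def test_best_pair_scores(self, let7a_result):
        best = let7a_result.best_pair
        assert best.forward.name == "F_1" and best.reverse.name == "R_1"
        assert (best.fprimer_anneal, best.rprimer_anneal, best.primer_dimer) == \
            (1.0, 1.0, 1.0)
        assert best.pair_score == pytest.approx(0.32)

    def test_footprint_overlap_rule(self, let7a_result, config):
        f1 = next(p for p in let7a_result.forwards if p.name == "F_1")
        r1 = next(p for p in let7a_result.reverses if p.name == "R_1")
        assert template_overlap(f1.candidate, r1.candidate) == 2  # retained
        kept = {(p.forward.name, p.reverse.name) for p in let7a_result.pairs}
        assert ("F_1", "R_1") in kept
        for p in let7a_result.pairs:
            assert template_overlap(p.forward.candidate, p.reverse.candidate) <= \
                config.max_pair_template_overlap

    def test_excessive_overlap_excluded(self, let7a_result):
        # specific length 18 forward vs 8-nt reverse on the 22-nt template
        # overlap by 4 and must be absent
        kept = {(p.forward.candidate.specific_length,
                 p.reverse.candidate.specific_length)
                for p in let7a_result.pairs}
        assert (18, 8) not in kept and (19, 8) not in kept

    def test_engineered_three_prime_cross_complement(self, config, let7a_result):
        template = let7a_result.template
        f = fwd_candidate("ACACACGGTAC", 11)
        fs = ScoredPrimer(candidate=f, score=score_primer(f, config), name="F_x")
        r = PrimerCandidate(orientation="reverse", sequence="TTTTGTACCTTTT",
                            specific_part="TTTT", tail="TTTTGTACC",
                            footprint=(18, 22), tm=59.0)
        rs = ScoredPrimer(candidate=r, score=score_primer(r, config), name="R_x")
        pairs = enumerate_pairs([fs], [rs], template, config)
        assert pairs and pairs[0].fprimer_anneal == 0.1  # 5-nt 3' match

    def test_pair_score_bounded_by_primer_scores(self, let7a_result):
        for p in let7a_result.pairs:
            assert p.pair_score <= min(p.forward.score.total,
                                       p.reverse.score.total) + 1e-12

    def test_tie_break_prefers_longer_reverse(self, let7a_result):
        f = let7a_result.forwards[0]
        r_long = let7a_result.reverses[0]   # specific length 8, score 0.5
        r_short = next(p for p in let7a_result.reverses
                       if p.candidate.specific_length == 3)  # also 0.5
        p_long = PrimerPair(f, r_long, 1.0, 1.0, 1.0)
        p_short = PrimerPair(f, r_short, 1.0, 1.0, 1.0)
        assert p_long.pair_score == p_short.pair_score
        assert rank_pairs([p_short, p_long])[0] is p_long

    def test_ranked_descending(self, let7a_result):
        scores = [p.pair_score for p in let7a_result.pairs]
        assert scores == sorted(scores, reverse=True)
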