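"""Primer and primer-pair scoring.

Each primer receives multiplicative penalty factors for the weak-base (A/T)
content of its 3'-terminal 2-, 3- and 5-nt windows and for 3'-anchored and
internal self-annealing; forward primers additionally receive
``specific_length**2 / 400``, which favors longer microRNA-specific parts.
A primer's score is the product of its factors.

Pairs multiply both primer scores with three cross-annealing factors
(forward-3' vs reverse, reverse-3' vs forward, and internal cross-
complementarity) and are ranked by that product.  All annealing is modeled
as two-molecule hybridization: a k-mer of one strand base-pairing with the
reverse complement of a k-mer found anywhere in the other (or in a second
copy of the same primer for self-annealing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from . import config as _cfg
from .candidates import PrimerCandidate, reverse_complement
from .config import DesignConfig
from .seqio import Template

_WEAK = frozenset("AT")


def weak_count(seq: str) -> int:
    """Number of weak (A/T) bases in ``seq``."""
    s = seq.upper()
    return sum(1 for c in s if c in _WEAK)


def _lookup(table: Dict[int, float], count: int) -> float:
    return table[count]


def end_scores(seq: str) -> tuple:
    """(two_last, three_last, five_last) factors from the 3'-end windows.

    Windows longer than the sequence are skipped and score a neutral 1.0.
    """
    s = seq.upper()
    out = []
    for window, table in (
        (2, _cfg.TWO_LAST_SCORES),
        (3, _cfg.THREE_LAST_SCORES),
        (5, _cfg.FIVE_LAST_SCORES),
    ):
        if len(s) < window:
            out.append(1.0)
        else:
            out.append(_lookup(table, weak_count(s[-window:])))
    return tuple(out)


def longest_three_prime_anneal(a: str, b: str) -> int:
    """Longest 3'-anchored annealing match of ``a`` against ``b``.

    The largest k such that the 3'-terminal k-mer of ``a`` is the reverse
    complement of some k-mer occurring anywhere in ``b``.  ``b`` may be a
    second copy of ``a`` (self-annealing); the matching k-mer may overlap
    a's own suffix, as for two molecules.
    """
    a = a.upper()
    b = b.upper()
    for k in range(min(len(a), len(b)), 0, -1):
        if reverse_complement(a[-k:]) in b:
            return k
    return 0


def longest_internal_anneal(a: str, b: str) -> int:
    """Longest internal annealing match between ``a`` and ``b``.

    The largest k such that some k-mer of ``a`` is the reverse complement of
    some k-mer of ``b`` -- equivalently the longest common substring of
    ``a`` and the reverse complement of ``b``, computed here by dynamic
    programming (sequences are primer-sized, so O(len(a)*len(b)) is cheap).
    """
    a = a.upper()
    rb = reverse_complement(b.upper())
    best = 0
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0] * (len(rb) + 1)
        for j, cb in enumerate(rb, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def three_prime_anneal_factor(k: int) -> float:
    if k > max(_cfg.THREE_PRIME_ANNEAL_SCORES):
        return _cfg.THREE_PRIME_ANNEAL_CLAMP
    return _cfg.THREE_PRIME_ANNEAL_SCORES.get(k, 1.0)


def internal_anneal_factor(k: int) -> float:
    if k > max(_cfg.INTERNAL_ANNEAL_SCORES):
        return _cfg.INTERNAL_ANNEAL_CLAMP
    return _cfg.INTERNAL_ANNEAL_SCORES.get(k, 1.0)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-primer factors and their product.

    ``length_score`` applies to forward primers only (1.0 for reverse);
    ``total`` is the exact product of all factors, kept unrounded -- reports
    round to two decimals at print time.
    """

    two_last_score: float
    three_last_score: float
    five_last_score: float
    three_self_anneal: float
    internal_self_anneal: float
    length_score: float
    total: float


def score_primer(candidate: PrimerCandidate, config: DesignConfig) -> ScoreBreakdown:
    """Full multiplicative score of one primer candidate."""
    seq = candidate.sequence
    two, three, five = end_scores(seq)
    self3 = three_prime_anneal_factor(longest_three_prime_anneal(seq, seq))
    internal = internal_anneal_factor(longest_internal_anneal(seq, seq))
    if candidate.orientation == "forward":
        length_score = candidate.specific_length ** 2 / config.length_score_denominator
    else:
        length_score = 1.0
    total = two * three * five * self3 * internal * length_score
    return ScoreBreakdown(
        two_last_score=two,
        three_last_score=three,
        five_last_score=five,
        three_self_anneal=self3,
        internal_self_anneal=internal,
        length_score=length_score,
        total=total,
    )


@dataclass(frozen=True)
class ScoredPrimer:
    """A candidate together with its score breakdown and report name."""

    candidate: PrimerCandidate
    score: ScoreBreakdown
    name: str = ""


@dataclass(frozen=True)
class PrimerPair:
    """A retained forward+reverse combination with cross-annealing factors."""

    forward: ScoredPrimer
    reverse: ScoredPrimer
    fprimer_anneal: float
    rprimer_anneal: float
    primer_dimer: float

    @property
    def pair_score(self) -> float:
        return (
            self.forward.score.total
            * self.reverse.score.total
            * self.fprimer_anneal
            * self.rprimer_anneal
            * self.primer_dimer
        )


def rank_primers(
    scored: Sequence[ScoredPrimer], prefix: str
) -> List[ScoredPrimer]:
    """Order candidates by descending score and assign F_1.../R_1... names.

    Ties break toward the longer specific part, then lexicographically by
    sequence, giving a deterministic total order.
    """
    ordered = sorted(
        scored,
        key=lambda s: (
            -s.score.total,
            -s.candidate.specific_length,
            s.candidate.sequence,
        ),
    )
    return [
        ScoredPrimer(candidate=s.candidate, score=s.score, name=f"{prefix}_{i}")
        for i, s in enumerate(ordered, start=1)
    ]


def template_overlap(f: PrimerCandidate, r: PrimerCandidate) -> int:
    """Width of the overlap between two specific-part footprints."""
    return max(0, min(f.footprint[1], r.footprint[1]) - max(f.footprint[0], r.footprint[0]))


def enumerate_pairs(
    forwards: Sequence[ScoredPrimer],
    reverses: Sequence[ScoredPrimer],
    template: Template,
    config: DesignConfig,
) -> List[PrimerPair]:
    """All forward x reverse combinations whose 3'-ends do not collide.

    A pair is dropped when the specific footprints overlap by more than
    ``config.max_pair_template_overlap`` template positions.  Retained pairs
    carry the three cross-annealing factors.
    """
    pairs: List[PrimerPair] = []
    for f in forwards:
        for r in reverses:
            if template_overlap(f.candidate, r.candidate) > config.max_pair_template_overlap:
                continue
            fseq, rseq = f.candidate.sequence, r.candidate.sequence
            pairs.append(
                PrimerPair(
                    forward=f,
                    reverse=r,
                    fprimer_anneal=three_prime_anneal_factor(
                        longest_three_prime_anneal(fseq, rseq)
                    ),
                    rprimer_anneal=three_prime_anneal_factor(
                        longest_three_prime_anneal(rseq, fseq)
                    ),
                    primer_dimer=internal_anneal_factor(
                        longest_internal_anneal(fseq, rseq)
                    ),
                )
            )
    return pairs


def rank_pairs(pairs: Sequence[PrimerPair]) -> List[PrimerPair]:
    """Descending by unrounded pair score.

    Equal scores prefer the longer reverse specific part, then the longer
    forward specific part, then the lexicographically smaller forward
    sequence.
    """
    return sorted(
        pairs,
        key=lambda p: (
            -p.pair_score,
            -p.reverse.candidate.specific_length,
            -p.forward.candidate.specific_length,
            p.forward.candidate.sequence,
        ),
    )
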