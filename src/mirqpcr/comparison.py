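"""Pairwise similarity between designed primer pairs.

When an assay fails, the recommended redesign strategy is to pick the pair
most *different* from the failed one rather than the next-ranked pair.  The
similarity score supports that choice: it combines, for each primer against
its counterpart, the position-wise agreement of the 3'-terminal trinucleotide
with a penalty on the difference in microRNA-specific length.  Differences in
the forward primer weigh twice as much, implemented by squaring its factor in
the product.  Identical pairs score exactly 1.0; lower means more different.

The concrete factor values are this package's interpretation (see
docs/methods.md); they are configurable in :mod:`mirqpcr.config`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from . import config as _cfg
from .scoring import PrimerPair, ScoredPrimer


def _primer_factor(a: ScoredPrimer, b: ScoredPrimer) -> float:
    sa, sb = a.candidate.sequence.upper(), b.candidate.sequence.upper()
    matches = sum(1 for x, y in zip(sa[-3:], sb[-3:]) if x == y)
    end3 = _cfg.COMPARISON_END3_SCORES[matches]
    dlen = abs(a.candidate.specific_length - b.candidate.specific_length)
    length = max(
        _cfg.COMPARISON_LENGTH_FLOOR, 1.0 - _cfg.COMPARISON_LENGTH_STEP * dlen
    )
    return end3 * length


def pair_similarity(a: PrimerPair, b: PrimerPair) -> float:
    """Similarity in (0, 1]; symmetric; 1.0 iff the pairs are identical-like."""
    f = _primer_factor(a.forward, b.forward)
    r = _primer_factor(a.reverse, b.reverse)
    return f * f * r


@dataclass(frozen=True)
class PairComparison:
    pair_a: str
    pair_b: str
    similarity: float


def compare_pairs(pairs: Sequence[PrimerPair]) -> List[PairComparison]:
    """Full similarity matrix (all ordered combinations) of ranked pairs.

    Pairs are identified by their 1-based rank (``pair_1`` is the
    best-ranked pair).
    """
    out: List[PairComparison] = []
    for i, a in enumerate(pairs, start=1):
        for j, b in enumerate(pairs, start=1):
            out.append(
                PairComparison(
                    pair_a=f"pair_{i}",
                    pair_b=f"pair_{j}",
                    similarity=pair_similarity(a, b),
                )
            )
    return out


def comparison_matrix(
    comparisons: Sequence[PairComparison],
) -> Tuple[List[str], Dict[Tuple[str, str], float]]:
    """Labels (in first-seen order) and a lookup dict for a matrix layout."""
    labels: List[str] = []
    for c in comparisons:
        if c.pair_a not in labels:
            labels.append(c.pair_a)
    values = {(c.pair_a, c.pair_b): c.similarity for c in comparisons}
    return labels, values
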