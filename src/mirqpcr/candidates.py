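"""Enumeration of forward and reverse primer candidates.

Forward candidates take the first 12-19 nt of the template (one candidate
per length).  A candidate colder than the target temperature is extended by
prepending tail nucleotides one at a time in the cycled order G, A, C, G, C;
one hotter than the target is trimmed from its 5'-end instead, which shifts
its footprint off the template 5'-end (recorded by ``five_prime_score`` 5
instead of 10).

Reverse candidates carry 3-8 template-complementary bases at the 3'-end,
preceded by the 15-T tract that pairs with the poly(A) tail added during
reverse transcription.  Their temperature is raised by prepending successive
3'-terminal letters of the RT-primer tag, so every reverse primer is a
suffix of RT-tag + poly-T plus its specific 3' bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

from .config import DesignConfig
from .seqio import Template
from .thermo import melting_temperature

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerCandidate:
    """One forward or reverse primer candidate.

    ``sequence`` is the full primer 5'->3' (tail + specific part for
    forward; tag tail + poly-T + specific part for reverse).  ``footprint``
    is the half-open 0-based interval of template positions covered by the
    specific part.  ``five_prime_score`` is informational only (10 when a
    forward primer is anchored at the template 5'-end, 5 when trimming moved
    it inward); it never enters any score.
    """

    orientation: str  # "forward" | "reverse"
    sequence: str
    specific_part: str
    tail: str
    footprint: Tuple[int, int]
    tm: float
    five_prime_score: int = 10

    @property
    def specific_length(self) -> int:
        return self.footprint[1] - self.footprint[0]


def forward_tail(k: int, config: DesignConfig) -> str:
    """Tail produced by prepending ``k`` letters of the cycled tail order.

    Because letters are prepended one at a time, the tail read 5'->3' is the
    reverse of the first ``k`` letters of the cycled order: k=4 gives
    ``GCAG``, k=5 gives ``CGCAG``.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    order = config.forward_tail_order
    taken = [order[i % len(order)] for i in range(k)]
    return "".join(reversed(taken))


def build_forward_candidates(
    template: Template, config: DesignConfig
) -> List[PrimerCandidate]:
    """All forward candidates for one template, deduplicated by sequence."""
    design = template.design_sequence
    lo, hi = config.forward_specific_range
    target = config.thermo.tm_target_C
    out: List[PrimerCandidate] = []
    seen = set()
    for length in range(lo, min(hi, len(design)) + 1):
        start = 0
        spec = design[:length]
        tail = ""
        if melting_temperature(spec, config.thermo) < target:
            k = 0
            while (
                melting_temperature(tail + spec, config.thermo) < target
                and k < config.max_forward_tail
            ):
                k += 1
                tail = forward_tail(k, config)
            if melting_temperature(tail + spec, config.thermo) < target:
                logger.warning(
                    "%s: forward candidate (%d nt specific) stays below "
                    "%.1f C after a full %d-nt tail",
                    template.name, length, target, config.max_forward_tail,
                )
        else:
            while (
                melting_temperature(spec, config.thermo) > target
                and len(spec) > config.min_primer_length
            ):
                start += 1
                spec = design[start:length]
            if melting_temperature(spec, config.thermo) > target:
                logger.warning(
                    "%s: forward candidate trimmed to the %d-nt floor still "
                    "exceeds %.1f C",
                    template.name, config.min_primer_length, target,
                )
        seq = tail + spec
        if seq in seen:
            continue
        seen.add(seq)
        out.append(
            PrimerCandidate(
                orientation="forward",
                sequence=seq,
                specific_part=spec,
                tail=tail,
                footprint=(start, length),
                tm=melting_temperature(seq, config.thermo),
                five_prime_score=10 if start == 0 else 5,
            )
        )
    return out


def build_reverse_candidates(
    template: Template, config: DesignConfig
) -> List[PrimerCandidate]:
    """All reverse candidates (one per specific length) for one template."""
    design = template.design_sequence
    n = len(design)
    lo, hi = config.reverse_specific_range
    target = config.thermo.tm_target_C
    poly_t = "T" * config.poly_t_length
    out: List[PrimerCandidate] = []
    seen = set()
    for k in range(lo, min(hi, n) + 1):
        spec = reverse_complement(design[n - k:])
        seq = poly_t + spec
        remaining = len(config.rt_tag)
        while melting_temperature(seq, config.thermo) < target and remaining > 0:
            remaining -= 1
            seq = config.rt_tag[remaining] + seq
        if melting_temperature(seq, config.thermo) < target:
            logger.warning(
                "%s: reverse candidate (%d nt specific) stays below %.1f C "
                "with the full RT tag", template.name, k, target,
            )
        if seq in seen:
            continue
        seen.add(seq)
        out.append(
            PrimerCandidate(
                orientation="reverse",
                sequence=seq,
                specific_part=spec,
                tail=seq[: len(seq) - len(spec)],
                footprint=(n - k, n),
                tm=melting_temperature(seq, config.thermo),
                five_prime_score=10,
            )
        )
    return out
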