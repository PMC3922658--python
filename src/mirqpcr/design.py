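"""The design pipeline: targets in, ranked scored primers and pairs out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .candidates import build_forward_candidates, build_reverse_candidates
from .comparison import PairComparison, compare_pairs
from .config import DesignConfig
from .scoring import (
    PrimerPair,
    ScoredPrimer,
    enumerate_pairs,
    rank_pairs,
    rank_primers,
    score_primer,
)
from .seqio import TargetRecord, Template, TemplateError, make_template

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetResult:
    """Everything designed for one target, in ranked order."""

    template: Template
    forwards: List[ScoredPrimer]
    reverses: List[ScoredPrimer]
    pairs: List[PrimerPair]
    comparisons: List[PairComparison]

    @property
    def best_pair(self) -> PrimerPair:
        if not self.pairs:
            raise ValueError(f"no primer pairs for target {self.template.name!r}")
        return self.pairs[0]


@dataclass
class ResultSet:
    """Results for a batch of targets plus per-target failures."""

    results: List[TargetResult] = field(default_factory=list)
    failures: List[Tuple[str, str]] = field(default_factory=list)  # (name, reason)


def design_target(record: TargetRecord, config: DesignConfig) -> TargetResult:
    """Design, score and rank all primers and pairs for one target."""
    template = make_template(record, config)
    forwards = rank_primers(
        [
            ScoredPrimer(candidate=c, score=score_primer(c, config))
            for c in build_forward_candidates(template, config)
        ],
        prefix="F",
    )
    reverses = rank_primers(
        [
            ScoredPrimer(candidate=c, score=score_primer(c, config))
            for c in build_reverse_candidates(template, config)
        ],
        prefix="R",
    )
    pairs = rank_pairs(enumerate_pairs(forwards, reverses, template, config))
    return TargetResult(
        template=template,
        forwards=forwards,
        reverses=reverses,
        pairs=pairs,
        comparisons=compare_pairs(pairs),
    )


def design_targets(
    records: Sequence[TargetRecord], config: DesignConfig = DesignConfig()
) -> ResultSet:
    """Process every target independently; failures are recorded, not fatal."""
    out = ResultSet()
    for record in records:
        try:
            out.results.append(design_target(record, config))
        except TemplateError as exc:
            logger.error("skipping %s: %s", record.name, exc)
            out.failures.append((record.name, str(exc)))
    return out
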