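"""Configuration objects: every tunable constant of the design method.

Two dataclasses hold all knobs. :class:`ThermoConfig` fixes the
nearest-neighbor melting-temperature model used to size primers toward the
59 degC target; :class:`DesignConfig` holds everything else -- candidate
length ranges, tail alphabets, the 3'-end / self-annealing score matrix and
the pair-overlap threshold.

The thermodynamic defaults are a calibration: the nearest-neighbor parameter
table, salt-correction scheme and strand concentrations are not uniquely
determined by the design rules themselves, so they were fixed by requiring
that the tail/trim algorithm regenerates the known-good reference primer set
for ssc-let-7a (see docs/methods.md).  Changing them changes which tail
lengths are chosen, not the scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

#: Nearest-neighbor parameter tables selectable by name. Values map onto
#: the tables shipped with Bio.SeqUtils.MeltingTemp.
NN_PARAMETER_SETS = (
    "breslauer_1986",
    "sugimoto_1996",
    "santalucia_1997",
    "santalucia_2004",
)


@dataclass(frozen=True)
class ThermoConfig:
    """Melting-temperature model settings.

    Parameters
    ----------
    sodium_mM : float
        Monovalent cation concentration in mM. The design protocol
        prescribes 115 mM NaCl.
    oligo_nM : float
        Primer strand concentration in nM (the strand in excess).
    template_nM : float
        Template strand concentration in nM.
    parameter_set : str
        Name of the nearest-neighbor enthalpy/entropy table, one of
        :data:`NN_PARAMETER_SETS`.
    salt_correction : int
        Salt-correction scheme index as defined by
        ``Bio.SeqUtils.MeltingTemp`` (7 = Owczarzy 2008 sodium correction).
    tm_target_C : float
        Target melting temperature in Celsius toward which primers are
        tailed or trimmed.
    """

    sodium_mM: float = 115.0
    oligo_nM: float = 40.0
    template_nM: float = 20.0
    parameter_set: str = "sugimoto_1996"
    salt_correction: int = 7
    tm_target_C: float = 59.0

    def __post_init__(self) -> None:
        if self.sodium_mM <= 0:
            raise ValueError("sodium_mM must be positive")
        if self.oligo_nM <= 0 or self.template_nM < 0:
            raise ValueError("strand concentrations must be positive")
        if self.parameter_set not in NN_PARAMETER_SETS:
            raise ValueError(
                f"unknown parameter_set {self.parameter_set!r}; "
                f"choose one of {NN_PARAMETER_SETS}"
            )


# -- Score matrix -----------------------------------------------------------
# Factors keyed by the number of weak (A/T) bases in the 3'-terminal 2-, 3-
# and 5-nt windows. A window that scores 1.0 is neutral.

TWO_LAST_SCORES: Dict[int, float] = {0: 0.7, 1: 1.0, 2: 0.7}
THREE_LAST_SCORES: Dict[int, float] = {0: 0.3, 1: 1.0, 2: 1.0, 3: 0.3}
FIVE_LAST_SCORES: Dict[int, float] = {0: 0.1, 1: 0.5, 2: 1.0, 3: 1.0, 4: 0.5, 5: 0.1}

#: Penalty for a 3'-anchored annealing match of length k (self or cross).
#: Matches of 5 nt or more block extension outright; >=6 clamps to the 5-nt
#: factor (monotone extension of the published matrix).
THREE_PRIME_ANNEAL_SCORES: Dict[int, float] = {4: 0.2, 5: 0.1}
THREE_PRIME_ANNEAL_CLAMP: float = 0.1

#: Penalty for the longest internal (anywhere-vs-anywhere) annealing match.
INTERNAL_ANNEAL_SCORES: Dict[int, float] = {6: 0.8, 7: 0.3, 8: 0.1}
INTERNAL_ANNEAL_CLAMP: float = 0.1

#: Pair-similarity: factor for the number of position-wise matches in the
#: 3'-terminal trinucleotide when comparing two primers for the same role.
COMPARISON_END3_SCORES: Dict[int, float] = {3: 1.0, 2: 0.7, 1: 0.4, 0: 0.2}
#: Pair-similarity: per-nucleotide penalty on specific-length difference and
#: its floor.
COMPARISON_LENGTH_STEP: float = 0.2
COMPARISON_LENGTH_FLOOR: float = 0.1


@dataclass(frozen=True)
class DesignConfig:
    """All design-method constants.

    ``forward_tail_order`` is consumed cyclically, one nucleotide prepended
    at a time (so the tail read 5'->3' is the reverse of the consumed
    letters).  ``rt_tag`` is the universal tag of the RT primer; reverse
    primers reuse its 3'-terminal letters, consumed one at a time toward the
    5'-end, in front of the 15-T tract.
    """

    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    forward_specific_range: Tuple[int, int] = (12, 19)
    reverse_specific_range: Tuple[int, int] = (3, 8)
    forward_tail_order: str = "GACGC"
    rt_tag: str = "CAGGTCCAG"
    poly_t_length: int = 15
    max_pair_template_overlap: int = 2
    length_score_denominator: float = 400.0
    min_template_length: int = 12
    #: shortest total primer length the 5'-trimming step may reach
    min_primer_length: int = 12
    #: how many full passes of the tail order may be prepended (the design
    #: rule allows the five tail nucleotides to be added "once more")
    max_tail_cycles: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.forward_specific_range
        if not (0 < lo <= hi):
            raise ValueError("invalid forward_specific_range")
        lo, hi = self.reverse_specific_range
        if not (0 < lo <= hi):
            raise ValueError("invalid reverse_specific_range")
        if self.poly_t_length < 0 or self.max_pair_template_overlap < 0:
            raise ValueError("negative length constant")
        if not self.forward_tail_order or not self.rt_tag:
            raise ValueError("tail alphabets must be non-empty")

    @property
    def max_forward_tail(self) -> int:
        return self.max_tail_cycles * len(self.forward_tail_order)
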