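"""Input parsing and template normalization.

MicroRNA targets arrive as FASTA-like text: a ``>name`` header line followed
by one or more sequence lines (RNA or DNA alphabet, any case).  Parsing is
strict -- duplicate names, ambiguity codes and headerless sequence are hard
errors with line numbers -- because a silently mis-parsed target would yield
primers for the wrong molecule.

Templates are the DNA-sense design sequences: U is rewritten to T, case is
normalized, and any run of 3'-terminal A residues is removed, since the
poly(A) tail added during cDNA synthesis makes those bases indistinguishable
from the primer-binding poly-T tract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

from .config import DesignConfig

_VALID = set("ACGTUacgtu")


class InputError(ValueError):
    """Malformed target list (duplicate name, bad character, no sequence)."""


class TemplateError(ValueError):
    """A single target cannot be turned into a usable design template."""


@dataclass(frozen=True)
class TargetRecord:
    """A named microRNA sequence exactly as supplied by the user."""

    name: str
    raw_sequence: str


@dataclass(frozen=True)
class Template:
    """Normalized DNA-sense design template.

    ``design_sequence`` is ``dna_sequence`` with its 3'-terminal A run
    removed; ``trimmed_a_count`` records how many A's were dropped, so that
    ``design_sequence + "A" * trimmed_a_count == dna_sequence`` always holds.
    """

    name: str
    dna_sequence: str
    trimmed_a_count: int

    @property
    def design_sequence(self) -> str:
        n = len(self.dna_sequence) - self.trimmed_a_count
        return self.dna_sequence[:n]


def parse_targets(text: str) -> List[TargetRecord]:
    """Parse FASTA-like text into a list of :class:`TargetRecord`.

    Sequence lines belonging to one header are concatenated; blank lines are
    tolerated anywhere.  Record order is preserved.

    Raises
    ------
    InputError
        On empty input, duplicate names, characters outside the unambiguous
        RNA/DNA alphabet (with the offending line number), or a header with
        no sequence.
    """
    records: List[TargetRecord] = []
    seen = set()
    name = None
    chunks: List[str] = []
    header_line = 0

    def flush() -> None:
        if name is None:
            return
        if not chunks:
            raise InputError(
                f"record {name!r} (line {header_line}) has no sequence"
            )
        if name in seen:
            raise InputError(f"duplicate record name {name!r}")
        seen.add(name)
        records.append(TargetRecord(name=name, raw_sequence="".join(chunks)))

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            flush()
            name = stripped[1:].strip()
            if not name:
                raise InputError(f"empty record name at line {lineno}")
            chunks = []
            header_line = lineno
        else:
            if name is None:
                raise InputError(
                    f"sequence without a preceding '>' header at line {lineno}"
                )
            bad = set(stripped) - _VALID
            if bad:
                raise InputError(
                    f"invalid character(s) {sorted(bad)} in sequence of "
                    f"{name!r} at line {lineno} (only unambiguous A/C/G/T/U "
                    "are accepted)"
                )
            chunks.append(stripped)
    flush()
    if not records:
        raise InputError("input contains no records")
    return records


def records_to_fasta(records: Iterable[TargetRecord]) -> str:
    """Serialize records back to FASTA-like text (inverse of parsing)."""
    return "".join(f">{r.name}\n{r.raw_sequence}\n" for r in records)


def make_template(record: TargetRecord, config: DesignConfig) -> Template:
    """Normalize one record into a design :class:`Template`.

    Raises
    ------
    TemplateError
        If, after removing the 3'-terminal A run, fewer than
        ``config.min_template_length`` designable bases remain.
    """
    dna = record.raw_sequence.upper().replace("U", "T")
    trimmed = len(dna) - len(dna.rstrip("A"))
    if len(dna) - trimmed < config.min_template_length:
        raise TemplateError(
            f"target {record.name!r}: only {len(dna) - trimmed} nt remain "
            f"after removing {trimmed} 3'-terminal A residue(s); at least "
            f"{config.min_template_length} are required for primer design"
        )
    return Template(name=record.name, dna_sequence=dna, trimmed_a_count=trimmed)
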