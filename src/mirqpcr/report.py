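"""Tab-separated result files.

Five fixed-name files are written per run, spreadsheet-compatible:

* ``result_f_primers.txt`` / ``result_r_primers.txt`` -- per-target ranked
  primer tables with every score factor.
* ``result_best_primer_pairs.txt`` -- the top-ranked pair per target.
* ``result_all_primer_pairs.txt`` -- every retained pair, ranked.
* ``result_comparison_of_pairs.txt`` -- per-target pair-similarity matrix.

Scores print at two decimals with one trailing zero dropped ("0.5", "1.0"),
matching the tabular conventions of the protocol; primer sequences print
lowercase.  Minimal readers for each layout are provided so written files
can be parsed back (round-trip at printed precision).
"""

from __future__ import annotations

import os
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Tuple

from .design import ResultSet, TargetResult
from .scoring import PrimerPair, ScoredPrimer

FILENAMES = (
    "result_best_primer_pairs.txt",
    "result_all_primer_pairs.txt",
    "result_f_primers.txt",
    "result_r_primers.txt",
    "result_comparison_of_pairs.txt",
)

_PRIMER_COLUMNS = (
    "Name", "Seq", "Length", "score", "two_last_score", "three_last_score",
    "five_last_score", "three_self_anneal", "internal_self_anneal",
    "five_prime_score",
)
_PAIR_COLUMNS = (
    "Name", "Sequence", "Score", "Fprimer_anneal", "Rprimer_anneal",
    "Primer_dimer",
)


def format_score(value: float) -> str:
    """Two-decimal half-up rounding, minimal trailing zeros ("0.5", "1.0")."""
    d = Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    s = f"{d:.2f}"
    if s.endswith("0"):
        s = s[:-1]
    return s


def _primer_row(p: ScoredPrimer) -> List[str]:
    s = p.score
    return [
        p.name,
        p.candidate.sequence.lower(),
        str(p.candidate.specific_length),
        format_score(s.total),
        format_score(s.two_last_score),
        format_score(s.three_last_score),
        format_score(s.five_last_score),
        format_score(s.three_self_anneal),
        format_score(s.internal_self_anneal),
        str(p.candidate.five_prime_score),
    ]


def _primer_file(results: List[TargetResult], orientation: str) -> List[str]:
    lines: List[str] = []
    for res in results:
        primers = res.forwards if orientation == "forward" else res.reverses
        lines.append(f"{res.template.name}\t{res.template.dna_sequence.lower()}")
        lines.append("Primers")
        lines.append("\t".join(_PRIMER_COLUMNS))
        for p in primers:
            lines.append("\t".join(_primer_row(p)))
        lines.append("")
    return lines


def _pair_block(label: str, template_seq: str, pair: PrimerPair) -> List[str]:
    return [
        "\t".join(
            [
                label,
                template_seq.lower(),
                format_score(pair.pair_score),
                format_score(pair.fprimer_anneal),
                format_score(pair.rprimer_anneal),
                format_score(pair.primer_dimer),
            ]
        ),
        "\t".join(
            [pair.forward.name, pair.forward.candidate.sequence.lower(),
             format_score(pair.forward.score.total)]
        ),
        "\t".join(
            [pair.reverse.name, pair.reverse.candidate.sequence.lower(),
             format_score(pair.reverse.score.total)]
        ),
    ]


def _best_pairs_file(results: List[TargetResult]) -> List[str]:
    lines = ["\t".join(_PAIR_COLUMNS)]
    for res in results:
        if not res.pairs:
            continue
        lines.extend(
            _pair_block(res.template.name, res.template.dna_sequence, res.best_pair)
        )
        lines.append("")
    return lines


def _all_pairs_file(results: List[TargetResult]) -> List[str]:
    lines = ["\t".join(_PAIR_COLUMNS)]
    for res in results:
        for i, pair in enumerate(res.pairs, start=1):
            lines.extend(
                _pair_block(
                    f"{res.template.name} pair {i}",
                    res.template.dna_sequence,
                    pair,
                )
            )
        lines.append("")
    return lines


def _comparison_file(results: List[TargetResult]) -> List[str]:
    from .comparison import comparison_matrix

    lines: List[str] = []
    for res in results:
        labels, values = comparison_matrix(res.comparisons)
        lines.append(res.template.name)
        lines.append("\t".join(["Name"] + labels))
        for a in labels:
            lines.append(
                "\t".join([a] + [format_score(values[(a, b)]) for b in labels])
            )
        lines.append("")
    return lines


def write_outputs(results: ResultSet, out_dir: str, crlf: bool = False) -> List[str]:
    """Write the five result files into ``out_dir``; returns the paths.

    The directory must exist and be writable; this is checked before any
    file is produced so a failed run never leaves a partial file set.
    """
    if not os.path.isdir(out_dir):
        raise OSError(f"output directory {out_dir!r} does not exist")
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir!r} is not writable")
    newline = "\r\n" if crlf else "\n"
    contents = {
        "result_best_primer_pairs.txt": _best_pairs_file(results.results),
        "result_all_primer_pairs.txt": _all_pairs_file(results.results),
        "result_f_primers.txt": _primer_file(results.results, "forward"),
        "result_r_primers.txt": _primer_file(results.results, "reverse"),
        "result_comparison_of_pairs.txt": _comparison_file(results.results),
    }
    paths = []
    for fname in FILENAMES:
        path = os.path.join(out_dir, fname)
        with open(path, "w", newline="") as fh:
            fh.write(newline.join(contents[fname]) + newline)
        paths.append(path)
    return paths


# -- readers (round-trip at printed precision) ------------------------------

def read_primer_file(text: str) -> Dict[str, List[Dict[str, str]]]:
    """Parse a forward/reverse primer file into {target: [row dicts]}."""
    out: Dict[str, List[Dict[str, str]]] = {}
    target = None
    columns: List[str] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            target = None
        elif target is None:
            target = line.split("\t")[0]
            out[target] = []
            columns = []
        elif line == "Primers":
            pass
        elif not columns:
            columns = line.split("\t")
        else:
            out[target].append(dict(zip(columns, line.split("\t"))))
        i += 1
    return out


def read_pair_file(text: str) -> List[Dict[str, object]]:
    """Parse a best/all pair file into a list of pair blocks."""
    lines = [ln for ln in text.splitlines()]
    columns = lines[0].split("\t")
    blocks: List[Dict[str, object]] = []
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        head = dict(zip(columns, lines[i].split("\t")))
        fname, fseq, fscore = lines[i + 1].split("\t")
        rname, rseq, rscore = lines[i + 2].split("\t")
        head["forward"] = {"Name": fname, "Seq": fseq, "score": fscore}
        head["reverse"] = {"Name": rname, "Seq": rseq, "score": rscore}
        blocks.append(head)
        i += 3
    return blocks


def read_comparison_file(text: str) -> Dict[str, Tuple[List[str], Dict[Tuple[str, str], str]]]:
    """Parse the comparison file into {target: (labels, {(a,b): value})}."""
    out: Dict[str, Tuple[List[str], Dict[Tuple[str, str], str]]] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        target = lines[i]
        labels = lines[i + 1].split("\t")[1:]
        values: Dict[Tuple[str, str], str] = {}
        i += 2
        for a in labels:
            row = lines[i].split("\t")
            for b, v in zip(labels, row[1:]):
                values[(row[0], b)] = v
            i += 1
        out[target] = (labels, values)
    return out
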