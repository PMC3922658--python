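# mirqpcr

Automatic, score-based design of DNA primer pairs for microRNA-specific
RT-qPCR.

## The problem

A mature microRNA is ~22 nt long — the size of a single PCR primer — so two
specific primers cannot be placed on it directly. In the microRNA-specific
RT-qPCR protocol the RNA is first polyadenylated and reverse-transcribed
with a tagged poly-T primer, which lengthens the template: the **forward
primer** matches 12–19 nt of the microRNA 5′-end (with a 5′ tail where
needed), and the **reverse primer** carries only 3–8
microRNA-complementary bases at its 3′-end, preceded by fifteen T residues
and part of the universal RT-primer tag. Designing such primers by hand is
tedious for more than a few targets; `mirqpcr` automates it and ranks every
candidate pair.

## The method

For each target the 3′-terminal A residues are removed (they are
indistinguishable from the poly(A) tail), then all candidate primers are
built and sized toward a melting temperature of **Tm = 59 °C** (nearest-
neighbor thermodynamics at 115 mM Na⁺): forwards too cold are extended
5′-ward one nucleotide at a time in the order G, A, C, G, C; forwards too
hot are trimmed from the 5′-end; reverses are extended with successive
3′-terminal letters of the RT tag.

Each primer then receives multiplicative penalty factors:

| feature (3′-anchored) | values → factor |
|---|---|
| last 2 nt | 0 or 2 weak (A/T) → 0.7; 1 weak → 1.0 |
| last 3 nt | 0 or 3 weak → 0.3; 1–2 weak → 1.0 |
| last 5 nt | 0 or 5 weak → 0.1; 1 or 4 → 0.5; 2–3 → 1.0 |
| 3′ self-annealing / dimer | ≥5 nt → 0.1; 4 nt → 0.2; less → 1.0 |
| internal self-annealing / dimer | ≥8 nt → 0.1; 7 → 0.3; 6 → 0.8; less → 1.0 |

Forward primers additionally get `L²/400` for a microRNA-specific part of
length `L`, favoring longer specific sequences. A primer's score is the
product of its factors, and a pair's score is

```
pair_score = forward_score × reverse_score
             × Fprimer_anneal × Rprimer_anneal × primer_dimer
```

where the three cross factors penalize forward-3′/reverse, reverse-3′/
forward and internal cross-annealing between the two primers. Pairs whose
specific footprints overlap by more than 2 nt on the template are excluded;
ties in pair score prefer the longer reverse primer. A pair-similarity
report supports redesign after a failed assay by quantifying how different
two candidate pairs are (forward differences weigh double).

## Worked example

Put targets in `input_miRs.txt` (FASTA-like; RNA or DNA, any case):

```
>ssc-let-7a
TGAGGTAGTAGGTTGTATAGTT
```

Run `mirqpcr` (or `mirqpcr --input my_targets.txt --out-dir results`). The
run prints

```
designed primers for 1 of 1 target(s); wrote 5 files to .
```

and writes `result_best_primer_pairs.txt`, `result_all_primer_pairs.txt`,
`result_f_primers.txt`, `result_r_primers.txt` and
`result_comparison_of_pairs.txt` — tab-separated files that open directly
in any spreadsheet program. The best-pair file contains

```
Name	Sequence	Score	Fprimer_anneal	Rprimer_anneal	Primer_dimer
ssc-let-7a	tgaggtagtaggttgtatagtt	0.32	1.0	1.0	1.0
F_1	gcagtgaggtagtaggttgt	0.64
R_1	ggtccagtttttttttttttttaactatac	0.5
```

i.e. the top-ranked pair combines the forward primer `gcagtgaggtagtaggttgt`
(16-nt specific part, score 16²/400 = 0.64, all penalty factors neutral; the
4-nt tail `gcag` lifts it to 59 °C) with the reverse primer
`ggtccagtttttttttttttttaactatac` (8 specific bases, 15 T's, 7 tag letters;
score 0.5 from its 3′-terminal 5-mer containing four weak bases). No
cross-annealing penalties apply, so the pair scores 0.64 × 0.5 = 0.32.
`result_f_primers.txt` lists all eight forward candidates with every score
factor (scores 0.64, 0.56, 0.42, 0.34, 0.25, 0.25, 0.09, 0.02); scores are
comparative within one target, not absolute predictions.

The same is available as a library:

```python
from mirqpcr import DesignConfig, design_target, parse_targets

record = parse_targets(">ssc-let-7a\nTGAGGTAGTAGGTTGTATAGTT")[0]
result = design_target(record, DesignConfig())
best = result.best_pair
print(best.forward.candidate.sequence, best.reverse.candidate.sequence,
      round(best.pair_score, 2))
```

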