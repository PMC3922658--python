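# Methods

## Design procedure

`mirqpcr` implements rule-based design of primer pairs for
microRNA-specific RT-qPCR. The procedure per target:

1. **Template normalization.** The input sequence (RNA or DNA, any case) is
   rewritten as uppercase DNA and any run of 3′-terminal A residues is
   removed: the cDNA template always carries ≥15 T's 3′ of the microRNA
   (from the tagged poly-T RT primer), so terminal A's carry no specificity.
   Targets with fewer than 12 designable bases after trimming are rejected
   individually; the rest of the batch proceeds.
2. **Forward candidates.** One candidate per specific length 12–19
   (clamped to the template). A candidate below the 59 °C melting target is
   extended by prepending nucleotides one at a time in the cycled order
   G, A, C, G, C (so a 4-letter tail reads `GCAG`, a 5-letter tail
   `CGCAG`); at most two full cycles (10 nt) are prepended. A candidate
   above the target is trimmed from its 5′-end (first value at or below
   target wins), which is recorded by the informational `five_prime_score`
   (10 = anchored at the microRNA 5′-end, 5 = trimmed inward); a candidate
   still too hot at the 12-nt floor is kept with a warning. Duplicate
   post-trim sequences are dropped, keeping the shortest specific length.
3. **Reverse candidates.** One candidate per specific length 3–8: fifteen
   T's followed by the reverse complement of the template 3′-end. The
   temperature is raised by prepending successive 3′-terminal letters of
   the RT tag (default `CAGGTCCAG`); if the tag runs out below target the
   maximal primer is kept with a warning.
4. **Scoring.** Multiplicative factors from the weak-base content of the
   3′-terminal 2/3/5-nt windows, 3′-anchored and internal self-annealing,
   and (forward only) `specific_length² / 400`. Annealing is modeled as
   two-molecule hybridization: the detectors find the longest k-mer of one
   strand whose reverse complement occurs anywhere in the other strand
   (or in a second copy of the same primer), with no self-overlap
   exclusion — a primer whose 3′-end is `TATA` therefore self-anneals with
   k = 4. Matches longer than the published penalty tables (≥6 nt
   3′-anchored, ≥9 nt internal) clamp to the strongest factor 0.1, a
   monotone extension.
5. **Pairs.** All forward × reverse combinations are kept unless their
   specific footprints overlap by more than 2 template positions (the
   published best reference pair itself overlaps by exactly 2, which fixes
   the threshold as "exclude > 2"). Pairs carry three cross-annealing
   factors and are ranked by the unrounded score product; ties prefer the
   longer reverse, then the longer forward specific part, then the
   lexicographically smaller forward sequence — a deterministic total
   order, so the whole pipeline is byte-reproducible.

## Melting-temperature model and its calibration

Primer sizing ("extend/trim until 59 °C is reached") needs a concrete Tm
model; the protocol prescribes nearest-neighbor thermodynamics at 115 mM
NaCl but not the parameter table, salt correction or strand concentrations.
These are exposed in `ThermoConfig` and were fixed by calibration: the
defaults must make the tail/trim algorithm regenerate the known-good
reference primer set for ssc-let-7a (eight forward candidates with their
`gcag`/`cgcag` tails, and the tagged reverse primers at specific lengths 8
and 4).

The calibration is strongly constraining. Exhaustive search over the
nearest-neighbor tables of Breslauer 1986, Sugimoto 1996 and SantaLucia
1997/2004 with every standard sodium correction and a wide concentration
range showed that most combinations cannot reproduce the reference set at
any threshold offset — physical duplex models tend to rank the long AT-rich
poly-T reverse primers hotter than the short GC-tailed forwards, which the
reference set contradicts for a single shared 59 °C target. One region of
parameter space is exactly feasible and is the default:

| parameter | default | note |
|---|---|---|
| parameter set | `sugimoto_1996` | duplex stacking ΔH/ΔS |
| salt correction | Owczarzy 2008 sodium correction | applied on 1/Tm |
| sodium | 115 mM | prescribed by the protocol |
| primer / template | 40 nM / 20 nM | calibration-determined |
| target | 59 °C | prescribed by the protocol |

Under these defaults every reference primer is regenerated and every
candidate's final tail is minimal (one letter fewer stays below target) —
asserted by the test suite. The Tm implementation is
`Bio.SeqUtils.MeltingTemp.Tm_NN`; tests check it within 1.5 °C against an
independently hand-typed Sugimoto/Owczarzy computation over 1,000 random
12–30-mers, plus duplex symmetry, salt monotonicity and GC-extension
monotonicity.

## Pair similarity

The redesign report scores how different two candidate pairs are. Per
primer role, a factor is the product of a 3′-agreement term (position-wise
matches in the 3′-terminal trinucleotide: 3 → 1.0, 2 → 0.7, 1 → 0.4,
0 → 0.2) and a length term `max(0.1, 1 − 0.2·|ΔL|)` on the specific-length
difference; the pair similarity is `forward² × reverse`, the squaring
giving forward differences double weight. Identical pairs score exactly
1.0. The published description fixes the ingredients (length difference,
last-three 3′ bases, double forward weight, identity → 1.0) but not the
functional form; these concrete values are this package's interpretation,
kept in `mirqpcr.config` so they can be changed, and no claim of
equivalence with any other implementation's similarity numbers is made.

## Output files

Five fixed-name tab-separated files (`result_best_primer_pairs.txt`,
`result_all_primer_pairs.txt`, `result_f_primers.txt`,
`result_r_primers.txt`, `result_comparison_of_pairs.txt`) open directly in
spreadsheet programs. Scores print at two decimals with one trailing zero
dropped (`0.5`, `1.0`); ranking always uses unrounded values. The layouts
of the forward-primer and best-pair files follow the published tables; the
all-pairs, reverse and comparison layouts extrapolate the same column
conventions. Line endings are LF by default with a `--crlf` flag.

## Numerical and degenerate-input choices

* Rounding for display is decimal half-up; all comparisons and ranking use
  full-precision floats; scores are exact products of factors.
* End-score windows that do not fit a very short sequence are neutral
  (factor 1.0); with a 15-T tract every real reverse primer is ≥18 nt, so
  this is a safety rail only.
* Ambiguity codes are rejected rather than expanded; duplicate target
  names, headerless sequence and characters outside A/C/G/T/U are hard
  parse errors with line numbers.
* The minimum designable template length (12 nt after A-trimming, the
  shortest forward specific part) and the 12-nt trimming floor are config
  fields.

## What the tests do and do not show

The deterministic pipeline is verified end-to-end against the reference
target's printed score table, best pair, and candidate sequences, and the
annealing detectors against exhaustive brute-force enumeration on 10,000
seeded random sequence pairs (lengths 8–35, the realistic primer range).
Random microRNA-like fixtures (19–25 nt, uniform base composition, seeded)
exercise parsing, candidate construction and report round-trips; they do
not emulate real microRNA base composition, family structure (single-base
paralogs), or RNA secondary structure, so passing tests say nothing about
wet-lab assay success rates — scores are comparative design heuristics, not
predictions of PCR efficiency, and validating primers still requires qPCR.

## Known limitations

* Secondary-structure handling is the heuristic two-molecule annealing
  model; no thermodynamic (ΔG) folding, no unimolecular hairpin model.
* No LNA thermodynamics (the method targets plain DNA primers).
* No off-target screening against a transcriptome or close microRNA family
  members; discriminating single-base paralogs may need a manually chosen
  shorter reverse primer from the all-pairs report.
* Tm calibration is tied to the reference design conditions; changing
  `ThermoConfig` changes which tail lengths are chosen.
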