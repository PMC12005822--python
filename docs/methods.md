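# Methods

This note records the models, parameter choices and known limitations
behind `scrca`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Ring and primer design

A repeat unit is a peptide with an explicit DNA encoding (3 nt per
residue).  The single-unit ring template is that DNA treated as a circle;
the 5′-phosphorylated linear form is the circle rotated so that its
ligation junction falls in the middle of the reverse primer's annealing
region.  Geometry (all configurable through `DesignConfig`):

| parameter   | default | meaning |
|-------------|---------|---------|
| overlap_len | 15 nt (12–25) | 5′ extension on each primer = vector terminal homology |
| anneal_len  | 20 nt   | 3′ annealing region of each primer |
| min_half    | 8 nt    | minimum reverse-primer bases on each side of the junction |
| split_half  | 12 nt   | half-width of dedicated split oligos in large rings |

With a 20-nt annealing region the reverse primer covers 10 nt on each side
of the junction, so it doubles as the split oligo that templates ring
ligation.  The forward primer's 3′ region matches the first `anneal_len`
bases of the linear form (plus strand); the reverse primer's 3′ region is
the reverse complement of (10-nt suffix + 10-nt prefix).  A GC-based
melting estimate (Wallace rule below 14 nt, length-corrected GC formula
above) is logged for each annealing region as a sanity check only; no
nearest-neighbor thermodynamics are attempted.

**Mixed-base templates.**  When IUPAC codes would fall inside a primer
window, the circle is rotated in 3-nt steps (codon-preserving, so the
amplicon reading frame is unchanged) until both windows are concrete; the
smallest such rotation is chosen, making the design deterministic.  The
rotation offset is recorded as the `junction` field and can be undone to
compare against the unrotated unit.  If no codon-phased rotation clears
the windows the design is refused rather than silently placing a primer
over a degenerate site.

**Large rings** concatenate unit DNAs; the reverse primer spans the
junction between the last and first unit and each other inter-unit
junction receives a dedicated 24-nt split oligo (12 nt per side), the
geometry of the published two-unit split DNA.  Mixed-base units are not
supported in large rings (rotation would move the recorded unit
boundaries).

**Block-copolymer primers.**  For simultaneous two-fragment cloning, the
A-block reverse primer's 5′ extension is the reverse complement of the
first `overlap_len` nt of the B-block amplicon, so the two amplicons share
exactly that much terminal homology; A-forward and B-reverse carry the
vector homologies and B-forward has no extension.  Because a repeat-unit
prefix recurs along the tract, the junction can map to several loci; this
is reported as a warning (assembly still checks only terminal homology,
as the chemistry does).

## Amplicon pool model

`simulate_rca` draws, per molecule: a repeat number from a named
distribution; one concrete expansion of the template (uniform per mixed
base site) that fills *all* repeats of that molecule — the processivity
assumption, since a single circle is copied continuously; and an end
state.  Defaults:

- repeat distribution: truncated geometric, success 0.3, support 1–20.
  The family is a named parameter because no empirical abundance profile
  of RCA pools is available to fit; the geometric shape encodes that each
  additional lap of the circle is completed with constant probability.
- `p_ss_end` = 0.2: probability a molecule is an incomplete intermediate,
  split evenly between a 3′ and a 5′ single-stranded end of `ss_len`
  (default 20 nt).  Incomplete molecules lack the overlap extension at the
  affected end, so they cannot be cloned alone — only their annealed
  hybrids can.  The value is a modelling choice (it controls the hybrid
  rate downstream) and is exposed in configuration.

Ladders are exact: length(n) = n·ring_size + total overlap bases.  Gel
mobility is not modelled; size selection filters on true lengths, with the
band→repeat-number assignment using a nearest-rung rule within a relative
tolerance (default 5 %).

## Hybrid (block-copolymer) formation

Incomplete-end molecules pair 3′-tail against 5′-gap.  Physically the two
single strands anneal anywhere in the shared periodic repeat; the model
reduces this to a backbone comparison over a 15-nt window of the joining
terminal units with up to 3 mismatches allowed — enough for two library
variants that differ only at one mixed-base codon inside the window to
hybridize, which is how block-copolymer mutants arise.  Joins happen with
probability `p_anneal` per randomly paired compatible couple; the child
concatenates both parents' unit lists and both outer overlaps, so total
repeat count is conserved exactly.

## Assembly and verification

Seamless assembly is modelled as exact terminal homology of `overlap_len`
(the chemistry tolerates rare mismatches; none are modelled, as no
mismatch data exist to calibrate against).  All fragment orders and
orientations are searched (≤ 2 fragments), so orientation control is an
outcome of the asymmetric homologies, not an input convention.  ORF
verification translates from the vector's start codon through the insert
and requires the N-tag prefix, the C-tag suffix and no internal stop; a
1-nt indel surfaces as a premature stop or lost tag.  The positivity rate
is the product of the colony-PCR and sequencing pass fractions, in
percent.

## Library statistics

Library size is the product of per-position degeneracies; enumeration is
lexicographic and duplicate-free.  Synthesis simulation draws every mixed
base site independently (per-site bias tables allowed; uniform default)
and realizes counts as one multinomial draw over the induced joint
distribution, which keeps 10⁶-molecule simulations at ~1728 bins cheap
and exact.  In diversity reports, percent abundances and occupancy use
the mutant total as denominator while the mutant/error split uses all
counted sequences — the two denominators of the standard abundance and
error plots.  The median is taken over observed variants (count ≥ 1);
never-seen variants are reported separately as missing.

## Read analysis

Only terminal repeat units are analyzed — the middle of a repetitive
amplicon is treated as unreliable, and no attempt is made to phase
internal repeats.  Reads are anchored by the known primer-derived flanks
with ≤ 1 mismatch (alignment-free: the flanks are short, fixed and
designed in-house), tried on both strands; the unit after the 5′ flank
and before the 3′ flank must fit inside a 90-nt trusted end window.
Classification is purely sequence-based (a variant's counts never affect
its class): a unit is a *mutant* iff it matches the design template at
every position, exact at fixed positions and within the IUPAC set at
mixed-base positions; substitutions at fixed positions, out-of-set bases
at design positions, and length variants are *errors*.  Variants with
fewer than 6 counts at both ends are dropped (low-count calls are
unreliable) but reported.  5′/3′ concordance is the Pearson correlation
of the two count vectors over retained variants.

## Charge/hydropathy screening

Net charge is a Henderson–Hasselbalch sum over D, E, C, Y, H, K, R side
chains and both termini.  The shipped pKa set is the EMBOSS-style table
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1); users can substitute any named table.  Published per-mutant
charge figures were produced by external calculators whose constants are
not printed, so third-decimal agreement with any specific source is not a
goal — rankings, which are driven by histidine content between pH 6.5 and
7.4, are insensitive to the table choice.  Hydropathy is the whole-
sequence Kyte–Doolittle mean (GRAVY), not a sliding window, matching the
one-value-per-mutant use.  Ranking sorts by |Δcharge| descending with
lexicographic id tie-breaks; cysteine-containing and block-copolymer
mutants can be excluded (aggregation risk and next-round template
complexity respectively).  No phase-separation or transition-temperature
prediction is attempted: the screening step mechanized here is exactly
the sequence-only computation that precedes purification.

## Synthetic data

The read generator emulates the platform's amplicon sequencing input:
flank + n×unit + flank (default n = 5), random strand per read, i.i.d.
per-base substitution errors (default 0.3 %), constant quality strings.
It does **not** emulate instrument quality profiles, indels (refused if
requested), chimeric reads, coverage dips from poor cluster formation in
the repeat interior, or adapter remnants — so passing tests demonstrate
correctness of the accounting, not robustness to every real-world
artifact.  Unit DNAs for the canonical study system are deterministic
reverse-translated stand-ins whose codon phases match the published
primer sequences; the `m10` winner unit is a synthetic stand-in with
histidine guests (the composition class the first screening round
selects).  All randomness in a fixture flows from one seed, and the truth
tables are sufficient to score any recovery statistic without re-reading
the FASTQ.

## Problem sizes and numerical choices

The test suite and acceptance script use: 10-rung ladders with ±1 %
multiplicative band noise for ring-size recovery; 36 pipeline combinations
(3 units × n = 1…12); 10⁶ molecules for synthesis simulation (multinomial,
so depth is nearly free); 50 000 reads at 0.3 % substitution with 16
Dirichlet-planted variants for abundance recovery, judged at ±3 standard
errors with the read count as the effective number of independent draws
(the 5′ and 3′ units of one read share its template draw and are not
independent).  Ties and degenerate inputs: empty size selections warn and
return empty pools; zero-variance concordance returns NaN with a warning;
degenerate-expansion requests above the cap (default 10⁶) are refused
with the analytic count reported.

## Known limitations

- No polymerase kinetics or branch-migration chemistry; the pool model is
  phenomenological.
- No oligo secondary-structure/hairpin screening or vendor synthesis
  constraints.
- Gel electrophoresis is represented only by true-length windows.
- Real libraries show vendor-specific mixed-base synthesis bias; the bias
  table is an input, not a prediction.
- Published wet-lab success rates and library statistics depend on
  unmodelled failure modes (transformation, cluster formation, vendor
  bias) and are deliberately out of scope.
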