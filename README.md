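# scrca

Design and in-silico simulation toolkit for **seamless cloning of
rolling-circle amplicons (SCRCA)** — a one-pot route to repetitive-sequence
genes encoding protein polymers (elastin-like and resilin-like
polypeptides, and their copolymers and mutant libraries).

## The problem

Genes encoding repeat polypeptides such as (VGVPG)ₙ elastin-like polymers
are notoriously hard to synthesize: restriction sites and unique PCR
priming sequences are scarce inside a repeat tract.  Rolling-circle
amplification (RCA) of a circularized ssDNA oligo encoding one repeat unit
produces a ladder of concatemer genes in a single isothermal reaction.  The
SCRCA trick is to run that RCA with forward/reverse primers carrying 15-nt
5′ **overlap extensions** matching the linearized expression vector, so any
rung excised from the ladder drops straight into the vector by seamless
(overlap-directed) cloning — insertion site and orientation both forced by
the homology.  Mixed-base (IUPAC) codons in the ring oligo turn the same
reaction into a repeat-unit mutant library for directed evolution.

This package implements the computational substance of that platform, for
people designing such constructs or analyzing the resulting libraries:

- `scrca.seqcore` — sequence types, degenerate-codon algebra
  (e.g. NDT → 12 amino acids, YWY → {F, Y, L, H}),
  Henderson–Hasselbalch net charge, Kyte–Doolittle GRAVY;
- `scrca.construct_design` — ring templates, junction-spanning reverse
  primer (= split oligo), multi-unit large rings, block-copolymer primer
  sets, next-round mixed-base templates;
- `scrca.rca_sim` — the theoretical amplicon ladder
  (length = *n*·ring_size + overlap bases), band→repeat-number assignment,
  and stochastic pool simulation with incomplete-end intermediates;
- `scrca.assembly_sim` — in-silico seamless assembly (1–2 fragments),
  hybrid block-copolymer formation from incomplete-end amplicons, ORF/tag
  verification, positivity-rate bookkeeping;
- `scrca.library_stats` — library enumeration (three NDT sites → 1728
  variants), ideal abundance (100 %/K), synthesis-bias simulation and
  diversity reports;
- `scrca.repeat_reads` — terminal-repeat-unit analysis of sequencing reads
  (anchor by primer flanks, 90-bp end windows, count ≥ 6 filter,
  mutant/error classification, 5′/3′ concordance, frequency matrices);
- `scrca.screen` — ranking of library mutants by pH-induced net-charge
  shift (default pH 7.4 vs 6.5) with cysteine/block filters, ELP-fraction
  and guest-residue composition metrics;
- `scrca.fixtures` — deterministic synthetic units, vectors and
  error-bearing sequencing reads with truth tables.

## The core quantities

For a ring of size *s* nt amplified with primers carrying *o*₁/*o*₂-nt
overlap extensions, the amplicon pool is a ladder with

    length(n) = n · s + o₁ + o₂        (n = 1, 2, 3, …)

A mixed-base template with per-position degeneracies *d*ᵢ defines a library
of K = ∏ᵢ *d*ᵢ nucleotide variants with ideal per-variant abundance
100 %/K (0.058 % for K = 1728).  Candidate mutants are scored by

    Δq = q(pH 7.4) − q(pH 6.5),  q(pH) = Σ over ionizable groups of
         ±1 / (1 + 10^±(pH − pKa))

and by GRAVY (mean Kyte–Doolittle hydropathy).

## Worked example

```python
from scrca.construct_design import design_ring
from scrca.fixtures import elp_unit, make_toy_vector
from scrca.rca_sim import predict_ladder, simulate_rca, size_select
from scrca.assembly_sim import infusion_assemble
from scrca.screen import build_records

vector = make_toy_vector()                 # MK … WPTHHHHHH expression tags
design = design_ring(elp_unit())           # (VGVPG)x6 unit, 90-nt ring
print(design.fwd_primer)                   # GATATACATATGAAAGTTGGTGTTCCAGGTGTTGG
print(design.rev_primer)                   # ATGATGAGTCGGCCAGAACACCAACACCTGGAACA
print(list(predict_ladder(design, 6).entries))
# [(1, 120), (2, 210), (3, 300), (4, 390), (5, 480), (6, 570)]

pool = simulate_rca(design, n_molecules=1000, p_ss_end=0.0, seed=1)
six = size_select(pool, target_n=6)        # "cut the 570-bp band"
rec = infusion_assemble([six.members[0][0]], vector).recombinants[0]
print(rec.reading_frame_ok, rec.tags_found)
# True ('MK', 'WPTHHHHHH')

r = build_records([rec])[0]
print(f"{r.charge_a:+.3f} {r.charge_b:+.3f} {r.delta_charge:+.3f} {r.gravy:+.3f}")
# -0.059 -0.007 -0.053 +1.200
```

Both primers are 35 nt: a 15-nt vector-homology extension plus a 20-nt
annealing region; the reverse primer spans the ring junction (10 nt each
side) and doubles as the split oligo for cyclization.  The six-repeat rung
of the ladder sits at 6·90 + 30 = 570 bp, and the assembled construct
translates as MK–(VGVPG)₃₆–WPTHHHHHH with an intact frame.  The E6
homopolymer barely changes charge between pH 7.4 and 6.5 (|Δq| ≈ 0.05,
termini only) — histidine-guest mutants from the NDT library shift much
more, which is exactly what the screening module ranks on.

A `scrca` console script exposes the same steps
(`scrca design`, `ladder`, `simulate`, `assemble`, `library-stats`,
`analyze-reads`, `screen`, `make-fixtures`); see `scrca --help`.

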