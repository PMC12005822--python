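"""In-silico design of SCRCA wet-ware.

Rolling-circle amplification of a circular ssDNA template encoding one
repeat unit yields, with overlap-bearing primers, a ladder of
repetitive-sequence genes ready for seamless cloning.  This module designs
the parts:

* single-unit ring templates with a junction-spanning reverse primer that
  doubles as the split oligo for ring ligation;
* multi-unit ("large") rings with dedicated split oligos over the
  inter-unit junctions;
* forward/reverse RCA primers carrying 5' overlap extensions matching the
  linearized vector termini;
* primer sets for simultaneous two-fragment (block-copolymer) cloning;
* next-round mixed-base templates for directed-evolution libraries.

Designs are deterministic given a configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

from . import published
from .seqcore import (
    IUPAC_DNA,
    DegenSeq,
    NucSeq,
    PepSeq,
    gc_fraction,
    melting_estimate,
    revcomp,
    translate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignError",
    "RepeatUnit",
    "VectorSpec",
    "DesignConfig",
    "RingDesign",
    "BlockPrimerSet",
    "BlockDesign",
    "ECOLI_PREFERRED_CODONS",
    "reverse_translate",
    "design_ring",
    "design_large_ring",
    "design_block_primers",
    "design_next_round",
    "junction_homology",
]


class DesignError(ValueError):
    """A requested design is geometrically or combinatorially impossible."""


#: Most-used codon per amino acid in E. coli, the default reverse-translation
#: policy.  A user-supplied table always takes precedence.
ECOLI_PREFERRED_CODONS: dict[str, str] = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


def reverse_translate(p: str, codon_table: dict[str, str] | None = None) -> NucSeq:
    """Deterministic reverse translation using one codon per amino acid.

    The result round-trips: ``translate(reverse_translate(p)) == p``.
    GC fraction of the output is logged as a design diagnostic.
    """
    pep = p if isinstance(p, PepSeq) else PepSeq(p)
    table = codon_table or ECOLI_PREFERRED_CODONS
    try:
        dna = NucSeq("".join(table[aa] for aa in pep))
    except KeyError as e:
        raise DesignError(f"no codon for residue {e.args[0]!r}") from None
    logger.debug("reverse_translate: %d nt, GC %.2f", len(dna), gc_fraction(dna))
    return dna


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat monomer: peptide, encoding DNA, optional mixed-base codons.

    At degenerate codons (IUPAC codes in ``dna``) the ``peptide`` letter is
    a placeholder (typically the parent's residue); at every concrete codon
    the DNA must translate to the stated residue.
    """

    name: str
    peptide: PepSeq
    dna: NucSeq | DegenSeq

    def __post_init__(self):
        pep = PepSeq(self.peptide)
        dna = self.dna if isinstance(self.dna, (NucSeq, DegenSeq)) else (
            NucSeq(self.dna) if set(str(self.dna).upper()) <= set("ACGT") else DegenSeq(self.dna)
        )
        object.__setattr__(self, "peptide", pep)
        object.__setattr__(self, "dna", dna)
        if len(dna) != 3 * len(pep):
            raise DesignError(
                f"unit {self.name!r}: dna length {len(dna)} != 3 x peptide length {len(pep)}"
            )
        for i in range(len(pep)):
            codon = dna[3 * i : 3 * i + 3]
            if any(len(IUPAC_DNA[c]) > 1 for c in codon):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if str(translate(codon)) != pep[i]:
                    raise DesignError(
                        f"unit {self.name!r}: codon {i} ({codon}) does not encode {pep[i]}"
                    )

    @property
    def is_degenerate(self) -> bool:
        return isinstance(self.dna, DegenSeq) and any(
            d > 1 for d in self.dna.site_degeneracies
        )

    @property
    def degenerate_codons(self) -> tuple[int, ...]:
        """0-based indices of codons containing mixed bases."""
        if not isinstance(self.dna, DegenSeq):
            return ()
        return tuple(
            sorted({p // 3 for p in self.dna.degenerate_positions()})
        )

    def rotated(self, codon_offset: int, name: str | None = None) -> "RepeatUnit":
        """Unit re-phased by a whole number of codons (circular template)."""
        r = (codon_offset % len(self.peptide)) * 3
        dna = self.dna.rotate(r) if r else self.dna
        pep = self.peptide[codon_offset % len(self.peptide):] + self.peptide[: codon_offset % len(self.peptide)]
        return RepeatUnit(name or f"{self.name}~rot{codon_offset}", PepSeq(pep), dna)


@dataclass(frozen=True)
class VectorSpec:
    """Termini of a linearized expression vector around the insertion site.

    ``upstream_end`` must end with the in-frame codons of ``n_term_tag``
    (start codon at ``cds_offset``); ``downstream_end`` must begin with the
    codons of ``c_term_tag`` followed by a stop.
    """

    upstream_end: NucSeq
    downstream_end: NucSeq
    n_term_tag: PepSeq
    c_term_tag: PepSeq
    cds_offset: int

    def __post_init__(self):
        object.__setattr__(self, "upstream_end", NucSeq(self.upstream_end))
        object.__setattr__(self, "downstream_end", NucSeq(self.downstream_end))
        object.__setattr__(self, "n_term_tag", PepSeq(self.n_term_tag))
        object.__setattr__(self, "c_term_tag", PepSeq(self.c_term_tag))
        up_cds = self.upstream_end[self.cds_offset :]
        if len(up_cds) != 3 * len(self.n_term_tag):
            raise DesignError("cds_offset inconsistent with N-terminal tag length")
        if str(translate(up_cds)) != str(self.n_term_tag):
            raise DesignError("upstream terminus does not encode the N-terminal tag")
        need = 3 * len(self.c_term_tag)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            down_pep = str(translate(self.downstream_end[: need + 3]))
        if down_pep[: len(self.c_term_tag)] != str(self.c_term_tag):
            raise DesignError("downstream terminus does not encode the C-terminal tag")
        if not down_pep.endswith("*"):
            raise DesignError("no stop codon after the C-terminal tag")

    @classmethod
    def with_tags(
        cls,
        n_term: str = published.N_TERM_TAG,
        c_term: str = published.C_TERM_TAG,
        codon_table: dict[str, str] | None = None,
    ) -> "VectorSpec":
        """Minimal vector termini encoding the tags in frame.

        The default MK/WPTHHHHHH termini reproduce the published
        inverse-PCR primer sequences of the platform's pET-derived vector.
        """
        n_pep, c_pep = PepSeq(n_term), PepSeq(c_term)
        if "*" in n_pep or "*" in c_pep:
            raise DesignError("tags must not contain stop symbols")
        prefix = "GTTTAACTTTAAGAAGGAGATATACAT"  # ribosome-binding region
        if (str(n_pep), str(c_pep)) == (published.N_TERM_TAG, published.C_TERM_TAG):
            n_dna = "ATGAAA"
            c_dna = published.VECTOR_C_TERM_PRIMER
        else:
            n_dna = str(reverse_translate(n_pep, codon_table))
            c_dna = str(reverse_translate(c_pep, codon_table))
        down = c_dna + "TAA" + "GCTGAGCAATAACTAGCATAA"
        return cls(
            upstream_end=NucSeq(prefix + n_dna),
            downstream_end=NucSeq(down),
            n_term_tag=n_pep,
            c_term_tag=c_pep,
            cds_offset=len(prefix),
        )


@dataclass(frozen=True)
class DesignConfig:
    """Geometry of a ring/primer design.

    overlap_len
        Length of the 5' overlap extensions (vector homology), 12-25 nt.
    anneal_len
        Length of each primer's 3' annealing region.
    min_half
        Minimum bases of the reverse primer on each side of the ring
        junction it spans.
    split_half
        Bases on each side of an inter-unit junction covered by a
        dedicated split oligo in large rings.
    """

    overlap_len: int = 15
    anneal_len: int = 20
    min_half: int = 8
    split_half: int = 12
    vector: VectorSpec | None = None
    codon_table: dict[str, str] | None = None

    def __post_init__(self):
        if not 12 <= self.overlap_len <= 25:
            raise DesignError("overlap_len must be in 12..25")
        h1 = self.anneal_len // 2
        if min(h1, self.anneal_len - h1) < self.min_half:
            raise DesignError("anneal_len too short for min_half on each junction side")


@dataclass(frozen=True)
class RingDesign:
    """A circular ssDNA template with its primers, overlaps and split oligos.

    ``linear`` is the 5'-phosphorylated linear form actually synthesized:
    the ring rotated so its ligation junction lies between the last and
    first base, centred under the reverse primer's annealing region.
    ``junction`` records the rotation offset into the original unit DNA.
    Overlap extensions are stored in plus-strand sense (``rev_overlap`` is
    the sequence appearing at the amplicon 3' end; the reverse primer
    carries its reverse complement).
    """

    units: tuple[RepeatUnit, ...]
    linear: NucSeq | DegenSeq
    junction: int
    fwd_primer: NucSeq | DegenSeq
    rev_primer: NucSeq | DegenSeq
    fwd_anneal: NucSeq
    rev_anneal: NucSeq
    fwd_overlap: NucSeq
    rev_overlap: NucSeq
    split_oligos: tuple[NucSeq, ...]
    overlap_len: int
    anneal_len: int
    vector: VectorSpec

    @property
    def ring(self) -> NucSeq | DegenSeq:
        cls = DegenSeq if isinstance(self.linear, DegenSeq) else NucSeq
        return cls(self.linear, circular=True)

    @property
    def ring_size(self) -> int:
        return len(self.linear)

    @property
    def unit(self) -> RepeatUnit:
        return self.units[0]

    @property
    def split_oligo(self) -> NucSeq:
        """The (first) split oligo; equals the reverse primer for single-unit rings."""
        return self.split_oligos[0]

    @property
    def is_degenerate(self) -> bool:
        return isinstance(self.linear, DegenSeq) and any(
            d > 1 for d in self.linear.site_degeneracies
        )

    def template_unit(self) -> RepeatUnit:
        """The repeat monomer in amplicon phase (rotated by the junction offset)."""
        if len(self.units) == 1:
            return self.units[0].rotated(self.junction // 3, name=self.units[0].name)
        pep = PepSeq("".join(str(u.peptide) for u in self.units))
        name = "+".join(u.name for u in self.units)
        return RepeatUnit(name, pep, self.linear)

    def oligos(self) -> list[tuple[str, str]]:
        """All designed oligos as (name, sequence) pairs, FASTA-ready."""
        out = [
            ("ring_linear", str(self.linear)),
            ("fwd_primer", str(self.fwd_primer)),
            ("rev_primer", str(self.rev_primer)),
        ]
        for i, s in enumerate(self.split_oligos):
            out.append((f"split_oligo_{i + 1}", str(s)))
        return out

    def to_dict(self) -> dict:
        return {
            "units": [u.name for u in self.units],
            "ring_size": self.ring_size,
            "junction": self.junction,
            "linear": str(self.linear),
            "fwd_primer": str(self.fwd_primer),
            "rev_primer": str(self.rev_primer),
            "fwd_overlap": str(self.fwd_overlap),
            "rev_overlap": str(self.rev_overlap),
            "split_oligos": [str(s) for s in self.split_oligos],
            "overlap_len": self.overlap_len,
            "anneal_len": self.anneal_len,
        }


def _window_concrete(dna: str, start: int, length: int) -> bool:
    L = len(dna)
    return all(dna[(start + i) % L] in "ACGT" for i in range(length))


def _choose_rotation(dna, anneal_len: int, h1: int) -> int:
    """Smallest codon-stepped rotation with concrete primer windows.

    Both primer annealing windows lie within the contiguous circular arc
    ``[r - h1, r + anneal_len)``; a rotation is acceptable when that arc
    contains no mixed-base site.  Rotating by whole codons keeps the
    amplicon reading frame intact.
    """
    L = len(dna)
    if not isinstance(dna, DegenSeq) or not dna.degenerate_positions():
        return 0
    for r in range(0, L, 3):
        if _window_concrete(dna, (r - h1) % L, h1 + anneal_len):
            return r
    raise DesignError(
        "no codon-phased junction placement avoids the mixed-base sites; "
        "shorten anneal_len or move degenerate codons"
    )


def _build_design(
    units: tuple[RepeatUnit, ...],
    dna,
    cfg: DesignConfig,
    vector: VectorSpec,
    split_oligos_fn,
) -> RingDesign:
    L = len(dna)
    h1 = cfg.anneal_len // 2
    h2 = cfg.anneal_len - h1
    if L < cfg.anneal_len + h1:
        raise DesignError(f"template too short ({L} nt) for anneal_len {cfg.anneal_len}")
    r = _choose_rotation(dna, cfg.anneal_len, h1)
    linear = dna.rotate(r) if r else dna
    fwd_anneal = NucSeq(linear[:cfg.anneal_len])
    rev_anneal = revcomp(NucSeq(linear[-h1:] + linear[:h2]))
    fwd_overlap = NucSeq(vector.upstream_end[-cfg.overlap_len :])
    rev_overlap = NucSeq(vector.downstream_end[: cfg.overlap_len])
    fwd_primer = NucSeq(fwd_overlap + fwd_anneal)
    rev_primer = NucSeq(revcomp(rev_overlap) + rev_anneal)
    logger.debug(
        "primer anneal Tm estimates: fwd %.1f C, rev %.1f C",
        melting_estimate(fwd_anneal),
        melting_estimate(rev_anneal),
    )
    design = RingDesign(
        units=units,
        linear=linear,
        junction=r,
        fwd_primer=fwd_primer,
        rev_primer=rev_primer,
        fwd_anneal=fwd_anneal,
        rev_anneal=rev_anneal,
        fwd_overlap=fwd_overlap,
        rev_overlap=rev_overlap,
        split_oligos=split_oligos_fn(linear, rev_primer),
        overlap_len=cfg.overlap_len,
        anneal_len=cfg.anneal_len,
        vector=vector,
    )
    return design


def design_ring(
    unit: RepeatUnit,
    cfg: DesignConfig | None = None,
    vector: VectorSpec | None = None,
) -> RingDesign:
    """Design a single-unit ring template and its RCA primer pair.

    The reverse primer anneals across the ligation junction of the linear
    ssDNA (>= ``min_half`` nt each side) and therefore doubles as the split
    oligo for cyclization.  Mixed-base units are rotated (by whole codons)
    so that no primer window covers a degenerate site; the emitted ring is
    then a :class:`~scrca.seqcore.DegenSeq` whose concrete positions are
    identical to the parent unit's.
    """
    cfg = cfg or DesignConfig()
    vector = vector or cfg.vector or VectorSpec.with_tags()
    return _build_design(
        (unit,), unit.dna, cfg, vector, lambda linear, rev: (rev,)
    )


def design_large_ring(
    units: list[RepeatUnit] | tuple[RepeatUnit, ...],
    cfg: DesignConfig | None = None,
    vector: VectorSpec | None = None,
) -> RingDesign:
    """Design a multi-unit ("large") ring for copolymer genes.

    The circular template concatenates the unit DNAs.  The reverse primer
    spans the junction between the last and first unit; every other
    inter-unit junction gets a dedicated split oligo (reverse complement
    of ``split_half`` nt on each side), matching the published 24-mer
    split DNA geometry for the two-unit RLP+ELP ring.
    """
    cfg = cfg or DesignConfig()
    vector = vector or cfg.vector or VectorSpec.with_tags()
    units = tuple(units)
    if len(units) < 2:
        raise DesignError("a large ring needs at least 2 units")
    degen = any(u.is_degenerate for u in units)
    seq_cls = DegenSeq if degen else NucSeq
    dna = seq_cls("".join(str(u.dna) for u in units))

    def _splits(linear, _rev):
        # junction positions in the (unrotated) concatenation; large rings
        # are only rotated when degenerate, in which case concrete windows
        # were already verified, so positions are recomputed on `linear`.
        out = []
        pos = 0
        for u in units[:-1]:
            pos += len(u.dna)
            left = linear[pos - cfg.split_half : pos]
            right = linear[pos : pos + cfg.split_half]
            out.append(revcomp(NucSeq(left + right)))
        return tuple(out)

    if degen:
        raise DesignError("degenerate units are not supported in large rings")
    return _build_design(units, dna, cfg, vector, _splits)


@dataclass(frozen=True)
class BlockPrimerSet:
    """Two primer pairs for simultaneous two-fragment seamless cloning."""

    a_fwd: NucSeq
    a_rev: NucSeq
    b_fwd: NucSeq
    b_rev: NucSeq
    junction: NucSeq
    overlap_len: int


@dataclass(frozen=True)
class BlockDesign:
    """Block-cloning primers plus the re-overlapped per-block ring designs."""

    primers: BlockPrimerSet
    block_a: RingDesign
    block_b: RingDesign


def design_block_primers(
    block_a: RingDesign,
    block_b: RingDesign,
    vector: VectorSpec | None = None,
    overlap_len: int = 15,
) -> BlockDesign:
    """Primer sets so that A- and B-block amplicons assemble as vector-A-B.

    The A reverse primer's 5' extension is the reverse complement of the
    first ``overlap_len`` nt of the B amplicon, so the two blocks share
    exactly that much terminal homology at their designed junction; A's
    forward and B's reverse primers carry the vector homologies.  B's
    forward primer has no extension (its 5' end *is* the junction).
    """
    if overlap_len < 12:
        raise DesignError("block overlap_len must be >= 12")
    vector = vector or block_a.vector
    junction = NucSeq(block_b.linear[:overlap_len])
    # ambiguity screen: the junction should map to a unique locus per unit
    for design, label in ((block_a, "A"), (block_b, "B")):
        doubled = str(design.linear) * 2
        if doubled.count(str(junction)) > len(design.units):
            warnings.warn(
                f"junction overlap maps to multiple loci in block {label}; "
                "assembly order may be ambiguous"
            )
    a_fwd = NucSeq(vector.upstream_end[-overlap_len:] + block_a.fwd_anneal)
    a_rev = NucSeq(revcomp(junction) + block_a.rev_anneal)
    b_fwd = NucSeq(block_b.fwd_anneal)
    b_rev = NucSeq(revcomp(NucSeq(vector.downstream_end[:overlap_len])) + block_b.rev_anneal)
    primers = BlockPrimerSet(a_fwd, a_rev, b_fwd, b_rev, junction, overlap_len)
    new_a = dataclasses.replace(
        block_a,
        fwd_primer=a_fwd,
        rev_primer=a_rev,
        fwd_overlap=NucSeq(vector.upstream_end[-overlap_len:]),
        rev_overlap=junction,
        overlap_len=overlap_len,
    )
    new_b = dataclasses.replace(
        block_b,
        fwd_primer=b_fwd,
        rev_primer=b_rev,
        fwd_overlap="",  # the B amplicon starts directly at its repeat tract
        rev_overlap=NucSeq(vector.downstream_end[:overlap_len]),
        overlap_len=overlap_len,
    )
    return BlockDesign(primers, new_a, new_b)


def design_next_round(
    winner: RepeatUnit,
    new_positions: list[int] | tuple[int, ...],
    degen_codon: str,
) -> RepeatUnit:
    """Next-round library template: fix the winner everywhere except
    ``new_positions`` (0-based codon indices), which receive ``degen_codon``.

    Mirrors deriving an m10-3YWY-style template from a first-round winner.
    """
    codon = DegenSeq(degen_codon)
    if len(codon) != 3:
        raise DesignError("degenerate codon must be 3 nt")
    positions = tuple(sorted(set(int(i) for i in new_positions)))
    if not positions:
        return winner
    taken = set(winner.degenerate_codons)
    clash = taken.intersection(positions)
    if clash:
        raise DesignError(f"positions already degenerate in the winner: {sorted(clash)}")
    if positions[0] < 0 or positions[-1] >= len(winner.peptide):
        raise DesignError("codon index out of range")
    bases = list(str(winner.dna))
    for i in positions:
        bases[3 * i : 3 * i + 3] = list(str(codon))
    return RepeatUnit(
        f"{winner.name}-{len(positions)}{codon}",
        winner.peptide,
        DegenSeq("".join(bases)),
    )


def junction_homology(end_seq: str, start_seq: str) -> int:
    """Length of the longest suffix of ``end_seq`` equal to a prefix of
    ``start_seq`` — the terminal homology seamless cloning would use."""
    a, b = str(end_seq).upper(), str(start_seq).upper()
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        if a[-k:] == b[:k]:
            best = k
    return best
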