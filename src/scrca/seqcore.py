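"""Sequence primitives for repetitive-gene design.

This module provides the small alphabet-checked sequence types the rest of
the package is built on (concrete DNA, IUPAC-degenerate DNA, peptides),
degenerate-codon algebra (expansion, encoded amino-acid sets), and the two
peptide physicochemistry calculations used for mutant screening:

* net charge at a given pH, as a Henderson–Hasselbalch sum over ionizable
  side chains and both termini;
* mean hydropathy (GRAVY) on the Kyte–Doolittle scale.

Translation and reverse complement delegate to Biopython; the sequence
types here are thin ``str`` subclasses so they interoperate with ordinary
string code (slicing returns plain ``str``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "DegeneracyCapError",
    "NucSeq",
    "DegenSeq",
    "PepSeq",
    "PkaTable",
    "DEFAULT_PKA",
    "KYTE_DOOLITTLE",
    "IUPAC_DNA",
    "revcomp",
    "translate",
    "expand_degenerate",
    "encoded_amino_acids",
    "net_charge",
    "mean_hydropathy",
    "gc_fraction",
    "melting_estimate",
    "read_fasta",
    "write_fasta",
]

DNA_BASES = "ACGT"

#: IUPAC nucleotide ambiguity codes mapped to the concrete bases they denote.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"


class AlphabetError(ValueError):
    """A sequence contained characters outside its declared alphabet."""


class DegeneracyCapError(ValueError):
    """A degenerate expansion would exceed the configured cap."""

    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(
            f"degenerate expansion has {count} members, exceeding cap {cap}"
        )


class NucSeq(str):
    """Concrete DNA sequence over {A,C,G,T}.

    ``circular=True`` marks a circularized molecule (an ssDNA ring).  Two
    circular sequences are rotations of one another iff their
    :meth:`canonical` forms are equal; plain equality stays positional so
    that linearized forms with a defined junction compare predictably.
    """

    __slots__ = ("circular",)
    circular: bool

    def __new__(cls, bases, circular: bool = False) -> "NucSeq":
        s = str(bases).upper()
        _check_alphabet(s, DNA_BASES, "nucleotide")
        obj = super().__new__(cls, s)
        obj.circular = bool(circular)
        return obj

    def rotate(self, offset: int) -> "NucSeq":
        """Rotate so the base at ``offset`` becomes position 0."""
        offset %= len(self)
        return type(self)(self[offset:] + self[:offset], circular=self.circular)

    def canonical(self) -> "NucSeq":
        """Lexicographically minimal rotation (identity if linear)."""
        if not self.circular:
            return self
        return min(self.rotate(i) for i in range(len(self)))


class DegenSeq(str):
    """DNA sequence over the 15 IUPAC codes, e.g. a mixed-base ring template."""

    __slots__ = ("circular",)
    circular: bool

    def __new__(cls, bases, circular: bool = False) -> "DegenSeq":
        s = str(bases).upper()
        _check_alphabet(s, "".join(IUPAC_DNA), "IUPAC nucleotide")
        obj = super().__new__(cls, s)
        obj.circular = bool(circular)
        return obj

    rotate = NucSeq.rotate

    @property
    def site_degeneracies(self) -> tuple[int, ...]:
        """Number of concrete bases admitted at each position (N=4, D=3, ...)."""
        return tuple(len(IUPAC_DNA[c]) for c in self)

    @property
    def expansion_count(self) -> int:
        """Total number of concrete sequences = product of site degeneracies."""
        return math.prod(self.site_degeneracies)

    def degenerate_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self) if len(IUPAC_DNA[c]) > 1)


class PepSeq(str):
    """Peptide over the 20 one-letter amino acids (plus ``*`` for a stop)."""

    __slots__ = ()

    def __new__(cls, residues) -> "PepSeq":
        s = str(residues).upper()
        _check_alphabet(s, AA_LETTERS + STOP, "amino acid")
        return super().__new__(cls, s)


def _check_alphabet(s: str, alphabet: str, kind: str) -> None:
    if not s:
        raise AlphabetError(f"empty {kind} sequence")
    bad = set(s) - set(alphabet)
    if bad:
        raise AlphabetError(f"invalid {kind} character(s): {sorted(bad)!r}")


# ---------------------------------------------------------------------------
# alphabet algebra


def revcomp(seq: str):
    """Watson–Crick reverse complement; preserves type and circular flag.

    Accepts plain strings, :class:`NucSeq` or :class:`DegenSeq` (IUPAC codes
    complement onto their partner sets).
    """
    if isinstance(seq, DegenSeq):
        return DegenSeq(str(Seq(seq).reverse_complement()), circular=seq.circular)
    ns = seq if isinstance(seq, NucSeq) else NucSeq(seq)
    return NucSeq(str(Seq(ns).reverse_complement()), circular=ns.circular)


def translate(seq: str, frame: int = 0) -> PepSeq:
    """Standard-genetic-code translation of complete codons from ``frame``.

    A stop codon is rendered as ``*`` with a warning; trailing bases that do
    not form a complete codon are ignored.
    """
    s = str(NucSeq(seq))[frame:]
    if len(s) < 3:
        raise ValueError("fewer than 3 bases after frame offset; nothing to translate")
    s = s[: len(s) - len(s) % 3]
    pep = str(Seq(s).translate())
    if STOP in pep:
        warnings.warn("translation contains a stop codon", stacklevel=2)
    return PepSeq(pep)


def expand_degenerate(d: str, cap: int = 10**6) -> list[NucSeq]:
    """All concrete sequences of a degenerate one, in lexicographic order.

    Refuses (reporting the analytic count) if the expansion would exceed
    ``cap``; the count itself is always cheap to compute.
    """
    ds = d if isinstance(d, DegenSeq) else DegenSeq(d)
    n = ds.expansion_count
    if n > cap:
        raise DegeneracyCapError(n, cap)
    choices = [sorted(IUPAC_DNA[c]) for c in ds]
    return [NucSeq("".join(t)) for t in product(*choices)]


def encoded_amino_acids(codon: str) -> set[str]:
    """Distinct amino acids (and ``*``) encoded by a degenerate codon."""
    ds = DegenSeq(codon)
    if len(ds) != 3:
        raise ValueError("codon must be 3 nt")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {str(translate(c)) for c in expand_degenerate(ds)}


# ---------------------------------------------------------------------------
# peptide physicochemistry

#: EMBOSS-style side-chain and terminal pKa values used by default for net
#: charge.  Alternative conventions (e.g. Lehninger, Sillero) shift absolute
#: charges slightly; pass a custom :class:`PkaTable` to use them.
_EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PkaTable:
    """Named pKa set for ionizable groups (side chains and both termini)."""

    name: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        required = set(_BASIC) | set(_ACIDIC) | {"Nterm", "Cterm"}
        missing = required - set(self.values)
        if missing:
            raise ValueError(f"pKa table missing entries: {sorted(missing)}")
        for k, v in self.values.items():
            if not 0 < v < 14:
                raise ValueError(f"pKa out of range for {k}: {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    @classmethod
    def emboss(cls) -> "PkaTable":
        return cls("EMBOSS", dict(_EMBOSS_PKA))


DEFAULT_PKA = PkaTable.emboss()


def net_charge(p: str, pH: float = 7.0, pka: PkaTable | None = None) -> float:
    """Net charge of a peptide in elementary-charge units.

    Henderson–Hasselbalch fractional charges summed over ionizable groups:
    a basic group contributes ``+1/(1+10**(pH-pKa))`` and an acidic group
    ``-1/(1+10**(pKa-pH))``.  Both termini are included; the result is
    strictly decreasing in pH.
    """
    pep = p if isinstance(p, PepSeq) else PepSeq(p)
    if STOP in pep:
        raise ValueError("peptide contains a stop symbol")
    if not 0 < pH < 14:
        raise ValueError("pH must be in (0, 14)")
    table = pka or DEFAULT_PKA
    pos = 1.0 / (1.0 + 10 ** (pH - table["Nterm"]))
    neg = -1.0 / (1.0 + 10 ** (table["Cterm"] - pH))
    for aa in pep:
        if aa in _BASIC:
            pos += 1.0 / (1.0 + 10 ** (pH - table[aa]))
        elif aa in _ACIDIC:
            neg -= 1.0 / (1.0 + 10 ** (table[aa] - pH))
    return pos + neg


#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def mean_hydropathy(p: str) -> float:
    """Mean Kyte–Doolittle hydropathy (GRAVY) of a peptide."""
    pep = p if isinstance(p, PepSeq) else PepSeq(p)
    if STOP in pep:
        raise ValueError("peptide contains a stop symbol")
    return sum(KYTE_DOOLITTLE[aa] for aa in pep) / len(pep)


# ---------------------------------------------------------------------------
# small DNA utilities


def gc_fraction(seq: str) -> float:
    s = str(NucSeq(seq))
    return (s.count("G") + s.count("C")) / len(s)


def melting_estimate(seq: str) -> float:
    """Simple GC-based melting temperature estimate (degC).

    Wallace rule for short oligos (<14 nt), otherwise the standard
    length-corrected GC formula.  Intended only as a design sanity check,
    not a nearest-neighbor thermodynamic prediction.
    """
    s = str(NucSeq(seq))
    gc = s.count("G") + s.count("C")
    if len(s) < 14:
        return 2.0 * (len(s) - gc) + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(s)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file to ``(id, sequence)`` pairs (uppercased)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    seqrecs = (
        SeqRecord(Seq(str(s)), id=str(name), description="") for name, s in records
    )
    SeqIO.write(seqrecs, str(path), "fasta")
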