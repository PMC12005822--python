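"""Deterministic synthetic inputs: toy units, vectors, and error-bearing reads.

Everything any other module needs for testing or demonstration is
generated here from a single seed — no downloads, no hidden entropy.  The
canonical study system ships as factories:

* :func:`elp_unit` — hydrophobic elastin-like unit (VGVPG)x6, 90 nt, with
  a substitutable guest position in each pentapeptide;
* :func:`rlp_unit` — hydrophilic resilin-like unit (GRGDSPYS)x4, 96 nt;
* :func:`elp_3ndt_unit` — the first-round library template: NDT codons at
  three guest sites (12 amino acids each, 1728 nucleotide variants);
* :func:`m10_unit` / :func:`m10_3ywy_unit` — a synthetic stand-in for a
  first-round histidine-guest winner and its second-round YWY template
  ({F, Y, L, H} at the remaining three guest sites).

:func:`make_reads` emits a FASTQ of full-length repeat-gene reads
(flank + n units + flank, random strand, per-base substitution errors)
plus truth tables sufficient to score any downstream recovery.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .construct_design import RepeatUnit, VectorSpec, design_next_round
from .repeat_reads import ReadRecord
from .seqcore import DegenSeq, NucSeq, PepSeq

__all__ = [
    "FixtureSpec",
    "elp_unit",
    "rlp_unit",
    "elp_3ndt_unit",
    "m10_unit",
    "m10_3ywy_unit",
    "ELP_GUEST_CODONS",
    "make_toy_vector",
    "make_read_records",
    "make_reads",
]

#: 0-based codon indices of the six substitutable guest positions of the
#: 30-residue ELP unit (the third residue of each VGVPG pentapeptide).
ELP_GUEST_CODONS = (2, 7, 12, 17, 22, 27)

_ELP_PENTamer_DNA = "GTTGGTGTTCCAGGT"  # V  G  V  P  G
_RLP_OCTamer_DNA = "GGTCGTGGTGATTCTCCATATTCT"  # G R G D S P Y S


def elp_unit() -> RepeatUnit:
    """Hydrophobic elastin-like repeat unit (VGVPG)x6; 30 aa, 90 nt."""
    return RepeatUnit("E", PepSeq("VGVPG" * 6), NucSeq(_ELP_PENTamer_DNA * 6))


def rlp_unit() -> RepeatUnit:
    """Hydrophilic resilin-like repeat unit (GRGDSPYS)x4; 32 aa, 96 nt."""
    return RepeatUnit("R", PepSeq("GRGDSPYS" * 4), NucSeq(_RLP_OCTamer_DNA * 4))


def elp_3ndt_unit() -> RepeatUnit:
    """First-round library template: NDT at guest codons X1-X3.

    Each NDT codon encodes one of 12 diverse amino acids; three such
    sites give 12^3 = 1728 nucleotide variants.
    """
    u = design_next_round(elp_unit(), ELP_GUEST_CODONS[:3], "NDT")
    return RepeatUnit("E-3NDT", u.peptide, u.dna)


def m10_unit(guests: tuple[str, str, str] = ("CAT", "GTT", "CAT")) -> RepeatUnit:
    """Synthetic stand-in for a first-round histidine-guest winner.

    Guest codons X1-X3 default to His/Val/His — the composition class the
    first screening round favours (histidine's side-chain pKa sits between
    pH 6.5 and 7.4, so these mutants shift charge on the small pH step).
    """
    base = elp_unit()
    bases = list(str(base.dna))
    pep = list(str(base.peptide))
    from .seqcore import translate

    for ci, codon in zip(ELP_GUEST_CODONS[:3], guests):
        bases[3 * ci : 3 * ci + 3] = list(codon.upper())
        pep[ci] = str(translate(codon))
    return RepeatUnit("m10", PepSeq("".join(pep)), NucSeq("".join(bases)))


def m10_3ywy_unit(guests: tuple[str, str, str] = ("CAT", "GTT", "CAT")) -> RepeatUnit:
    """Second-round template: YWY at the remaining guest codons X4-X6.

    YWY encodes exactly {F, Y, L, H}; three sites give 8^3 = 512
    nucleotide variants over 4^3 = 64 amino-acid combinations.
    """
    u = design_next_round(m10_unit(guests), ELP_GUEST_CODONS[3:], "YWY")
    return RepeatUnit("m10-3YWY", u.peptide, u.dna)


def make_toy_vector(
    tags: tuple[str, str] = ("MK", "WPTHHHHHH"),
    codon_table: dict[str, str] | None = None,
) -> VectorSpec:
    """Minimal linearized-vector termini encoding ``tags`` in frame.

    The defaults reproduce the published MK / WPTHHHHHH expression tags
    (and the corresponding inverse-PCR primer sequences).  Tags containing
    stop symbols are rejected.
    """
    n_term, c_term = tags
    return VectorSpec.with_tags(n_term, c_term, codon_table)


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic repeat-library sequencing run.

    ``variants`` are the planted concrete unit sequences with
    ``abundances`` (summing to 1); every read is
    flank5 + n_units x (one variant) + flank3 on a random strand with
    per-base substitution errors at ``sub_rate``.  Identical specs give
    byte-identical outputs.
    """

    variants: tuple[str, ...]
    abundances: tuple[float, ...]
    flank5: str
    flank3: str
    n_reads: int = 50_000
    n_units: int = 5
    sub_rate: float = 0.003
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.variants:
            raise ValueError("no variants")
        if len(self.variants) != len(self.abundances):
            raise ValueError("variants and abundances differ in length")
        if len({len(v) for v in self.variants}) != 1:
            raise ValueError("variants must share one length")
        ab = np.asarray(self.abundances, dtype=float)
        if (ab < 0).any() or not np.isclose(ab.sum(), 1.0):
            raise ValueError("abundances must be a distribution")
        for rate in (self.sub_rate, self.indel_rate):
            if not 0 <= rate <= 0.1:
                raise ValueError("error rates must be in [0, 0.1]")
        if self.indel_rate:
            raise NotImplementedError("indel simulation not supported")
        object.__setattr__(self, "variants", tuple(str(v).upper() for v in self.variants))


_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGT", b"TGCA"):
    _COMP[a] = b
_CODE = np.full(256, 255, dtype=np.uint8)
for i, a in enumerate(b"ACGT"):
    _CODE[a] = i
_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_read_records(
    spec: FixtureSpec,
) -> tuple[list[ReadRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate reads in memory.

    Returns ``(reads, per_read_truth, planted)``: the reads, a per-read
    table (variant index, strand, substitution count) and the planted
    abundance table.  All randomness flows from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.variants)
    templates = np.stack(
        [
            np.frombuffer(
                (spec.flank5 + v * spec.n_units + spec.flank3).encode(), dtype=np.uint8
            )
            for v in spec.variants
        ]
    )
    choice = rng.choice(k, size=spec.n_reads, p=np.asarray(spec.abundances))
    reads = templates[choice].copy()
    err = rng.random(reads.shape) < spec.sub_rate
    if err.any():
        codes = _CODE[reads[err]]
        shift = rng.integers(1, 4, size=codes.shape[0])
        reads[err] = _BASE[(codes + shift) % 4]
    n_subs = err.sum(axis=1)
    flip = rng.random(spec.n_reads) < 0.5
    reads[flip] = _COMP[reads[flip]][:, ::-1]
    records = [
        ReadRecord(f"read_{i}", reads[i].tobytes().decode())
        for i in range(spec.n_reads)
    ]
    per_read = pd.DataFrame(
        {
            "read_id": [r.id for r in records],
            "variant_index": choice,
            "strand": np.where(flip, "-", "+"),
            "n_substitutions": n_subs,
        }
    )
    planted = pd.DataFrame(
        {
            "variant_index": np.arange(k),
            "variant": list(spec.variants),
            "abundance": list(spec.abundances),
        }
    )
    return records, per_read, planted


def make_reads(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write the simulated run to disk: FASTQ + truth tables (TSV).

    Returns the paths.  Quality strings are constant (the error model is
    the explicit substitution rate, not a quality model).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, per_read, planted = make_read_records(spec)
    fastq = out / "reads.fastq"
    with open(fastq, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{'I' * len(r.bases)}\n")
    truth_reads = out / "truth_reads.tsv"
    per_read.to_csv(truth_reads, sep="\t", index=False)
    truth_planted = out / "truth_planted.tsv"
    planted.to_csv(truth_planted, sep="\t", index=False)
    return {"fastq": fastq, "truth_reads": truth_reads, "truth_planted": truth_planted}
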