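"""In-silico seamless (overlap-directed) assembly and screening bookkeeping.

Seamless cloning joins fragments whose termini share exact homology of the
designed overlap length; because the overlaps are asymmetric, insertion
site and orientation are both forced — the failure mode of blunt-end RCA
cloning that the overlap-bearing primers eliminate.  This module:

* assembles one or two amplicons into the vector by homology-chain search
  (orientation and two-fragment order emerge from the homology graph, not
  from input order);
* anneals incomplete-end amplicons into hybrid block-copolymer genes;
* verifies reading frame and terminal tags of assembled constructs;
* computes the positivity rate used to book-keep cloning success.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import permutations, product

import numpy as np

from .construct_design import VectorSpec
from .rca_sim import Amplicon, AmpliconPool
from .seqcore import NucSeq, PepSeq, revcomp, translate

__all__ = [
    "Recombinant",
    "AssemblyResult",
    "ScreeningTally",
    "infusion_assemble",
    "form_hybrids",
    "verify_orf",
    "positivity_rate",
    "colony_pcr_length",
]


@dataclass(frozen=True)
class Recombinant:
    """An assembled insert with frame/tag verification state."""

    insert: str
    n_repeats: int
    unit_variants: tuple[str, ...]
    reading_frame_ok: bool | None = None
    tags_found: tuple[str, str] | None = None
    peptide: str | None = None
    stop_position: int | None = None
    name: str = ""

    @property
    def is_block(self) -> bool:
        return len(set(self.unit_variants)) >= 2


@dataclass(frozen=True)
class AssemblyResult:
    """Recombinants plus per-junction diagnostics for failed chains."""

    recombinants: tuple[Recombinant, ...]
    diagnostics: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.recombinants)

    def __len__(self):
        return len(self.recombinants)

    def __bool__(self):
        return bool(self.recombinants)


def _chain_junctions(parts: list[str], overlap_len: int) -> list[bool]:
    return [
        a[-overlap_len:] == b[:overlap_len] and len(a) >= overlap_len and len(b) >= overlap_len
        for a, b in zip(parts, parts[1:])
    ]


def infusion_assemble(
    fragments: list[Amplicon],
    vector: VectorSpec,
    overlap_len: int = 15,
) -> AssemblyResult:
    """Assemble 1 or 2 amplicons into the vector by terminal homology.

    A product exists only for an arrangement
    ``vector-upstream -> fragment(s) -> vector-downstream`` in which every
    junction shares exact terminal homology of ``overlap_len``.  All
    fragment orders and orientations are tried; reverse-oriented fragments
    never satisfy the asymmetric overlaps of a correct design.  Distinct
    successful products are returned (deduplicated), with diagnostics for
    the failures.
    """
    if not 1 <= len(fragments) <= 2:
        raise ValueError("seamless assembly supports 1 or 2 fragments")
    up, down = str(vector.upstream_end), str(vector.downstream_end)
    diagnostics: list[str] = []
    seen: dict[str, Recombinant] = {}
    for order in permutations(range(len(fragments))):
        for flips in product((False, True), repeat=len(fragments)):
            seqs, variants, n_tot = [], [], 0
            for idx, flip in zip(order, flips):
                frag = fragments[idx]
                seqs.append(revcomp(frag.sequence) if flip else frag.sequence)
                variants.extend(reversed(frag.unit_variants) if flip else frag.unit_variants)
                n_tot += frag.n_repeats
            parts = [up, *seqs, down]
            ok = _chain_junctions(parts, overlap_len)
            if all(ok):
                insert = ""
                for s in seqs:
                    insert += s[overlap_len:]
                insert = insert[: len(insert) - len(down[:overlap_len])]
                # strip the downstream homology the last fragment carries
                rec = Recombinant(
                    insert=insert,
                    n_repeats=n_tot,
                    unit_variants=tuple(variants),
                )
                rec = verify_orf(rec, vector)
                seen.setdefault(insert, rec)
            else:
                bad = [str(i) for i, good in enumerate(ok) if not good]
                diagnostics.append(
                    f"order={order} flips={flips}: no {overlap_len}-nt homology at "
                    f"junction(s) {','.join(bad)}"
                )
    return AssemblyResult(tuple(seen.values()), tuple(diagnostics))


def verify_orf(rec: Recombinant, vector: VectorSpec) -> Recombinant:
    """Translate the assembled CDS and check tags and reading frame.

    The CDS runs from the vector's start codon through the insert into the
    downstream terminus.  ``reading_frame_ok`` requires the translation to
    begin with the N-terminal tag and reach the C-terminal tag with no
    internal stop; any frameshift surfaces as a premature stop or a
    missing tag, and the first stop's residue index is recorded.
    """
    full = str(vector.upstream_end) + str(rec.insert) + str(vector.downstream_end)
    cds = full[vector.cds_offset :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pep = str(translate(cds))
    stop = pep.find("*")
    translated = pep[:stop] if stop >= 0 else pep
    n_tag, c_tag = str(vector.n_term_tag), str(vector.c_term_tag)
    ok = (
        stop >= 0
        and translated.startswith(n_tag)
        and translated.endswith(c_tag)
        and len(translated) > len(n_tag) + len(c_tag) - 1
    )
    found = (
        n_tag if translated.startswith(n_tag) else "",
        c_tag if translated.endswith(c_tag) else "",
    )
    return replace(
        rec,
        reading_frame_ok=bool(ok),
        tags_found=found,
        peptide=translated,
        stop_position=stop if stop >= 0 else None,
    )


def _anneal_compatible(a: Amplicon, b: Amplicon, min_anneal: int, max_mismatch: int) -> bool:
    """Can a's 3' single-stranded tail pair into b's 5' single-stranded end?

    Both tails lie inside the repeat tract, so pairing reduces to the two
    molecules agreeing on the repeat-unit backbone over the annealing
    window; mixed-base design positions may differ (that is precisely how
    hybrid block-copolymer genes of two variants arise).
    """
    ta = a.unit_variants[-1][-min_anneal:]
    tb = b.unit_variants[0][-min_anneal:]
    if len(ta) < min_anneal or len(tb) < min_anneal:
        return False
    mismatches = sum(x != y for x, y in zip(ta, tb))
    return mismatches <= max_mismatch


def form_hybrids(
    pool: AmpliconPool,
    p_anneal: float = 0.5,
    min_anneal: int = 15,
    max_mismatch: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AmpliconPool:
    """Anneal complementary incomplete-end amplicons into hybrids.

    Molecules with a 3' single-stranded region pair with molecules with a
    5' single-stranded region; a compatible random pair joins with
    probability ``p_anneal`` into one longer blunt amplicon whose unit
    list concatenates both parents' lists — a block-copolymer gene when
    the parents carry different variants.  Unpaired molecules pass
    through.  Total repeat count is conserved.
    """
    if not 0 <= p_anneal <= 1:
        raise ValueError("p_anneal must be in [0, 1]")
    rng = rng or np.random.default_rng(seed)
    ss3 = [a for a in pool.molecules() if a.end_state == "ss3prime"]
    ss5 = [a for a in pool.molecules() if a.end_state == "ss5prime"]
    rest = [a for a in pool.molecules() if a.end_state == "blunt"]
    rng.shuffle(ss3)
    rng.shuffle(ss5)
    out: Counter[Amplicon] = Counter(rest)
    n_pairs = min(len(ss3), len(ss5))
    joined = rng.random(n_pairs) < p_anneal
    for i in range(n_pairs):
        a, b = ss3[i], ss5[i]
        if joined[i] and _anneal_compatible(a, b, min_anneal, max_mismatch):
            out[
                Amplicon(
                    n_repeats=a.n_repeats + b.n_repeats,
                    unit_variants=a.unit_variants + b.unit_variants,
                    fwd_overlap=a.fwd_overlap,
                    rev_overlap=b.rev_overlap,
                    end_state="blunt",
                )
            ] += 1
        else:
            out[a] += 1
            out[b] += 1
    for a in ss3[n_pairs:] + ss5[n_pairs:]:
        out[a] += 1
    members = tuple(
        (a, m) for a, m in sorted(out.items(), key=lambda t: (t[0].sequence, t[0].end_state))
    )
    return AmpliconPool(
        members, params={**pool.params, "p_anneal": p_anneal}, seed=pool.seed
    )


@dataclass(frozen=True)
class ScreeningTally:
    """Colony-PCR and sequencing outcomes for a batch of transformants."""

    colony_pcr: tuple[int, int]
    sequencing: tuple[int, int]

    def __post_init__(self):
        for pos, tests in (self.colony_pcr, self.sequencing):
            if tests <= 0:
                raise ValueError("tests must be > 0")
            if not 0 <= pos <= tests:
                raise ValueError("positives must be in [0, tests]")


def positivity_rate(t: ScreeningTally) -> float:
    """Percent success: product of the colony-PCR and sequencing pass fractions."""
    (p1, n1), (p2, n2) = t.colony_pcr, t.sequencing
    return 100.0 * (p1 / n1) * (p2 / n2)


def colony_pcr_length(
    rec: Recombinant, vector: VectorSpec, upstream_extra: int = 0, downstream_extra: int = 0
) -> int:
    """Predicted colony-PCR amplicon length for a recombinant.

    ``*_extra`` add the vector bases between each sequencing-primer site
    and the recorded terminus (0 for the minimal toy vector).  No gel
    mobility model — the number is the true length in bp.
    """
    return (
        upstream_extra
        + len(vector.upstream_end)
        + len(rec.insert)
        + len(vector.downstream_end)
        + downstream_extra
    )
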