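"""Charge/hydropathy screening of library mutants for directed evolution.

Before purifying anything, candidates are ranked computationally: the
repeat-tract peptide of each recombinant gets its net charge at a pH pair
(default 7.4 vs 6.5, biological vs slightly acidic), the charge shift
between them, and its mean Kyte-Doolittle hydropathy.  Mutants whose
charge responds most to the small pH step (histidine-guest mutants, with
side-chain pKa between the two pH values) rank highest; cysteine-bearing
mutants (irreversible aggregation risk) and block-copolymer mutants
(next-round template complexity) can be filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .assembly_sim import Recombinant
from .library_stats import LibraryDesign
from .seqcore import PepSeq, PkaTable, mean_hydropathy, net_charge, translate

logger = logging.getLogger(__name__)

__all__ = [
    "MutantRecord",
    "RankPolicy",
    "CompositionMetrics",
    "build_records",
    "rank_candidates",
    "elp_fraction",
    "guest_residue_table",
    "charge_hydropathy_table",
]


@dataclass(frozen=True)
class MutantRecord:
    """A translated candidate with the quantities screening uses."""

    id: str
    peptide: str
    unit_variants: tuple[str, ...]
    charge_a: float
    charge_b: float
    delta_charge: float
    gravy: float
    has_cys: bool
    is_block: bool


@dataclass(frozen=True)
class RankPolicy:
    exclude_cys: bool = True
    exclude_block: bool = True
    top_k: int | None = None


def build_records(
    candidates: Iterable[Recombinant],
    ph_pair: tuple[float, float] = (7.4, 6.5),
    pka: PkaTable | None = None,
) -> list[MutantRecord]:
    """Evaluate recombinants into screening records (deterministic).

    Candidates without an intact reading frame are skipped with a log
    entry.  The peptide scored is the repeat tract (the insert's
    translation), not the tagged full-length product, matching how the
    responsive part of the polymer is designed.
    """
    ph_a, ph_b = ph_pair
    records = []
    for i, rec in enumerate(candidates):
        name = rec.name or f"m{i + 1}"
        if rec.reading_frame_ok is False:
            logger.info("skipping %s: reading frame not intact", name)
            continue
        try:
            pep = str(translate(rec.insert))
        except ValueError:
            logger.info("skipping %s: untranslatable insert", name)
            continue
        if "*" in pep:
            logger.info("skipping %s: internal stop in repeat tract", name)
            continue
        ca = net_charge(pep, ph_a, pka)
        cb = net_charge(pep, ph_b, pka)
        records.append(
            MutantRecord(
                id=name,
                peptide=pep,
                unit_variants=tuple(rec.unit_variants),
                charge_a=ca,
                charge_b=cb,
                delta_charge=ca - cb,
                gravy=mean_hydropathy(pep),
                has_cys="C" in pep,
                is_block=len(set(rec.unit_variants)) >= 2,
            )
        )
    return records


def rank_candidates(
    records: Sequence[MutantRecord],
    policy: RankPolicy | None = None,
    key: Callable[[MutantRecord], float] | None = None,
) -> list[MutantRecord]:
    """Filter then sort candidates, best first.

    Default key is the magnitude of the pH-induced charge shift; ties
    break lexicographically by id so rankings are deterministic.  An
    empty shortlist after filtering is logged, not raised.
    """
    policy = policy or RankPolicy()
    key = key or (lambda r: abs(r.delta_charge))
    kept = [
        r
        for r in records
        if not (policy.exclude_cys and r.has_cys)
        and not (policy.exclude_block and r.is_block)
    ]
    if not kept:
        logger.info(
            "no candidates survive filters (cys=%s, block=%s) from %d records",
            policy.exclude_cys,
            policy.exclude_block,
            len(records),
        )
        return []
    ranked = sorted(kept, key=lambda r: (-key(r), r.id))
    return ranked[: policy.top_k] if policy.top_k is not None else ranked


def elp_fraction(
    units: Sequence[str],
    unit_classes: Mapping[str, str] | Callable[[str], str],
) -> float:
    """Percent of repeat residues contributed by ELP-class units.

    ``units`` are the construct's repeat-unit DNA sequences in order;
    ``unit_classes`` maps each (or classifies it) to ``"ELP"`` or
    ``"RLP"``.  E.g. six 32-aa RLP units plus six 30-aa ELP units give
    100 * 180/372 = 48.4%.
    """
    if not units:
        raise ValueError("no units")
    classify = unit_classes if callable(unit_classes) else unit_classes.__getitem__
    elp = total = 0
    for u in units:
        n_res = len(u) // 3
        try:
            cls = classify(u)
        except KeyError:
            raise ValueError(f"unclassified unit {u[:12]}...") from None
        if cls not in ("ELP", "RLP"):
            raise ValueError(f"unit class must be ELP or RLP, got {cls!r}")
        total += n_res
        if cls == "ELP":
            elp += n_res
    return 100.0 * elp / total


@dataclass(frozen=True)
class CompositionMetrics:
    """Construct-level composition: ELP fraction and guest-residue table."""

    elp_fraction: float
    guest_residues: pd.DataFrame


def guest_residue_table(
    records: Sequence[MutantRecord], design: LibraryDesign
) -> pd.DataFrame:
    """Guest residues of each record at the design's mixed-base codons.

    Reads the residue off each record's *first* repeat unit (processive
    amplification makes units within a molecule identical; block mutants
    report their first block).  Columns are X1..Xk in codon order.
    """
    positions = design.unit.degenerate_codons
    cols = [f"X{i + 1}" for i in range(len(positions))]
    rows = {}
    for rec in records:
        first = rec.unit_variants[0] if rec.unit_variants else None
        if first is None or len(first) < 3 * (max(positions, default=0) + 1):
            rows[rec.id] = [None] * len(positions)
            continue
        pep = str(translate(first))
        rows[rec.id] = [pep[ci] for ci in positions]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def charge_hydropathy_table(records: Sequence[MutantRecord]) -> pd.DataFrame:
    """Scatter-ready (gravy, net charge) table, one row per mutant."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "gravy": [r.gravy for r in records],
            "charge_a": [r.charge_a for r in records],
            "charge_b": [r.charge_b for r in records],
            "delta_charge": [r.delta_charge for r in records],
            "has_cys": [r.has_cys for r in records],
            "is_block": [r.is_block for r in records],
        }
    )
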