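"""Degenerate repeat-unit library combinatorics and diversity statistics.

A mixed-base ring template defines a library whose size is the product of
the per-position degeneracies (e.g. three NDT codons -> 12^3 = 1728
nucleotide variants encoding 12^3 amino-acid combinations; three YWY
codons -> 8^3 = 512 nucleotide variants over 4^3 = 64 amino-acid
combinations).  This module enumerates such libraries, computes the ideal
per-variant abundance (100%/K), simulates oligo synthesis with per-site
base bias, and reduces observed unit counts to the standard diversity
report (most-abundant-variant occupancy, median variant abundance,
mutant/error fractions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .construct_design import RepeatUnit
from .seqcore import (
    IUPAC_DNA,
    DegeneracyCapError,
    DegenSeq,
    NucSeq,
    encoded_amino_acids,
    expand_degenerate,
    translate,
)

if TYPE_CHECKING:  # pragma: no cover
    from .repeat_reads import UnitCountTable

__all__ = [
    "LibraryDesign",
    "AbundanceReport",
    "enumerate_library",
    "ideal_abundance",
    "simulate_synthesis",
    "diversity_report",
]


@dataclass(frozen=True)
class LibraryDesign:
    """A repeat unit with mixed-base codons, viewed as a variant library."""

    unit: RepeatUnit

    @property
    def dna(self) -> DegenSeq | NucSeq:
        return self.unit.dna

    @property
    def unit_length(self) -> int:
        return len(self.unit.dna)

    @property
    def degenerate_nt_positions(self) -> tuple[int, ...]:
        if isinstance(self.unit.dna, DegenSeq):
            return self.unit.dna.degenerate_positions()
        return ()

    @property
    def nucleotide_variant_count(self) -> int:
        if isinstance(self.unit.dna, DegenSeq):
            return self.unit.dna.expansion_count
        return 1

    @property
    def aa_variant_count(self) -> int:
        """Distinct peptide count: product of per-codon amino-acid choices."""
        total = 1
        for ci in self.unit.degenerate_codons:
            codon = self.unit.dna[3 * ci : 3 * ci + 3]
            aas = encoded_amino_acids(codon) - {"*"}
            total *= len(aas)
        return total

    @classmethod
    def from_ring(cls, design) -> "LibraryDesign":
        """Library defined by a ring design, in amplicon (rotated) phase."""
        return cls(design.template_unit())


def enumerate_library(d: LibraryDesign, cap: int = 10**6) -> pd.DataFrame:
    """Complete, duplicate-free, lexicographic variant table with translations."""
    variants = expand_degenerate(d.dna, cap=cap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        peptides = [str(translate(v)) for v in variants]
    return pd.DataFrame({"dna": [str(v) for v in variants], "peptide": peptides})


def ideal_abundance(d: LibraryDesign) -> float:
    """Ideal per-variant abundance in percent: 100 / variant count.

    Returned at full precision; report to ~3 significant figures
    (100/1728 prints as 0.058%).
    """
    k = d.nucleotide_variant_count
    if k < 1:
        raise ValueError("variant count must be >= 1")
    return 100.0 / k


@dataclass(frozen=True)
class AbundanceReport:
    """Diversity statistics of a variant-count table.

    Percent abundances of mutant variants use the mutant total as
    denominator; ``mutant_fraction``/``error_fraction`` use all counted
    sequences (the two denominators of the standard mutant-vs-error and
    occupancy plots).  Variants the design admits but the counts never
    show are tallied as ``n_missing``.
    """

    table: pd.DataFrame  # columns: dna, count, pct (observed mutants, sorted)
    max_occupancy: float
    median_abundance: float
    ideal_abundance: float
    mutant_fraction: float
    error_fraction: float
    n_observed: int
    n_missing: int
    total_mutant: int
    total_error: int

    @classmethod
    def from_counts(
        cls,
        mutant_counts: Mapping[str, int],
        error_count: int,
        design: LibraryDesign,
    ) -> "AbundanceReport":
        counts = {k: int(v) for k, v in mutant_counts.items() if v > 0}
        if not counts and error_count == 0:
            raise ValueError("empty counts")
        total_mut = sum(counts.values())
        total = total_mut + error_count
        tab = (
            pd.DataFrame({"dna": list(counts), "count": list(counts.values())})
            .sort_values(["count", "dna"], ascending=[False, True])
            .reset_index(drop=True)
        )
        if total_mut:
            tab["pct"] = 100.0 * tab["count"] / total_mut
            max_occ = float(tab["pct"].iloc[0])
            median = float(tab["pct"].median())
        else:
            tab["pct"] = []
            max_occ = float("nan")
            median = float("nan")
        return cls(
            table=tab,
            max_occupancy=max_occ,
            median_abundance=median,
            ideal_abundance=ideal_abundance(design),
            mutant_fraction=100.0 * total_mut / total,
            error_fraction=100.0 * error_count / total,
            n_observed=len(tab),
            n_missing=design.nucleotide_variant_count - len(tab),
            total_mutant=total_mut,
            total_error=error_count,
        )

    def summary(self) -> dict[str, float]:
        return {
            "max_occupancy_pct": self.max_occupancy,
            "median_abundance_pct": self.median_abundance,
            "ideal_abundance_pct": self.ideal_abundance,
            "mutant_fraction_pct": self.mutant_fraction,
            "error_fraction_pct": self.error_fraction,
            "n_observed": self.n_observed,
            "n_missing": self.n_missing,
        }


def _site_probs(
    d: LibraryDesign, base_bias: Mapping[int, Mapping[str, float]] | None
) -> list[tuple[int, list[str], np.ndarray]]:
    """Per degenerate site: (position, allowed bases sorted, probabilities)."""
    if base_bias:
        unknown = set(base_bias) - set(d.degenerate_nt_positions)
        if unknown:
            raise ValueError(
                f"bias given for non-degenerate position(s): {sorted(unknown)}"
            )
    out = []
    for pos in d.degenerate_nt_positions:
        allowed = sorted(IUPAC_DNA[d.dna[pos]])
        if base_bias and pos in base_bias:
            bias = base_bias[pos]
            if set(bias) - set(allowed):
                raise ValueError(f"bias at position {pos} names disallowed bases")
            p = np.array([float(bias.get(b, 0.0)) for b in allowed])
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"bias at position {pos} is not a distribution")
        else:
            p = np.full(len(allowed), 1.0 / len(allowed))
        out.append((pos, allowed, p))
    return out


def simulate_synthesis(
    d: LibraryDesign,
    n_molecules: int = 10**6,
    base_bias: Mapping[int, Mapping[str, float]] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    cap: int = 10**6,
) -> AbundanceReport:
    """Simulate oligo synthesis of the library and report realized diversity.

    Each molecule draws every mixed-base site independently (uniform by
    default, or with a per-site ``base_bias``); the variant counts are a
    single multinomial draw over the induced joint distribution, so large
    ``n_molecules`` are cheap.  Synthesis bias skews abundances away from
    the ideal 100%/K and drives the median below it.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = rng or np.random.default_rng(seed)
    variants = enumerate_library(d, cap=cap)["dna"].to_numpy()
    sites = _site_probs(d, base_bias)
    probs = np.ones(len(variants))
    for pos, allowed, p in sites:
        base_idx = {b: i for i, b in enumerate(allowed)}
        idx = np.array([base_idx[v[pos]] for v in variants])
        probs *= p[idx]
    probs /= probs.sum()
    counts = rng.multinomial(n_molecules, probs)
    return AbundanceReport.from_counts(
        dict(zip(variants, counts)), error_count=0, design=d
    )


def diversity_report(counts: "UnitCountTable", d: LibraryDesign) -> AbundanceReport:
    """Diversity statistics from classified terminal-unit counts.

    Uses the combined 5'+3' counts per variant; invariant to the row
    order of the input table.
    """
    tab = counts.table
    if tab.empty:
        raise ValueError("empty count table")
    combined = tab["count5"] + tab["count3"]
    mutants = tab["class"] == "mutant"
    mutant_counts = dict(zip(tab.loc[mutants, "variant"], combined[mutants]))
    error_count = int(combined[~mutants].sum())
    return AbundanceReport.from_counts(mutant_counts, error_count, d)
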