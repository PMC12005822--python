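"""Sequencing-read analysis of repeat-library genes.

Repetitive amplicons sequence poorly in the middle (poor cluster
formation), but the terminal repeat units — inside a trusted window at
each read end — are reliable.  The workflow here mirrors that analysis:

1. anchor each read by its known primer-derived flanks (either strand,
   small mismatch budget) and orient it;
2. extract the first (5') and last (3') repeat unit from the trusted end
   windows;
3. tally units per distinct sequence at each end, dropping low-count
   variants (default: fewer than 6 at both ends);
4. classify each unit as *mutant* (fits the mixed-base design template)
   or *error* (any deviation at a fixed backbone position, a base outside
   the IUPAC set at a design position, or a length variant);
5. summarize: 5'/3' count concordance (Pearson) and per-position symbol
   frequency matrices for logo-style displays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .library_stats import LibraryDesign
from .seqcore import IUPAC_DNA, revcomp

__all__ = [
    "ReadRecord",
    "Flanks",
    "ExtractConfig",
    "UnitCountTable",
    "PositionFrequencyMatrix",
    "read_fastx",
    "extract_terminal_units",
    "extract_all",
    "count_units",
    "classify_unit",
    "end_concordance",
    "frequency_matrix",
]


@dataclass(frozen=True)
class ReadRecord:
    id: str
    bases: str
    qualities: tuple[int, ...] | None = None


@dataclass(frozen=True)
class Flanks:
    """Plus-strand sequences immediately flanking the repeat tract."""

    five_prime: str
    three_prime: str


@dataclass(frozen=True)
class ExtractConfig:
    """Anchoring/extraction parameters.

    end_window
        Trusted bases after the 5' flank (and before the 3' flank); a
        terminal unit must fit inside it.
    max_mismatch
        Mismatch budget when locating a flank (alignment-free: flanks are
        short, fixed and designed in-house).
    """

    end_window: int = 90
    max_mismatch: int = 1


def read_fastx(path) -> list[ReadRecord]:
    """Read FASTQ (or FASTA) into ReadRecords; format sniffed from content."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    out = []
    for rec in SeqIO.parse(path, fmt):
        quals = rec.letter_annotations.get("phred_quality")
        out.append(
            ReadRecord(rec.id, str(rec.seq).upper(), tuple(quals) if quals else None)
        )
    return out


def _find_approx(seq: str, pattern: str, max_mismatch: int) -> int:
    """First position of ``pattern`` in ``seq`` with <= max_mismatch
    substitutions; -1 if absent.  Exact search first, vectorized Hamming
    scan as fallback."""
    pos = seq.find(pattern)
    if pos >= 0 or max_mismatch == 0:
        return pos
    k = len(pattern)
    if len(seq) < k:
        return -1
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    mism = (windows != pat).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return int(hits[0]) if hits.size else -1


def extract_terminal_units(
    read: ReadRecord | str,
    design: LibraryDesign,
    flanks: Flanks,
    cfg: ExtractConfig | None = None,
) -> tuple[str | None, str | None]:
    """Extract the 5'-terminal and 3'-terminal repeat units of one read.

    The read is oriented by the 5' flank (searched on both strands); the
    unit after the 5' flank and the unit before the 3' flank are returned
    when they fit inside the trusted end windows, ``None`` per unreadable
    side.  An unanchored read returns ``(None, None)``.
    """
    cfg = cfg or ExtractConfig()
    unit_len = design.unit_length
    if unit_len > cfg.end_window:
        raise ValueError("end_window shorter than one repeat unit")
    seq = read.bases if isinstance(read, ReadRecord) else str(read)
    seq = seq.upper()
    f5, f3 = flanks.five_prime.upper(), flanks.three_prime.upper()
    pos5 = _find_approx(seq, f5, cfg.max_mismatch)
    if pos5 < 0:
        seq = str(revcomp(seq))
        pos5 = _find_approx(seq, f5, cfg.max_mismatch)
        if pos5 < 0:
            return None, None
    unit5 = None
    start = pos5 + len(f5)
    if start + unit_len <= len(seq):
        unit5 = seq[start : start + unit_len]
    unit3 = None
    if f3:
        tail_start = max(0, len(seq) - (cfg.end_window + len(f3) + unit_len))
        pos3 = _find_approx(seq[tail_start:], f3, cfg.max_mismatch)
        if pos3 >= 0:
            pos3 += tail_start
            if pos3 - unit_len >= 0:
                unit3 = seq[pos3 - unit_len : pos3]
    return unit5, unit3


def extract_all(
    reads: Iterable[ReadRecord | str],
    design: LibraryDesign,
    flanks: Flanks,
    cfg: ExtractConfig | None = None,
) -> pd.DataFrame:
    """Per-read extraction table with columns read_id, unit5, unit3, anchored."""
    rows = []
    for i, read in enumerate(reads):
        rid = read.id if isinstance(read, ReadRecord) else f"read_{i}"
        u5, u3 = extract_terminal_units(read, design, flanks, cfg)
        rows.append((rid, u5, u3, u5 is not None or u3 is not None))
    return pd.DataFrame(rows, columns=["read_id", "unit5", "unit3", "anchored"])


def classify_unit(u: str, d: LibraryDesign) -> str:
    """``mutant`` iff the unit fits the design template at every position
    (exact at fixed positions, within the IUPAC set at mixed-base
    positions); anything else — including length variants — is ``error``."""
    template = str(d.dna)
    if len(u) != len(template):
        return "error"
    for base, code in zip(u.upper(), template):
        if base not in IUPAC_DNA.get(code, ""):
            return "error"
    return "mutant"


@dataclass(frozen=True)
class UnitCountTable:
    """Per-variant counts at the 5' and 3' terminal units.

    ``table`` columns: variant, count5, count3, class, peptide.  Variants
    below ``min_count`` at both ends are dropped from ``table`` and kept
    in ``dropped``.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame
    min_count: int

    @property
    def mutants(self) -> pd.DataFrame:
        return self.table[self.table["class"] == "mutant"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def count_units(
    pairs: Iterable[tuple[str | None, str | None]] | pd.DataFrame,
    design: LibraryDesign,
    min_count: int = 6,
) -> UnitCountTable:
    """Tally extracted terminal units into a classified count table.

    Accepts an iterable of ``(unit5, unit3)`` pairs or an
    :func:`extract_all` frame.  Counting is exact and order-independent;
    a variant is retained if it reaches ``min_count`` at either end.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if isinstance(pairs, pd.DataFrame):
        it = zip(pairs["unit5"], pairs["unit3"])
    else:
        it = iter(pairs)
    c5: dict[str, int] = {}
    c3: dict[str, int] = {}
    for u5, u3 in it:
        if u5:
            c5[u5] = c5.get(u5, 0) + 1
        if u3:
            c3[u3] = c3.get(u3, 0) + 1
    variants = sorted(set(c5) | set(c3))
    from .seqcore import translate  # local import to avoid cycle at module load

    rows = []
    for v in variants:
        cls = classify_unit(v, design)
        pep = ""
        if len(v) % 3 == 0 and len(v) >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pep = str(translate(v))
        rows.append((v, c5.get(v, 0), c3.get(v, 0), cls, pep))
    tab = pd.DataFrame(rows, columns=["variant", "count5", "count3", "class", "peptide"])
    keep = (tab["count5"] >= min_count) | (tab["count3"] >= min_count)
    return UnitCountTable(
        table=tab[keep].reset_index(drop=True),
        dropped=tab[~keep].reset_index(drop=True),
        min_count=min_count,
    )


def end_concordance(t: UnitCountTable) -> float:
    """Pearson correlation between 5' and 3' counts over retained variants.

    High concordance indicates processive amplification: one template's
    variant occupies every repeat of a molecule, so both ends agree.
    Degenerate variance yields NaN with a warning.
    """
    tab = t.table
    if len(tab) < 3:
        raise ValueError("need at least 3 variants for a correlation")
    x = tab["count5"].to_numpy(dtype=float)
    y = tab["count3"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("end concordance undefined: zero variance in counts")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Column-stochastic per-position symbol frequencies.

    ``freqs`` rows are positions, columns the alphabet; each row sums to
    1.  ``flagged`` marks mixed-base design positions.
    """

    freqs: pd.DataFrame
    flagged: tuple[int, ...] = ()

    def __post_init__(self):
        sums = self.freqs.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")

    def to_tsv(self, path) -> None:
        self.freqs.to_csv(path, sep="\t")

    def plot(self, ax=None):
        """Stacked-bar rendering of the per-position frequencies.

        Requires matplotlib (optional dependency); mixed-base design
        positions are marked on the x axis.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, len(self.freqs) / 6), 2.5))
        bottom = np.zeros(len(self.freqs))
        for symbol in self.freqs.columns:
            vals = self.freqs[symbol].to_numpy()
            ax.bar(self.freqs.index, vals, bottom=bottom, width=0.9, label=symbol)
            bottom += vals
        ax.set_xlabel("position")
        ax.set_ylabel("frequency")
        for pos in self.flagged:
            ax.axvline(pos, color="k", lw=0.5, ls=":")
        return ax


_ALPHABETS = {"dna": "ACGT", "protein": "ACDEFGHIKLMNPQRSTVWY"}


def frequency_matrix(
    seqs: Sequence[str],
    alphabet: str = "dna",
    design: LibraryDesign | None = None,
    weights: Sequence[int] | None = None,
) -> PositionFrequencyMatrix:
    """Position frequency matrix of equal-length sequences.

    ``alphabet`` is ``"dna"``, ``"protein"`` or an explicit symbol string;
    optional ``weights`` count each sequence multiple times (e.g. variant
    read counts); a ``design`` flags its mixed-base positions.
    """
    seqs = [s.upper() for s in seqs]
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged sequence lengths")
    letters = _ALPHABETS.get(alphabet, alphabet)
    w = np.ones(len(seqs), dtype=float) if weights is None else np.asarray(weights, float)
    if len(w) != len(seqs) or (w < 0).any() or w.sum() == 0:
        raise ValueError("bad weights")
    mat = np.zeros((L, len(letters)))
    index = {c: j for j, c in enumerate(letters)}
    for s, wi in zip(seqs, w):
        for i, c in enumerate(s):
            if c not in index:
                raise ValueError(f"symbol {c!r} outside alphabet")
            mat[i, index[c]] += wi
    mat /= mat.sum(axis=1, keepdims=True)
    freqs = pd.DataFrame(mat, columns=list(letters))
    freqs.index.name = "position"
    flagged = ()
    if design is not None:
        if alphabet == "protein":
            flagged = tuple(design.unit.degenerate_codons)
        else:
            flagged = tuple(design.degenerate_nt_positions)
    return PositionFrequencyMatrix(freqs, flagged)
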