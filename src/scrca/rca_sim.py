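"""Amplicon-ladder prediction and stochastic RCA pool simulation.

Rolling-circle amplification of an n-repeat gene from a ring of size *s*
with overlap-bearing primers yields products of predictable length
``n * s + overlap_total``; electrophoresed pools show a ladder with rung
spacing *s*.  This module predicts that ladder, maps observed band sizes
back to repeat numbers, and draws synthetic amplicon pools.

The pool model captures the features downstream analysis depends on:

* repeat numbers drawn from a named distribution (the pool's abundance
  profile is an open parameter — default truncated geometric);
* processive copying: all repeat units within one molecule come from the
  *same* concrete expansion of a mixed-base template;
* incomplete ends: with probability ``p_ss_end`` a molecule is left with a
  single-stranded region at its 3' or 5' end (equally likely) and lacks
  the corresponding overlap extension — the raw material for hybrid
  block-copolymer formation during cloning.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .construct_design import RingDesign
from .seqcore import IUPAC_DNA, DegenSeq, NucSeq, write_fasta

__all__ = [
    "Ladder",
    "Amplicon",
    "AmpliconPool",
    "predict_ladder",
    "assign_bands",
    "fit_ladder",
    "simulate_rca",
    "size_select",
    "geometric_repeat_dist",
]

END_STATES = ("blunt", "ss3prime", "ss5prime")


@dataclass(frozen=True)
class Ladder:
    """Theoretical amplicon lengths: n * ring_size + overlap_total."""

    ring_size: int
    overlap_total: int
    entries: tuple[tuple[int, int], ...]

    def length(self, n: int) -> int:
        return n * self.ring_size + self.overlap_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["n", "length"])


def predict_ladder(design: RingDesign, n_max: int) -> Ladder:
    """Ladder of theoretical amplicon lengths for 1..n_max ring copies."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    ring = design.ring_size
    ov = len(design.fwd_overlap) + len(design.rev_overlap)
    return Ladder(ring, ov, tuple((n, n * ring + ov) for n in range(1, n_max + 1)))


def assign_bands(
    observed: Iterable[float], ladder: Ladder, tol: float = 0.05
) -> list[tuple[float, int | None]]:
    """Map observed band sizes (bp) to repeat numbers.

    Each band goes to the nearest ladder rung if the relative error is
    within ``tol``; otherwise it is reported unassigned (``None``).
    """
    if not 0 < tol <= 0.2:
        raise ValueError("tol must be in (0, 0.2]")
    out: list[tuple[float, int | None]] = []
    for band in observed:
        n, length = min(ladder.entries, key=lambda e: abs(band - e[1]))
        out.append((band, n if abs(band - length) / length <= tol else None))
    return out


def fit_ladder(bands: dict[int, float]):
    """Least-squares fit of band length on repeat number.

    Returns ``(ring_size_est, overlap_est, r)`` — slope, intercept and
    Pearson correlation of the linear fit; on noiseless theoretical
    lengths the slope is the ring size exactly and r = 1.
    """
    ns = np.array(sorted(bands), dtype=float)
    if ns.size < 2:
        raise ValueError("need at least two bands to fit")
    lengths = np.array([bands[int(n)] for n in ns], dtype=float)
    res = stats.linregress(ns, lengths)
    return res.slope, res.intercept, res.rvalue


@dataclass(frozen=True)
class Amplicon:
    """One linear dsDNA product (plus-strand representation).

    ``unit_variants`` lists the concrete repeat-unit sequence of each copy
    in order.  Incomplete molecules (``end_state`` ss3prime/ss5prime) lack
    the overlap extension at the affected end and carry an ``ss_len``-nt
    single-stranded region there; only molecules with both overlaps can be
    seamlessly cloned on their own.
    """

    n_repeats: int
    unit_variants: tuple[str, ...]
    fwd_overlap: str
    rev_overlap: str
    end_state: str = "blunt"
    ss_len: int = 0

    def __post_init__(self):
        if self.end_state not in END_STATES:
            raise ValueError(f"bad end_state {self.end_state!r}")
        if self.n_repeats != len(self.unit_variants):
            raise ValueError("n_repeats inconsistent with unit_variants")
        if (self.end_state == "blunt") != (self.ss_len == 0):
            raise ValueError("ss_len inconsistent with end_state")

    @property
    def repeat_region(self) -> str:
        return "".join(self.unit_variants)

    @property
    def sequence(self) -> str:
        left = self.fwd_overlap if self.end_state != "ss5prime" else ""
        right = self.rev_overlap if self.end_state != "ss3prime" else ""
        return left + self.repeat_region + right

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconPool:
    """Amplicons with multiplicities, plus the parameters that made them."""

    members: tuple[tuple[Amplicon, int], ...]
    params: dict = field(default_factory=dict, compare=False)
    seed: int | None = None

    def __post_init__(self):
        if any(m <= 0 for _, m in self.members):
            raise ValueError("multiplicities must be positive")

    def __iter__(self) -> Iterator[tuple[Amplicon, int]]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_molecules(self) -> int:
        return sum(m for _, m in self.members)

    @property
    def total_repeats(self) -> int:
        return sum(a.n_repeats * m for a, m in self.members)

    def molecules(self) -> Iterator[Amplicon]:
        for a, m in self.members:
            for _ in range(m):
                yield a

    def repeat_histogram(self) -> dict[int, int]:
        h: Counter[int] = Counter()
        for a, m in self.members:
            h[a.n_repeats] += m
        return dict(sorted(h.items()))

    def digest(self) -> str:
        """Stable content hash: identical seed+params give identical pools."""
        h = hashlib.sha256()
        for a, m in sorted(
            self.members, key=lambda t: (t[0].sequence, t[0].end_state, t[1])
        ):
            h.update(
                f"{a.sequence}|{a.end_state}|{a.ss_len}|{m}\n".encode()
            )
        return h.hexdigest()

    def to_fasta(self, path) -> None:
        records = []
        for i, (a, m) in enumerate(self.members):
            tag = f"amplicon_{i} n={a.n_repeats};endstate={a.end_state};mult={m}"
            records.append((tag, a.sequence))
        write_fasta(path, records)


def geometric_repeat_dist(p: float = 0.3, n_max: int = 20) -> dict[int, float]:
    """Truncated geometric distribution over repeat numbers 1..n_max."""
    if not 0 < p < 1 or n_max < 1:
        raise ValueError("need 0 < p < 1 and n_max >= 1")
    w = np.array([(1 - p) ** (n - 1) * p for n in range(1, n_max + 1)])
    w /= w.sum()
    return {n: float(x) for n, x in zip(range(1, n_max + 1), w)}


def _validate_dist(dist: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
    ns = np.array(sorted(dist), dtype=int)
    ps = np.array([dist[int(n)] for n in ns], dtype=float)
    if ns.size == 0 or (ns < 1).any() or (ps < 0).any() or not np.isclose(ps.sum(), 1.0):
        raise ValueError("repeat_dist must be a proper distribution over n >= 1")
    return ns, ps / ps.sum()


def simulate_rca(
    design: RingDesign,
    n_molecules: int = 1000,
    repeat_dist: dict[int, float] | None = None,
    p_ss_end: float = 0.2,
    ss_len: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AmpliconPool:
    """Draw a synthetic amplicon pool from a ring design.

    Each molecule results from processive copying of a single circular
    template: for mixed-base rings one concrete expansion is drawn per
    molecule (uniformly per site) and *all* its repeat units are identical.
    End states are ss3prime or ss5prime each with probability
    ``p_ss_end / 2``, else blunt.  Deterministic given ``seed``.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not 0 <= p_ss_end <= 1:
        raise ValueError("p_ss_end must be in [0, 1]")
    rng = rng or np.random.default_rng(seed)
    dist = repeat_dist or geometric_repeat_dist()
    ns, ps = _validate_dist(dist)
    draw_n = rng.choice(ns, size=n_molecules, p=ps)

    template = str(design.linear)
    degen_pos = (
        design.linear.degenerate_positions()
        if isinstance(design.linear, DegenSeq)
        else ()
    )
    site_draws = {
        pos: rng.choice(sorted(IUPAC_DNA[template[pos]]), size=n_molecules)
        for pos in degen_pos
    }
    u = rng.random(n_molecules)

    counts: Counter[tuple] = Counter()
    chars = list(template)
    for i in range(n_molecules):
        for pos in degen_pos:
            chars[pos] = site_draws[pos][i]
        unit = "".join(chars) if degen_pos else template
        if u[i] < p_ss_end / 2:
            state = "ss3prime"
        elif u[i] < p_ss_end:
            state = "ss5prime"
        else:
            state = "blunt"
        counts[(unit, int(draw_n[i]), state)] += 1

    members = []
    for (unit, n, state), mult in sorted(counts.items()):
        members.append(
            (
                Amplicon(
                    n_repeats=n,
                    unit_variants=(unit,) * n,
                    fwd_overlap=str(design.fwd_overlap),
                    rev_overlap=str(design.rev_overlap),
                    end_state=state,
                    ss_len=0 if state == "blunt" else ss_len,
                ),
                mult,
            )
        )
    params = {
        "n_molecules": n_molecules,
        "repeat_dist": {int(k): float(v) for k, v in dist.items()},
        "p_ss_end": p_ss_end,
        "ss_len": ss_len,
        "ring_size": design.ring_size,
        "overlap_total": len(design.fwd_overlap) + len(design.rev_overlap),
    }
    return AmpliconPool(tuple(members), params=params, seed=seed)


def size_select(
    pool: AmpliconPool,
    target_n: int | None = None,
    window: tuple[float, float] | None = None,
    tol: float = 0.02,
) -> AmpliconPool:
    """Gel excision on true lengths: keep amplicons inside a bp window.

    ``target_n`` converts to the window ``predicted_length * (1 +/- tol)``
    using the pool's recorded ring size and overlap total.  Multiplicities
    are preserved; an empty result is returned (with a warning) rather
    than raised.
    """
    if (target_n is None) == (window is None):
        raise ValueError("give exactly one of target_n or window")
    if target_n is not None:
        ring = pool.params["ring_size"]
        ov = pool.params["overlap_total"]
        pred = target_n * ring + ov
        window = (pred * (1 - tol), pred * (1 + tol))
    lo, hi = window
    if hi < lo:
        raise ValueError("empty window")
    kept = tuple((a, m) for a, m in pool.members if lo <= len(a) <= hi)
    if not kept:
        warnings.warn("size selection produced an empty pool")
    return AmpliconPool(kept, params={**pool.params, "window": (lo, hi)}, seed=pool.seed)
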