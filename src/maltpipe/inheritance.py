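"""Tetrad segregation analysis and the serial-passage division budget.

A dominant allele at a single heterozygous locus segregates 2:2 in every
tetrad, giving equal numbers of trait-positive and trait-negative spores.
Departures (4:0, 3:1) point to multilocus architecture, gene conversion at
the locus, or phenotyping error; a small tolerated fraction of deviant
tetrads is configurable.

The division budget models the selection opportunity in a serial-passage
evolution experiment: lineages diluted 1:10 every few days, with cells that
cannot use the primary carbon source dividing roughly once per day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binomtest

from .core_seq import AnalysisError, InputError

POSITIVE = "positive"
NEGATIVE = "negative"
DEAD = "dead"
PHENOTYPES = (POSITIVE, NEGATIVE, DEAD)
PATTERNS = ("4:0", "3:1", "2:2", "1:3", "0:4")


@dataclass(frozen=True)
class TetradPattern:
    pattern: str  # "#positive:#negative" among viable spores
    n_viable: int
    complete: bool  # no dead spores


@dataclass(frozen=True)
class SegregationResult:
    n_tetrads: int  # fully viable tetrads analysed
    n_tetrads_total: int
    pattern_counts: dict[str, int]
    n_pos_spores: int
    n_neg_spores: int
    binomial_p: float
    consistent_single_locus: bool
    deviant_fraction: float


@dataclass(frozen=True)
class EvolutionRegime:
    """Serial-passage regime: passages, days between them, division rate,
    and the number of evolving lineages (strains x replicates)."""

    n_passages: int
    days_per_passage: tuple[float, float]  # (min, max) days between passages
    divisions_per_day: float
    n_lineages: int

    def __post_init__(self) -> None:
        lo, hi = self.days_per_passage
        if self.n_passages < 0 or self.n_lineages <= 0 or self.divisions_per_day <= 0:
            raise InputError("regime parameters must be positive")
        if not (0 < lo <= hi):
            raise InputError("days_per_passage must satisfy 0 < min <= max")


@dataclass(frozen=True)
class DivisionEstimate:
    exact: float
    rounded: int  # nearest 10, the convention used when quoting totals


def classify_tetrad(spores: Sequence[str]) -> TetradPattern:
    """Pattern of one tetrad: #positive:#negative among viable spores."""
    if len(spores) != 4:
        raise InputError(f"a tetrad has 4 spores, got {len(spores)}")
    for s in spores:
        if s not in PHENOTYPES:
            raise InputError(f"unknown phenotype {s!r}; expected one of {PHENOTYPES}")
    n_pos = sum(s == POSITIVE for s in spores)
    n_neg = sum(s == NEGATIVE for s in spores)
    return TetradPattern(
        pattern=f"{n_pos}:{n_neg}",
        n_viable=n_pos + n_neg,
        complete=(n_pos + n_neg == 4),
    )


def segregation_analysis(
    tetrads: pd.DataFrame | Iterable[Sequence[str]],
    deviant_tolerance: float = 0.10,
) -> SegregationResult:
    """Tally tetrad patterns and test single-locus 2:2 segregation.

    Only fully viable tetrads enter the pattern tally and the spore counts.
    ``consistent_single_locus`` is true when the fraction of fully viable
    tetrads deviating from 2:2 is at most ``deviant_tolerance`` (default 10%;
    occasional gene-conversion 3:1 tetrads are reported but tolerated).
    ``binomial_p`` is the exact two-sided binomial p-value (minimum-likelihood
    two-sided definition) for the positive-spore count against 1:1.
    """
    if isinstance(tetrads, pd.DataFrame):
        spore_cols = [c for c in tetrads.columns if c.startswith("spore")]
        if len(spore_cols) != 4:
            raise InputError("tetrad table needs columns spore1..spore4")
        rows = [tuple(r) for r in tetrads[spore_cols].itertuples(index=False)]
    else:
        rows = [tuple(t) for t in tetrads]

    patterns = [classify_tetrad(r) for r in rows]
    viable = [p for p in patterns if p.complete]
    if not viable:
        raise AnalysisError("no fully viable tetrads; segregation undefined")

    counts = {pat: 0 for pat in PATTERNS}
    for p in viable:
        counts[p.pattern] += 1
    n_pos = sum(int(p.pattern.split(":")[0]) for p in viable)
    n_neg = sum(int(p.pattern.split(":")[1]) for p in viable)
    deviant = 1.0 - counts["2:2"] / len(viable)
    p_value = exact_binomial_p(n_pos, n_pos + n_neg)
    return SegregationResult(
        n_tetrads=len(viable),
        n_tetrads_total=len(patterns),
        pattern_counts=counts,
        n_pos_spores=n_pos,
        n_neg_spores=n_neg,
        binomial_p=float(p_value),
        consistent_single_locus=deviant <= deviant_tolerance,
        deviant_fraction=deviant,
    )


def exact_binomial_p(k: int, n: int) -> float:
    """Exact two-sided binomial p-value against 1:1, minimum-likelihood
    two-sided definition (sum of all outcome probabilities <= P(observed))."""
    return float(binomtest(k, n, 0.5, alternative="two-sided").pvalue)


def expected_category_counts(n_tetrads: int) -> tuple[int, int]:
    """Expected (positive, negative) spore counts from fully viable tetrads
    under single-dominant-locus 2:2 segregation."""
    if n_tetrads < 0:
        raise InputError("n_tetrads must be >= 0")
    return (2 * n_tetrads, 2 * n_tetrads)


def estimate_divisions(regime: EvolutionRegime) -> DivisionEstimate:
    """Total cell divisions available to selection across all lineages.

    n_passages x mean passage interval x divisions/day x n_lineages; the
    passage interval is the midpoint of the stated (min, max) range. The
    rounded figure (nearest 10) is how such totals are conventionally quoted;
    the exact product is retained.
    """
    lo, hi = regime.days_per_passage
    exact = regime.n_passages * ((lo + hi) / 2.0) * regime.divisions_per_day
    exact *= regime.n_lineages
    return DivisionEstimate(exact=exact, rounded=int(round(exact / 10.0) * 10))
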