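"""Bulk-segregant mapping from pooled allele counts.

Two pools of segregants — trait-positive and trait-negative — are sequenced
as bulks. At a causal locus for a fully penetrant dominant trait the pools
carry opposite alleles at (near-)fixation; elsewhere free recombination keeps
both pools near 50%. The scan calls near-fixed differences per site, then
tiles the genome into non-overlapping windows (1 kb by default) and reports
windows holding fixed differences as candidate regions.

Depth-inflated windows are annotated, not dropped: collapsed paralogs (e.g.
ribosomal-protein gene families) attract reads from several loci and mimic
fixed differences, the classic BSA artifact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_seq import InputError

POOL_COUNT_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "pos_ref",
    "pos_alt",
    "neg_ref",
    "neg_alt",
]


@dataclass
class PoolCounts:
    """Per-site ref/alt read counts for the two phenotype pools.

    ``df`` columns: contig, pos (1-based), ref, alt, pos_ref, pos_alt
    (trait-positive pool), neg_ref, neg_alt (trait-negative pool), and an
    optional boolean ``multiallelic`` flag.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in POOL_COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"pool counts missing column(s): {missing}")
        if "multiallelic" not in self.df.columns:
            self.df = self.df.assign(multiallelic=False)
        counts = self.df[["pos_ref", "pos_alt", "neg_ref", "neg_alt"]]
        if (counts.to_numpy() < 0).any():
            raise InputError("negative read counts")
        for contig, sub in self.df.groupby("contig", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise InputError(
                    f"positions not strictly increasing on contig {contig!r}"
                )

    def __len__(self) -> int:
        return len(self.df)


class SiteStatus(enum.Enum):
    FIXED_DIFFERENCE = "fixed_difference"
    NOT_FIXED = "not_fixed"
    LOW_DEPTH = "low_depth"


@dataclass(frozen=True)
class CandidateWindow:
    contig: str
    start: int  # 1-based inclusive
    end: int
    n_fixed: int
    mean_depth_ratio: float = float("nan")
    artifact_flag: bool = False


@dataclass(frozen=True)
class Region:
    """Adjacent candidate windows merged into one reported region."""

    contig: str
    start: int
    end: int
    n_fixed: int
    n_windows: int


@dataclass
class ScanResult:
    windows: list[CandidateWindow]
    regions: list[Region]
    n_sites: int
    n_fixed_sites: int
    thresholds: dict = field(default_factory=dict)


def call_fixed_sites(
    counts: PoolCounts,
    min_depth: int = 10,
    fix_hi: float = 0.95,
    fix_lo: float = 0.05,
) -> pd.DataFrame:
    """Call near-fixed allele-frequency differences between the pools.

    A site is a fixed difference when the alt-allele frequency is >= fix_hi
    in one pool and <= fix_lo in the other, with both pool depths >= min_depth.
    Returns the input table with freq_pos, freq_neg and status columns added.
    """
    df = counts.df.copy()
    depth_pos = df["pos_ref"] + df["pos_alt"]
    depth_neg = df["neg_ref"] + df["neg_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_pos = np.where(depth_pos > 0, df["pos_alt"] / depth_pos, np.nan)
        freq_neg = np.where(depth_neg > 0, df["neg_alt"] / depth_neg, np.nan)
    low = (depth_pos < min_depth) | (depth_neg < min_depth)
    fixed = (
        ((freq_pos >= fix_hi) & (freq_neg <= fix_lo))
        | ((freq_pos <= fix_lo) & (freq_neg >= fix_hi))
    ) & ~low
    status = np.where(
        low,
        SiteStatus.LOW_DEPTH.value,
        np.where(fixed, SiteStatus.FIXED_DIFFERENCE.value, SiteStatus.NOT_FIXED.value),
    )
    return df.assign(freq_pos=freq_pos, freq_neg=freq_neg, status=status)


def window_scan(
    calls: pd.DataFrame,
    contig_lengths: dict[str, int],
    window: int = 1000,
    min_fixed: int = 1,
) -> ScanResult:
    """Tile each contig into non-overlapping windows and report those with
    at least ``min_fixed`` fixed-difference sites.

    Adjacent candidate windows are additionally merged into regions so a
    locus spanning a tile boundary is reported once.
    """
    if window <= 0:
        raise InputError("window size must be positive")
    fixed = calls[calls["status"] == SiteStatus.FIXED_DIFFERENCE.value]
    windows: list[CandidateWindow] = []
    for contig, length in contig_lengths.items():
        sub = fixed[fixed["contig"] == contig]
        if len(sub):
            idx = (sub["pos"].to_numpy() - 1) // window
            tally = np.bincount(idx, minlength=(length + window - 1) // window)
        else:
            tally = np.zeros((length + window - 1) // window, dtype=int)
        for wi, n in enumerate(tally):
            if n >= min_fixed:
                windows.append(
                    CandidateWindow(
                        contig=contig,
                        start=wi * window + 1,
                        end=min((wi + 1) * window, length),
                        n_fixed=int(n),
                    )
                )

    regions: list[Region] = []
    for w in windows:
        if (
            regions
            and regions[-1].contig == w.contig
            and regions[-1].end + 1 == w.start
        ):
            last = regions[-1]
            regions[-1] = Region(
                contig=last.contig,
                start=last.start,
                end=w.end,
                n_fixed=last.n_fixed + w.n_fixed,
                n_windows=last.n_windows + 1,
            )
        else:
            regions.append(
                Region(
                    contig=w.contig,
                    start=w.start,
                    end=w.end,
                    n_fixed=w.n_fixed,
                    n_windows=1,
                )
            )
    return ScanResult(
        windows=windows,
        regions=regions,
        n_sites=len(calls),
        n_fixed_sites=int(len(fixed)),
        thresholds={"window": window, "min_fixed": min_fixed},
    )


def flag_artifacts(
    result: ScanResult,
    counts: PoolCounts,
    depth_ratio_threshold: float = 1.8,
) -> ScanResult:
    """Annotate candidate windows whose mean depth is inflated relative to
    the genome median — a proxy for collapsed-paralog mapping artifacts.

    The flag never removes a window; it only marks it suspect.
    """
    df = counts.df
    total_depth = (
        df["pos_ref"] + df["pos_alt"] + df["neg_ref"] + df["neg_alt"]
    ).to_numpy()
    median_depth = float(np.median(total_depth)) if len(df) else float("nan")

    annotated: list[CandidateWindow] = []
    for w in result.windows:
        mask = (
            (df["contig"] == w.contig)
            & (df["pos"] >= w.start)
            & (df["pos"] <= w.end)
        ).to_numpy()
        if mask.any() and median_depth > 0:
            ratio = float(total_depth[mask].mean()) / median_depth
        else:
            ratio = float("nan")
        annotated.append(
            replace(
                w,
                mean_depth_ratio=ratio,
                artifact_flag=bool(ratio > depth_ratio_threshold),
            )
        )
    result.windows = annotated
    result.thresholds["depth_ratio_threshold"] = depth_ratio_threshold
    return result
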