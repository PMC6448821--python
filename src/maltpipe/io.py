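"""Readers and writers for the formats the pipeline touches.

FASTA via Bio.SeqIO; pooled allele counts as an eight-column TSV or a
minimal VCF subset (CHROM/POS/REF/ALT plus per-sample AD, first two samples
taken as trait-positive then trait-negative pool) via pysam; candidate
windows as BED. Internally coordinates are 0-based half-open; reports are
1-based inclusive, BED is 0-based half-open, and every writer states its
convention, thresholds and seed in header comments so outputs are
self-describing and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .bsa import CandidateWindow, PoolCounts, POOL_COUNT_COLUMNS, ScanResult
from .core_seq import GeneSequence, InputError

logger = logging.getLogger("maltpipe")

SCHEMA_VERSION = 1


def read_fasta(path: str | Path, is_cds: bool = False) -> list[GeneSequence]:
    """Read a FASTA file into GeneSequences.

    Lowercase residues are uppercased with a warning; duplicate ids are
    rejected; an empty file returns an empty list with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
        return []
    seen: set[str] = set()
    out: list[GeneSequence] = []
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"lowercase bases in {rec.id!r} uppercased", stacklevel=2)
            seq = seq.upper()
        out.append(GeneSequence(id=rec.id, seq=seq, is_cds=is_cds))
    return out


def write_fasta(seqs: Iterable[GeneSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def read_pool_counts(path: str | Path, dialect: str = "tsv") -> PoolCounts:
    """Read per-site two-pool allele counts from TSV or a minimal VCF.

    The TSV dialect expects the eight columns contig, pos, ref, alt,
    pos_ref, pos_alt, neg_ref, neg_alt. The VCF dialect uses CHROM, POS,
    REF, ALT and per-sample AD from the first two samples (positive pool
    first); multiallelic records are collapsed to ref vs the highest-depth
    alt and flagged.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in POOL_COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"{path}: missing TSV column(s) {missing}")
        return PoolCounts(df[POOL_COUNT_COLUMNS].copy())
    if dialect == "vcf_min":
        return _read_vcf_min(path)
    raise InputError(f"unknown pool-count dialect {dialect!r}")


def _read_vcf_min(path: str | Path) -> PoolCounts:
    rows = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) < 2:
            raise InputError(f"{path}: need two samples (positive, negative pool)")
        pos_sample, neg_sample = samples[0], samples[1]
        for rec in vcf:
            if not rec.alts:
                continue
            ads = {}
            for name in (pos_sample, neg_sample):
                ad = rec.samples[name].get("AD")
                if ad is None or ad[0] is None:
                    raise InputError(
                        f"{path}: record {rec.chrom}:{rec.pos} missing AD for "
                        f"sample {name!r}"
                    )
                ads[name] = list(ad)
            multiallelic = len(rec.alts) > 1
            if multiallelic:
                n_multi += 1
                total_per_alt = [
                    ads[pos_sample][i + 1] + ads[neg_sample][i + 1]
                    for i in range(len(rec.alts))
                ]
                ai = int(max(range(len(rec.alts)), key=total_per_alt.__getitem__))
            else:
                ai = 0
            rows.append(
                {
                    "contig": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref[0],
                    "alt": rec.alts[ai][0],
                    "pos_ref": ads[pos_sample][0],
                    "pos_alt": ads[pos_sample][ai + 1],
                    "neg_ref": ads[neg_sample][0],
                    "neg_alt": ads[neg_sample][ai + 1],
                    "multiallelic": multiallelic,
                }
            )
    if n_multi:
        logger.info("collapsed %d multiallelic record(s) to ref vs major alt", n_multi)
    return PoolCounts(pd.DataFrame(rows))


def _header_lines(seed: int | None, thresholds: dict | None) -> list[str]:
    lines = [f"maltpipe v{__version__}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    for k, v in (thresholds or {}).items():
        lines.append(f"{k}={v}")
    return lines


def write_windows_bed(
    windows: list[CandidateWindow],
    path: str | Path,
    seed: int | None = None,
    thresholds: dict | None = None,
) -> None:
    """BED (0-based half-open) of candidate windows: a 1-based inclusive
    window 1001-2000 emits start 1000, end 2000."""
    with open(path, "w") as fh:
        for line in _header_lines(seed, thresholds):
            fh.write(f"# {line}\n")
        fh.write("# coordinates: BED 0-based half-open\n")
        for w in windows:
            name = f"n_fixed={w.n_fixed}" + (";artifact" if w.artifact_flag else "")
            fh.write(f"{w.contig}\t{w.start - 1}\t{w.end}\t{name}\n")


def read_windows_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED back as 1-based inclusive (contig, start, end) — test aid."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, start, end = line.split("\t")[:3]
        out.append((contig, int(start) + 1, int(end)))
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "value") and obj.__class__.__module__.startswith("maltpipe"):
        return obj.value  # enums
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def write_report_json(
    report,
    path: str | Path,
    seed: int | None = None,
    thresholds: dict | None = None,
) -> None:
    """Versioned JSON envelope around any report dataclass; coordinates in
    the payload are 1-based inclusive."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "tool": f"maltpipe v{__version__}",
        "seed": seed,
        "thresholds": thresholds or {},
        "coordinates": "1-based inclusive",
        "report": _jsonable(report),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_fixed_sites_tsv(
    calls: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    thresholds: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(seed, thresholds):
            fh.write(f"# {line}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        calls.to_csv(fh, sep="\t", index=False)


def write_identity_track_tsv(
    track,
    path: str | Path,
    seed: int | None = None,
    label: str = "",
) -> None:
    """Identity track as (center, percent_identity) TSV, centers 1-based."""
    with open(path, "w") as fh:
        for line in _header_lines(seed, {"window": track.window, "step": track.step}):
            fh.write(f"# {line}\n")
        fh.write("# coordinates: 1-based window centers\n")
        if label:
            fh.write(f"# track: {label}\n")
        fh.write("center\tpercent_identity\n")
        for c, v in zip(track.centers, track.values):
            fh.write(f"{c + 1}\t{v:.2f}\n")


def summarize_scan(result: ScanResult) -> dict:
    return {
        "n_sites": result.n_sites,
        "n_fixed_sites": result.n_fixed_sites,
        "n_candidate_windows": len(result.windows),
        "n_regions": len(result.regions),
        "n_artifact_flagged": sum(w.artifact_flag for w in result.windows),
        "thresholds": result.thresholds,
    }
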