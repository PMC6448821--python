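"""Sequence primitives: pairwise global alignment, identity tracks, codon work.

Everything downstream (chimera detection, the simulator's self-checks) builds
on these. Coordinates are 0-based half-open internally; human-facing reports
are 1-based inclusive and say so in their headers.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGTN")
GAP = "-"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))


class InputError(ValueError):
    """Invalid user-facing input (exit code 2 at the CLI)."""


class AnalysisError(RuntimeError):
    """Analysis cannot proceed on otherwise well-formed input (exit code 3)."""


@dataclass(frozen=True)
class GeneSequence:
    """A named nucleotide sequence over {A,C,G,T,N}.

    ``is_cds`` asserts the sequence is a coding sequence read in frame from
    position 1, hence length divisible by 3.
    """

    id: str
    seq: str
    is_cds: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )
        if self.is_cds and len(self.seq) % 3 != 0:
            raise InputError(
                f"CDS {self.id!r} has length {len(self.seq)}, not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gap-padded sequences in register.

    Invariants: equal row lengths; ungapping a row reproduces the input
    sequence; no column is gap in both rows.
    """

    id_a: str
    id_b: str
    aln_a: str
    aln_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aln_a) != len(self.aln_b):
            raise ValueError("alignment rows differ in length")
        for ca, cb in zip(self.aln_a, self.aln_b):
            if ca == GAP and cb == GAP:
                raise ValueError("all-gap column in alignment")

    @property
    def length(self) -> int:
        return len(self.aln_a)

    def ungapped(self, row: str) -> str:
        aln = self.aln_a if row == "a" else self.aln_b
        return aln.replace(GAP, "")


@dataclass(frozen=True)
class IdentityTrack:
    """Sliding-window percent identity along an alignment.

    ``centers`` are 0-based alignment-column indices of window centers;
    writers convert to 1-based. Windows that are mostly N are dropped.
    """

    window: int
    step: int
    centers: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.values):
            raise ValueError("centers/values length mismatch")
        if any(not (0.0 <= v <= 100.0) for v in self.values):
            raise ValueError("identity values outside [0, 100]")


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-padded CDS rows whose gaps come in whole-codon ('---') units."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("codon alignment rows differ in length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError("codon alignment column count not divisible by 3")

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")


class SubstitutionClass(enum.Enum):
    NONE = "none"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    MULTI_HIT = "multi_hit"
    STOP_INVOLVED = "stop_involved"


@dataclass(frozen=True)
class Translation:
    """Protein product of a CDS with stop-codon bookkeeping."""

    protein: str
    terminal_stop: bool
    internal_stop_positions: tuple[int, ...] = field(default=())

    @property
    def clean(self) -> bool:
        return not self.internal_stop_positions


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_align(
    a: GeneSequence,
    b: GeneSequence,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment under linear gap costs.

    Deterministic: of the co-optimal alignments the first in the aligner's
    canonical enumeration order is always returned.
    """
    aligner = _make_aligner(match, mismatch, gap)
    result = aligner.align(a.seq, b.seq)
    best = result[0]
    aln = PairwiseAlignment(
        id_a=a.id, id_b=b.id, aln_a=best[0], aln_b=best[1], score=float(best.score)
    )
    assert aln.ungapped("a") == a.seq and aln.ungapped("b") == b.seq
    return aln


def percent_identity(aln: PairwiseAlignment, level: str = "nt") -> float:
    """Percent identity over comparable (gap-free) columns.

    Columns with a gap in either row are excluded from the denominator
    (p-identity convention). ``level="aa"`` translates the ungapped rows,
    realigns the proteins globally and scores that alignment; both rows must
    then ungap to valid in-frame CDS.
    """
    if level == "aa":
        prot_a = translate_cds(GeneSequence(aln.id_a, aln.ungapped("a"), is_cds=True))
        prot_b = translate_cds(GeneSequence(aln.id_b, aln.ungapped("b"), is_cds=True))
        aligner = _make_aligner(1.0, -1.0, -2.0)
        best = aligner.align(prot_a.protein, prot_b.protein)[0]
        row_a, row_b = best[0], best[1]
    elif level == "nt":
        row_a, row_b = aln.aln_a, aln.aln_b
    else:
        raise InputError(f"unknown identity level {level!r}")

    matches = comparable = 0
    for ca, cb in zip(row_a, row_b):
        if ca == GAP or cb == GAP:
            continue
        comparable += 1
        if ca == cb and ca != "N" and ca != "X":
            matches += 1
    if comparable == 0:
        raise AnalysisError("no comparable (gap-free) columns; identity undefined")
    return 100.0 * matches / comparable


def sliding_identity(
    aln: PairwiseAlignment,
    window: int = 10,
    step: int = 1,
    n_mask_fraction: float = 0.5,
) -> IdentityTrack:
    """Percent identity in sliding windows along the alignment.

    Inside a window, gap columns count as mismatches (indel-rich windows
    score low rather than disappear). N never counts as a match; windows
    with more than ``n_mask_fraction`` N-containing columns are masked out
    of the track.
    """
    if window < 1 or step < 1:
        raise InputError("window and step must be positive")
    n = aln.length
    if window > n:
        raise InputError(f"window {window} exceeds alignment length {n}")

    arr_a = np.frombuffer(aln.aln_a.encode(), dtype="S1")
    arr_b = np.frombuffer(aln.aln_b.encode(), dtype="S1")
    is_match = (arr_a == arr_b) & (arr_a != b"-") & (arr_a != b"N")
    has_n = (arr_a == b"N") | (arr_b == b"N")

    match_cum = np.concatenate(([0], np.cumsum(is_match)))
    n_cum = np.concatenate(([0], np.cumsum(has_n)))

    centers: list[int] = []
    values: list[float] = []
    for start in range(0, n - window + 1, step):
        end = start + window
        if (n_cum[end] - n_cum[start]) > n_mask_fraction * window:
            continue
        centers.append(start + (window - 1) // 2)
        values.append(100.0 * (match_cum[end] - match_cum[start]) / window)
    return IdentityTrack(
        window=window, step=step, centers=tuple(centers), values=tuple(values)
    )


def translate_cds(nt: GeneSequence) -> Translation:
    """Standard-code translation of an in-frame CDS.

    Codons containing N translate to 'X'. A terminal stop is removed and
    flagged; internal stops trigger a warning and are flagged (translated
    as '*', not silently dropped).
    """
    if len(nt.seq) % 3 != 0:
        raise InputError(f"CDS {nt.id!r} length {len(nt.seq)} not divisible by 3")
    protein = str(Seq(nt.seq).translate())
    terminal_stop = protein.endswith("*")
    if terminal_stop:
        protein = protein[:-1]
    internal = tuple(i for i, aa in enumerate(protein) if aa == "*")
    if internal:
        warnings.warn(
            f"CDS {nt.id!r} contains internal stop codon(s) at protein "
            f"position(s) {[i + 1 for i in internal]}",
            stacklevel=2,
        )
    return Translation(
        protein=protein,
        terminal_stop=terminal_stop,
        internal_stop_positions=internal,
    )


def codon_align(
    protein_alignment: dict[str, str], cds: dict[str, GeneSequence]
) -> CodonAlignment:
    """Back-translate a protein alignment onto the source CDS sequences.

    Each residue expands to its source codon; each gap expands to '---'.
    Raises a consistency error naming the first offending residue if a
    protein row does not translate from its CDS.
    """
    if set(protein_alignment) != set(cds):
        raise InputError("protein alignment and CDS sets carry different ids")
    rows: dict[str, str] = {}
    for seq_id, prot_row in protein_alignment.items():
        seq = cds[seq_id]
        translated = translate_cds(seq).protein
        residues = prot_row.replace(GAP, "")
        if residues != translated:
            pos = next(
                (i for i, (x, y) in enumerate(zip(residues, translated)) if x != y),
                min(len(residues), len(translated)),
            )
            raise InputError(
                f"protein row for {seq_id!r} disagrees with its CDS translation "
                f"at residue {pos + 1}"
            )
        out: list[str] = []
        codon_i = 0
        for aa in prot_row:
            if aa == GAP:
                out.append("---")
            else:
                out.append(seq.seq[3 * codon_i : 3 * codon_i + 3])
                codon_i += 1
        rows[seq_id] = "".join(out)
    return CodonAlignment(rows=rows)


def classify_codon_change(ref_codon: str, alt_codon: str) -> SubstitutionClass:
    """Classify a codon substitution by its amino-acid effect.

    Identical codons -> NONE; a single-position difference is SYNONYMOUS or
    NONSYNONYMOUS by comparing translated residues; two or more differing
    positions -> MULTI_HIT. Stop codons on either side are flagged as
    STOP_INVOLVED rather than silently classified.
    """
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or set(codon) - set("ACGT"):
            raise InputError(f"not a valid codon: {codon!r}")
    if ref_codon in STOP_CODONS or alt_codon in STOP_CODONS:
        return SubstitutionClass.STOP_INVOLVED
    n_diff = sum(r != a for r, a in zip(ref_codon, alt_codon))
    if n_diff == 0:
        return SubstitutionClass.NONE
    if n_diff >= 2:
        return SubstitutionClass.MULTI_HIT
    aa_ref = _STANDARD_TABLE.forward_table[ref_codon]
    aa_alt = _STANDARD_TABLE.forward_table[alt_codon]
    return (
        SubstitutionClass.SYNONYMOUS
        if aa_ref == aa_alt
        else SubstitutionClass.NONSYNONYMOUS
    )
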