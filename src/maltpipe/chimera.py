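"""Ectopic gene-conversion (chimeric allele) detection.

A candidate gene is compared against a panel of paralogs. At *informative
sites* — alignment columns where two parents differ — the candidate's base
votes for one parent or the other. A chimeric allele created by gene
conversion shows a backbone of recipient-matching sites interrupted by one
(or more) contiguous run of donor-matching sites: the conversion tract.

Tracts are delimited two ways, because clustered-SNP evidence cannot pin an
exchange breakpoint to a base: the *minimal span* covers the donor-matching
sites themselves, while the *maximal span* extends to just inside the nearest
flanking recipient-matching sites, the widest interval consistent with the
observed markers. All spans are 1-based inclusive in candidate coordinates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .core_seq import (
    GAP,
    AnalysisError,
    GeneSequence,
    InputError,
    SubstitutionClass,
    classify_codon_change,
    global_align,
    translate_cds,
)


class SiteState(enum.Enum):
    MATCHES_A = "matches_A"
    MATCHES_B = "matches_B"
    MATCHES_BOTH = "matches_both"
    MATCHES_NEITHER = "matches_neither"


@dataclass(frozen=True)
class SiteAssignment:
    """One informative site: where the two parents disagree, whom does the
    candidate match?  ``position_candidate`` is 1-based in the ungapped
    candidate sequence."""

    position_candidate: int
    state: SiteState
    candidate_base: str
    parent_a_base: str
    parent_b_base: str


@dataclass(frozen=True)
class ConversionTract:
    donor_id: str
    recipient_id: str
    minimal_span: tuple[int, int]
    maximal_span: tuple[int, int]
    n_support_sites: int
    n_snps_vs_recipient: int = 0
    n_nonsynonymous: int = 0
    n_synonymous: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maximal_span
        mlo, mhi = self.minimal_span
        if not (lo <= mlo <= mhi <= hi):
            raise ValueError("minimal_span must nest within maximal_span")


@dataclass(frozen=True)
class ChimeraReport:
    candidate_id: str
    recipient_id: str
    donor_id: str
    tracts: tuple[ConversionTract, ...]
    residual_unexplained_sites: int
    n_informative_sites: int
    n_gap_columns_skipped: int
    isolated_donor_sites: tuple[int, ...] = field(default=())
    tie: bool = False


def _project_onto_candidate(
    candidate: GeneSequence, parent: GeneSequence
) -> list[str | None]:
    """Parent base in register with each candidate position (None = gap).

    Equal-length sequences are treated as already in positional register
    (the convention of the simulator and of conversion between same-length
    paralogs); otherwise the register comes from global alignment.
    """
    if len(parent.seq) == len(candidate.seq):
        return list(parent.seq)
    aln = global_align(candidate, parent)
    proj: list[str | None] = []
    for c_char, p_char in zip(aln.aln_a, aln.aln_b):
        if c_char == GAP:
            continue
        proj.append(None if p_char == GAP else p_char)
    assert len(proj) == len(candidate.seq)
    return proj


def informative_sites(
    candidate: GeneSequence,
    parent_a: GeneSequence,
    parent_b: GeneSequence,
) -> tuple[list[SiteAssignment], int]:
    """Assign the candidate's base to a parent at every site where the
    parents differ.

    The three-way register is built by aligning each parent to the candidate
    and projecting onto candidate coordinates. Positions where either
    projection is a gap are skipped; the count of skipped otherwise-
    informative positions is returned alongside the assignments.
    """
    proj_a = _project_onto_candidate(candidate, parent_a)
    proj_b = _project_onto_candidate(candidate, parent_b)
    return _sites_from_projections(candidate.seq, proj_a, proj_b)


def _sites_from_projections(
    cand_seq: str, proj_a: list[str | None], proj_b: list[str | None]
) -> tuple[list[SiteAssignment], int]:
    sites: list[SiteAssignment] = []
    n_gap_skipped = 0
    for i, (c, a, b) in enumerate(zip(cand_seq, proj_a, proj_b)):
        if a is None or b is None:
            n_gap_skipped += 1
            continue
        if a == b:
            continue
        if c == a:
            state = SiteState.MATCHES_A
        elif c == b:
            state = SiteState.MATCHES_B
        else:
            state = SiteState.MATCHES_NEITHER
        sites.append(
            SiteAssignment(
                position_candidate=i + 1,
                state=state,
                candidate_base=c,
                parent_a_base=a,
                parent_b_base=b,
            )
        )
    return sites, n_gap_skipped


def infer_tracts(
    assignments: list[SiteAssignment],
    min_run: int = 3,
    donor_state: SiteState = SiteState.MATCHES_B,
    candidate_length: int | None = None,
) -> tuple[list[ConversionTract], list[int]]:
    """Segment donor-matching runs into conversion tracts.

    Maximal runs of >= ``min_run`` consecutive donor-state sites (consecutive
    among parent-assigned informative sites) become tracts. Shorter runs are
    returned separately as isolated donor-matching positions — point
    conversions or homoplasy, not tract evidence.
    """
    recipient_state = (
        SiteState.MATCHES_A if donor_state == SiteState.MATCHES_B else SiteState.MATCHES_B
    )
    informative = [
        s for s in assignments if s.state in (donor_state, recipient_state)
    ]
    informative.sort(key=lambda s: s.position_candidate)

    runs: list[list[SiteAssignment]] = []
    current: list[SiteAssignment] = []
    for site in informative:
        if site.state == donor_state:
            current.append(site)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)

    tracts: list[ConversionTract] = []
    isolated: list[int] = []
    recipient_positions = [
        s.position_candidate for s in informative if s.state == recipient_state
    ]
    last_pos = candidate_length if candidate_length is not None else (
        informative[-1].position_candidate if informative else 0
    )
    for run in runs:
        if len(run) < min_run:
            isolated.extend(s.position_candidate for s in run)
            continue
        first, last = run[0].position_candidate, run[-1].position_candidate
        prev_recip = max(
            (p for p in recipient_positions if p < first), default=0
        )
        next_recip = min(
            (p for p in recipient_positions if p > last), default=last_pos + 1
        )
        tracts.append(
            ConversionTract(
                donor_id="",
                recipient_id="",
                minimal_span=(first, last),
                maximal_span=(prev_recip + 1, next_recip - 1),
                n_support_sites=len(run),
            )
        )
    return tracts, isolated


def tract_statistics(
    tract: ConversionTract,
    candidate: GeneSequence,
    recipient: GeneSequence,
) -> ConversionTract:
    """Count substitutions of the candidate against the recipient inside the
    tract's maximal span, split synonymous / nonsynonymous per codon.

    SNPs are counted per nucleotide position. Codon effects use the codon
    overlap with the span; a codon hit at two or three positions is counted
    once, as nonsynonymous when the amino acid changes, else synonymous.
    """
    lo, hi = tract.maximal_span
    if not (1 <= lo <= hi <= len(candidate.seq)):
        raise InputError(
            f"tract span {tract.maximal_span} outside candidate 1..{len(candidate.seq)}"
        )
    proj = _project_onto_candidate(candidate, recipient)
    n_snps = sum(
        1
        for i in range(lo - 1, hi)
        if proj[i] is not None and proj[i] != candidate.seq[i]
    )

    n_syn = n_nonsyn = 0
    if candidate.is_cds:
        first_codon = (lo - 1) // 3
        last_codon = (hi - 1) // 3
        for ci in range(first_codon, last_codon + 1):
            cand_codon = candidate.seq[3 * ci : 3 * ci + 3]
            recip = proj[3 * ci : 3 * ci + 3]
            if any(b is None for b in recip) or len(cand_codon) < 3:
                continue
            recip_codon = "".join(recip)  # type: ignore[arg-type]
            if "N" in cand_codon or "N" in recip_codon:
                continue
            cls = classify_codon_change(recip_codon, cand_codon)
            if cls == SubstitutionClass.SYNONYMOUS:
                n_syn += 1
            elif cls == SubstitutionClass.NONSYNONYMOUS:
                n_nonsyn += 1
            elif cls in (SubstitutionClass.MULTI_HIT, SubstitutionClass.STOP_INVOLVED):
                aa_c = translate_cds(GeneSequence("c", cand_codon, is_cds=True)).protein
                aa_r = translate_cds(GeneSequence("r", recip_codon, is_cds=True)).protein
                if aa_c != aa_r:
                    n_nonsyn += 1
                else:
                    n_syn += 1
    return replace(
        tract,
        n_snps_vs_recipient=n_snps,
        n_nonsynonymous=n_nonsyn,
        n_synonymous=n_syn,
    )


def scan_gene_family(
    candidate: GeneSequence,
    panel: list[GeneSequence],
    min_run: int = 3,
) -> ChimeraReport:
    """Find the (recipient, donor) paralog pair that best explains the
    candidate as a gene-conversion chimera.

    Every ordered pair from the panel is scored; the pair leaving the fewest
    informative sites matching neither parent wins, with ties broken by
    fewer inferred tracts, then lexicographically by (recipient, donor) id.
    """
    if len(panel) < 2:
        raise InputError("panel must contain at least 2 paralogs")
    if len({g.id for g in panel}) != len(panel):
        raise InputError("panel ids must be unique")

    projections = {g.id: _project_onto_candidate(candidate, g) for g in panel}
    by_id = {g.id: g for g in panel}

    best_key: tuple | None = None
    best: ChimeraReport | None = None
    tie = False
    for recipient in sorted(by_id):
        for donor in sorted(by_id):
            if recipient == donor:
                continue
            sites, n_gap = _sites_from_projections(
                candidate.seq, projections[recipient], projections[donor]
            )
            tracts, isolated = infer_tracts(
                sites,
                min_run=min_run,
                donor_state=SiteState.MATCHES_B,
                candidate_length=len(candidate.seq),
            )
            residual = sum(1 for s in sites if s.state == SiteState.MATCHES_NEITHER)
            key = (residual, len(tracts), recipient, donor)
            if best_key is None or key < best_key:
                # pairs arrive in lexicographic order, so a strictly better
                # key means a fresh unique optimum
                tie = False
                best_key = key
                best = ChimeraReport(
                    candidate_id=candidate.id,
                    recipient_id=recipient,
                    donor_id=donor,
                    tracts=tuple(
                        replace(t, donor_id=donor, recipient_id=recipient)
                        for t in tracts
                    ),
                    residual_unexplained_sites=residual,
                    n_informative_sites=len(sites),
                    n_gap_columns_skipped=n_gap,
                    isolated_donor_sites=tuple(isolated),
                )
            elif key[:2] == best_key[:2]:
                tie = True

    assert best is not None
    completed = tuple(
        tract_statistics(t, candidate, by_id[best.recipient_id]) for t in best.tracts
    )
    return replace(best, tracts=completed, tie=tie)
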