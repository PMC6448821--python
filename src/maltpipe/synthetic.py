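"""Seeded generators for every input the pipeline consumes, with ground truth.

The default scenario emulates the genetics of a maltotriose-utilization
mapping experiment in *Saccharomyces eubayanus*: a four-member MALT
transporter paralog family at ~80% nucleotide identity, a single ~230-bp
ectopic gene-conversion tract copying donor sequence into a recipient
paralog, 15 fully viable backcross tetrads segregating the derived allele
2:2 (30 trait-positive and 30 trait-negative segregants), and pooled
sequencing of the two phenotype bulks at ~100x depth simulated at the
allele-count level with a per-read error rate.

All generators are pure functions of (parameters, seed) via
``numpy.random.default_rng``; the same seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bsa import PoolCounts
from .core_seq import GeneSequence, InputError, SENSE_CODONS, STOP_CODONS

BASES = np.frombuffer(b"ACGT", dtype="S1")
BASE_INDEX = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
# transition partner first, then the two transversions
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


class ConfigError(InputError):
    pass


@dataclass(frozen=True)
class FamilyParams:
    """Paralog-family generator parameters.

    ``target_nt_identity`` is the pairwise nucleotide identity every pair of
    family members should realize (within +/-2 percentage points); 1848 bp
    (~616 aa) is a typical MFS sugar-transporter CDS length.
    """

    n_genes: int = 4
    cds_length: int = 1848
    target_nt_identity: float = 0.80
    ts_tv_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0 or self.cds_length < 9:
            raise ConfigError("cds_length must be a multiple of 3 and >= 9")
        if not (0.0 < self.target_nt_identity <= 1.0):
            raise ConfigError("target_nt_identity must lie in (0, 1]")
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")


@dataclass(frozen=True)
class TrueConversion:
    donor_id: str
    recipient_id: str
    tract: tuple[int, int]  # 1-based inclusive, recipient coordinates


@dataclass(frozen=True)
class ScenarioConfig:
    genome_length: int = 100_000
    contig: str = "chrI"
    n_genes: int = 4
    cds_length: int = 1848
    target_nt_identity: float = 0.80
    tract_length: int = 230
    n_tetrads: int = 15
    marker_spacing: int = 500
    coverage: float = 100.0
    error_rate: float = 0.005
    causal: bool = True

    def __post_init__(self) -> None:
        if self.genome_length < 2 * self.marker_spacing:
            raise ConfigError("genome too short for the marker spacing")
        if self.tract_length < 1 or self.tract_length > self.cds_length:
            raise ConfigError("tract_length must lie in [1, cds_length]")


@dataclass
class ScenarioTruth:
    """Everything needed to score downstream calls against the simulation."""

    config: ScenarioConfig
    seed: int
    marker_positions: list[int]
    causal_marker_index: int | None
    causal_window: tuple[int, int] | None  # 1-based inclusive, default tiling
    conversion: TrueConversion | None
    phenotypes: list[str]  # per spore, tetrad-major order
    genotypes: list[list[int]]  # spore x marker, 1 = derived allele

    def to_json(self) -> str:
        d = asdict(self)
        d["config"] = asdict(self.config)
        return json.dumps(d, indent=2)


def _random_cds(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random in-frame CDS as an S1 array: ATG start, sense codons only."""
    n_codons = length // 3
    codons = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    seq = "ATG" + "".join(SENSE_CODONS[i] for i in codons[1:])
    return np.frombuffer(seq.encode(), dtype="S1").copy()


def _mutate_site(seq: np.ndarray, pos: int, rng: np.random.Generator,
                 ts_tv_ratio: float) -> bool:
    """Propose a point mutation at pos; reject if it creates a stop codon.

    Transitions are favoured over each transversion by ``ts_tv_ratio``.
    Returns True if the mutation was applied.
    """
    old = BASE_INDEX[bytes(seq[pos])]
    ts = _TRANSITION[old]
    tv = [b for b in range(4) if b != old and b != ts]
    w = np.array([ts_tv_ratio, 1.0, 1.0])
    new = rng.choice([ts, tv[0], tv[1]], p=w / w.sum())
    codon_start = 3 * (pos // 3)
    codon = seq[codon_start : codon_start + 3].copy()
    codon[pos - codon_start] = BASES[new]
    if codon.tobytes().decode() in STOP_CODONS:
        return False
    seq[pos] = BASES[new]
    return True


def _pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    return float((a == b).mean())


def simulate_gene_family(
    params: FamilyParams,
) -> tuple[list[GeneSequence], GeneSequence]:
    """Derive a paralog family from a common random ancestor by codon-aware
    point mutation until every pair sits within +/-2 percentage points of the
    target nucleotide identity.

    Mutations that would create a stop codon are rejected, so every family
    member stays a clean CDS and amino-acid identity tracks nucleotide
    identity, as in real Malt transporter paralogs. The first codon (ATG) is
    never mutated. Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    L = params.cds_length
    t = params.target_nt_identity
    ancestor = _random_cds(rng, L)
    seqs = [ancestor.copy() for _ in range(params.n_genes)]

    if t < 1.0:
        # per-branch divergence m solving pairwise mismatch 2m(1-m) + 0.625 m^2
        # (0.625 = chance two independent non-ancestral bases differ under
        # uniform choice; close enough as a starting point, then corrected)
        a, b, c = -1.375, 2.0, -(1.0 - t)
        m = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
        k = int(round(0.95 * m * L))  # slight undershoot; correction adds more
        mutable = np.arange(3, L)  # keep the start codon
        for seq in seqs:
            for pos in rng.choice(mutable, size=k, replace=False):
                _mutate_site(seq, int(pos), rng, params.ts_tv_ratio)

        # nudge any pair still above the band by mutating where it agrees
        for _ in range(40 * L):
            worst = None
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    ident = _pairwise_identity(seqs[i], seqs[j])
                    if ident > t and (worst is None or ident > worst[0]):
                        worst = (ident, i, j)
            if worst is None:
                break
            _, i, j = worst
            agree = np.flatnonzero((seqs[i] == seqs[j])[3:]) + 3
            pos = int(rng.choice(agree))
            target_seq = seqs[j] if rng.integers(2) else seqs[i]
            _mutate_site(target_seq, pos, rng, params.ts_tv_ratio)

        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                ident = _pairwise_identity(seqs[i], seqs[j])
                if not (t - 0.02 <= ident <= t + 0.02):
                    raise ConfigError(
                        f"could not realize pairwise identity {t:.2f} "
                        f"(pair {i},{j} at {ident:.3f})"
                    )

    genes = [
        GeneSequence(id=f"MALT{i + 1}", seq=s.tobytes().decode(), is_cds=True)
        for i, s in enumerate(seqs)
    ]
    anc = GeneSequence(id="ancestor", seq=ancestor.tobytes().decode(), is_cds=True)
    return genes, anc


def apply_gene_conversion(
    recipient: GeneSequence, donor: GeneSequence, tract: tuple[int, int]
) -> GeneSequence:
    """Copy the donor's sequence into the recipient over ``tract``
    (1-based inclusive), leaving the donor untouched — ectopic gene
    conversion producing a chimeric allele."""
    if len(recipient.seq) != len(donor.seq):
        raise InputError("recipient and donor must be positionally comparable")
    start, end = tract
    if not (1 <= start <= end <= len(recipient.seq)):
        raise InputError(f"tract {tract} out of bounds 1..{len(recipient.seq)}")
    seq = recipient.seq[: start - 1] + donor.seq[start - 1 : end] + recipient.seq[end:]
    return GeneSequence(
        id=f"{recipient.id}-{donor.id}-chimera", seq=seq, is_cds=recipient.is_cds
    )


def simulate_backcross_tetrads(
    n_tetrads: int,
    n_markers: int,
    causal_index: int | None,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tetrads from selfing-free meiosis of a heterozygote with ``n_markers``
    unlinked heterozygous loci.

    Every locus segregates exactly 2:2 within each tetrad; loci assort
    independently (free recombination). Phenotype is dominant presence of
    the derived allele at ``causal_index``; with ``causal_index=None`` the
    trait has no genetic basis and phenotypes are assigned by a random,
    genotype-independent 2:2 split per tetrad.

    Returns a tetrad table (tetrad_id, spore1..spore4) and a genotype array
    of shape (n_tetrads, 4, n_markers) with 1 = derived allele.
    """
    if causal_index is not None and not (0 <= causal_index < n_markers):
        raise InputError("causal_index out of range")
    rng = np.random.default_rng(seed)
    genotypes = np.zeros((n_tetrads, 4, n_markers), dtype=np.int8)
    for ti in range(n_tetrads):
        for mi in range(n_markers):
            carriers = rng.choice(4, size=2, replace=False)
            genotypes[ti, carriers, mi] = 1

    rows = []
    for ti in range(n_tetrads):
        if causal_index is not None:
            pos_mask = genotypes[ti, :, causal_index] == 1
        else:
            pos_mask = np.zeros(4, dtype=bool)
            pos_mask[rng.choice(4, size=2, replace=False)] = True
        spores = ["positive" if p else "negative" for p in pos_mask]
        rows.append({"tetrad_id": f"T{ti + 1:03d}", **{
            f"spore{k + 1}": spores[k] for k in range(4)
        }})
    return pd.DataFrame(rows), genotypes


def simulate_pool_counts(
    pool_pos_genotypes: np.ndarray,
    pool_neg_genotypes: np.ndarray,
    positions: np.ndarray,
    contig: str,
    coverage: float = 100.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> PoolCounts:
    """Pooled-sequencing allele counts at the marker sites.

    Depth per pool per site is Poisson(coverage); alt reads are
    Binomial(depth, f(1-e) + (1-f)e) with f the pool's true derived-allele
    frequency and e the per-read error rate. Ref allele 'A', alt 'G'
    throughout (allele identity carries no information here).
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    if pool_pos_genotypes.size == 0 or pool_neg_genotypes.size == 0:
        raise InputError("both pools must be non-empty")
    rng = np.random.default_rng(seed)
    n_sites = pool_pos_genotypes.shape[1]
    rows = {}
    for name, geno in (("pos", pool_pos_genotypes), ("neg", pool_neg_genotypes)):
        f = geno.mean(axis=0)
        depth = rng.poisson(coverage, size=n_sites)
        p_alt = f * (1 - error_rate) + (1 - f) * error_rate
        alt = rng.binomial(depth, p_alt)
        rows[f"{name}_alt"] = alt
        rows[f"{name}_ref"] = depth - alt
    df = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions.astype(int),
            "ref": "A",
            "alt": "G",
            "pos_ref": rows["pos_ref"],
            "pos_alt": rows["pos_alt"],
            "neg_ref": rows["neg_ref"],
            "neg_alt": rows["neg_alt"],
        }
    )
    return PoolCounts(df)


@dataclass
class Scenario:
    truth: ScenarioTruth
    candidate: GeneSequence
    panel: list[GeneSequence]
    tetrads: pd.DataFrame
    pool_counts: PoolCounts


def make_scenario(config: ScenarioConfig | None = None, seed: int = 0,
                  out_dir: str | Path | None = None) -> Scenario:
    """End-to-end scenario: paralog family + conversion chimera, backcross
    tetrads, and pooled allele counts, with ground truth.

    With ``config.causal=False`` no conversion occurs, phenotypes are
    genotype-independent, and the truth records no causal locus (the null
    scenario for false-positive calibration). If ``out_dir`` is given the
    scenario is also written out as FASTA/TSV plus a truth JSON.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    genes, _ = simulate_gene_family(
        FamilyParams(
            n_genes=cfg.n_genes,
            cds_length=cfg.cds_length,
            target_nt_identity=cfg.target_nt_identity,
            seed=int(sub[0]),
        )
    )
    recipient, donor = genes[3], genes[2]  # MALT4 backbone, MALT3 donor

    markers = np.arange(cfg.marker_spacing, cfg.genome_length + 1,
                        cfg.marker_spacing)
    n_markers = len(markers)

    if cfg.causal:
        start = int(rng.integers(1, cfg.cds_length - cfg.tract_length + 2))
        tract = (start, start + cfg.tract_length - 1)
        candidate = apply_gene_conversion(recipient, donor, tract)
        candidate = GeneSequence("MALT434", candidate.seq, is_cds=True)
        conversion = TrueConversion(
            donor_id=donor.id, recipient_id=recipient.id, tract=tract
        )
        causal_idx = int(rng.integers(0, n_markers))
        causal_pos = int(markers[causal_idx])
        causal_window = ((causal_pos - 1) // 1000 * 1000 + 1,
                         min((causal_pos - 1) // 1000 * 1000 + 1000,
                             cfg.genome_length))
    else:
        candidate = GeneSequence("MALT434", recipient.seq, is_cds=True)
        conversion = None
        causal_idx = None
        causal_window = None

    tetrads, genotypes = simulate_backcross_tetrads(
        cfg.n_tetrads, n_markers, causal_idx, seed=int(sub[1])
    )
    flat = genotypes.reshape(-1, n_markers)
    phenotypes = []
    for ti in range(cfg.n_tetrads):
        for k in range(4):
            phenotypes.append(tetrads.iloc[ti][f"spore{k + 1}"])
    pheno = np.array(phenotypes)
    pool_counts = simulate_pool_counts(
        flat[pheno == "positive"],
        flat[pheno == "negative"],
        positions=markers,
        contig=cfg.contig,
        coverage=cfg.coverage,
        error_rate=cfg.error_rate,
        seed=int(sub[2]),
    )

    truth = ScenarioTruth(
        config=cfg,
        seed=seed,
        marker_positions=[int(p) for p in markers],
        causal_marker_index=causal_idx,
        causal_window=causal_window,
        conversion=conversion,
        phenotypes=list(pheno),
        genotypes=[[int(g) for g in row] for row in flat],
    )
    scenario = Scenario(
        truth=truth,
        candidate=candidate,
        panel=genes,
        tetrads=tetrads,
        pool_counts=pool_counts,
    )
    if out_dir is not None:
        _write_scenario(scenario, Path(out_dir))
    return scenario


def _write_scenario(s: Scenario, out_dir: Path) -> None:
    from . import io as io_mod

    out_dir.mkdir(parents=True, exist_ok=True)
    io_mod.write_fasta([s.candidate], out_dir / "candidate.fasta")
    io_mod.write_fasta(s.panel, out_dir / "panel.fasta")
    s.tetrads.to_csv(out_dir / "tetrads.tsv", sep="\t", index=False)
    s.pool_counts.df.drop(columns=["multiallelic"]).to_csv(
        out_dir / "pool_counts.tsv", sep="\t", index=False
    )
    (out_dir / "truth.json").write_text(s.truth.to_json() + "\n")
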