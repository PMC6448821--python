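"""Parameter-recovery benchmarks of the pipeline on simulated truth.

Each function runs many independently seeded scenarios at the study's
conditions (four-paralog family at 80% nt identity, 1848-bp CDS, one 230-bp
conversion tract; 15 tetrads giving 30+30 segregant pools at 100x depth with
0.5% sequencing error) and scores the pipeline's calls against the
simulator's ground truth. Used by the test suite and the reproduction
script; also handy for re-calibrating thresholds.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path

import numpy as np

from . import bsa
from .chimera import scan_gene_family
from .core_seq import GeneSequence
from .synthetic import (
    FamilyParams,
    ScenarioConfig,
    apply_gene_conversion,
    make_scenario,
    simulate_gene_family,
)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def chimera_recovery(
    n_reps: int = 200,
    seed: int = 0,
    tract_length: int = 230,
    min_run: int = 3,
    target_nt_identity: float = 0.80,
    cds_length: int = 1848,
) -> dict:
    """Recovery of a known conversion tract by the gene-family scan.

    Per replicate: simulate a paralog family, convert one 230-bp donor tract
    into the recipient, scan. Scored: does the report name the true
    (recipient, donor) pair AND does its maximal span contain the true
    tract; separately, does the reported SNP count match a brute-force
    per-position diff inside the reported span.
    """
    n_recovered = 0
    n_snp_agree = 0
    for rep_seed in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        genes, _ = simulate_gene_family(
            FamilyParams(
                cds_length=cds_length,
                target_nt_identity=target_nt_identity,
                seed=int(rep_seed),
            )
        )
        recipient, donor = genes[3], genes[2]
        start = int(rng.integers(1, cds_length - tract_length + 2))
        tract = (start, start + tract_length - 1)
        chim = apply_gene_conversion(recipient, donor, tract)
        candidate = GeneSequence("MALT434", chim.seq, is_cds=True)
        report = scan_gene_family(candidate, genes, min_run=min_run)

        ok_pair = (
            report.recipient_id == recipient.id and report.donor_id == donor.id
        )
        ok_span = any(
            t.maximal_span[0] <= tract[0] and t.maximal_span[1] >= tract[1]
            for t in report.tracts
        )
        if ok_pair and ok_span:
            n_recovered += 1
        by_id = {g.id: g for g in genes}
        snp_ok = all(
            t.n_snps_vs_recipient
            == sum(
                1
                for i in range(t.maximal_span[0] - 1, t.maximal_span[1])
                if candidate.seq[i] != by_id[t.recipient_id].seq[i]
            )
            for t in report.tracts
        )
        if snp_ok:
            n_snp_agree += 1
    return {
        "n_reps": n_reps,
        "recovery_pct": 100.0 * n_recovered / n_reps,
        "snp_oracle_agreement_pct": 100.0 * n_snp_agree / n_reps,
    }


def _scan_scenario(scenario) -> bsa.ScanResult:
    calls = bsa.call_fixed_sites(scenario.pool_counts)
    result = bsa.window_scan(
        calls,
        {scenario.truth.config.contig: scenario.truth.config.genome_length},
    )
    return bsa.flag_artifacts(result, scenario.pool_counts)


def bsa_power(n_reps: int = 100, seed: int = 0) -> dict:
    """Detection frequency of the causal 1-kb window under default
    thresholds in causal scenarios."""
    n_detected = 0
    for rep_seed in _child_seeds(seed, n_reps):
        scenario = make_scenario(seed=int(rep_seed))
        result = _scan_scenario(scenario)
        lo, hi = scenario.truth.causal_window
        if any(w.start == lo and w.end == hi for w in result.windows):
            n_detected += 1
    return {"n_reps": n_reps, "detection_pct": 100.0 * n_detected / n_reps}


def bsa_null_rate(n_reps: int = 100, seed: int = 0) -> dict:
    """Mean candidate windows per null (no causal locus) 100-kb scenario."""
    n_windows = 0
    for rep_seed in _child_seeds(seed, n_reps):
        scenario = make_scenario(ScenarioConfig(causal=False), seed=int(rep_seed))
        n_windows += len(_scan_scenario(scenario).windows)
    return {"n_reps": n_reps, "mean_false_windows": n_windows / n_reps}


def cli_byte_determinism(seed: int = 0) -> bool:
    """Run the simulate and bsa-scan CLI twice with one seed; compare every
    output file byte for byte."""
    from click.testing import CliRunner

    from .cli import main as cli_main

    runner = CliRunner()
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        dirs = [tmp_path / "run1", tmp_path / "run2"]
        for d in dirs:
            res = runner.invoke(
                cli_main, ["simulate", "--seed", str(seed), "--out-dir", str(d)]
            )
            assert res.exit_code == 0, res.output
            res = runner.invoke(
                cli_main,
                [
                    "bsa-scan",
                    "--counts", str(d / "pool_counts.tsv"),
                    "--genome-length", "100000",
                    "--seed", str(seed),
                    "--out-prefix", str(d / "scan"),
                ],
            )
            assert res.exit_code == 0, res.output
        files = sorted(p.name for p in dirs[0].iterdir())
        if files != sorted(p.name for p in dirs[1].iterdir()):
            return False
        return all(
            filecmp.cmp(dirs[0] / f, dirs[1] / f, shallow=False) for f in files
        )
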