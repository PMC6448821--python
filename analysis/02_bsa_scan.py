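#!/usr/bin/env python
"""Bulk-segregant fixed-difference window scan of the simulated pools.

Reads results/scenario/pool_counts.tsv (run 01_simulate_scenario.py first),
calls near-fixed differences between the trait-positive and trait-negative
pools (alt frequency >= 0.95 in one pool and <= 0.05 in the other, both
depths >= 10), tiles the genome into 1-kb windows and reports candidates.
Compares the result with the scenario's recorded causal window.
"""

import json
from pathlib import Path

from maltpipe import bsa, io

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scenario_dir = ROOT / "scenario"
    truth = json.loads((scenario_dir / "truth.json").read_text())
    pc = io.read_pool_counts(scenario_dir / "pool_counts.tsv")
    calls = bsa.call_fixed_sites(pc)
    result = bsa.window_scan(
        calls, {truth["config"]["contig"]: truth["config"]["genome_length"]}
    )
    result = bsa.flag_artifacts(result, pc)

    out = ROOT / "bsa"
    out.mkdir(parents=True, exist_ok=True)
    io.write_windows_bed(result.windows, out / "candidate_windows.bed",
                         seed=truth["seed"], thresholds=result.thresholds)
    io.write_fixed_sites_tsv(calls, out / "fixed_sites.tsv",
                             seed=truth["seed"], thresholds=result.thresholds)
    io.write_report_json(io.summarize_scan(result), out / "summary.json",
                         seed=truth["seed"], thresholds=result.thresholds)

    print(f"{result.n_fixed_sites}/{result.n_sites} sites are fixed differences")
    for w in result.windows:
        mark = " <- causal" if list(truth["causal_window"]) == [w.start, w.end] else ""
        flag = " [artifact?]" if w.artifact_flag else ""
        print(f"  window {w.contig}:{w.start}-{w.end}  n_fixed={w.n_fixed}"
              f"  depth_ratio={w.mean_depth_ratio:.2f}{flag}{mark}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
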