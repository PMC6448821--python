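#!/usr/bin/env python
"""Tetrad segregation analysis of the simulated backcross.

Reads results/scenario/tetrads.tsv, tallies 2:2 / 3:1 / 4:0 patterns over
the fully viable tetrads, and tests the spore counts against the 1:1 ratio
expected for a dominant single-locus trait.
"""

import json
from pathlib import Path

import pandas as pd

from maltpipe import io
from maltpipe.inheritance import expected_category_counts, segregation_analysis

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "scenario" / "tetrads.tsv", sep="\t")
    result = segregation_analysis(table)
    out = ROOT / "segregation.json"
    io.write_report_json(result, out)

    exp_pos, exp_neg = expected_category_counts(result.n_tetrads)
    print(f"{result.n_tetrads} fully viable tetrads "
          f"(of {result.n_tetrads_total} total)")
    print(f"  patterns: " + ", ".join(
        f"{k}x{v}" for k, v in result.pattern_counts.items() if v))
    print(f"  spores: {result.n_pos_spores} positive / "
          f"{result.n_neg_spores} negative "
          f"(expected {exp_pos}/{exp_neg} under 2:2)")
    print(f"  exact binomial p vs 1:1 = {result.binomial_p:.3f}")
    print(f"  consistent with a single dominant locus: "
          f"{result.consistent_single_locus}")
    print(f"report written to {out}")


if __name__ == "__main__":
    main()
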