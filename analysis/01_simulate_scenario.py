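#!/usr/bin/env python
"""Generate the default synthetic mapping scenario with ground truth.

One 100-kb genome with markers every 500 bp; a four-member MALT-like
transporter family at 80% nucleotide identity; a single 230-bp gene-
conversion tract copied from the MALT3-like donor into the MALT4-like
recipient to form the chimeric candidate; 15 fully viable backcross
tetrads; pooled allele counts for the 30+30 segregant bulks at 100x depth.

Writes FASTA/TSV inputs plus truth.json under results/scenario/.
"""

import sys
from pathlib import Path

from maltpipe.synthetic import make_scenario

SEED = 20240
OUT = Path(__file__).resolve().parent.parent / "results" / "scenario"


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    scenario = make_scenario(seed=seed, out_dir=OUT)
    truth = scenario.truth
    print(f"scenario written to {OUT} (seed {seed})")
    print(f"  causal marker at {truth.marker_positions[truth.causal_marker_index]:,} bp"
          f" -> true 1-kb window {truth.causal_window}")
    print(f"  conversion tract {truth.conversion.tract} "
          f"({truth.conversion.donor_id} -> {truth.conversion.recipient_id})")
    n_pos = truth.phenotypes.count("positive")
    print(f"  {len(truth.phenotypes)} spores: {n_pos} positive, "
          f"{len(truth.phenotypes) - n_pos} negative")


if __name__ == "__main__":
    main()
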