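#!/usr/bin/env python
"""Division budget of the serial-passage evolution experiments.

Two regimes, both 100 passages at a 3-4 day interval with about one cell
division per day for strains unable to use the primary carbon source:
a single strain evolved in triplicate (3 lineages), and two strains in
triplicate (6 lineages).
"""

import json
from pathlib import Path

from maltpipe.inheritance import EvolutionRegime, estimate_divisions

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    regimes = {
        "one_strain_triplicate": EvolutionRegime(
            n_passages=100, days_per_passage=(3.0, 4.0),
            divisions_per_day=1.0, n_lineages=3),
        "two_strains_triplicate": EvolutionRegime(
            n_passages=100, days_per_passage=(3.0, 4.0),
            divisions_per_day=1.0, n_lineages=6),
    }
    report = {}
    for name, regime in regimes.items():
        est = estimate_divisions(regime)
        report[name] = {"exact": est.exact, "rounded": est.rounded}
        print(f"{name}: {est.rounded:,} divisions "
              f"(exact {est.exact:,.0f}; {regime.n_lineages} lineages x "
              f"{regime.n_passages} passages x 3.5 d x "
              f"{regime.divisions_per_day}/d)")
    ROOT.mkdir(exist_ok=True)
    (ROOT / "division_budget.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"report written to {ROOT / 'division_budget.json'}")


if __name__ == "__main__":
    main()
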