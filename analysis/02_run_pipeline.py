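"""Run the full contact-network comparison on the synthetic study system.

Consumes results/fixtures/ (built by 01_build_fixtures.py), writes the full
report bundle to results/bundle/, and checks the recovered made/lost
contacts against the recorded ground truth.
"""

import json
from pathlib import Path

from pcnkit.report import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
FIX = ROOT / "results" / "fixtures"
OUT = ROOT / "results" / "bundle"


def main() -> None:
    truth = json.loads((FIX / "ground_truth.json").read_text())
    mutants = sorted(FIX.glob("mutant_*.pdb"))
    result = run_pipeline(RunConfig(), FIX / "reference.pdb", mutants, OUT)

    print(f"reference network: {result['per_structure']['reference']}")
    exact = 0
    for name, counts in result["diff"].items():
        want = truth[name]
        rep = json.loads((OUT / "diff" / f"{name}.json").read_text())
        ok = (sorted(rep["made"]) == want["made"]
              and sorted(rep["lost"]) == want["lost"])
        exact += ok
        print(f"  {name}: made={counts['n_made']} lost={counts['n_lost']} "
              f"ground-truth match: {'yes' if ok else 'NO'}")
    print(f"{exact}/{len(result['diff'])} mutants recovered exactly")
    print(f"union: {result['union']['made']['total']} made / "
          f"{result['union']['lost']['total']} lost "
          f"({result['union']['made']['long_range']} long-range made)")
    print(f"degree changes: avg fraction "
          f"{result['degree_changes']['average_changed_fraction']:.3f}, "
          f"max |delta| {result['degree_changes']['max_abs_change']}")
    print(f"cross-structure RMSD range: {result['rmsd']['min_A']:.3f}"
          f"-{result['rmsd']['max_A']:.3f} A -> {OUT}")


if __name__ == "__main__":
    main()
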