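"""Build the synthetic study system: one reference chain and six mutants.

The reference is a 40-residue helix-coil-strand-coil-helix chain; each
mutant differs from it by three feasible contact edits sampled from its own
seed, with the ground-truth made/lost sets recorded next to the coordinate
files.  Writes results/fixtures/.
"""

import json
import sys
from pathlib import Path

from pcnkit import synth

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "fixtures"

REFERENCE_SPEC = synth.SyntheticSpec(
    n_residues=40,
    segments=(("helix", 12), ("coil", 6), ("strand", 8), ("coil", 4),
              ("helix", 10)),
    seed=7,
    noise_sd=0.15,
)
MUTANT_SEEDS = (101, 102, 103, 104, 105, 106)


def main(seed_offset: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = synth.make_structure(REFERENCE_SPEC, structure_id="reference")
    (OUT / "reference.pdb").write_text(synth.write_pdb(ref))
    truth = {}
    for s in MUTANT_SEEDS:
        mut, made, lost = synth.random_mutant(ref, s + seed_offset, n_edits=3)
        name = f"mutant_{s + seed_offset}"
        mut = mut.with_coords(mut.coords, id=name)
        (OUT / f"{name}.pdb").write_text(synth.write_pdb(mut))
        truth[name] = {"made": sorted(list(p) for p in made),
                       "lost": sorted(list(p) for p in lost)}
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    n_made = len({tuple(p) for t in truth.values() for p in t["made"]})
    n_lost = len({tuple(p) for t in truth.values() for p in t["lost"]})
    print(f"reference: {len(ref)} residues, {len(MUTANT_SEEDS)} mutants")
    print(f"ground truth union: {n_made} unique contacts injected, "
          f"{n_lost} removed -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
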