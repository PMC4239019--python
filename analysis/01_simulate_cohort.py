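#!/usr/bin/env python
"""Simulate the study cohort and write it as a plain-text fixture.

Generates one cohort at the study's group sizes — tumour subgroups WNT
(n=8), SHH (n=21), Group 3 (n=22), Group 4 (n=14) and developmental
controls NSC (n=3), NPC (n=3), NFGM (n=2), NFB (n=1, single pooled
profile) — with planted gradient co-expression modules, subgroup-exclusive
markers and a below-detection gene fraction, plus the ground-truth tables
every later script checks against. The developmental gradient is simulated
at 1.5 log2 units per stage so the alignment analyses downstream operate on
a clearly ordered continuum.
"""

import argparse
from pathlib import Path

from devalign import SimulationParams, paper_cohort_design, simulate_cohort, write_fixture

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()

    design = paper_cohort_design()
    params = SimulationParams(seed=args.seed, gradient_slope=1.5)
    matrix, truth = simulate_cohort(design, params)
    paths = write_fixture(matrix, truth, args.out)

    print(f"cohort: {matrix.n_genes} genes x {matrix.n_samples} samples")
    for kind in ("control", "tumor"):
        for g in matrix.groups(kind=kind):
            stage = (f", stage {matrix.stage_of_group(g)}" if kind == "control"
                     else f", latent stage {truth.stage_map[g]}")
            print(f"  {kind:7s} {g:7s} n={len(matrix.samples_in_group(g)):2d}{stage}")
    print(f"planted: {len(truth.module_genes)} module genes in "
          f"{truth.module_membership.max()} gradient modules, "
          f"{len(truth.marker_genes)} exclusive markers, "
          f"{len(truth.below_detection)} genes below the 200-unit detection limit")
    print(f"wrote {len(paths)} files under {args.out}")


if __name__ == "__main__":
    main()
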