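#!/usr/bin/env python
"""Developmental intersect differential expression.

Runs every (subgroup, control) comparison — Student t tests against the
multi-sample controls, the sigma-fold membership rule against the single
pooled NFB profile — and applies the step-wise exclusivity intersect:
a gene is exclusive ("$") for a subgroup when it is significantly
over-expressed versus every multi-sample control and in no other subgroup.
Writes the per-comparison tables, the exclusivity classification and a
signed-fold top table per subgroup, then scores the calls against the
planted markers.
"""

import argparse
from pathlib import Path

from devalign import (
    compute_group_stats, detection_filter, read_fixture, run_all_comparisons,
    stepwise_exclusive, top_table,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--k-sigma", type=float, default=2.0)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "intersect")
    args = parser.parse_args()

    matrix, truth = read_fixture(args.cohort)
    filtered, _ = detection_filter(matrix)
    args.out.mkdir(parents=True, exist_ok=True)

    stats = compute_group_stats(filtered)
    flat = stats.table.copy()
    flat.columns = [f"{g}.{s}" for g, s in flat.columns]
    flat.rename_axis("gene_id").to_csv(args.out / "group_stats.tsv", sep="\t")

    results = run_all_comparisons(filtered, alpha=args.alpha, k_sigma=args.k_sigma)
    for res in results:
        res.table.rename_axis("gene_id").to_csv(
            args.out / f"{res.subgroup}_vs_{res.control}.tsv", sep="\t")

    calls = stepwise_exclusive(results, direction="up", alpha=args.alpha)
    calls.classes.rename_axis("gene_id").to_csv(args.out / "exclusivity.tsv", sep="\t")

    print(f"{len(results)} comparisons over {filtered.n_genes} detected genes "
          f"(alpha {args.alpha}, sigma cutoff {args.k_sigma})")
    for s in calls.classes.columns:
        called = set(calls.exclusive_genes(s))
        planted = set(truth.marker_sets[s]) & set(filtered.gene_ids)
        tp = len(called & planted)
        print(f"  {s:7s} exclusive {len(called):3d} genes "
              f"({tp} of {len(planted)} planted markers; "
              f"{len(called) - tp} others)  shared {len(calls.shared_genes(s))}")

    # top over-expressed table vs the subgroup's planted-stage neighbourhood
    res = next(r for r in results if r.subgroup == "Group3" and r.control == "NFGM")
    top = top_table(res, n=8, direction="up")
    top.to_csv(args.out / "top_Group3_vs_NFGM.tsv", sep="\t")
    print("\ntop over-expressed genes, Group3 vs NFGM (signed fold):")
    for g, row in top.iterrows():
        marker = " (planted Group3 marker)" if g in set(truth.marker_sets["Group3"]) else ""
        print(f"  {g:12s} fch {row['fch']:6.2f} p {row['p']:.2e}{marker}")


if __name__ == "__main__":
    main()
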