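"""Gene-set over-representation of exclusivity sets and module gene lists.

A transparent hypergeometric test against user-supplied GMT collections:
for each set, the one-sided probability of drawing at least the observed
overlap when |query| genes are sampled from the universe. The universe is
meant to be the post-detection-filter gene space, so genes the platform
could never have reported are not counted as misses. Raw p-values are
reported alongside Benjamini-Hochberg adjusted ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a universe."""

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] | None = None

    def __post_init__(self):
        if not self.sets:
            raise ValueError("gene-set collection is empty")
        self.sets = {name: set(genes) & self.universe for name, genes in self.sets.items()}

    @property
    def n_universe(self) -> int:
        return len(self.universe)


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        name, description, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = set(genes)
        descriptions[name] = description
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets, descriptions


def write_gmt(sets: dict[str, list[str] | set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(Path(path), "w", newline="\n") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def load_collection(gmt_path, universe) -> GeneSetCollection:
    sets, descriptions = read_gmt(gmt_path)
    return GeneSetCollection(sets=sets, universe=set(universe), descriptions=descriptions)


def overrepresentation(query, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    p = P(X >= overlap) with X ~ Hypergeom(N = |universe|, K = |set|,
    n = |query ∩ universe|). Returns a table sorted by p (ties by set name)
    with BH-adjusted p and the contributing genes.
    """
    query = set(query) & collection.universe
    if not query:
        raise ValueError("query has no overlap with the universe")
    n_universe = collection.n_universe
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        overlap = sorted(query & members)
        p = float(hypergeom.sf(len(overlap) - 1, n_universe, len(members), len(query)))
        rows.append({
            "set": name,
            "set_size": len(members),
            "query_size": len(query),
            "overlap": len(overlap),
            "p": min(p, 1.0),
            "contributing_genes": ",".join(overlap),
        })
    table = pd.DataFrame(rows).sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    table["p_adj_bh"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table[["set", "set_size", "query_size", "overlap", "p", "p_adj_bh", "contributing_genes"]]
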