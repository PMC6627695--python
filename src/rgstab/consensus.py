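"""Geometric-mean consensus ranking across stability methods, plus top-k
overlap (Venn region) summaries."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .stability import StabilityTable

__all__ = ["ConsensusTable", "combine", "top_k_overlap"]


@dataclass
class ConsensusTable:
    """Per-gene method ranks, their geometric mean, and the final rank.

    The geometric mean of integer ranks (never of raw stability values) is
    the comprehensive stability score; lower is better.  Ties on the
    geomean are broken by the better delta-Ct rank (it aggregates all
    pairwise information), then input order.
    """

    dataset: str
    frame: pd.DataFrame  # index gene; rank_<method>..., geomean, consensus_rank

    @property
    def geomean(self) -> pd.Series:
        return self.frame["geomean"]

    @property
    def ranks(self) -> pd.Series:
        return self.frame["consensus_rank"]

    def best(self, k: int = 1) -> list:
        return list(self.frame.sort_values("consensus_rank").index[:k])

    def to_csv_frame(self) -> pd.DataFrame:
        out = self.frame.reset_index()
        out.insert(0, "dataset", self.dataset)
        return out


def combine(tables: list[StabilityTable]) -> ConsensusTable:
    """Combine per-method rankings into the geomean consensus.

    All tables must cover the same gene set and dataset label; at least two
    methods are required (the study design uses four).
    """
    if len(tables) < 1:
        raise ValueError("need at least one StabilityTable")
    datasets = {t.dataset for t in tables}
    if len(datasets) != 1:
        raise ValueError(f"tables mix datasets: {sorted(datasets)}")
    genes = list(tables[0].frame.index)
    gene_set = set(genes)
    for t in tables[1:]:
        other = set(t.frame.index)
        if other != gene_set:
            raise ValueError(
                "gene sets differ: only-in-first="
                f"{sorted(gene_set - other)}, only-in-other={sorted(other - gene_set)}"
            )
    rank_cols = {}
    for t in tables:
        rank_cols[f"rank_{t.method}"] = t.ranks.reindex(genes).astype(int)
    frame = pd.DataFrame(rank_cols, index=pd.Index(genes, name="gene"))
    ranks = frame.to_numpy(dtype=float)
    frame["geomean"] = np.exp(np.log(ranks).mean(axis=1))

    tie_key = (
        frame["rank_deltact"].to_numpy()
        if "rank_deltact" in frame
        else np.zeros(len(genes))
    )
    order = np.lexsort((np.arange(len(genes)), tie_key, frame["geomean"].to_numpy()))
    consensus = np.empty(len(genes), dtype=int)
    consensus[order] = np.arange(1, len(genes) + 1)
    frame["consensus_rank"] = consensus
    return ConsensusTable(dataset=tables[0].dataset, frame=frame)


def top_k_overlap(tables: list[StabilityTable], k: int) -> dict:
    """Top-k sets per method and exclusive Venn region counts.

    Region keys join method names with "&" (e.g. "bestkeeper&genorm" counts
    genes in exactly those two methods' top-k sets); region counts sum to
    the size of the union.
    """
    if not tables:
        raise ValueError("need at least one StabilityTable")
    n = len(tables[0].frame.index)
    if k > n:
        raise ValueError(f"k={k} exceeds gene count {n}")
    sets = {t.method: set(t.best(k)) for t in tables}
    methods = [t.method for t in tables]
    union = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(methods) + 1):
        for subset in combinations(methods, r):
            inside = set(subset)
            members = set.intersection(*(sets[m] for m in inside))
            for m in methods:
                if m not in inside:
                    members = members - sets[m]
            regions["&".join(subset)] = len(members)
    return {
        "k": k,
        "methods": methods,
        "sets": {m: sorted(map(str, s)) for m, s in sets.items()},
        "regions": regions,
        "union_size": len(union),
    }
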