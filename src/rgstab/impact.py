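"""How the choice of reference gene changes downstream conclusions.

Given a Ct matrix, normalizing a target against a reference gene is a
per-sample subtraction (delta-Ct = Ct_target - Ct_reference; one cycle is
roughly a two-fold abundance difference at ideal efficiency).  This module
quantifies the consequences of that choice: group comparisons (unpaired
pooled-variance t-test with optional Grubbs outlier screening),
reference-target correlation, and the correlation-distance average-linkage
clustering used for heatmaps of reference-normalized, row-centered values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist

from .ct import CorrelationReport, CtMatrix, GroupDesign

__all__ = [
    "NormalizedExpression",
    "GrubbsResult",
    "ComparisonResult",
    "ClusterResult",
    "normalize",
    "grubbs_test",
    "grubbs_critical",
    "compare_groups",
    "significance_tier",
    "gene_correlation",
    "cluster_heatmap",
    "linkage_to_newick",
]


@dataclass
class NormalizedExpression:
    """Per-sample delta-Ct of one target against one reference gene."""

    target: str
    reference: str
    data: pd.DataFrame  # index sample; columns: delta_ct, group (if design given)
    self_normalized: bool = False

    def group_values(self, group) -> np.ndarray:
        if "group" not in self.data.columns:
            raise ValueError("no group labels attached; pass a GroupDesign")
        sel = self.data.loc[self.data["group"] == group, "delta_ct"]
        if sel.empty:
            raise KeyError(f"group {group!r} not present")
        return sel.to_numpy()


def normalize(
    m: CtMatrix, target, reference, design: GroupDesign | None = None
) -> NormalizedExpression:
    """delta-Ct of target vs reference per sample, with group labels.

    Normalizing a gene against itself is permitted (all zeros) but flagged,
    since it is almost always a pipeline wiring mistake.
    """
    t = m.gene(target)
    r = m.gene(reference)
    if t.isna().any() or r.isna().any():
        raise ValueError("target and reference must be completely detected")
    data = pd.DataFrame({"delta_ct": t - r})
    data.index.name = "sample"
    if design is not None:
        data["group"] = [design.group_of(s) for s in data.index]
    self_norm = target == reference
    if self_norm:
        warnings.warn(
            f"target and reference are the same gene ({target!r}); "
            "delta-Ct is identically zero",
            UserWarning,
            stacklevel=2,
        )
    return NormalizedExpression(
        target=str(target),
        reference=str(reference),
        data=data,
        self_normalized=self_norm,
    )


# ---------------------------------------------------------------------------
# Outlier screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrubbsResult:
    n: int
    g: float            # max |x - mean| / sd  (NaN when sd == 0)
    critical: float
    is_outlier: bool
    outlier_index: int | None
    outlier_value: float | None
    degenerate: bool = False  # sd == 0: statistic undefined


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value via the t quantile at alpha/(2N)
    with N-2 degrees of freedom."""
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    t = _stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(x, alpha: float = 0.05) -> GrubbsResult:
    """Single-outlier two-sided Grubbs' test on the most extreme point."""
    x = np.asarray(list(x), dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs' test needs n >= 3")
    sd = x.std(ddof=1)
    crit = grubbs_critical(n, alpha)
    if sd == 0:
        return GrubbsResult(
            n=n, g=float("nan"), critical=crit, is_outlier=False,
            outlier_index=None, outlier_value=None, degenerate=True,
        )
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    out = g > crit
    return GrubbsResult(
        n=n, g=g, critical=float(crit), is_outlier=out,
        outlier_index=idx if out else None,
        outlier_value=float(x[idx]) if out else None,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

TIERS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
    (0.1, "#"),
)


def significance_tier(p: float) -> str:
    """Map a p-value to the figure-annotation tier; "#" marks the
    0.05 < p <= 0.1 trend band."""
    for bound, tier in TIERS:
        if p <= bound:
            return tier
    return "ns"


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    t: float
    df: int
    p: float
    tier: str
    n_a: int
    n_b: int
    outliers: dict = field(default_factory=dict)  # group -> GrubbsResult or None


def compare_groups(
    ne: NormalizedExpression,
    group_a,
    group_b,
    screen_outliers: bool = False,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Unpaired Student's t-test (pooled variance, two-tailed) on delta-Ct.

    With ``screen_outliers`` a single two-sided Grubbs pass (at most one
    point removed per group) precedes the test; flags are always reported
    even when screening is off.
    """
    a = ne.group_values(group_a)
    b = ne.group_values(group_b)
    outliers = {}
    for label, vec in ((group_a, a), (group_b, b)):
        outliers[label] = grubbs_test(vec, alpha) if vec.size >= 3 else None
    if screen_outliers:
        res_a, res_b = outliers[group_a], outliers[group_b]
        if res_a is not None and res_a.is_outlier:
            a = np.delete(a, res_a.outlier_index)
        if res_b is not None and res_b.is_outlier:
            b = np.delete(b, res_b.outlier_index)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples after screening")
    t, p = _stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(p):  # both groups constant and equal: no evidence of difference
        t, p = 0.0, 1.0
    return ComparisonResult(
        group_a=str(group_a),
        group_b=str(group_b),
        t=float(t),
        df=int(a.size + b.size - 2),
        p=float(p),
        tier=significance_tier(float(p)),
        n_a=int(a.size),
        n_b=int(b.size),
        outliers=outliers,
    )


def gene_correlation(m: CtMatrix, gene_a, gene_b) -> CorrelationReport:
    """Pearson correlation of two genes' Ct values across samples."""
    a = m.gene(gene_a)
    b = m.gene(gene_b)
    paired = pd.concat([a, b], axis=1).dropna()
    if paired.shape[0] < 3:
        raise ValueError("fewer than 3 paired samples; correlation undefined")
    return CorrelationReport.from_vectors(paired.iloc[:, 0], paired.iloc[:, 1])


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Row/column average-linkage dendrograms on correlation distance over
    reference-normalized, row-centered values."""

    reference: str
    centered: pd.DataFrame        # rows = genes (reference dropped), centered
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    dropped_rows: list            # zero-variance rows excluded from the tree

    @property
    def row_order(self) -> list:
        return [self.centered.index[i] for i in _hier.leaves_list(self.row_linkage)]

    @property
    def col_order(self) -> list:
        return [self.centered.columns[i] for i in _hier.leaves_list(self.col_linkage)]

    def merge_table(self, axis: str = "rows") -> pd.DataFrame:
        z = self.row_linkage if axis == "rows" else self.col_linkage
        return pd.DataFrame(
            {
                "step": np.arange(1, z.shape[0] + 1),
                "left": z[:, 0].astype(int),
                "right": z[:, 1].astype(int),
                "height": z[:, 2],
                "size": z[:, 3].astype(int),
            }
        )

    def newick(self, axis: str = "rows") -> str:
        if axis == "rows":
            return linkage_to_newick(self.row_linkage, list(self.centered.index))
        return linkage_to_newick(self.col_linkage, list(self.centered.columns))


def linkage_to_newick(z: np.ndarray, labels: list) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths
    derived from merge heights."""
    tree = _hier.to_tree(z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def cluster_heatmap(
    m: CtMatrix, reference, design: GroupDesign | None = None
) -> ClusterResult:
    """Reference-normalize, row-center, then cluster rows and columns with
    correlation distance (1 - Pearson r) and average linkage.

    The reference row is dropped (it is identically zero after
    normalization).  Rows with zero variance after centering have undefined
    correlation distance; they are excluded from the dendrogram and
    reported, never silently imputed.
    """
    m.require_complete()
    if reference not in m.values.index:
        raise KeyError(f"reference gene {reference!r} not in matrix")
    ref = m.values.loc[reference]
    norm = m.values.drop(index=reference).sub(ref, axis=1)
    centered = norm.sub(norm.mean(axis=1), axis=0)

    row_sd = centered.std(axis=1, ddof=0)
    dropped = list(centered.index[row_sd == 0.0])
    if dropped:
        warnings.warn(
            f"zero-variance rows excluded from clustering: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    kept = centered.loc[row_sd > 0.0]
    if kept.shape[0] < 3 or kept.shape[1] < 3:
        raise ValueError("need at least 3 usable rows and 3 columns to cluster")
    col_sd = kept.std(axis=0, ddof=0)
    if (col_sd == 0.0).any():
        bad = list(kept.columns[col_sd == 0.0])
        raise ValueError(f"zero-variance sample columns, distance undefined: {bad}")

    row_link = _hier.linkage(pdist(kept.to_numpy(), metric="correlation"), "average")
    col_link = _hier.linkage(pdist(kept.to_numpy().T, metric="correlation"), "average")
    return ClusterResult(
        reference=str(reference),
        centered=kept,
        row_linkage=row_link,
        col_linkage=col_link,
        dropped_rows=dropped,
    )
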