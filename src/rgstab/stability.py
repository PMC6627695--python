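"""The four reference-gene stability estimators.

All four score each candidate gene with a *stability value* where lower
means more stable, and assign integer ranks 1..n (1 = most stable):

* **BestKeeper** works on raw Ct and scores a gene by the mean absolute
  deviation of its Ct around the gene's arithmetic mean (the applet's
  "SD (+/- Ct)" dispersion), with CV% as an auxiliary diagnostic.
* **geNorm** works on relative quantities q = (1+E)^(Ct_min - Ct).  The
  pairwise variation V_jk is the sample SD (n-1) of log2(q_j/q_k) over
  samples; a gene's M value is the mean V against all other candidates.
  The least stable gene is excluded and M recomputed until two genes
  remain, which share the final M.
* **Comparative delta-Ct** scores gene g by the mean, over all other genes
  h, of the sample SD of the per-sample difference of transformed values
  (plain Ct differences at 100% efficiency).
* **NormFinder** fits a model-based decomposition of log2 quantities into
  sample effects, gene effects and (with groups) gene-by-group effects,
  and combines each gene's estimated intragroup variance with its shrunk
  intergroup deviation into a stability value rho.

geNorm, delta-Ct and NormFinder operate on differences or doubly-centered
values and are therefore invariant to per-sample additive Ct offsets
(technical loading differences); BestKeeper is not -- this asymmetry is
asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ct import CtMatrix, GroupDesign

__all__ = [
    "EfficiencyModel",
    "RelativeQuantityMatrix",
    "StabilityTable",
    "GeNormTrace",
    "NormFinderResult",
    "relative_quantities",
    "bestkeeper",
    "genorm",
    "deltact",
    "normfinder",
    "run_all",
    "METHODS",
]

METHODS = ("bestkeeper", "genorm", "deltact", "normfinder")


class EfficiencyModel:
    """Per-gene amplification efficiency E, with amplification factor 1+E.

    E = 1 is ideal PCR (the product doubles each cycle, factor 2).  Accepts
    a single global value or a gene -> E mapping; every E must lie in
    (0, 1].
    """

    def __init__(self, efficiency: float | Mapping = 1.0):
        self._eff = efficiency
        for e in (
            efficiency.values() if isinstance(efficiency, Mapping) else [efficiency]
        ):
            if not (0.0 < float(e) <= 1.0):
                raise ValueError(f"efficiency {e} outside (0, 1]")

    def as_series(self, gene_ids: Sequence) -> pd.Series:
        if isinstance(self._eff, Mapping):
            missing = [g for g in gene_ids if g not in self._eff]
            if missing:
                raise KeyError(f"no efficiency for genes: {missing}")
            vals = [float(self._eff[g]) for g in gene_ids]
        else:
            vals = [float(self._eff)] * len(gene_ids)
        return pd.Series(vals, index=pd.Index(gene_ids), name="E")

    def factors(self, gene_ids: Sequence) -> pd.Series:
        """Amplification factors 1+E per gene."""
        return self.as_series(gene_ids) + 1.0


@dataclass
class RelativeQuantityMatrix:
    """Gene x sample relative quantities q in (0, 1].

    q_gs = (1+E_g)^(Ct_min,g - Ct_gs) with Ct_min,g the gene's minimum over
    the analyzed samples, so each gene's largest q is exactly 1.
    """

    values: pd.DataFrame

    def __post_init__(self):
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("relative quantities must be > 0")

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)


@dataclass
class StabilityTable:
    """Per-gene stability values and integer ranks for one method/dataset."""

    method: str
    dataset: str
    frame: pd.DataFrame  # index gene; columns: value, rank (+ extras)

    @classmethod
    def from_values(
        cls,
        method: str,
        dataset: str,
        values: pd.Series,
        extras: pd.DataFrame | None = None,
    ) -> "StabilityTable":
        """Rank ascending by value; ties keep input (gene) order."""
        order = np.argsort(values.to_numpy(), kind="stable")
        ranks = np.empty(len(values), dtype=int)
        ranks[order] = np.arange(1, len(values) + 1)
        frame = pd.DataFrame({"value": values.astype(float), "rank": ranks})
        if extras is not None:
            frame = frame.join(extras)
        frame.index.name = "gene"
        return cls(method=method, dataset=dataset, frame=frame)

    @property
    def values(self) -> pd.Series:
        return self.frame["value"]

    @property
    def ranks(self) -> pd.Series:
        return self.frame["rank"]

    def best(self, k: int = 1) -> list:
        return list(self.frame.sort_values("rank").index[:k])

    def to_csv_frame(self) -> pd.DataFrame:
        out = self.frame.reset_index()
        out.insert(0, "dataset", self.dataset)
        out.insert(0, "method", self.method)
        return out


@dataclass
class GeNormTrace:
    """Stepwise-exclusion record: (gene, M at exclusion) in exclusion order,
    plus the surviving most-stable pair and their shared final M."""

    exclusions: list = field(default_factory=list)
    final_pair: tuple = ()
    final_m: float = float("nan")


@dataclass
class NormFinderResult:
    rho: pd.Series
    sigma2: pd.DataFrame            # gene x group intragroup variances
    d_hat: pd.DataFrame | None      # gene x group raw intergroup deviations
    d_shrunk: pd.DataFrame | None   # shrunk deviations
    gamma2: float | None            # estimated variance of true deviations


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------

def relative_quantities(
    m: CtMatrix, eff: EfficiencyModel | float = 1.0
) -> RelativeQuantityMatrix:
    """Transform Ct to relative quantities (1+E)^(Ct_min - Ct) per gene."""
    m.require_complete()
    if not isinstance(eff, EfficiencyModel):
        eff = EfficiencyModel(eff)
    factors = eff.factors(m.gene_ids).to_numpy()[:, None]
    ct = m.values.to_numpy()
    delta = ct.min(axis=1, keepdims=True) - ct
    q = np.power(factors, delta)
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=m.values.index, columns=m.values.columns)
    )


def _transformed_log2(m: CtMatrix, eff: EfficiencyModel | float) -> pd.DataFrame:
    """log2 of relative quantities, i.e. -Ct * log2(1+E) up to a per-gene
    constant that every pairwise/centered statistic cancels."""
    return relative_quantities(m, eff).log2


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(m: CtMatrix, dataset: str = "all") -> StabilityTable:
    """BestKeeper descriptive dispersion on raw Ct values.

    Dispersion = mean absolute deviation around the gene's arithmetic mean
    (deliberately not the n-1 sample SD); CV% = 100 * dispersion / mean is
    reported as an auxiliary column.
    """
    m.require_complete()
    if m.n_samples < 2:
        raise ValueError("bestkeeper needs at least 2 samples")
    ct = m.values
    mean = ct.mean(axis=1)
    mad = (ct.sub(mean, axis=0)).abs().mean(axis=1)
    extras = pd.DataFrame(
        {"cv_percent": 100.0 * mad / mean, "mean_ct": mean}
    )
    return StabilityTable.from_values("bestkeeper", dataset, mad, extras)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _pairwise_v(y: np.ndarray) -> np.ndarray:
    """Matrix of sample SDs (ddof=1) of y_j - y_k for all gene pairs.

    V_jk depends only on genes j and k, so it never changes as other genes
    are excluded; sd(y_j - y_k)^2 = var_j + var_k - 2 cov_jk.
    """
    c = np.cov(y, ddof=1)
    c = np.atleast_2d(c)
    d = np.diag(c)
    v2 = d[:, None] + d[None, :] - 2.0 * c
    return np.sqrt(np.clip(v2, 0.0, None))


def genorm(
    q: RelativeQuantityMatrix, dataset: str = "all"
) -> tuple[StabilityTable, GeNormTrace]:
    """geNorm M values with stepwise exclusion.

    Each round the gene with the largest M (ties: the later gene in input
    order) is excluded and M recomputed over the survivors, until two genes
    remain sharing the final M.  Ranks: the final pair takes 1 and 2,
    ordered by their M in the last 3-gene round (tie -> input order); the
    excluded genes take 3, 4, ... in reverse exclusion order.  The reported
    stability value of each gene is its M at exclusion (final pair: the
    shared final M).
    """
    genes = list(q.values.index)
    n = len(genes)
    if n < 3:
        raise ValueError("genorm needs at least 3 genes")
    if q.values.shape[1] < 2:
        raise ValueError("genorm needs at least 2 samples")
    y = q.log2.to_numpy()
    v = _pairwise_v(y)

    remaining = list(range(n))
    trace = GeNormTrace()
    values = np.empty(n)
    ranks = np.empty(n, dtype=int)
    last3_m: dict[int, float] = {}
    next_rank = n
    while len(remaining) > 2:
        sub = v[np.ix_(remaining, remaining)]
        m_vals = sub.sum(axis=1) / (len(remaining) - 1)
        if len(remaining) == 3:
            last3_m = dict(zip(remaining, m_vals))
        worst_local = max(
            (i for i, mv in enumerate(m_vals) if mv == m_vals.max())
        )  # tie -> later in input order
        worst = remaining[worst_local]
        values[worst] = m_vals[worst_local]
        ranks[worst] = next_rank
        next_rank -= 1
        trace.exclusions.append((genes[worst], float(m_vals[worst_local])))
        remaining.pop(worst_local)

    j, k = remaining
    final_m = float(v[j, k])
    values[j] = values[k] = final_m
    trace.final_pair = (genes[j], genes[k])
    trace.final_m = final_m
    # rank 1/2 by M in the last 3-gene round; tie -> input order
    if n == 3:
        pass  # last3_m populated above
    mj, mk = last3_m.get(j, final_m), last3_m.get(k, final_m)
    if (mj < mk) or (mj == mk and j < k):
        ranks[j], ranks[k] = 1, 2
    else:
        ranks[j], ranks[k] = 2, 1

    frame = pd.DataFrame(
        {"value": values, "rank": ranks}, index=pd.Index(genes, name="gene")
    )
    table = StabilityTable(method="genorm", dataset=dataset, frame=frame)
    return table, trace


# ---------------------------------------------------------------------------
# Comparative delta-Ct
# ---------------------------------------------------------------------------

def deltact(
    m: CtMatrix, eff: EfficiencyModel | float = 1.0, dataset: str = "all"
) -> StabilityTable:
    """Comparative delta-Ct stability: mean over partner genes of the
    sample SD of the per-sample pairwise difference of transformed values.

    At E = 1 the transformed difference is just Ct_g - Ct_h (up to sign)
    and the statistic equals the mean of geNorm's pairwise V row.
    """
    if m.n_genes < 2:
        raise ValueError("deltact needs at least 2 genes")
    if m.n_samples < 2:
        raise ValueError("deltact needs at least 2 samples")
    y = _transformed_log2(m, eff).to_numpy()
    v = _pairwise_v(y)
    stab = v.sum(axis=1) / (m.n_genes - 1)
    return StabilityTable.from_values(
        "deltact", dataset, pd.Series(stab, index=m.values.index)
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _intragroup_variances(y: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene residual variances within one group.

    y is the gene x sample block *after* per-sample centering (column means
    over genes removed).  The naive per-gene variance around the gene's own
    mean is biased because each column mean contains a 1/l share of the
    gene itself: E[s2_i] = sigma2_i (1 - 2/l) + sum_k sigma2_k / l**2.
    Solving the moment equations gives

        sigma2_i = l/(l-2) * ( s2_i - sum_k s2_k / (l (l-1)) )

    clipped at zero.  Needs l >= 3 genes and n >= 2 samples.
    """
    l, n = y.shape
    if l < 3:
        raise ValueError("normfinder needs at least 3 genes")
    if n < 2:
        raise ValueError("normfinder needs at least 2 samples per group")
    resid = y - y.mean(axis=1, keepdims=True)
    s2 = (resid**2).sum(axis=1) / (n - 1)
    sigma2 = l / (l - 2) * (s2 - s2.sum() / (l * (l - 1)))
    return np.clip(sigma2, 0.0, None)


def normfinder(
    q: RelativeQuantityMatrix,
    design: GroupDesign | None = None,
    use_groups: bool = False,
    dataset: str = "all",
) -> tuple[StabilityTable, NormFinderResult]:
    """Model-based stability value rho (lower = more stable).

    Works on y = log2(q) with per-sample means (over genes) removed.

    Single-group mode: rho_g = sqrt(sigma2_g), the bias-corrected
    intragroup SD.

    Multi-group mode: per gene and group the intragroup variance sigma2_ig
    and the intergroup deviation d_ig (the gene's sample-effect-corrected
    group mean minus its across-group mean; deviations sum to zero over
    genes within each group by construction) are estimated.  d is shrunk
    toward zero in proportion to its sampling variance sigma2_ig/n_g
    against the between-gene deviation variance gamma2 (method of
    moments), and

        rho_ig = |d_shrunk_ig| + sqrt(sigma2_ig / n_g),
        rho_g  = mean over groups of rho_ig.
    """
    genes = list(q.values.index)
    y = q.log2.to_numpy()
    y = y - y.mean(axis=0, keepdims=True)  # remove per-sample effects

    if not use_groups:
        sigma2 = _intragroup_variances(y)
        rho = pd.Series(np.sqrt(sigma2), index=pd.Index(genes, name="gene"))
        table = StabilityTable.from_values("normfinder", dataset, rho)
        result = NormFinderResult(
            rho=rho,
            sigma2=pd.DataFrame({"all": sigma2}, index=rho.index),
            d_hat=None,
            d_shrunk=None,
            gamma2=None,
        )
        return table, result

    if design is None:
        raise ValueError("use_groups=True requires a GroupDesign")
    samples = list(q.values.columns)
    group_labels = [design.group_of(s) for s in samples]
    groups = list(dict.fromkeys(group_labels))
    if len(groups) < 2:
        raise ValueError("use_groups=True requires at least 2 groups")
    cols = {g: [i for i, lab in enumerate(group_labels) if lab == g] for g in groups}
    small = [g for g, idx in cols.items() if len(idx) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    k = len(groups)
    l = len(genes)
    n_g = np.array([len(cols[g]) for g in groups], dtype=float)
    group_means = np.column_stack([y[:, cols[g]].mean(axis=1) for g in groups])
    sigma2 = np.column_stack(
        [_intragroup_variances(y[:, cols[g]]) for g in groups]
    )

    d_hat = group_means - group_means.mean(axis=1, keepdims=True)
    samp_var = sigma2 / n_g[None, :]  # sampling variance of each group mean
    # sampling variance of d_hat: the across-group mean re-enters with
    # weight 1/k, so Var(d_ig) = ((k-1)/k)^2 v_ig + sum_{g'!=g} v_ig'/k^2
    var_d = ((k - 1) / k) ** 2 * samp_var + (
        samp_var.sum(axis=1, keepdims=True) - samp_var
    ) / k**2
    # variance of the true deviations, from the mean square of the observed
    # ones over the (l-1)(k-1) free cells left by the sum constraints; the
    # sampling-noise share is deliberately not subtracted off, which keeps
    # the shrinkage conservative and gamma2 strictly positive whenever any
    # deviation is observed
    gamma2 = float((d_hat**2).sum() / ((l - 1) * (k - 1)))
    denom = gamma2 + var_d
    with np.errstate(invalid="ignore"):
        d_shrunk = np.where(denom > 0, d_hat * gamma2 / np.where(denom > 0, denom, 1.0), 0.0)

    rho_ig = np.abs(d_shrunk) + np.sqrt(samp_var)
    rho = pd.Series(rho_ig.mean(axis=1), index=pd.Index(genes, name="gene"))
    table = StabilityTable.from_values("normfinder", dataset, rho)
    result = NormFinderResult(
        rho=rho,
        sigma2=pd.DataFrame(sigma2, index=rho.index, columns=groups),
        d_hat=pd.DataFrame(d_hat, index=rho.index, columns=groups),
        d_shrunk=pd.DataFrame(d_shrunk, index=rho.index, columns=groups),
        gamma2=gamma2,
    )
    return table, result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_all(
    m: CtMatrix,
    design: GroupDesign,
    dataset: str = "pooled",
    eff: EfficiencyModel | float = 1.0,
) -> dict[str, StabilityTable]:
    """Run the four estimators on one dataset (a group label or "pooled").

    Pooled mode runs NormFinder with the design's groups; a single-group
    dataset runs it in single-group mode.  Gene ordering is consistent
    across the returned tables.
    """
    if dataset == "pooled":
        sub = m.subset_samples([s for s in design.sample_ids if s in m.values.columns])
        use_groups = True
    else:
        sub = m.subset_samples(
            [s for s in design.samples_in(dataset) if s in m.values.columns]
        )
        use_groups = False
    sub.require_complete()
    q = relative_quantities(sub, eff)
    tables = {
        "bestkeeper": bestkeeper(sub, dataset=dataset),
        "genorm": genorm(q, dataset=dataset)[0],
        "deltact": deltact(sub, eff, dataset=dataset),
        "normfinder": normfinder(
            q, design=design, use_groups=use_groups, dataset=dataset
        )[0],
    }
    return tables
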