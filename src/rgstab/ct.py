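"""Ct matrices, sample metadata, detection filtering and descriptive statistics.

The single input currency of every downstream stage is a gene x sample table
of quantification-cycle values (Ct / Cq / Crt -- the two dialects are treated
as the same quantity, the label is kept purely as metadata).  Undetected
assays are carried as NaN.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "Undetermined")

__all__ = [
    "CtMatrix",
    "GroupDesign",
    "CorrelationReport",
    "DetectionFilterResult",
    "read_ct_table",
    "write_ct_table",
    "read_sample_sheet",
    "filter_complete_detection",
    "describe",
    "dataset_correlation",
]


class CtMatrix:
    """A genes x samples grid of quantification-cycle values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  NaN marks
        an undetected (missing) call; every present value must be finite and
        positive (a PCR machine never reports a non-positive cycle).
    label
        Which dialect the source used ("Ct", "Cq" or "Crt"); metadata only.
    """

    def __init__(self, values: pd.DataFrame, label: str = "Ct"):
        values = values.copy()
        dup_genes = values.index[values.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene ids: {dup_genes}")
        dup_samples = values.columns[values.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample ids: {dup_samples}")
        values = values.astype(float)
        arr = values.to_numpy()
        present = ~np.isnan(arr)
        if np.any(~np.isfinite(arr[present])):
            raise ValueError("non-finite Ct value present")
        if np.any(arr[present] <= 0):
            raise ValueError("Ct values must be > 0")
        values.index.name = "gene"
        values.columns.name = None
        self.values = values
        self.label = label

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def require_complete(self) -> None:
        if not self.is_complete:
            raise ValueError(
                "operation requires a completely detected matrix; "
                "run filter_complete_detection first"
            )

    def subset_samples(self, sample_ids: Sequence) -> "CtMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return CtMatrix(self.values.loc[:, list(sample_ids)], label=self.label)

    def subset_genes(self, gene_ids: Sequence) -> "CtMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        return CtMatrix(self.values.loc[list(gene_ids)], label=self.label)

    def gene(self, gene_id) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(f"unknown gene id: {gene_id!r}")
        return self.values.loc[gene_id]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CtMatrix({self.n_genes} genes x {self.n_samples} samples, label={self.label!r})"


class GroupDesign:
    """Maps each sample to a donor and an experimental group.

    Groups partition the samples (e.g. precursor / differentiated /
    hypertrophic chondrocyte regions).  Group-aware analyses require at
    least two samples per analyzed group.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"donor_id", "group"}
        if not required.issubset(frame.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample ids in design: {dup}")
        self.frame = frame

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple]) -> "GroupDesign":
        """Build from ``{sample_id: (donor_id, group)}`` preserving order."""
        frame = pd.DataFrame(
            {
                "donor_id": [v[0] for v in mapping.values()],
                "group": [v[1] for v in mapping.values()],
            },
            index=pd.Index(list(mapping.keys()), name="sample_id"),
        )
        return cls(frame)

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def groups(self) -> list:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.frame["group"]))

    def samples_in(self, group) -> list:
        if group not in set(self.frame["group"]):
            raise KeyError(f"group {group!r} not present in design")
        return list(self.frame.index[self.frame["group"] == group])

    def group_of(self, sample_id):
        return self.frame.loc[sample_id, "group"]

    def validate_for(self, m: CtMatrix, min_per_group: int = 2) -> None:
        missing = [s for s in m.sample_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        counts = self.frame.loc[m.sample_ids, "group"].value_counts()
        small = counts[counts < min_per_group]
        if len(small):
            raise ValueError(
                f"groups with fewer than {min_per_group} samples: {list(small.index)}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = self.frame["group"].value_counts().to_dict()
        return f"GroupDesign({len(self.frame)} samples, groups={sizes})"


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between two paired vectors, with the qualitative
    band convention used for inter-dataset comparisons (R^2 > 0.8 very
    strong, < 0.6 fair, otherwise intermediate)."""

    r: float
    r2: float
    band: str
    n: int

    @staticmethod
    def band_of(r2: float) -> str:
        if r2 > 0.8:
            return "very strong"
        if r2 < 0.6:
            return "fair"
        return "intermediate"

    @classmethod
    def from_vectors(cls, x: Iterable[float], y: Iterable[float]) -> "CorrelationReport":
        x = np.asarray(list(x), dtype=float)
        y = np.asarray(list(y), dtype=float)
        if x.shape != y.shape:
            raise ValueError("vectors must have equal length")
        if x.size < 3:
            raise ValueError("need at least 3 paired observations for a correlation")
        r = float(_stats.pearsonr(x, y).statistic)
        return cls(r=r, r2=r * r, band=cls.band_of(r * r), n=int(x.size))


class DetectionFilterResult(NamedTuple):
    matrix: CtMatrix
    n_removed: int
    removed_genes: list


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_ct_table(
    path,
    sep: str | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    label: str = "Ct",
) -> CtMatrix:
    """Read a wide Ct table (first column gene ids, header row sample ids).

    Cells matching one of ``missing_tokens`` (after stripping whitespace)
    become the missing marker; any other non-numeric cell is an error that
    names its row/column coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=_infer_sep(path, sep), index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str).str.strip()
    tokens = set(missing_tokens)
    stripped = raw.apply(lambda col: col.str.strip())
    missing_mask = stripped.isin(tokens)
    numeric = stripped.mask(missing_mask).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing_mask
    if bad.any().any():
        coords = [
            f"(gene={g!r}, sample={s!r}, cell={stripped.at[g, s]!r})"
            for g, s in zip(*np.where(bad.to_numpy()))
            for g, s in [(bad.index[g], bad.columns[s])]
        ]
        raise ValueError("non-numeric cells: " + "; ".join(coords))
    return CtMatrix(numeric, label=label)


def write_ct_table(m: CtMatrix, path, sep: str | None = None) -> None:
    """Write a CtMatrix so that a read round-trips bit-identically
    (full repr precision; missing as empty cells)."""
    path = Path(path)
    out = m.values.copy()
    buf = io.StringIO()
    out.to_csv(buf, sep=_infer_sep(path, sep), na_rep="")
    path.write_text(buf.getvalue())


def read_sample_sheet(path, sep: str | None = None) -> GroupDesign:
    """Read a sample sheet CSV with columns sample_id, donor_id, group."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    if "sample_id" not in frame.columns:
        raise ValueError("sample sheet must have a sample_id column")
    frame = frame.set_index("sample_id")
    return GroupDesign(frame)


def write_sample_sheet(design: GroupDesign, path, sep: str | None = None) -> None:
    path = Path(path)
    out = design.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_infer_sep(path, sep))


# ---------------------------------------------------------------------------
# Filtering and descriptive statistics
# ---------------------------------------------------------------------------

def filter_complete_detection(m: CtMatrix) -> DetectionFilterResult:
    """Keep only genes detected (non-missing) in every sample.

    Gene order is preserved.  Raises if nothing survives, since every
    downstream stability analysis needs at least one complete gene.
    """
    complete = ~m.values.isna().any(axis=1)
    kept = m.values.loc[complete]
    removed = list(m.values.index[~complete])
    if kept.shape[0] == 0:
        raise ValueError("no completely detected genes")
    return DetectionFilterResult(
        matrix=CtMatrix(kept, label=m.label),
        n_removed=len(removed),
        removed_genes=removed,
    )


def _select_samples(m: CtMatrix, design: GroupDesign | None, group) -> CtMatrix:
    if group is None:
        return m
    if design is None:
        raise ValueError("a GroupDesign is required to select a group")
    samples = [s for s in design.samples_in(group) if s in m.values.columns]
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples in the matrix")
    return m.subset_samples(samples)


def describe(
    m: CtMatrix, design: GroupDesign | None = None, group=None
) -> pd.DataFrame:
    """Per-gene descriptive statistics over the selected sample subset.

    Returns a DataFrame (index gene) with columns n, mean, sd, min, max.
    The sd is the ordinary sample standard deviation (n-1 denominator);
    missing calls are excluded from each gene's statistics.
    """
    sub = _select_samples(m, design, group).values
    out = pd.DataFrame(
        {
            "n": sub.notna().sum(axis=1),
            "mean": sub.mean(axis=1),
            "sd": sub.std(axis=1, ddof=1),
            "min": sub.min(axis=1),
            "max": sub.max(axis=1),
        }
    )
    out.index.name = "gene"
    return out


def dataset_correlation(
    m: CtMatrix, design: GroupDesign, group_a, group_b
) -> CorrelationReport:
    """Pearson correlation between two groups' per-gene mean Ct vectors.

    Each gene contributes one point (its arithmetic-mean Ct in group A
    against group B), the gene-wise pairing used for inter-dataset scatter
    plots; donor-level pairing is not assumed.
    """
    a = _select_samples(m, design, group_a).values.mean(axis=1)
    b = _select_samples(m, design, group_b).values.mean(axis=1)
    paired = pd.concat([a, b], axis=1).dropna()
    if paired.shape[0] < 3:
        raise ValueError("fewer than 3 paired genes; correlation undefined")
    return CorrelationReport.from_vectors(paired.iloc[:, 0], paired.iloc[:, 1])
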