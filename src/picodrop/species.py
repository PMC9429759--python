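"""Species-level community profiling.

Relative abundances are estimated from marker-gene read counts: per
sample, a species' coverage is the mean over its markers of
``count * read_length / gene_length`` and abundances are coverages
normalised to sum to one.  On top of the abundance table sit Shannon and
Simpson alpha diversity, Bray-Curtis and Jaccard beta diversity, and
classical-scaling principal coordinate analysis (PCoA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

DEFAULT_READ_LENGTH = 150


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise DomainError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise DomainError("distance matrix must have zero diagonal")
        if np.any(v < 0):
            raise DomainError("distances must be >= 0")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PCoAResult:
    """Classical-scaling embedding: coordinates on the retained
    (positive-eigenvalue) axes, the eigenvalues, and the proportion of
    positive inertia each axis explains."""

    samples: pd.DataFrame  # index sample id, columns PCo1..PCok
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "species", "gene", "count", "gene_length"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"marker count table missing columns {sorted(missing)}")
    if len(table) == 0:
        raise ParseError("marker count table is empty")
    if (table["count"] < 0).any() or (table["gene_length"] <= 0).any():
        raise ParseError("counts must be >= 0 and gene lengths > 0")
    if table.duplicated(["sample", "species", "gene"]).any():
        raise ParseError("duplicate (sample, species, gene) rows")
    return table


def relative_abundance(
    table: pd.DataFrame, read_length: int = DEFAULT_READ_LENGTH
) -> pd.DataFrame:
    """Samples x species relative-abundance matrix from marker counts.

    Species coverage in a sample is the mean over that species' markers of
    ``count * read_length / gene_length``; marker panels of unequal size
    therefore do not bias the estimate.  A sample with zero total coverage
    yields an all-zero row (with a warning) rather than NaNs.
    """
    table = _validate_counts(table)
    cov = table.assign(
        coverage=table["count"] * read_length / table["gene_length"]
    )
    per_species = (
        cov.groupby(["sample", "species"], sort=True)["coverage"]
        .mean()
        .unstack(fill_value=0.0)
    )
    totals = per_species.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero marker coverage: {list(per_species.index[zero])}"
        )
        totals[zero] = 1.0
    return per_species.div(totals, axis=0)


def alpha_diversity(abundance: pd.DataFrame, metric: str = "shannon") -> pd.Series:
    """Per-sample Shannon entropy (natural log) or Simpson index 1 - sum p^2.

    All-zero rows are undefined and reported as NaN.
    """
    p = abundance.to_numpy(float)
    zero_rows = p.sum(axis=1) == 0
    if metric == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        vals = -terms.sum(axis=1)
    elif metric == "simpson":
        vals = 1.0 - (p**2).sum(axis=1)
    else:
        raise DomainError(f"unknown alpha metric {metric!r}")
    vals = np.where(zero_rows, np.nan, vals)
    return pd.Series(vals, index=abundance.index, name=metric)


def beta_diversity(
    abundance: pd.DataFrame,
    metric: str = "bray_curtis",
    presence_threshold: float = 0.0,
) -> DistanceMatrix:
    """Pairwise Bray-Curtis or (presence/absence) Jaccard distances.

    Jaccard presence means abundance strictly above ``presence_threshold``.
    A pair of all-zero samples gets distance 0 with a warning.
    """
    if len(abundance) < 2:
        raise DomainError("beta diversity needs at least two samples")
    p = abundance.to_numpy(float)
    n = len(p)
    d = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            a, b = p[i], p[j]
            if metric == "bray_curtis":
                denom = (a + b).sum()
                if denom == 0:
                    warned = True
                    dist = 0.0
                else:
                    dist = 1.0 - 2.0 * np.minimum(a, b).sum() / denom
            elif metric == "jaccard":
                pa, pb = a > presence_threshold, b > presence_threshold
                union = (pa | pb).sum()
                if union == 0:
                    warned = True
                    dist = 0.0
                else:
                    dist = 1.0 - (pa & pb).sum() / union
            else:
                raise DomainError(f"unknown beta metric {metric!r}")
            d[i, j] = d[j, i] = dist
    if warned:
        warnings.warn("sample pair(s) with empty union: distance set to 0")
    return DistanceMatrix(ids=list(abundance.index), values=d)


def pcoa(distances: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical multidimensional scaling of a distance matrix.

    Double-centres the squared distances (B = -1/2 J D^2 J), keeps the
    positive eigenvalues, and scales eigenvectors by the square roots of
    their eigenvalues.  Negative eigenvalues (non-Euclidean input) are
    dropped; proportions explained are relative to the positive part.
    """
    if n_axes is not None and n_axes < 1:
        raise DomainError("n_axes must be >= 1")
    d = distances.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-9 * max(eigval.max(), 1.0)
    pos = eigval > tol
    if not pos.any():
        warnings.warn("degenerate distance matrix: no positive eigenvalues")
        coords = np.zeros((n, 1))
        return PCoAResult(
            samples=pd.DataFrame(coords, index=distances.ids, columns=["PCo1"]),
            eigenvalues=eigval[:1],
            proportion_explained=np.array([0.0]),
        )
    ev = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(ev)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        ev = ev[:n_axes]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        samples=pd.DataFrame(coords, index=distances.ids, columns=cols),
        eigenvalues=ev,
        proportion_explained=ev / eigval[pos].sum(),
    )
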