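"""Expression-matrix container, I/O, standardization and microarray preprocessing.

The central container is :class:`ExpressionMatrix`, a thin immutable wrapper
around a ``samples x genes`` float array with sample/gene identifiers and a
flag recording whether each gene has been standardized to mean 0, variance 1
(the scale on which the mixture model operates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "load_expression",
    "standardize",
    "preprocess_leukemia",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x genes expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression values; must be finite.
    sample_ids, gene_ids : sequences of str
        Row and column identifiers; gene ids must be unique.
    standardized : bool
        True once each gene column has mean 0 and unit variance (n-1 divisor).
    """

    values: np.ndarray
    sample_ids: tuple = field(default=None)
    gene_ids: tuple = field(default=None)
    standardized: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains missing or non-finite values")
        object.__setattr__(self, "values", values)
        n, p = values.shape
        sample_ids = self.sample_ids
        gene_ids = self.gene_ids
        if sample_ids is None:
            sample_ids = tuple(f"sample_{i}" for i in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
        if gene_ids is None:
            gene_ids = tuple(f"gene_{j}" for j in range(p))
        else:
            gene_ids = tuple(str(g) for g in gene_ids)
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} rows")
        if len(gene_ids) != p:
            raise ValueError(f"{len(gene_ids)} gene ids for {p} columns")
        seen, dupes = set(), []
        for g in gene_ids:
            if g in seen:
                dupes.append(g)
            seen.add(g)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))}")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "gene_ids", gene_ids)
        if self.standardized:
            mean = values.mean(axis=0)
            var = values.var(axis=0, ddof=1) if n > 1 else np.ones(p)
            if np.abs(mean).max(initial=0.0) > 1e-8 or np.abs(var - 1).max(initial=0.0) > 1e-6:
                raise ValueError("standardized flag set but columns are not standardized")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=tuple(map(str, df.index)),
            gene_ids=tuple(map(str, df.columns)),
            standardized=standardized,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.gene_ids)
        )

    def select_genes(self, idx) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene column indices."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx],
            sample_ids=self.sample_ids,
            gene_ids=tuple(self.gene_ids[j] for j in idx),
            standardized=False,
        )


def load_expression(path, orientation: str = "samples", sep=None) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with one header row and one identifier column.
    orientation : {"samples", "genes"}
        What the file's *rows* are.  ``"genes"`` transposes after reading.
    sep : str, optional
        Field delimiter; sniffed when omitted.
    """
    if orientation not in ("samples", "genes"):
        raise ValueError("orientation must be 'samples' or 'genes'")
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"no data columns found in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if df.isna().to_numpy().any():
        raise ValueError(f"missing values in {path}")
    if orientation == "genes":
        df = df.T
    return ExpressionMatrix.from_dataframe(df)


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene to mean 0 and unit variance (n-1 divisor).

    Raises
    ------
    ValueError
        If a gene is constant across samples (zero variance).
    """
    if X.standardized:
        return X
    values = X.values
    if X.n < 2:
        raise ValueError("need at least two samples to standardize")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [X.gene_ids[j] for j in zero]
        raise ValueError(f"constant gene(s) cannot be standardized: {names}")
    return replace(X, values=(values - mean) / sd, standardized=True)


def preprocess_leukemia(
    X: ExpressionMatrix,
    floor: float = 100.0,
    ceil: float = 16000.0,
    ratio_min: float = 5.0,
    range_min: float = 500.0,
    top_k: int = 300,
) -> ExpressionMatrix:
    """Dudoit-style microarray preprocessing: clamp, filter, variance screen.

    Steps, applied to raw (unstandardized) intensities:

    1. thresholding: values below ``floor`` are set to ``floor``, values above
       ``ceil`` to ``ceil``;
    2. filtering: a gene is kept only if ``max/min > ratio_min`` *and*
       ``max - min > range_min`` across samples (on the clamped values);
    3. screening: the ``top_k`` surviving genes with the largest sample
       variances (n-1 divisor, clamped unstandardized values) are retained,
       ties broken by gene-id order;
    4. the result is standardized per gene.
    """
    if X.standardized:
        raise ValueError("preprocessing expects raw (unstandardized) expression")
    vals = np.clip(X.values, floor, ceil)
    gmax = vals.max(axis=0)
    gmin = vals.min(axis=0)
    keep = np.flatnonzero((gmax / gmin > ratio_min) & (gmax - gmin > range_min))
    if top_k > keep.size:
        raise ValueError(
            f"top_k={top_k} exceeds the {keep.size} genes surviving the filter"
        )
    var = vals[:, keep].var(axis=0, ddof=1)
    # stable rank: descending variance, gene-id order breaks exact ties
    order = sorted(range(keep.size), key=lambda i: (-var[i], X.gene_ids[keep[i]]))
    chosen = np.sort(keep[np.asarray(order[:top_k])])
    clamped = ExpressionMatrix(
        values=vals, sample_ids=X.sample_ids, gene_ids=X.gene_ids
    )
    return standardize(clamped.select_genes(chosen))
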