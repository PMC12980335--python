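"""Reading and writing two-gene expression tables.

The universal in-memory container is :class:`GenePairMatrix`: per-sample
expression of one gene pair plus a cohort label (``healthy`` / ``cancer`` /
``unknown``).  Tables are plain delimited text with a header row; the
delimiter is inferred from the file extension (``.csv`` → comma, anything
else → tab) unless given explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COHORT_LABELS = ("healthy", "cancer", "unknown")


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class GenePairMatrix:
    """n samples x 2 genes of expression with cohort labels.

    Parameters
    ----------
    sample_ids : list of str
        Unique opaque identifiers, one per row.
    gene_names : (str, str)
        Names of the two genes (e.g. ``("OGT", "OGA")``); must differ.
    values : ndarray of shape (n, 2)
        Expression values in arbitrary (but consistent) units; all finite.
    cohort : ndarray of str, shape (n,)
        Per-sample label in ``{"healthy", "cancer", "unknown"}``.
    n_dropped : int
        Rows removed for missing/non-finite expression when the matrix was
        read from a file; 0 for programmatically built matrices.
    """

    sample_ids: list[str]
    gene_names: tuple[str, str]
    values: np.ndarray
    cohort: np.ndarray
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cohort = np.asarray(self.cohort, dtype=object)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = self.values.shape[0]
        if n < 1:
            raise ValueError("GenePairMatrix needs at least one sample")
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must be an (n, 2) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if len(self.sample_ids) != n or len(self.cohort) != n:
            raise ValueError("sample_ids, values and cohort must agree in length")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(self.gene_names) != 2 or self.gene_names[0] == self.gene_names[1]:
            raise ValueError("gene_names must be two distinct names")
        bad = set(self.cohort) - set(COHORT_LABELS)
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "GenePairMatrix":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("subset selects zero samples")
        return GenePairMatrix(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            gene_names=self.gene_names,
            values=self.values[mask],
            cohort=self.cohort[mask],
        )

    def labelled(self, label: str) -> "GenePairMatrix":
        """Samples carrying one cohort label (``unknown`` rows are never
        included in a fit or test that needs a label)."""
        return self.subset(self.cohort == label)

    @property
    def healthy(self) -> "GenePairMatrix":
        return self.labelled("healthy")

    @property
    def cancer(self) -> "GenePairMatrix":
        return self.labelled("cancer")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                self.gene_names[0]: self.values[:, 0],
                self.gene_names[1]: self.values[:, 1],
                "cohort": self.cohort,
            }
        )


def normalize_cohort(raw) -> np.ndarray:
    """Map arbitrary labels case-insensitively onto healthy/cancer/unknown."""
    out = []
    for v in raw:
        s = str(v).strip().lower() if v is not None and not pd.isna(v) else ""
        out.append(s if s in ("healthy", "cancer") else "unknown")
    return np.asarray(out, dtype=object)


def read_expression_table(
    path: str | Path,
    gene1: str,
    gene2: str,
    cohort_column: str | None = None,
    sample_column: str | None = None,
    delimiter: str | None = None,
    log2: bool = False,
) -> GenePairMatrix:
    """Read a delimited expression table into a :class:`GenePairMatrix`.

    Rows with a missing or non-finite value in either gene column are dropped
    and counted (``matrix.n_dropped``).  Cohort labels are normalised
    case-insensitively; anything other than healthy/cancer becomes
    ``unknown``.  With ``log2=True`` a log2(x+1) transform is applied at read
    time (the tool is otherwise unit-agnostic).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such expression table: {path}")
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    for col in (gene1, gene2):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    if cohort_column is not None and cohort_column not in df.columns:
        raise ValueError(f"cohort column {cohort_column!r} not found in {path.name}")
    if sample_column is None and "sample_id" in df.columns:
        sample_column = "sample_id"
    if sample_column is not None and sample_column not in df.columns:
        raise ValueError(f"sample column {sample_column!r} not found in {path.name}")

    vals = df[[gene1, gene2]].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    keep = np.isfinite(vals).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing/non-finite expression", n_dropped)
    df = df.loc[keep]
    vals = vals[keep]
    if vals.shape[0] == 0:
        raise ValueError(f"no usable rows in {path.name} after filtering")
    if log2:
        if (vals < 0).any():
            raise ValueError("log2 transform requires non-negative expression")
        vals = np.log2(vals + 1.0)

    ids = (
        df[sample_column].astype(str).tolist()
        if sample_column is not None
        else [f"S{i}" for i in df.index]
    )
    cohort = (
        normalize_cohort(df[cohort_column])
        if cohort_column is not None
        else np.asarray(["unknown"] * vals.shape[0], dtype=object)
    )
    return GenePairMatrix(
        sample_ids=ids,
        gene_names=(gene1, gene2),
        values=vals,
        cohort=cohort,
        n_dropped=n_dropped,
    )


def write_scores_table(
    path: str | Path,
    matrix: GenePairMatrix,
    scores: np.ndarray,
    delimiter: str | None = None,
) -> None:
    """Write ``sample_id, gene1, gene2, cohort, regulation_score`` columns.

    Scores must be one per sample and inside [0, 1] (the regulation-score
    contract); values round-trip through :func:`read_expression_table`.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.shape[0] != matrix.n_samples:
        raise ValueError(
            f"got {scores.shape[0] if scores.ndim == 1 else scores.shape} scores "
            f"for {matrix.n_samples} samples"
        )
    if not np.all(np.isfinite(scores)) or scores.min() < 0 or scores.max() > 1:
        raise ValueError("regulation scores must be finite and within [0, 1]")
    df = matrix.to_frame()
    df["regulation_score"] = scores
    df.to_csv(path, sep=_delimiter_for(path, delimiter), index=False,
              float_format="%.15g")
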