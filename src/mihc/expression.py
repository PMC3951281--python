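"""Time-course expression matrices: I/O and preprocessing.

The pipeline operates on genes-by-timepoints matrices of expression
log-ratios (e.g. two-colour microarray time courses over a cell cycle).
Raw series are normalised in two steps before any correlation is taken:
the first value of every gene is shifted to zero, so that profiles are
compared by their *change* over time rather than their absolute level,
and a short centred moving average smooths out single-timepoint spikes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourseMatrix",
    "read_expression",
    "write_expression",
    "preprocess",
]


class ExpressionFormatError(ValueError):
    """Raised for malformed expression files (header, cells, duplicates)."""


@dataclass
class TimeCourseMatrix:
    """Genes x ordered time points of expression log-ratios.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    time_points
        Strictly increasing sampling times (minutes).
    values
        Real matrix of shape ``(len(gene_ids), len(time_points))``.
    missing_mask
        Boolean matrix, ``True`` where a measurement is missing.
    """

    gene_ids: list[str]
    time_points: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = next(g for g in self.gene_ids if self.gene_ids.count(g) > 1)
            raise ExpressionFormatError(f"duplicate gene id: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.time_points)):
            raise ExpressionFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.time_points)} time points"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ExpressionFormatError("missing_mask shape mismatch")
        if len(self.time_points) > 1 and not np.all(np.diff(self.time_points) > 0):
            raise ExpressionFormatError("time points must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except AttributeError:
            self._index = {g: i for i, g in enumerate(self.gene_ids)}
            return self._index[gene]

    def profile(self, gene: str) -> np.ndarray:
        """Expression profile of one gene (1-D view)."""
        return self.values[self.index_of(gene)]

    def subset(self, genes) -> "TimeCourseMatrix":
        """Row-subset preserving the given gene order."""
        idx = [self.index_of(g) for g in genes]
        return TimeCourseMatrix(
            gene_ids=list(genes),
            time_points=self.time_points.copy(),
            values=self.values[idx].copy(),
            missing_mask=self.missing_mask[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.time_points)
        return df.mask(self.missing_mask)


def read_expression(
    path,
    sep: str | None = None,
    missing_tokens: tuple[str, ...] = ("NA", "NaN", ""),
) -> TimeCourseMatrix:
    """Read a delimited genes x time-points matrix.

    The file must have a header row of numeric time points and one row per
    gene, the first column being the gene identifier.  ``sep=None`` infers
    tab vs comma from the file extension (``.csv`` means comma).

    Raises
    ------
    ExpressionFormatError
        On a non-numeric header, a non-numeric cell that is not a missing
        token, or a duplicate gene id.
    """
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(missing_tokens),
        keep_default_na=False, dtype=str,
    )
    try:
        tps = np.asarray([float(c) for c in df.columns], dtype=float)
    except ValueError as exc:
        raise ExpressionFormatError(f"malformed header (non-numeric time point): {exc}") from exc
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dup = df.index[df.index.duplicated()][0]
        raise ExpressionFormatError(f"duplicate gene id: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g = bad.index[bad.any(axis=1)][0]
        c = bad.columns[bad.loc[g]][0]
        raise ExpressionFormatError(
            f"non-numeric cell at gene {g!r}, time point {c!r}: {df.loc[g, c]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    return TimeCourseMatrix(
        gene_ids=gene_ids,
        time_points=tps,
        values=values,
        missing_mask=np.isnan(values),
    )


def write_expression(m: TimeCourseMatrix, path, sep: str = "\t", missing_token: str = "NA") -> None:
    """Write a matrix in the format accepted by :func:`read_expression`."""
    df = m.to_frame()
    df.columns = [format(t, "g") for t in m.time_points]
    df.to_csv(path, sep=sep, na_rep=missing_token, index_label="gene")


def _impute_row(row: np.ndarray, mask: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linear interpolation along time; edges held at the nearest observation."""
    out = row.copy()
    obs = ~mask
    # np.interp clamps outside the observed range, which gives nearest-value
    # fill for leading/trailing gaps.
    out[mask] = np.interp(t[mask], t[obs], row[obs])
    return out


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with truncated edge windows (length preserved)."""
    if window == 1:
        return values.copy()
    half = window // 2
    n = values.shape[1]
    padded = np.concatenate(
        [np.zeros((values.shape[0], 1)), np.cumsum(values, axis=1)], axis=1
    )
    out = np.empty_like(values, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[:, i] = (padded[:, hi] - padded[:, lo]) / (hi - lo)
    return out


def preprocess(
    m: TimeCourseMatrix,
    smooth_window: int = 3,
    max_missing_frac: float = 0.3,
) -> TimeCourseMatrix:
    """Impute, zero the first value of each profile, then smooth.

    Missing values are linearly interpolated along the time axis (edge gaps
    take the nearest observed value); genes missing more than
    ``max_missing_frac`` of their points are dropped with a warning.  Each
    surviving row is then shifted so its first entry is 0, and smoothed with
    a centred moving average of width ``smooth_window`` (edge windows are
    truncated to the available neighbours).

    ``smooth_window`` must be odd and >= 1; with window 1 only the baseline
    shift is applied.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    frac = m.missing_mask.mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d gene(s) with > %.0f%% missing values: %s%s",
            len(dropped), 100 * max_missing_frac, ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    gene_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    values = m.values[keep].copy()
    mask = m.missing_mask[keep]
    for i in np.nonzero(mask.any(axis=1))[0]:
        values[i] = _impute_row(values[i], mask[i], m.time_points)
    values = values - values[:, :1]
    values = _moving_average(values, smooth_window)
    return TimeCourseMatrix(
        gene_ids=gene_ids,
        time_points=m.time_points.copy(),
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
    )
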