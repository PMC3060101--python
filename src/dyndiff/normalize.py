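"""Cross-array quantile normalization, flooring, probe collapse, display transform."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dyndiff.errors import ValidationError

logger = logging.getLogger("dyndiff")


@dataclass(frozen=True)
class NormalizationConfig:
    floor_epsilon: float = 1.0
    collapse_strategy: str = "max_mean_probe"
    tie_method: str = "average"
    joint_lines: bool = True  # normalize both lines' arrays together

    def __post_init__(self) -> None:
        if self.floor_epsilon <= 0:
            raise ValidationError("floor_epsilon must be > 0")
        if self.collapse_strategy != "max_mean_probe":
            raise ValidationError(f"unknown collapse strategy {self.collapse_strategy!r}")
        if self.tie_method != "average":
            raise ValidationError(f"unknown tie method {self.tie_method!r}")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column (array) onto the common empirical distribution.

    The reference distribution is the vector of row-wise means of the
    column-sorted matrix; each column's values are replaced by the reference
    value at their within-column rank.  Tied values receive the average of the
    tied reference values, so within-column rank order is preserved.

    A single-column matrix is returned unchanged.
    """
    if matrix.shape[1] < 1:
        raise ValidationError("quantile normalization needs at least one column")
    if matrix.isna().any().any():
        raise ValidationError("quantile normalization does not accept missing values")
    if matrix.shape[1] == 1:
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        vals = x[:, j]
        order = np.argsort(vals, kind="mergesort")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # tied input values get the mean of the reference values they span
        out[:, j] = pd.Series(mapped).groupby(vals).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def floor_intensities(matrix: pd.DataFrame, epsilon: float = 1.0) -> pd.DataFrame:
    """Replace every value below ``epsilon`` with ``epsilon``; logs the count."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    n_floored = int((matrix.to_numpy() < epsilon).sum())
    if n_floored:
        logger.info("floored %d cells below epsilon=%g", n_floored, epsilon)
    return matrix.clip(lower=epsilon)


def collapse_probes(
    matrix: pd.DataFrame,
    annotation: pd.Series,
    strategy: str = "max_mean_probe",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    Under ``max_mean_probe`` the probe with the highest mean intensity across
    all samples represents its gene; ties break to the lexicographically
    smaller probe id.  Probes without annotation are dropped (count logged).
    Every output row equals one input probe row verbatim.
    """
    if strategy != "max_mean_probe":
        raise ValidationError(f"unknown collapse strategy {strategy!r}")
    if annotation is None or len(annotation) == 0:
        raise ValidationError("empty probe-to-gene annotation")
    annotated = matrix.index.intersection(annotation.index)
    dropped = len(matrix.index) - len(annotated)
    if dropped:
        logger.info("dropped %d probes without gene annotation", dropped)
    if len(annotated) == 0:
        raise ValidationError("no probes in the matrix carry annotation")
    sub = matrix.loc[annotated]
    means = sub.mean(axis=1)
    frame = pd.DataFrame(
        {"gene": annotation.loc[annotated].values, "mean": means.values},
        index=annotated,
    )
    winners: dict[str, str] = {}
    for gene, g in frame.groupby("gene", sort=True):
        top = g[g["mean"] == g["mean"].max()]
        winners[gene] = min(top.index)
    genes = sorted(winners)
    collapsed = sub.loc[[winners[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene")
    return collapsed


def log2_mean_center(series: pd.DataFrame | pd.Series | np.ndarray):
    """Display transform for trajectory figures: log2, then center per gene.

    ``output = log2(x) - mean(log2(x))`` along the time axis; rows sum to 0.
    Values must be strictly positive (floor first).
    """
    arr = np.asarray(series, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("log2_mean_center requires strictly positive values; floor first")
    logged = np.log2(arr)
    centered = logged - logged.mean(axis=-1, keepdims=True)
    if isinstance(series, pd.DataFrame):
        return pd.DataFrame(centered, index=series.index, columns=series.columns)
    if isinstance(series, pd.Series):
        return pd.Series(centered, index=series.index, name=series.name)
    return centered
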