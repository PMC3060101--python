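"""Validation-assay calculators: ddCt qPCR quantitation, glucose uptake,
proliferation percent increase, condition fold change, doubling time."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from dyndiff.errors import ValidationError


# ---------------------------------------------------------------------------
# qPCR: Livak 2^(-ddCt) with dual reference genes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrTable:
    """Replicate Ct measurements with designated reference genes and calibrator.

    ``table`` rows: sample, gene, ct, replicate.  ``reference_genes`` are
    combined by arithmetic mean of their per-gene mean Cts (equivalently the
    geometric mean of reference expression).  The calibrator sample's relative
    expression is 1.0 by definition.
    """

    table: pd.DataFrame
    reference_genes: tuple[str, ...]
    calibrator: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"qPCR table missing columns: {sorted(missing)}")
        ct = self.table["ct"]
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValidationError("Ct values must be positive and finite")
        if not self.reference_genes:
            raise ValidationError("at least one reference gene is required")
        if self.calibrator not in set(self.table["sample"]):
            raise ValidationError(f"calibrator sample {self.calibrator!r} absent from table")

    @classmethod
    def read(
        cls, path: str | Path, reference_genes: tuple[str, ...], calibrator: str
    ) -> "QpcrTable":
        table = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
        return cls(table=table, reference_genes=tuple(reference_genes), calibrator=calibrator)


def _delta_ct(table: pd.DataFrame, reference_genes: tuple[str, ...], sample: str, target: str):
    """Mean-Ct dCt for one (sample, target) and its variance from replicate SEM."""
    sub = table[table["sample"] == sample]

    def mean_ct(gene: str) -> tuple[float, float]:
        cts = sub.loc[sub["gene"] == gene, "ct"].to_numpy(dtype=float)
        if cts.size == 0:
            raise ValidationError(f"sample {sample!r} has no Ct for gene {gene!r}")
        var_mean = cts.var(ddof=1) / cts.size if cts.size > 1 else 0.0
        return float(cts.mean()), float(var_mean)

    t_mean, t_var = mean_ct(target)
    ref_means, ref_vars = zip(*(mean_ct(g) for g in reference_genes))
    k = len(reference_genes)
    dct = t_mean - float(np.mean(ref_means))
    var = t_var + float(np.sum(ref_vars)) / k**2
    return dct, var


def ddct_relative_expression(table: QpcrTable) -> pd.DataFrame:
    """Relative expression 2^(-ddCt) per (sample, target gene).

    dCt = mean target Ct - mean of reference-gene mean Cts;
    ddCt = dCt(sample) - dCt(calibrator); the calibrator row is exactly 1.0.
    Replicate dispersion is propagated (first order) to ``rel_expr_sd``.
    """
    targets = sorted(set(table.table["gene"]) - set(table.reference_genes))
    samples = sorted(set(table.table["sample"]))
    rows = []
    for target in targets:
        with_target = [
            s for s in samples
            if ((table.table["sample"] == s) & (table.table["gene"] == target)).any()
        ]
        if table.calibrator not in with_target:
            raise ValidationError(
                f"calibrator {table.calibrator!r} has no Ct for target {target!r}"
            )
        cal_dct, cal_var = _delta_ct(
            table.table, table.reference_genes, table.calibrator, target
        )
        for sample in with_target:
            dct, var = _delta_ct(table.table, table.reference_genes, sample, target)
            if sample == table.calibrator:
                ddct, ddct_var, rel = 0.0, cal_var + var, 1.0
            else:
                ddct = dct - cal_dct
                ddct_var = var + cal_var
                rel = float(2.0 ** (-ddct))
            # delta method: sd(2^-x) = 2^-x * ln2 * sd(x)
            rel_sd = rel * np.log(2.0) * float(np.sqrt(ddct_var))
            rows.append(
                {
                    "sample": sample, "target": target, "delta_ct": dct,
                    "delta_delta_ct": ddct, "rel_expr": rel, "rel_expr_sd": rel_sd,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# glucose uptake
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UptakeRecord:
    condition: str
    glucose_start: float  # mg/ml
    glucose_end: float  # mg/ml
    cell_count: float  # cells at assay end
    duration_hours: float = 48.0

    def __post_init__(self) -> None:
        if self.glucose_start < 0 or self.glucose_end < 0:
            raise ValidationError("glucose concentrations must be >= 0")
        if self.cell_count <= 0:
            raise ValidationError("cell count must be > 0")


def glucose_uptake(record: UptakeRecord) -> float:
    """Glucose consumed per million cells: (start - end) / (cells / 1e6).

    A negative result (end > start) is returned but flagged with a warning —
    it signals assay failure, not a value to clip.
    """
    uptake = (record.glucose_start - record.glucose_end) / (record.cell_count / 1e6)
    if uptake < 0:
        warnings.warn(
            f"negative glucose uptake for condition {record.condition!r}: "
            "end concentration exceeds start",
            stacklevel=2,
        )
    return float(uptake)


# ---------------------------------------------------------------------------
# condition fold change / proliferation
# ---------------------------------------------------------------------------

def condition_fold_change(values_a, values_b) -> tuple[float, float]:
    """Fold change mean(b)/mean(a) with a first-order propagated standard error.

    SE(fold) = fold * sqrt((SE_a/mean_a)^2 + (SE_b/mean_b)^2), with SE the
    standard error of each condition mean (0 for a single replicate).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("each condition needs at least one replicate")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_a == 0:
        raise ValidationError("denominator condition has zero mean")
    fold = mean_b / mean_a
    se_a = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0
    se_b = b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else 0.0
    se = abs(fold) * np.sqrt((se_a / mean_a) ** 2 + (se_b / mean_b) ** 2)
    return float(fold), float(se)


def percent_increase(count_t0: float, count_t: float) -> float:
    """Percent change in count relative to the starting count."""
    if count_t0 <= 0:
        raise ValidationError("starting count must be > 0")
    return 100.0 * (count_t - count_t0) / count_t0


# ---------------------------------------------------------------------------
# doubling time
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSeries:
    condition: str
    times_hours: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_hours, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times_hours", t)
        object.__setattr__(self, "counts", c)
        if t.shape != c.shape or t.size < 2:
            raise ValidationError("growth series needs >= 2 matched (time, count) pairs")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValidationError("counts must be > 0")


def doubling_time(series: GrowthSeries) -> float:
    """Population doubling time from a least-squares exponential fit.

    ln2 / slope of the ln(count) vs time regression; a non-positive slope
    (no net growth) is an error.
    """
    fit = stats.linregress(series.times_hours, np.log(series.counts))
    if fit.slope <= 0:
        raise ValidationError("no net growth: non-positive slope in log-linear fit")
    return float(np.log(2.0) / fit.slope)
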