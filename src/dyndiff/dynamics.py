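"""Differential trajectory statistic: dynamic prefilter, r(t) ratio trajectories,
and calling of oncogene-specific gene regulation.

The statistic for gene g is

    r_g(t) = ln[ (H_g(t) / A_g(t)) / (H_g(0) / A_g(0)) ]

where H is the oncogene-transformed line and A the parental line.  r is 0 at
t=0 by construction and cancels any regulation shared by both lines.  After
kinase inhibition a gene whose expression the oncogene was maintaining falls in
H relative to its own t=0 level, driving r negative — such genes are classed
``oncogene_up`` (the oncogene up-regulated them); genes the oncogene repressed
rise, driving r positive (``oncogene_down``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dyndiff import normalize as _norm
from dyndiff.errors import ValidationError
from dyndiff.io import TimeSeriesExperiment

#: relative tolerance for inclusive threshold comparisons at the boundary
BOUNDARY_RTOL = 1e-9

ONCOGENE_UP = "oncogene_up"
ONCOGENE_DOWN = "oncogene_down"
NOT_DIFFERENTIAL = "not_differential"


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for the prefilter and the differential call.

    Folds are compared inclusively (``>=``) on the natural-log scale with a
    relative tolerance of 1e-9 at the boundary.
    """

    prefilter_fold: float = 1.7
    prefilter_cap: int = 2500
    call_fold: float = 2.0
    quantile: bool = True  # cross-array quantile normalization on/off
    floor_epsilon: float = 1.0
    separate_lines: bool = False  # normalize each line's arrays separately

    def __post_init__(self) -> None:
        if self.prefilter_fold < 1 or self.call_fold < 1:
            raise ValidationError("fold thresholds must be >= 1")
        if self.prefilter_cap < 1:
            raise ValidationError("prefilter cap must be >= 1")
        if self.floor_epsilon <= 0:
            raise ValidationError("floor_epsilon must be > 0")


@dataclass(frozen=True)
class DifferentialTrajectory:
    """Per-gene normalized log-ratio trajectory, anchored at r(0)=0."""

    gene: str
    times: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if self.times.shape != self.r.shape:
            raise ValidationError("times and r must have equal length")


@dataclass(frozen=True)
class GeneCall:
    gene: str
    klass: str  # oncogene_up | oncogene_down | not_differential
    max_abs_r: float
    time_of_extreme: float
    direction: str  # "down" (r fell), "up" (r rose), "none"
    passed_prefilter: bool = True


class GeneCallSet:
    """Collection of per-gene calls with summary helpers."""

    def __init__(self, calls: list[GeneCall]):
        self.calls = list(calls)
        genes = [c.gene for c in self.calls]
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate genes in call set")
        self._by_gene = {c.gene: c for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def __getitem__(self, gene: str) -> GeneCall:
        return self._by_gene[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneCallSet):
            return NotImplemented
        return self.to_frame().reset_index(drop=True).equals(
            other.to_frame().reset_index(drop=True)
        )

    @property
    def genes(self) -> list[str]:
        return [c.gene for c in self.calls]

    def classes(self) -> pd.Series:
        return pd.Series({c.gene: c.klass for c in self.calls})

    def differential(self) -> list[GeneCall]:
        return [c for c in self.calls if c.klass != NOT_DIFFERENTIAL]

    def counts(self) -> dict[str, int]:
        out = {ONCOGENE_UP: 0, ONCOGENE_DOWN: 0, NOT_DIFFERENTIAL: 0}
        for c in self.calls:
            out[c.klass] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "gene": [c.gene for c in self.calls],
                "class": [c.klass for c in self.calls],
                "max_abs_r": [c.max_abs_r for c in self.calls],
                "time_of_extreme": [c.time_of_extreme for c in self.calls],
                "direction": [c.direction for c in self.calls],
                "passed_prefilter": [c.passed_prefilter for c in self.calls],
            }
        )
        return frame.sort_values(
            ["max_abs_r", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def _at_least(value: float, threshold: float) -> bool:
    """Inclusive >= with relative tolerance at the boundary."""
    return value >= threshold * (1.0 - BOUNDARY_RTOL)


# ---------------------------------------------------------------------------
# per-gene operations
# ---------------------------------------------------------------------------

def timepoint_fold_change(series: np.ndarray) -> np.ndarray:
    """Direction-symmetric fold change of each time point relative to t=0.

    ``fold(t) = max(x_t/x_0, x_0/x_t)``; the first element (t=0) is 1 exactly.
    """
    x = np.asarray(series, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("fold change requires strictly positive intensities")
    ratio = x / x[..., :1]
    return np.maximum(ratio, 1.0 / ratio)


def series_fold_change(series: np.ndarray) -> dict[str, float]:
    """Both candidate definitions of a series' overall expression change.

    ``extreme_vs_t0``: the largest direction-symmetric fold relative to t=0.
    ``max_vs_min``:    max(series) / min(series).
    """
    x = np.asarray(series, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("fold change requires strictly positive intensities")
    return {
        "extreme_vs_t0": float(timepoint_fold_change(x).max()),
        "max_vs_min": float(x.max() / x.min()),
    }


def differential_trajectory(
    h_series: np.ndarray,
    a_series: np.ndarray,
    times: np.ndarray,
    gene: str = "",
) -> DifferentialTrajectory:
    """r(t) = ln[(H(t)/A(t)) / (H(0)/A(0))]; r(0) is set to 0 exactly."""
    h = np.asarray(h_series, dtype=float)
    a = np.asarray(a_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if h.shape != a.shape or h.shape != t.shape:
        raise ValidationError("line series and time grid lengths differ")
    if t[0] != 0.0:
        raise ValidationError("time grid must start at t=0")
    if np.any(h <= 0) or np.any(a <= 0):
        raise ValidationError("trajectories require strictly positive intensities")
    r = np.log(h / a) - np.log(h[0] / a[0])
    r[0] = 0.0
    return DifferentialTrajectory(gene=gene, times=t, r=r)


def call_differential(trajectory: DifferentialTrajectory, config: PipelineConfig) -> GeneCall:
    """Classify a trajectory against the call threshold.

    Differential iff ``max_t |r(t)| >= ln(call_fold)`` (inclusive).  A negative
    extreme means the oncogene was maintaining expression (``oncogene_up``);
    a positive extreme means it was repressing (``oncogene_down``).
    """
    abs_r = np.abs(trajectory.r)
    idx = int(np.argmax(abs_r))
    max_abs_r = float(abs_r[idx])
    t_ext = float(trajectory.times[idx])
    if _at_least(max_abs_r, np.log(config.call_fold)):
        if trajectory.r[idx] < 0:
            klass, direction = ONCOGENE_UP, "down"
        else:
            klass, direction = ONCOGENE_DOWN, "up"
    else:
        klass, direction = NOT_DIFFERENTIAL, "none"
    return GeneCall(
        gene=trajectory.gene,
        klass=klass,
        max_abs_r=max_abs_r,
        time_of_extreme=t_ext,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# experiment-level operations
# ---------------------------------------------------------------------------

def prefilter_dynamic(
    experiment: TimeSeriesExperiment, config: PipelineConfig
) -> list[str]:
    """Genes whose oncogene-line series moves at least ``prefilter_fold``
    relative to t=0 at any later time point, ranked by max fold descending
    (ties broken by gene id ascending) and truncated at ``prefilter_cap``.
    """
    h = experiment.oncogene.to_numpy(dtype=float)
    if np.any(h <= 0):
        raise ValidationError("prefilter requires strictly positive intensities")
    folds = timepoint_fold_change(h)
    max_fold = folds[:, 1:].max(axis=1)
    genes = experiment.feature_ids.to_numpy()
    keep = np.array([_at_least(f, config.prefilter_fold) for f in max_fold])
    ranked = sorted(
        zip(genes[keep], max_fold[keep]), key=lambda gf: (-gf[1], gf[0])
    )
    return [g for g, _ in ranked[: config.prefilter_cap]]


def run_pipeline(
    experiment: TimeSeriesExperiment,
    config: PipelineConfig | None = None,
) -> tuple[GeneCallSet, dict[str, DifferentialTrajectory], dict[str, pd.DataFrame], dict]:
    """Full analysis: floor -> quantile normalize -> collapse -> prefilter ->
    trajectories -> calls.

    Returns the call set (every gene appears; genes failing the prefilter are
    ``not_differential`` with ``passed_prefilter=False``), the trajectories of
    prefiltered genes, log2 mean-centered display series per called gene, and
    a machine-readable run report with per-stage counts.
    """
    config = config or PipelineConfig()
    report: dict = {
        "prefilter_fold": config.prefilter_fold,
        "prefilter_cap": config.prefilter_cap,
        "call_fold": config.call_fold,
        "quantile": config.quantile,
        "floor_epsilon": config.floor_epsilon,
        "n_probes": int(len(experiment.feature_ids)),
    }

    n_times = len(experiment.times)
    h = _norm.floor_intensities(experiment.oncogene, config.floor_epsilon)
    a = _norm.floor_intensities(experiment.parental, config.floor_epsilon)

    if config.quantile:
        if config.separate_lines:
            h = _norm.quantile_normalize(h)
            a = _norm.quantile_normalize(a)
        else:
            joint = pd.concat(
                [h.add_prefix("H@"), a.add_prefix("A@")], axis=1
            )
            joint = _norm.quantile_normalize(joint)
            h = joint.iloc[:, :n_times].set_axis(experiment.times, axis=1)
            a = joint.iloc[:, n_times:].set_axis(experiment.times, axis=1)

    if experiment.annotation is not None:
        h = _norm.collapse_probes(h, experiment.annotation)
        a = _norm.collapse_probes(a, experiment.annotation)
        a = a.loc[h.index]
    report["n_genes"] = int(len(h.index))

    normalized = TimeSeriesExperiment(
        times=experiment.times, parental=a, oncogene=h
    )
    kept = prefilter_dynamic(normalized, config)
    report["n_prefiltered"] = len(kept)
    kept_set = set(kept)

    trajectories: dict[str, DifferentialTrajectory] = {}
    display: dict[str, pd.DataFrame] = {}
    calls: list[GeneCall] = []
    for gene in h.index:
        if gene in kept_set:
            traj = differential_trajectory(
                h.loc[gene].to_numpy(), a.loc[gene].to_numpy(), experiment.times, gene
            )
            trajectories[gene] = traj
            call = call_differential(traj, config)
            calls.append(
                GeneCall(
                    gene=call.gene, klass=call.klass, max_abs_r=call.max_abs_r,
                    time_of_extreme=call.time_of_extreme, direction=call.direction,
                    passed_prefilter=True,
                )
            )
            if call.klass != NOT_DIFFERENTIAL:
                display[gene] = pd.DataFrame(
                    {
                        "time_hours": experiment.times,
                        "oncogene": _norm.log2_mean_center(h.loc[gene].to_numpy()),
                        "parental": _norm.log2_mean_center(a.loc[gene].to_numpy()),
                    }
                )
        else:
            calls.append(
                GeneCall(
                    gene=gene, klass=NOT_DIFFERENTIAL, max_abs_r=0.0,
                    time_of_extreme=0.0, direction="none", passed_prefilter=False,
                )
            )
    call_set = GeneCallSet(calls)
    report["n_called"] = len(call_set.differential())
    report["counts"] = call_set.counts()
    return call_set, trajectories, display, report
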