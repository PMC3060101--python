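"""Synthetic inhibitor-chase experiment generator with known ground truth.

The generative model: gene g in line L has steady-state (pre-inhibition)
expression B_g * F_gL, where F_gL is the multiplicative oncogene-driven effect
(F=1: not regulated in that line; F<1: repressed).  After the kinase is
inhibited at t=0, log-expression relaxes exponentially toward the baseline:

    mu_gL(t) = B_g * F_gL ** exp(-t / tau_g)

so mu(0) = B*F and mu(t -> inf) = B.  Observed intensity is mu * exp(eps)
with eps ~ Normal(0, sigma^2), drawn independently per gene/line/time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dyndiff.errors import ConfigurationError, ValidationError
from dyndiff.io import (
    ONCOGENE,
    PARENTAL,
    SampleSheet,
    TimeSeriesExperiment,
)

LABEL_ONCOGENE_UP = "oncogene_up"
LABEL_ONCOGENE_DOWN = "oncogene_down"
LABEL_SHARED = "shared"
LABEL_UNREGULATED = "unregulated"

TRUTH_COLUMNS = [
    "gene", "label", "baseline", "fold_oncogene", "fold_parental",
    "tau_hours", "sigma",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 2000
    n_timepoints: int = 16
    dt_hours: float = 3.0
    frac_oncogene_specific: float = 0.05
    frac_shared_regulated: float = 0.0
    frac_oncogene_down: float = 0.0  # fraction of oncogene-specific genes repressed
    fold_effect_range: tuple[float, float] = (3.0, 5.0)
    tau_range_hours: tuple[float, float] = (5.0, 15.0)
    noise_sigma: float = 0.1
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if self.dt_hours <= 0:
            raise ConfigurationError("dt_hours must be > 0")
        for name in ("frac_oncogene_specific", "frac_shared_regulated", "frac_oncogene_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_oncogene_specific + self.frac_shared_regulated > 1.0:
            raise ConfigurationError(
                "frac_oncogene_specific + frac_shared_regulated must not exceed 1"
            )
        lo, hi = self.fold_effect_range
        if not (lo > 1.0 and hi >= lo):
            raise ConfigurationError("fold_effect_range bounds must be > 1 and ordered")
        lo, hi = self.tau_range_hours
        if not (lo > 0 and hi >= lo):
            raise ConfigurationError("tau_range_hours bounds must be > 0 and ordered")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.probes_per_gene < 1:
            raise ConfigurationError("probes_per_gene must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=float) * self.dt_hours


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene generative parameters and true class labels."""

    table: pd.DataFrame  # columns TRUTH_COLUMNS, indexed by gene

    def __post_init__(self) -> None:
        missing = set(TRUTH_COLUMNS) - {"gene"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"truth table missing columns: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def labels(self) -> pd.Series:
        return self.table["label"]

    def write(self, path: str | Path) -> None:
        self.table.reset_index(names="gene").to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        table = pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
        return cls(table)


def _class_counts(config: SyntheticConfig) -> tuple[int, int, int, int]:
    n_specific = int(round(config.n_genes * config.frac_oncogene_specific))
    n_shared = int(round(config.n_genes * config.frac_shared_regulated))
    n_down = int(round(n_specific * config.frac_oncogene_down))
    n_up = n_specific - n_down
    n_unreg = config.n_genes - n_specific - n_shared
    return n_up, n_down, n_shared, n_unreg


def simulate_experiment(
    config: SyntheticConfig,
) -> tuple[TimeSeriesExperiment, SyntheticTruth]:
    """Draw a two-line inhibitor-chase experiment; fully reproducible from seed.

    Returns the experiment (with probe annotation when ``probes_per_gene`` > 1)
    and the generating truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    times = config.times

    n_up, n_down, n_shared, n_unreg = _class_counts(config)
    labels = np.array(
        [LABEL_ONCOGENE_UP] * n_up
        + [LABEL_ONCOGENE_DOWN] * n_down
        + [LABEL_SHARED] * n_shared
        + [LABEL_UNREGULATED] * n_unreg
    )
    rng.shuffle(labels)

    genes = np.array([f"G{i:06d}" for i in range(1, n + 1)])
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    lo, hi = config.fold_effect_range
    fold = rng.uniform(lo, hi, size=n)
    tau = rng.uniform(*config.tau_range_hours, size=n)

    fold_h = np.ones(n)
    fold_a = np.ones(n)
    is_up = labels == LABEL_ONCOGENE_UP
    is_down = labels == LABEL_ONCOGENE_DOWN
    is_shared = labels == LABEL_SHARED
    fold_h[is_up] = fold[is_up]
    fold_h[is_down] = 1.0 / fold[is_down]
    fold_h[is_shared] = fold[is_shared]
    fold_a[is_shared] = fold[is_shared]

    decay = np.exp(-times[None, :] / tau[:, None])  # (genes, times)
    matrices: dict[str, pd.DataFrame] = {}
    for line, f_line in ((ONCOGENE, fold_h), (PARENTAL, fold_a)):
        mu = baseline[:, None] * np.power(f_line[:, None], decay)
        eps = rng.normal(0.0, config.noise_sigma, size=mu.shape)
        matrices[line] = pd.DataFrame(
            mu * np.exp(eps), index=pd.Index(genes, name="probe_id"), columns=times
        )

    annotation = None
    if config.probes_per_gene > 1:
        k = config.probes_per_gene
        probe_ids, probe_genes, blocks = [], [], {ONCOGENE: [], PARENTAL: []}
        for j in range(1, k + 1):
            # per-probe multiplicative offset so probe means differ within a gene
            offset = np.exp(rng.normal(0.0, 0.25, size=n))
            for line in (ONCOGENE, PARENTAL):
                blocks[line].append(matrices[line].to_numpy() * offset[:, None])
            probe_ids.extend(f"{g}_p{j}" for g in genes)
            probe_genes.extend(genes)
        order = np.argsort(probe_ids, kind="mergesort")
        for line in (ONCOGENE, PARENTAL):
            stacked = np.vstack(blocks[line])[order]
            matrices[line] = pd.DataFrame(
                stacked,
                index=pd.Index(np.array(probe_ids)[order], name="probe_id"),
                columns=times,
            )
        annotation = pd.Series(
            np.array(probe_genes)[order], index=np.array(probe_ids)[order], name="gene"
        )

    experiment = TimeSeriesExperiment(
        times=times,
        parental=matrices[PARENTAL],
        oncogene=matrices[ONCOGENE],
        annotation=annotation,
    )
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "label": labels,
                "baseline": baseline,
                "fold_oncogene": fold_h,
                "fold_parental": fold_a,
                "tau_hours": tau,
                "sigma": config.noise_sigma,
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    return experiment, truth


def experiment_to_tables(
    experiment: TimeSeriesExperiment,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Flatten an experiment into the matrix + sample-sheet format the ingest
    module reads (sample ids ``A_t<hh>`` / ``H_t<hh>``)."""
    def sample_id(prefix: str, t: float) -> str:
        return f"{prefix}_t{t:05.1f}".replace(".", "_")

    cols, rows = {}, []
    for prefix, line, m in (
        ("A", PARENTAL, experiment.parental),
        ("H", ONCOGENE, experiment.oncogene),
    ):
        for t in experiment.times:
            sid = sample_id(prefix, t)
            cols[sid] = m[t].to_numpy()
            rows.append({"sample_id": sid, "cell_line": line, "time_hours": t})
    matrix = pd.DataFrame(cols, index=experiment.parental.index)
    return matrix, SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(calls, truth: SyntheticTruth) -> dict:
    """Confusion-matrix-derived recovery rates of a call set against truth.

    For each called class (``oncogene_up``, ``oncogene_down``) reports
    sensitivity TP/(TP+FN), specificity TN/(TN+FP) and the false-discovery
    proportion FP/(TP+FP) (0 when nothing is called).  Truth labels ``shared``
    and ``unregulated`` map to expected call ``not_differential``.
    """
    call_classes = calls.classes()
    truth_labels = truth.labels()
    if set(call_classes.index) != set(truth_labels.index):
        raise ValidationError("call set and truth cover different gene universes")
    call_classes = call_classes.loc[truth_labels.index]

    report: dict = {"n_genes": int(len(truth_labels))}
    for klass in (LABEL_ONCOGENE_UP, LABEL_ONCOGENE_DOWN):
        truth_pos = truth_labels == klass
        called_pos = call_classes == klass
        tp = int((truth_pos & called_pos).sum())
        fp = int((~truth_pos & called_pos).sum())
        fn = int((truth_pos & ~called_pos).sum())
        tn = int((~truth_pos & ~called_pos).sum())
        report[klass] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            # None (not NaN) when undefined, to keep reports deterministic
            # under equality and JSON-serializable
            "sensitivity": tp / (tp + fn) if (tp + fn) else None,
            "specificity": tn / (tn + fp) if (tn + fp) else None,
            "false_discovery_proportion": fp / (tp + fp) if (tp + fp) else 0.0,
        }
    return report
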