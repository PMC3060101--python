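import numpy as np
import pandas as pd
import pytest

from dyndiff.io import SampleSheet, TimeSeriesExperiment


@pytest.fixture
def grid16():
    return np.arange(16, dtype=float) * 3.0


def make_experiment(parental, oncogene, times, gene_ids=None, annotation=None):
    """Build a TimeSeriesExperiment from raw per-line arrays."""
    parental = np.atleast_2d(np.asarray(parental, dtype=float))
    oncogene = np.atleast_2d(np.asarray(oncogene, dtype=float))
    times = np.asarray(times, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(parental.shape[0])]
    idx = pd.Index(gene_ids, name="probe_id")
    return TimeSeriesExperiment(
        times=times,
        parental=pd.DataFrame(parental, index=idx, columns=times),
        oncogene=pd.DataFrame(oncogene, index=idx, columns=times),
        annotation=annotation,
    )


def make_sheet(samples):
    """samples: iterable of (sample_id, cell_line, time_hours)."""
    return SampleSheet(
        pd.DataFrame(samples, columns=["sample_id", "cell_line", "time_hours"])
    )


@pytest.fixture
def tiny_matrix():
    return pd.DataFrame(
        [[2.0, 5.0], [4.0, 1.0], [6.0, 3.0]],
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=["s1", "s2"],
    )
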