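import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dyndiff.dynamics import (
    NOT_DIFFERENTIAL,
    ONCOGENE_DOWN,
    ONCOGENE_UP,
    PipelineConfig,
    call_differential,
    differential_trajectory,
    prefilter_dynamic,
    run_pipeline,
    series_fold_change,
    timepoint_fold_change,
)
from dyndiff.errors import ValidationError
from dyndiff.simulate import SyntheticConfig, simulate_experiment

from conftest import make_experiment

positive_series = arrays(np.float64, 6, elements=st.floats(0.1, 1e4))


class TestTimepointFoldChange:
    def test_constant_series(self):
        np.testing.assert_allclose(timepoint_fold_change(np.full(5, 3.0)), np.ones(5))

    def test_doubling(self):
        folds = timepoint_fold_change(np.array([10.0, 20.0]))
        np.testing.assert_allclose(folds, [1.0, 2.0])

    def test_halving_symmetric(self):
        folds = timepoint_fold_change(np.array([10.0, 5.0]))
        np.testing.assert_allclose(folds, [1.0, 2.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            timepoint_fold_change(np.array([1.0, 0.0]))

    @settings(max_examples=50, deadline=None)
    @given(positive_series)
    def test_folds_at_least_one_and_anchor(self, x):
        folds = timepoint_fold_change(x)
        assert folds[0] == 1.0
        assert (folds >= 1.0).all()


class TestSeriesFoldChange:
    def test_both_definitions(self):
        out = series_fold_change(np.array([4.0, 8.0, 2.0]))
        assert out["extreme_vs_t0"] == pytest.approx(2.0)
        assert out["max_vs_min"] == pytest.approx(4.0)


class TestDifferentialTrajectory:
    def test_r0_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        t = np.arange(5, dtype=float)
        tr = differential_trajectory(rng.uniform(1, 9, 5), rng.uniform(1, 9, 5), t)
        assert tr.r[0] == 0.0

    def test_equal_lines_give_zero(self):
        t = np.arange(4, dtype=float)
        x = np.array([2.0, 3.0, 5.0, 7.0])
        np.testing.assert_allclose(differential_trajectory(x, x, t).r, 0.0)

    def test_doubled_h_gives_ln2(self):
        t = np.array([0.0, 3.0])
        tr = differential_trajectory(np.array([5.0, 10.0]), np.array([4.0, 4.0]), t)
        assert tr.r[1] == pytest.approx(np.log(2.0), rel=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(ValidationError):
            differential_trajectory(np.ones(3), np.ones(4), np.arange(3.0))

    def test_nonpositive_intensity(self):
        with pytest.raises(ValidationError):
            differential_trajectory(np.array([1.0, -1.0]), np.ones(2), np.arange(2.0))

    @settings(max_examples=50, deadline=None)
    @given(positive_series, positive_series)
    def test_antisymmetry_under_line_swap(self, h, a):
        t = np.arange(6, dtype=float)
        fwd = differential_trajectory(h, a, t)
        rev = differential_trajectory(a, h, t)
        np.testing.assert_allclose(fwd.r, -rev.r, atol=1e-9)


class TestCallDifferential:
    def traj(self, r, times=None):
        from dyndiff.dynamics import DifferentialTrajectory

        r = np.asarray(r, dtype=float)
        t = np.arange(len(r), dtype=float) * 3.0 if times is None else times
        return DifferentialTrajectory(gene="g", times=t, r=r)

    def test_exact_twofold_boundary_is_called(self):
        call = call_differential(self.traj([0.0, np.log(2.0)]), PipelineConfig())
        assert call.klass == ONCOGENE_DOWN

    def test_zero_trajectory_not_differential(self):
        call = call_differential(self.traj([0.0, 0.0, 0.0]), PipelineConfig())
        assert call.klass == NOT_DIFFERENTIAL

    def test_ratio_falling_to_quarter_is_oncogene_up(self):
        # normalized ratio 0.25 at the last point -> r = ln(0.25) < -ln 2
        r = np.zeros(16)
        r[-1] = np.log(0.25)
        call = call_differential(self.traj(r), PipelineConfig())
        assert call.klass == ONCOGENE_UP
        assert call.direction == "down"
        assert call.time_of_extreme == 45.0
        assert call.max_abs_r == pytest.approx(np.log(4.0))

    def test_call_swaps_class_when_trajectory_negated(self):
        r = np.array([0.0, 0.3, 1.1, 0.4])
        up = call_differential(self.traj(-r), PipelineConfig())
        down = call_differential(self.traj(r), PipelineConfig())
        assert up.klass == ONCOGENE_UP and down.klass == ONCOGENE_DOWN
        assert up.max_abs_r == down.max_abs_r

    def test_threshold_monotonicity(self):
        r = np.array([0.0, 0.5, 0.8])
        called = {
            fold: call_differential(self.traj(r), PipelineConfig(call_fold=fold)).klass
            for fold in (1.2, 1.6, 2.0, 2.4)
        }
        was_called = [k != NOT_DIFFERENTIAL for k in called.values()]
        # once a threshold stops the call, no higher threshold re-adds it
        assert was_called == sorted(was_called, reverse=True)


class TestPrefilter:
    def test_exact_boundary_retained(self):
        exp = make_experiment(
            parental=[[1.0, 1.0]], oncogene=[[10.0, 17.0]], times=[0.0, 3.0]
        )
        assert prefilter_dynamic(exp, PipelineConfig()) == ["g0"]

    def test_constant_gene_excluded(self):
        exp = make_experiment(
            parental=[[1.0, 1.0]], oncogene=[[10.0, 10.0]], times=[0.0, 3.0]
        )
        assert prefilter_dynamic(exp, PipelineConfig()) == []

    def test_prefilter_uses_oncogene_line_only(self):
        exp = make_experiment(
            parental=[[1.0, 99.0]], oncogene=[[10.0, 10.0]], times=[0.0, 3.0]
        )
        assert prefilter_dynamic(exp, PipelineConfig()) == []

    def test_cap_and_ranking_match_brute_force(self):
        rng = np.random.default_rng(7)
        n = 300
        h0 = rng.uniform(10, 100, n)
        folds = rng.uniform(1.0, 6.0, n)
        h = np.column_stack([h0, h0 * folds, h0])
        a = np.tile(rng.uniform(10, 100, n)[:, None], (1, 3))
        genes = [f"g{i:03d}" for i in range(n)]
        exp = make_experiment(a, h, [0.0, 3.0, 6.0], gene_ids=genes)
        cap = 100
        got = prefilter_dynamic(exp, PipelineConfig(prefilter_fold=1.7, prefilter_cap=cap))
        # brute force: symmetric max fold per gene, threshold, sort, truncate
        max_fold = {}
        for i, g in enumerate(genes):
            f = max(max(h[i, j] / h[i, 0], h[i, 0] / h[i, j]) for j in (1, 2))
            if f >= 1.7 * (1 - 1e-9):
                max_fold[g] = f
        expected = sorted(max_fold, key=lambda g: (-max_fold[g], g))[:cap]
        assert got == expected
        assert len(got) == cap

    def test_raising_threshold_never_adds_genes(self):
        exp, _ = simulate_experiment(SyntheticConfig(n_genes=200, noise_sigma=0.3, seed=3))
        previous = None
        for fold in (1.2, 1.5, 1.7, 2.0, 3.0):
            kept = set(prefilter_dynamic(exp, PipelineConfig(prefilter_fold=fold)))
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestRunPipeline:
    def test_no_effect_limit_zero_calls(self):
        config = SyntheticConfig(
            n_genes=40, frac_oncogene_specific=0.0, noise_sigma=0.0, seed=0
        )
        exp, _ = simulate_experiment(config)
        calls, trajectories, display, report = run_pipeline(exp)
        assert report["n_called"] == 0
        assert display == {}

    def test_strong_gene_called_oncogene_up(self):
        # one gene with fold 4, tau 5 h: relaxes to ~0.25 of its start
        times = np.arange(16, dtype=float) * 3.0
        h = 100.0 * 4.0 ** np.exp(-times / 5.0)
        a = np.full(16, 100.0)
        flat = np.full(16, 50.0)
        exp = make_experiment(
            parental=np.vstack([a, flat]), oncogene=np.vstack([h, flat]),
            times=times, gene_ids=["hit", "null"],
        )
        calls, _, display, _ = run_pipeline(exp, PipelineConfig(quantile=False))
        assert calls["hit"].klass == ONCOGENE_UP
        assert calls["null"].klass == NOT_DIFFERENTIAL
        assert "hit" in display
        # display series are log2 mean-centered: rows sum to 0
        assert abs(display["hit"]["oncogene"].sum()) < 1e-9

    def test_scale_invariance_of_calls(self):
        # quantile normalization restores a rescaled array's distribution, so
        # calls are unchanged provided no gene sits on the decision boundary
        # (the common reference shifts slightly with the rescaled column)
        config = SyntheticConfig(
            n_genes=150, frac_oncogene_specific=0.1, fold_effect_range=(4.0, 6.0),
            tau_range_hours=(5.0, 10.0), noise_sigma=0.05, seed=6,
        )
        exp, _ = simulate_experiment(config)
        calls, _, _, _ = run_pipeline(exp)
        margins = np.array(
            [abs(c.max_abs_r - np.log(2.0)) for c in calls if c.passed_prefilter]
        )
        assert margins.min() > 0.1  # guard: nothing near the call boundary
        scaled_onco = exp.oncogene.copy()
        scaled_onco[exp.times[4]] *= 5.0  # rescale one array
        exp2 = exp.with_matrices(exp.parental, scaled_onco)
        calls2, _, _, _ = run_pipeline(exp2)
        pd.testing.assert_series_equal(calls.classes(), calls2.classes())

    def test_stage_counts_match_independent_oracle(self):
        config = SyntheticConfig(
            n_genes=2000, frac_oncogene_specific=0.05, noise_sigma=0.1, seed=1
        )
        exp, _ = simulate_experiment(config)
        calls, _, _, report = run_pipeline(exp)

        # independently scripted five-step re-implementation
        h = exp.oncogene.clip(lower=1.0)
        a = exp.parental.clip(lower=1.0)
        joint = np.hstack([h.to_numpy(), a.to_numpy()])
        ref = np.sort(joint, axis=0).mean(axis=1)
        qn = np.empty_like(joint)
        for j in range(joint.shape[1]):
            order = np.argsort(joint[:, j], kind="stable")
            qn[order, j] = ref
        hq, aq = qn[:, :16], qn[:, 16:]
        n_pre = n_called_up = n_called_down = 0
        for i in range(len(exp.feature_ids)):
            f = np.maximum(hq[i] / hq[i][0], hq[i][0] / hq[i])
            if f[1:].max() >= 1.7 * (1 - 1e-9):
                n_pre += 1
                r = np.log(hq[i] / aq[i]) - np.log(hq[i][0] / aq[i][0])
                ext = r[np.argmax(np.abs(r))]
                if abs(ext) >= np.log(2.0) * (1 - 1e-9):
                    if ext < 0:
                        n_called_up += 1
                    else:
                        n_called_down += 1
        assert report["n_prefiltered"] == n_pre
        counts = calls.counts()
        assert counts[ONCOGENE_UP] == n_called_up
        assert counts[ONCOGENE_DOWN] == n_called_down

    def test_probe_collapse_path(self):
        config = SyntheticConfig(
            n_genes=60, frac_oncogene_specific=0.1, noise_sigma=0.05,
            probes_per_gene=3, seed=5,
        )
        exp, truth = simulate_experiment(config)
        assert len(exp.feature_ids) == 180
        calls, _, _, report = run_pipeline(exp)
        assert report["n_probes"] == 180
        assert report["n_genes"] == 60
        assert set(calls.genes) == set(truth.genes)
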