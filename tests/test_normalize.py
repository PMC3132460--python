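import numpy as np
import pandas as pd
import pytest

from subtelcnv.normalize import (
    BatchEffectRemover,
    GCBiasCorrector,
    gc_correct,
    median_center,
    remove_batch_pca,
)
from subtelcnv.pipeline import candidate_territory
from subtelcnv.simulate import (
    IntensityMatrix,
    SimulationConfig,
    copy_number_at_probes,
)


def _matrix_from_array(values, prefix="s"):
    n = values.shape[1]
    ids = [f"{prefix}{j}" for j in range(n)]
    frame = pd.DataFrame(values, columns=ids)
    frame.index.name = "probe_id"
    samples = pd.DataFrame(
        {"sample_id": ids, "status": ["control"] * n, "batch": [0] * n}
    )
    return IntensityMatrix(frame, samples)


class TestMedianCenter:
    def test_worked_columns(self):
        m = _matrix_from_array(
            np.array([[-1.0, 1.0], [0.0, 2.0], [3.0, 3.0]])
        )
        out = median_center(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 3.0])
        np.testing.assert_allclose(out[:, 1], [-1.0, 0.0, 1.0])

    def test_constant_column_becomes_zero_and_idempotent(self):
        m = _matrix_from_array(np.full((5, 1), 7.5))
        once = median_center(m)
        assert np.all(once.values.to_numpy() == 0.0)
        twice = median_center(once)
        np.testing.assert_array_equal(
            once.values.to_numpy(), twice.values.to_numpy()
        )


class TestGCCorrection:
    def test_exact_linear_signal_removed(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.7, 500)
        X = np.outer(2.0 * (gc - gc.mean()), np.ones(4))
        corrector = GCBiasCorrector(gc=gc).fit(X)
        assert np.abs(corrector.transform(X)).max() < 1e-9

    def test_gc_independent_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.3, 0.7, 2_000)
        X = rng.normal(0, 0.2, (2_000, 3))
        corrector = GCBiasCorrector(gc=gc).fit(X)
        resid = corrector.transform(X)
        # fitted slope is O(1/sqrt(n)): matrix essentially unchanged
        assert np.abs(resid - X).max() < 0.05

    def test_simulated_gc_bias_removed(self, default_study):
        matrix = median_center(default_study.matrix)
        corrected, _ = gc_correct(matrix, default_study.design)
        gc = default_study.design.gc
        X = corrected.values.to_numpy()
        # check non-carrier samples: no residual GC correlation
        for t in default_study.truths[:20]:
            if t.carrier:
                continue
            j = list(corrected.values.columns).index(t.sample_id)
            r = np.corrcoef(X[:, j], gc)[0, 1]
            assert abs(r) < 0.05

    def test_linear_correction_is_idempotent(self, default_study):
        matrix = median_center(default_study.matrix)
        once, _ = gc_correct(matrix, default_study.design)
        twice, _ = gc_correct(once, default_study.design)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9
        )

    def test_loess_removes_nonlinear_gc_trend(self):
        rng = np.random.default_rng(6)
        gc = np.sort(rng.uniform(0.3, 0.7, 1_500))
        trend = np.sin(8.0 * gc)  # nonlinear in gc
        X = trend[:, None] + rng.normal(0, 0.05, (1_500, 2))
        corrector = GCBiasCorrector(gc=gc, method="loess").fit(X)
        resid = corrector.transform(X)
        # most of the nonlinear trend's variance is gone
        assert resid.var() < 0.25 * X.var()
        for j in range(2):
            assert abs(np.corrcoef(resid[:, j], gc)[0, 1]) < 0.1

    def test_constant_gc_skips_with_warning(self):
        X = np.random.default_rng(2).normal(size=(50, 2))
        m = _matrix_from_array(X)

        class FlatDesign:
            gc = np.full(50, 0.5)

            def __len__(self):
                return 50

        out, report = gc_correct(m, FlatDesign())
        assert report.warnings
        np.testing.assert_array_equal(out.values.to_numpy(), X)


class TestBatchRemoval:
    def test_k_zero_is_identity_with_warning(self):
        X = np.random.default_rng(3).normal(size=(40, 6))
        m = _matrix_from_array(X)
        out, report = remove_batch_pca(m, k=0)
        np.testing.assert_array_equal(out.values.to_numpy(), X)
        assert report.warnings and report.n_components_removed == 0

    def test_rank_one_artifact_removed_exactly(self):
        rng = np.random.default_rng(4)
        artifact = np.outer(rng.normal(size=300), rng.normal(size=8))
        remover = BatchEffectRemover(n_components=1).fit(artifact)
        resid = remover.transform(artifact)
        assert (
            np.linalg.norm(resid) < 1e-6 * np.linalg.norm(artifact)
        )

    def test_variance_fractions_non_increasing(self):
        X = np.random.default_rng(5).normal(size=(200, 10))
        remover = BatchEffectRemover(n_components=3).fit(X)
        fr = remover.variance_explained_
        assert all(a >= b for a, b in zip(fr, fr[1:]))
        assert all(0 <= f <= 1 for f in fr)

    def test_k_must_be_below_sample_count(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            BatchEffectRemover(n_components=3).fit(X)

    def test_dimensions_and_order_preserved(self, default_study):
        matrix = median_center(default_study.matrix)
        out, _ = remove_batch_pca(matrix, k=2)
        assert out.values.shape == matrix.values.shape
        assert list(out.values.index) == list(matrix.values.index)
        assert list(out.values.columns) == list(matrix.values.columns)

    def test_batch_shrunk_signal_preserved(self, region):
        """Removing k=2 PCs (CNV territory excluded from estimation)
        shrinks a known two-batch rank-1 artifact by >= 90% while the
        carrier-vs-noncarrier shift at the locus moves by < 10%."""
        from subtelcnv.pipeline import simulate_study

        config = SimulationConfig(batch_effect_sd=0.0, seed=8)
        study = simulate_study(config, region)
        territory = candidate_territory(study)

        # inject a known rank-1 batch artifact on top of the simulation
        rng = np.random.default_rng(8)
        probe_factor = rng.normal(size=study.matrix.n_probes)
        all_truths = study.truths + study.panel_truths
        loading = np.where(
            np.array([t.batch for t in all_truths]) == 0, 0.15, -0.15
        )
        dirty = study.matrix.copy_with_values(
            study.matrix.values.to_numpy() + np.outer(probe_factor, loading)
        )
        matrix = median_center(
            dirty, design=study.design, exclude_intervals=[territory]
        )
        out, _ = remove_batch_pca(
            matrix, k=2, exclude_intervals=[territory], design=study.design
        )

        batches = np.array([t.batch for t in all_truths])
        unit = probe_factor / np.linalg.norm(probe_factor)

        def batch_amplitude(m):
            X = m.values.to_numpy()
            diff = X[:, batches == 0].mean(axis=1) - X[:, batches == 1].mean(axis=1)
            return abs(diff @ unit)

        assert batch_amplitude(out) <= 0.1 * batch_amplitude(matrix)

        def carrier_shift(m):
            X = m.values.to_numpy()
            shifts = []
            for j, t in enumerate(study.truths):
                if not t.carrier:
                    continue
                inside = copy_number_at_probes(study.design, t) == 1
                shifts.append(X[inside, j].mean() - X[~inside, j].mean())
            return np.mean(shifts)

        before, after = carrier_shift(matrix), carrier_shift(out)
        assert abs(after - before) < 0.1 * abs(before)
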