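import numpy as np
import pandas as pd
import pytest

from subtelcnv.acgh import (
    SmoothedTrack,
    build_envelope,
    classify_probes,
    loss_hull,
    moving_average,
    segment_calls,
    validate_samples,
)
from subtelcnv.region import build_region_model
from subtelcnv.simulate import (
    ArrayDesign,
    IntensityMatrix,
    SimulationConfig,
    copy_number_at_probes,
    simulate_log2_matrix,
)
from subtelcnv.pipeline import run_validation_study, evaluate_verdicts


def _track(values, sample_id="s0", window=1):
    return SmoothedTrack(sample_id, np.asarray(values, dtype=float), window)


class TestMovingAverage:
    def test_constant_track_is_unchanged(self):
        np.testing.assert_array_equal(
            moving_average(np.full(9, 3.25), 5), np.full(9, 3.25)
        )

    def test_window_one_is_identity(self):
        x = np.array([0.0, -1.0, 2.0, 0.5])
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_worked_example_with_truncation(self):
        x = np.array([0.0, 0.0, -1.0, -1.0, -1.0, 0.0, 0.0])
        out = moving_average(x, 3)
        assert out[3] == pytest.approx(-1.0)
        assert out[2] == pytest.approx(-2.0 / 3.0)
        assert out[0] == pytest.approx(0.0)  # truncated to two values

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average(np.zeros(10), 4)


class TestEnvelope:
    def test_identical_panel_gives_zero_sd(self):
        tracks = [_track([0.2, -0.1, 0.0], sample_id=f"n{i}") for i in range(4)]
        env = build_envelope(tracks)
        np.testing.assert_array_equal(env.sd, np.zeros(3))
        np.testing.assert_array_equal(env.median, [0.2, -0.1, 0.0])
        np.testing.assert_array_equal(env.mean, [0.2, -0.1, 0.0])

    def test_two_sample_sd_closed_form(self):
        env = build_envelope([_track([0.1]), _track([-0.1], sample_id="s1")])
        assert env.median[0] == pytest.approx(0.0)
        assert env.sd[0] == pytest.approx(0.1 * np.sqrt(2.0))

    def test_sd_estimator_tracks_population_sd(self):
        # Monte-Carlo oracle: mean of 15-sample SD estimates stays within
        # 5% of the generating sigma (the n-1 estimator's small-sample
        # bias, factor c4(15) ~ 0.983, sits inside that band)
        rng = np.random.default_rng(12)
        draws = rng.normal(0.0, 0.25, size=(1_000, 15))
        sds = draws.std(axis=1, ddof=1)
        assert abs(sds.mean() - 0.25) < 0.05 * 0.25

    def test_single_sample_panel_rejected(self):
        with pytest.raises(ValueError):
            build_envelope([_track([0.0])])


class TestClassification:
    def test_threshold_rule_and_strict_boundary(self):
        env = build_envelope(
            [_track([0.1, 0.1, 0.1]), _track([-0.1, -0.1, -0.1], "s1")]
        )  # median 0, sd ~0.1414
        sd = env.sd[0]
        track = _track([-0.25, -0.05, -sd])
        classes = classify_probes(track, env)
        assert list(classes) == ["loss", "unchanged", "unchanged"]

    def test_zero_sd_never_calls_boundary_values(self):
        env = build_envelope([_track([0.0, 0.0]), _track([0.0, 0.0], "s1")])
        classes = classify_probes(_track([0.0, -0.01]), env)
        assert list(classes) == ["unchanged", "loss"]


class TestSegmentation:
    @pytest.fixture()
    def small_region(self):
        return build_region_model(
            region_start=0,
            region_end=10_000,
            gap=(4_000, 5_000),
            lcr_masks=((6_000, 6_500),),
        )

    @pytest.fixture()
    def small_design(self, small_region):
        from subtelcnv.simulate import build_array_design

        return build_array_design(
            small_region, "tiling", spacing_bp=100, probe_length=60, seed=0
        )

    def test_null_calls_partition_region(self, small_region, small_design):
        classes = np.array(["unchanged"] * len(small_design), dtype=object)
        segs = segment_calls(classes, small_design, small_region, min_run=3)
        segs = sorted(segs, key=lambda s: s.start)
        assert segs[0].start == 0 and segs[-1].end == 10_000
        for prev, nxt in zip(segs, segs[1:]):
            assert prev.end == nxt.start
        assert sum(s.span_bp for s in segs) == 10_000
        no_calls = {(s.start, s.end) for s in segs if s.cls == "no_call"}
        assert no_calls == {(4_000, 5_000), (6_000, 6_500)}
        assert not [s for s in segs if s.cls == "loss"]

    def test_min_run_boundary(self, small_region, small_design):
        classes = np.array(["unchanged"] * len(small_design), dtype=object)
        classes[10:13] = "loss"  # exactly min_run probes
        segs = segment_calls(classes, small_design, small_region, min_run=3)
        losses = [s for s in segs if s.cls == "loss"]
        assert len(losses) == 1 and losses[0].n_probes == 3
        # one probe fewer is demoted
        classes[12] = "unchanged"
        segs = segment_calls(classes, small_design, small_region, min_run=3)
        assert not [s for s in segs if s.cls == "loss"]

    def test_partition_holds_for_arbitrary_classes(
        self, small_region, small_design
    ):
        rng = np.random.default_rng(0)
        classes = np.where(
            rng.random(len(small_design)) < 0.3, "loss", "unchanged"
        ).astype(object)
        segs = segment_calls(classes, small_design, small_region, min_run=2)
        segs = sorted(segs, key=lambda s: s.start)
        assert segs[0].start == small_region.region_start
        assert segs[-1].end == small_region.region_end
        assert all(a.end == b.start for a, b in zip(segs, segs[1:]))

    def test_hull_extends_through_abutting_no_call(
        self, small_region, small_design
    ):
        classes = np.array(["unchanged"] * len(small_design), dtype=object)
        # loss run ending right at the gap boundary
        mids = small_design.midpoints
        left = np.nonzero((mids >= 2_000) & (mids < 4_000))[0]
        classes[left] = "loss"
        segs = segment_calls(classes, small_design, small_region, min_run=3)
        hull = loss_hull(segs)
        assert hull[1] == 5_000  # extended through the gap
        assert loss_hull(segs, extend_through_no_call=False)[1] == 4_000


class TestValidation:
    def test_noise_free_verdicts_match_truth_exactly(self, noise_free_study):
        study = noise_free_study
        segs, verdicts = validate_samples(
            study.cohort_matrix(),
            study.panel_matrix(),
            study.design,
            study.region,
            window=5,
            min_run=10,
        )
        truth = {t.sample_id: t.carrier for t in study.truths}
        for _, row in verdicts.iterrows():
            assert bool(row["carrier"]) == truth[row["sample_id"]]

    def test_empty_case_set_gives_empty_verdicts(self, noise_free_study):
        study = noise_free_study
        empty = study.matrix.subset_samples([])
        segs, verdicts = validate_samples(
            empty, study.panel_matrix(), study.design, study.region
        )
        assert segs == {} and len(verdicts) == 0

    def test_self_consistency_of_normal_panel(self, default_study):
        """A panel member called against the envelope built including
        itself receives < 5% of probes in called loss segments under
        default noise (the run constraint suppresses the ~Phi(-1)
        per-probe threshold exceedances the 1-SD rule produces by
        construction)."""
        from subtelcnv.acgh import (
            build_envelope,
            classify_probes,
            smooth_matrix,
            segment_calls,
        )

        study = default_study
        panel = study.panel_matrix()
        tracks = smooth_matrix(panel, 5)
        env = build_envelope(tracks)
        n_probes = len(study.design)
        for track in tracks[:5]:
            classes = classify_probes(track, env)
            segs = segment_calls(
                classes, study.design, study.region, sample_id=track.sample_id
            )
            called_loss = sum(
                s.n_probes for s in segs if s.cls == "loss"
            )
            assert called_loss / n_probes < 0.05

    def test_deeper_deletions_never_lose_loss_probes(self, region):
        """Monotonicity: making the simulated shift more negative cannot
        reduce loss-classed probes inside the true interval."""
        from subtelcnv.acgh import build_envelope, classify_probes, smooth_matrix
        from subtelcnv.simulate import build_array_design, simulate_cohort

        design = build_array_design(region, "tiling", seed=6)
        base = dict(
            n_cases=1, n_controls=0, p_case=1.0, p_control=0.0,
            gc_slope=0.0, batch_effect_sd=0.0, seed=6,
        )
        prev_count = -1
        for response in (0.4, 0.6, 0.8, 1.0):
            config = SimulationConfig(response_factor=response, **base)
            truths = simulate_cohort(config, region)
            panel_cfg = SimulationConfig(
                n_cases=0, n_controls=15, p_case=0.0, p_control=0.0,
                gc_slope=0.0, batch_effect_sd=0.0, seed=6,
            )
            panel_truths = simulate_cohort(panel_cfg, region)
            matrix = simulate_log2_matrix(design, truths + panel_truths, config)
            case = matrix.subset_samples([truths[0].sample_id])
            panel = matrix.subset_samples(
                [t.sample_id for t in panel_truths]
            )
            env = build_envelope(smooth_matrix(panel, 5))
            track = smooth_matrix(case, 5)[0]
            classes = classify_probes(track, env)
            inside = copy_number_at_probes(design, truths[0]) == 1
            count = int(np.sum(classes[inside] == "loss"))
            assert count >= prev_count
            prev_count = count

    def test_default_noise_verdict_accuracy(self, default_study):
        segs, verdicts, _ = run_validation_study(default_study)
        scores = evaluate_verdicts(default_study.truths, verdicts, segs)
        assert scores["accuracy"] >= 0.95
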