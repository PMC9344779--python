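"""Patch classifier: architecture counting, training, grid, overlays."""

import numpy as np
import pytest

from cytodetect.patch_cnn import (PatchClassifierConfig, ProbabilityMap,
                                  build_classifier, default_table1_grid,
                                  is_overlearned, load_checkpoint,
                                  render_overlay, run_table1_grid,
                                  save_checkpoint, score_image,
                                  train_classifier)
from cytodetect.windowing import (LABEL_NON_NUCLEUS, LABEL_NUCLEUS,
                                  WindowDataset, WindowSample)


def _fast_cfg(**kw):
    kw.setdefault("epochs", 1)
    return PatchClassifierConfig(**kw)


def _const_sample(label, value, origin=(0, 0)):
    return WindowSample(patch=np.full((96, 96, 3), value, dtype=np.uint8),
                        label=label, origin=origin, source_id="t")


def _toy_dataset(n=8):
    """Trivially separable dark-vs-light patches."""
    train = [_const_sample(LABEL_NUCLEUS, 30, (i, 0)) for i in range(n)] + \
            [_const_sample(LABEL_NON_NUCLEUS, 220, (i, 1)) for i in range(n)]
    test = [_const_sample(LABEL_NUCLEUS, 35, (0, 2)),
            _const_sample(LABEL_NON_NUCLEUS, 210, (1, 2))]
    return WindowDataset(train=train, test=test, split_seed=0)


class TestArchitecture:
    @pytest.mark.parametrize("depth", [18, 24])
    def test_counted_depth(self, depth):
        clf = build_classifier(_fast_cfg(n_layers=depth))
        assert clf.depth == depth

    def test_unsupported_depth_lists_supported(self):
        with pytest.raises(ValueError, match="18"):
            build_classifier(_fast_cfg(n_layers=20))

    @pytest.mark.parametrize("activation", ["relu", "sigmoid"])
    def test_softmax_outputs_sum_to_one(self, activation):
        clf = build_classifier(_fast_cfg(activation=activation))
        rng = np.random.default_rng(0)
        patches = rng.integers(0, 256, (5, 96, 96, 3), dtype=np.uint8)
        probs = clf.predict_proba(patches)
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()


class TestTraining:
    def test_history_length_and_single_class_accuracy(self):
        """One epoch on constant-label data drives that class to accuracy 1."""
        ds = _toy_dataset()
        ds.train = [s for s in ds.train if s.label == LABEL_NUCLEUS]
        ds.test = [s for s in ds.test if s.label == LABEL_NUCLEUS]
        res = train_classifier(build_classifier(_fast_cfg(epochs=3)), ds)
        assert len(res.history) == 3
        assert res.train_accuracy == 1.0

    def test_separable_toy_data_learns(self):
        res = train_classifier(
            build_classifier(_fast_cfg(epochs=25, batch_size=8,
                                       learning_rate=0.01)),
            _toy_dataset())
        assert res.history[-1]["train_loss"] < res.history[0]["train_loss"]
        assert res.test_accuracy == 1.0

    def test_reproducible_under_seed(self):
        a = train_classifier(build_classifier(_fast_cfg(epochs=2,
                                                        learning_seed=11)),
                             _toy_dataset())
        b = train_classifier(build_classifier(_fast_cfg(epochs=2,
                                                        learning_seed=11)),
                             _toy_dataset())
        assert a.history == b.history

    def test_empty_split_errors(self):
        ds = _toy_dataset()
        ds.test = []
        with pytest.raises(ValueError):
            train_classifier(build_classifier(_fast_cfg()), ds)


class TestGrid:
    def test_default_grid_matches_documented_nine_rows(self):
        grid = default_table1_grid()
        assert len(grid) == 9
        assert [(g.activation, g.epochs, g.n_layers, g.dropout_rate)
                for g in grid] == [
            ("relu", 5, 18, 0.25), ("relu", 20, 18, 0.25),
            ("relu", 50, 18, 0.25), ("relu", 5, 24, 0.25),
            ("relu", 20, 24, 0.25), ("relu", 50, 24, 0.25),
            ("relu", 5, 18, 0.5), ("relu", 20, 18, 0.5),
            ("sigmoid", 20, 18, 0.25)]

    def test_overlearning_verdict_on_reported_gap(self):
        """A 99.8 % train / 89.1 % test pair is overlearned at gap 0.05."""
        assert is_overlearned(0.998, 0.891, 0.05)
        assert not is_overlearned(0.9562, 0.9314, 0.05)

    def test_single_config_grid_report(self):
        results, report = run_table1_grid(_toy_dataset(),
                                          [_fast_cfg(epochs=2)])
        assert len(results) == 1 and len(report) == 1
        row = report.iloc[0]
        assert set(report.columns) >= {"train_accuracy", "test_accuracy",
                                       "overlearned", "rank"}
        if not row["overlearned"]:
            assert row["rank"] == 1.0

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            run_table1_grid(_toy_dataset(), [])


class TestScoringAndOverlay:
    def test_score_image_counts_and_range(self):
        clf = build_classifier(_fast_cfg(epochs=1))
        train_classifier(clf, _toy_dataset())
        image = np.full((288, 384, 3), 220, dtype=np.uint8)
        pmap = score_image(clf, image, source_id="x")
        assert len(pmap.probs) == 3 * 4
        assert all(0 <= p <= 1 for p in pmap.probs.values())

    def test_untrained_classifier_errors(self):
        clf = build_classifier(_fast_cfg())
        with pytest.raises(RuntimeError):
            score_image(clf, np.zeros((96, 96, 3), dtype=np.uint8))

    def test_overlay_threshold_semantics(self):
        image = np.full((96, 288, 3), 100, dtype=np.uint8)
        pmap = ProbabilityMap(probs={(0, 0): 0.95, (0, 96): 0.60,
                                     (0, 192): 0.40})
        out = render_overlay(image, pmap)
        red, yellow, untouched = out[48, 48], out[48, 144], out[48, 240]
        assert red[0] > red[2] and red[1] == red[2]  # reddish tint
        assert yellow[0] == yellow[1] > yellow[2]  # yellowish tint
        assert np.array_equal(untouched, [100, 100, 100])

    def test_overlay_strict_boundaries(self):
        """p = 0.9 exactly is yellow; p = 0.5 exactly is untinted."""
        image = np.full((96, 192, 3), 100, dtype=np.uint8)
        pmap = ProbabilityMap(probs={(0, 0): 0.9, (0, 96): 0.5})
        out = render_overlay(image, pmap)
        assert out[48, 48][0] == out[48, 48][1] > out[48, 48][2]  # yellow
        assert np.array_equal(out[48, 144], [100, 100, 100])

    def test_overlay_idempotent_and_validates_thresholds(self):
        image = np.full((96, 96, 3), 90, dtype=np.uint8)
        pmap = ProbabilityMap(probs={(0, 0): 0.7})
        assert np.array_equal(render_overlay(image, pmap),
                              render_overlay(image, pmap))
        with pytest.raises(ValueError):
            render_overlay(image, pmap, red_threshold=0.4, yellow_threshold=0.5)


def test_checkpoint_roundtrip(tmp_path):
    clf = build_classifier(_fast_cfg(epochs=1, learning_seed=3))
    train_classifier(clf, _toy_dataset())
    patches = np.random.default_rng(1).integers(0, 256, (4, 96, 96, 3),
                                                dtype=np.uint8)
    save_checkpoint(clf, tmp_path / "model.npz")
    loaded = load_checkpoint(tmp_path / "model.npz")
    assert loaded.trained
    assert np.allclose(loaded.predict_proba(patches),
                       clf.predict_proba(patches))
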