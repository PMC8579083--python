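import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metrano._net import SegNet, TrainConfig
from metrano.detect import (
    MetastasisDetector3D,
    detect_lesions,
    dice_loss,
    extract_bounding_boxes,
    label_components,
)
from metrano.pipeline import OracleProbabilityModel
from metrano.volio import BoundingBox, LabelMap


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self, rng):
        t = (rng.random((10, 10, 10)) > 0.5).astype(float)
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_is_one(self, rng):
        t = (rng.random((10, 10, 10)) > 0.5).astype(float)
        assert dice_loss(1 - t, t) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_half_prediction(self):
        # p = 0.5 everywhere, half the voxels true: closed form gives 0.5
        t = np.zeros((10, 10, 10))
        t[:5] = 1.0
        assert dice_loss(np.full_like(t, 0.5), t) == pytest.approx(0.5, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded_for_binary_inputs(self, seed):
        r = np.random.default_rng(seed)
        a = (r.random((6, 6)) > 0.5).astype(float)
        b = (r.random((6, 6)) > 0.5).astype(float)
        lab = dice_loss(a, b)
        assert lab == pytest.approx(dice_loss(b, a), abs=1e-12)
        assert 0.0 <= lab <= 1.0


def _flood_fill_components(mask: np.ndarray) -> int:
    """Brute-force 26-connected component count by BFS."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    n = 0
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask & ~seen)):
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            for a, b, c in offsets:
                p = (x + a, y + b, z + c)
                if all(0 <= q < s for q, s in zip(p, mask.shape)) and mask[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    return n


class TestLabelComponents:
    def test_corner_touching_blobs_are_one_component(self):
        m = np.zeros((8, 8, 8), bool)
        m[2, 2, 2] = True
        m[3, 3, 3] = True  # touches only at a corner: joined under 26-connectivity
        labels = label_components(m)
        assert labels.max() == 1

    def test_min_voxels_removes_specks(self):
        m = np.zeros((10, 10, 10), bool)
        m[1, 1, 1] = True  # single voxel
        m[5:8, 5:8, 5:8] = True
        labels = label_components(m, min_voxels=2)
        assert labels.max() == 1
        assert labels[1, 1, 1] == 0

    def test_matches_flood_fill_on_random_grids(self):
        r = np.random.default_rng(3)
        for _ in range(40):
            m = r.random((12, 12, 12)) > r.uniform(0.6, 0.9)
            assert label_components(m).max() == _flood_fill_components(m)


class TestDetectLesions:
    def test_oracle_passthrough_reproduces_truth_components(self, rng):
        truth = np.zeros((16, 16, 16), np.float32)
        truth[2:5, 2:5, 2:5] = 1.0
        truth[10:13, 10:13, 10:13] = 1.0
        out = detect_lesions(truth, OracleProbabilityModel(truth), min_voxels=2)
        assert sorted(out.ids) == [1, 2]
        assert np.array_equal(out.mask(), truth > 0)

    def test_all_zero_probability_gives_empty_map(self):
        x = np.zeros((8, 8, 8), np.float32)
        out = detect_lesions(x, OracleProbabilityModel(x))
        assert out.ids == []

    def test_padding_invariance(self):
        # zero padding around the content must not change detections
        core = np.zeros((16, 16, 16), np.float32)
        core[5:9, 5:9, 5:9] = 1.0
        padded = np.pad(core, 8)
        small = detect_lesions(core, OracleProbabilityModel(core))
        big = detect_lesions(padded, OracleProbabilityModel(padded))
        assert big.ids == small.ids
        assert np.array_equal(big.labels[8:24, 8:24, 8:24], small.labels)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            detect_lesions(np.zeros((8, 8, 8)), OracleProbabilityModel(np.zeros((6, 6, 6))))


class TestExtractBoundingBoxes:
    def test_tight_box_per_component(self):
        m = np.zeros((20, 20, 20), np.int32)
        m[10:13, 10:13, 10:13] = 1
        boxes = extract_bounding_boxes(LabelMap(m))
        assert boxes == [BoundingBox((10, 10, 10), (13, 13, 13))]

    def test_empty_map_gives_empty_list(self):
        assert extract_bounding_boxes(np.zeros((5, 5, 5), np.int32)) == []

    def test_margin_clamped_at_edges(self):
        m = np.zeros((10, 10, 10), np.int32)
        m[0:2, 8:10, 4:6] = 1
        (box,) = extract_bounding_boxes(LabelMap(m), margin=4)
        assert box.lo == (0, 4, 0)
        assert box.hi == (6, 10, 10)

    def test_order_is_ascending_label_id(self):
        m = np.zeros((20, 20, 20), np.int32)
        m[15:17, 1:3, 1:3] = 1
        m[1:3, 1:3, 1:3] = 2
        boxes = extract_bounding_boxes(LabelMap(m))
        assert boxes[0].lo[0] == 15 and boxes[1].lo[0] == 1


class TestDetectorTraining:
    @pytest.fixture(scope="class")
    def blob_samples(self):
        """Small synthetic cubes: one bright blob on noisy background."""
        r = np.random.default_rng(5)
        samples = []
        for _ in range(6):
            x = r.normal(0.3, 0.05, size=(16, 16, 16)).astype(np.float32)
            y = np.zeros((16, 16, 16), np.float32)
            c = r.integers(4, 12, size=3)
            zz = np.stack(np.meshgrid(*[np.arange(16)] * 3, indexing="ij"), axis=-1)
            inside = ((zz - c) ** 2).sum(-1) <= 9
            x[inside] = r.uniform(0.8, 1.0)
            y[inside] = 1.0
            samples.append((np.clip(x, 0, 1), y))
        return samples

    def test_training_decreases_dice_loss(self, blob_samples):
        cfg = TrainConfig.tiny(epochs=6, seed=1, val_fraction=0.0, patches_per_volume=4)
        det = MetastasisDetector3D(base_channels=4, train_crop=None, train_config=cfg)
        det.fit([x for x, _ in blob_samples], [y for _, y in blob_samples])
        hist = det.loss_history_["train_loss"]
        assert hist[-1] < hist[0]

    def test_seeded_rerun_identical_history(self, blob_samples):
        cfg = TrainConfig.tiny(epochs=2, seed=3, val_fraction=0.0)
        X = [x for x, _ in blob_samples]
        y = [y for _, y in blob_samples]
        h1 = MetastasisDetector3D(base_channels=4, train_config=cfg).fit(X, y).loss_history_
        h2 = MetastasisDetector3D(base_channels=4, train_config=cfg).fit(X, y).loss_history_
        assert h1 == h2

    def test_checkpoint_round_trip(self, blob_samples, tmp_path):
        cfg = TrainConfig.tiny(epochs=1, seed=0, val_fraction=0.0)
        det = MetastasisDetector3D(base_channels=4, train_config=cfg)
        det.fit([x for x, _ in blob_samples], [y for _, y in blob_samples])
        det.save(tmp_path / "det.npz")
        back = MetastasisDetector3D.load(tmp_path / "det.npz")
        x = blob_samples[0][0]
        np.testing.assert_array_equal(back.predict_proba(x), det.predict_proba(x))

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError, match="2"):
            MetastasisDetector3D().fit([np.zeros((8, 8, 8))], [np.zeros((8, 8, 8))])

    def test_all_background_labels_warn(self, blob_samples):
        cfg = TrainConfig.tiny(epochs=1, seed=0, val_fraction=0.0)
        X = [x for x, _ in blob_samples[:2]]
        with pytest.warns(UserWarning, match="background"):
            MetastasisDetector3D(base_channels=4, train_config=cfg).fit(X, [np.zeros_like(x) for x in X])


class TestNetGradients:
    def test_backprop_matches_finite_differences(self):
        from metrano._net import _sigmoid, soft_dice_loss

        r = np.random.default_rng(0)
        net = SegNet(2, base_channels=3, seed=1)
        x = r.random((1, 8, 8)).astype(np.float32)
        y = (r.random((8, 8)) > 0.7).astype(np.float32)

        def loss():
            return soft_dice_loss(_sigmoid(net.forward(x, keep=True))[0], y)

        for layer in net._layers:
            layer.zero_grad()
        z = net.forward(x)
        p = _sigmoid(z)[0]
        _, gp = soft_dice_loss(p, y)
        net.backward((gp * p * (1 - p)).astype(np.float32)[None])
        eps = 1e-3
        for layer, idx in [(net.conv1, (0, 0, 1, 1)), (net.conv2, (2, 1, 0, 2)), (net.conv4, (0, 1, 0, 0))]:
            w0 = layer.W[idx]
            layer.W[idx] = w0 + eps
            lp, _ = loss()
            layer.W[idx] = w0 - eps
            lm, _ = loss()
            layer.W[idx] = w0
            assert (lp - lm) / (2 * eps) == pytest.approx(float(layer.gW[idx]), abs=2e-4)
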