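import numpy as np
import pytest

from annoret import _nn
from annoret.core import Candidate, SphericalROI, Task, Volume
from annoret.detector import (
    DetectorConfig,
    TrainingError,
    augment_positive,
    extract_candidates,
    extract_organ_mask,
    extract_voi,
    label_candidates,
    preprocess,
    run_cad,
    train,
)
from annoret.synth import PhantomParams, generate_dataset, generate_phantom


@pytest.fixture(scope="module")
def chest_cfg():
    return DetectorConfig.for_task("chest")


@pytest.fixture(scope="module")
def brain_cfg():
    return DetectorConfig.for_task("brain")


@pytest.fixture(scope="module")
def chest_phantom():
    params = PhantomParams.for_task("chest")
    return generate_phantom(params, 1, 0, seed=21)


class TestConfig:
    def test_voi_shift_invariant(self):
        with pytest.raises(ValueError):
            DetectorConfig(voi_edge=8, shift_range=4)

    def test_bad_scale_range(self):
        with pytest.raises(ValueError):
            DetectorConfig(scale_range=(1.2, 0.8))

    def test_published_defaults(self):
        chest = DetectorConfig.for_task("chest", desk=False)
        assert chest.voi_edge == 32
        assert chest.learning_rate == pytest.approx(1.0e-5)
        assert chest.momentum == pytest.approx(0.99)
        assert chest.weight_decay == pytest.approx(0.001)
        assert chest.batch_size == 8
        assert chest.epochs == 500
        brain = DetectorConfig.for_task("brain", desk=False)
        assert brain.target_spacing_mm == pytest.approx(0.469)
        assert brain.epochs == 10


class TestPreprocess:
    def test_already_isotropic_unchanged(self, chest_cfg):
        vol = Volume(
            np.random.default_rng(0).normal(size=(20, 20, 20)),
            spacing=(1, 1, 1), origin=(0, 0, 0), task=Task.CHEST,
        )
        out = preprocess(vol, chest_cfg)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-6)

    def test_resample_doubles_shape(self, chest_cfg):
        vol = Volume(
            np.zeros((16, 16, 16)), spacing=(2, 2, 2), origin=(0, 0, 0),
            task=Task.CHEST,
        )
        out = preprocess(vol, chest_cfg)
        for dim in out.shape:
            assert abs(dim - 32) <= 1
        np.testing.assert_allclose(out.spacing, (1, 1, 1))

    def test_standardization_monotone(self, brain_cfg, rng):
        ramp = np.linspace(0, 1, 24**3).reshape(24, 24, 24)
        vol = Volume(ramp, spacing=(1, 1, 1), origin=(0, 0, 0), task=Task.BRAIN)
        out = preprocess(vol, brain_cfg)
        flat_in = ramp.reshape(-1)
        flat_out = out.voxels.reshape(-1)
        idx = rng.integers(0, flat_in.size, size=(1000, 2))
        for i, j in idx:
            if flat_in[i] < flat_in[j]:
                assert flat_out[i] <= flat_out[j] + 1e-9

    def test_constant_volume_warns(self, brain_cfg):
        vol = Volume(np.full((8, 8, 8), 3.0), spacing=(1, 1, 1), origin=(0, 0, 0))
        with pytest.warns(UserWarning, match="skipped"):
            preprocess(vol, brain_cfg)


class TestOrganMask:
    def _tube_volume(self, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        vox = np.full((40, 40, 40), 0.05)
        vox[18:22, 18:22, 5:35] = 1.0  # one bright tube
        if noise_sd:
            vox = vox + rng.normal(0, noise_sd, vox.shape)
        return Volume(vox, spacing=(1, 1, 1), origin=(0, 0, 0), task=Task.BRAIN)

    def test_brain_tube_coverage(self, brain_cfg):
        vol = self._tube_volume()
        mask = extract_organ_mask(vol, brain_cfg)
        tube = np.zeros(vol.shape, dtype=bool)
        tube[18:22, 18:22, 5:35] = True
        assert mask[tube].mean() >= 0.90

    def test_mask_noise_robustness(self, brain_cfg):
        ref = extract_organ_mask(self._tube_volume(), brain_cfg)
        for seed in range(5):
            noisy = self._tube_volume(noise_sd=0.05, seed=seed)
            mask = extract_organ_mask(noisy, brain_cfg)
            dice = 2 * (mask & ref).sum() / max(mask.sum() + ref.sum(), 1)
            assert dice >= 0.95

    def test_empty_mask_on_flat_volume(self, chest_cfg):
        vol = Volume(np.zeros((16, 16, 16)), spacing=(1, 1, 1), origin=(0, 0, 0))
        mask = extract_organ_mask(vol, chest_cfg)
        assert not mask.any()

    def test_empty_mask_warns_in_extraction(self, chest_cfg):
        vol = Volume(np.zeros((16, 16, 16)), spacing=(1, 1, 1), origin=(0, 0, 0))
        with pytest.warns(UserWarning, match="empty organ mask"):
            out = extract_candidates(vol, np.zeros(vol.shape, bool), chest_cfg)
        assert out == []


class TestCandidates:
    def test_lesion_yields_candidate(self, chest_cfg):
        params = PhantomParams.for_task("chest")
        vol, rois = generate_phantom(params, 1, 0, seed=33)
        lesion = rois[0]
        pvol = preprocess(vol, chest_cfg)
        mask = extract_organ_mask(pvol, chest_cfg)
        cands = extract_candidates(pvol, mask, chest_cfg, "x")
        assert any(
            lesion.distance_to(c.centroid) <= lesion.radius for c in cands
        )

    def test_background_only_finite(self, chest_cfg):
        params = PhantomParams.for_task("chest")
        vol, _ = generate_phantom(params, 0, 0, seed=5)
        pvol = preprocess(vol, chest_cfg)
        mask = extract_organ_mask(pvol, chest_cfg)
        cands = extract_candidates(pvol, mask, chest_cfg, "x")
        assert len(cands) <= chest_cfg.max_candidates
        assert all(np.isfinite(c.score) for c in cands)

    def test_contrast_sweep_monotone_disappearance(self, chest_cfg):
        centre = (32.0, 32.0, 32.0)
        hits = []
        for contrast in (0.8, 0.4, 0.2, 0.1, 0.0):
            rng = np.random.default_rng(9)
            vox = 0.2 + rng.normal(0, 0.04, size=(64, 64, 64))
            xx, yy, zz = np.indices(vox.shape)
            d = np.sqrt((xx - 32) ** 2 + (yy - 32) ** 2 + (zz - 32) ** 2)
            vox += contrast * (d <= 4)
            vol = Volume(vox, spacing=(1, 1, 1), origin=(0, 0, 0), task=Task.CHEST)
            mask = np.ones(vol.shape, bool)
            cands = extract_candidates(vol, mask, chest_cfg, "x")
            hits.append(
                any(np.linalg.norm(np.subtract(c.centroid, centre)) <= 4 for c in cands)
            )
        assert hits[0]  # high contrast found
        assert not hits[-1]  # vanished at zero contrast
        # once gone it stays gone as contrast keeps dropping
        first_miss = hits.index(False)
        assert all(not h for h in hits[first_miss:])


class TestLabelCandidates:
    def _roi(self, diameter, centroid=(0, 0, 0)):
        return SphericalROI("c", centroid, diameter, "R1")

    def test_exact_centroid_positive(self):
        cand = Candidate("c", (0, 0, 0), 0.5)
        assert label_candidates([cand], [self._roi(6)])[0]

    def test_floor_applies_to_small_roi(self):
        cand = Candidate("c", (2.9, 0, 0), 0.5)
        assert label_candidates([cand], [self._roi(4.0)])[0]

    def test_beyond_radius_and_floor_negative(self):
        cand = Candidate("c", (5.0, 0, 0), 0.5)
        assert not label_candidates([cand], [self._roi(6.0)])[0]


class TestAugmentation:
    def test_exactly_29(self, chest_phantom, chest_cfg, rng):
        vol, rois = chest_phantom
        pvol = preprocess(vol, chest_cfg)
        out = augment_positive(pvol, rois[0].centroid, chest_cfg, rng)
        assert len(out) == 29
        assert all(v.shape == (16, 16, 16) for v in out)

    def test_identity_draw(self, chest_phantom, chest_cfg):
        vol, rois = chest_phantom
        pvol = preprocess(vol, chest_cfg)
        base = extract_voi(pvol, rois[0].centroid, 16)
        same = extract_voi(pvol, rois[0].centroid, 16, (0, 0, 0), 1.0, (0, 0, 0))
        np.testing.assert_array_equal(base, same)

    def test_rng_states_differ(self, chest_phantom, chest_cfg):
        vol, rois = chest_phantom
        pvol = preprocess(vol, chest_cfg)
        a = augment_positive(pvol, rois[0].centroid, chest_cfg,
                             np.random.default_rng(1))
        b = augment_positive(pvol, rois[0].centroid, chest_cfg,
                             np.random.default_rng(2))
        assert any(not np.array_equal(x, y) for x, y in zip(a, b))

    def test_same_rng_state_reproduces(self, chest_phantom, chest_cfg):
        vol, rois = chest_phantom
        pvol = preprocess(vol, chest_cfg)
        a = augment_positive(pvol, rois[0].centroid, chest_cfg,
                             np.random.default_rng(7))
        b = augment_positive(pvol, rois[0].centroid, chest_cfg,
                             np.random.default_rng(7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestLinearBaselineSeparable:
    def test_training_accuracy_one(self, rng):
        from annoret.detector import _ClassifierCore

        cfg = DetectorConfig.for_task("chest", voi_edge=8, shift_range=2)
        bright = [np.full((8, 8, 8), 1.0) + rng.normal(0, 0.05, (8, 8, 8))
                  for _ in range(20)]
        dark = [rng.normal(0, 0.05, (8, 8, 8)) for _ in range(20)]
        core = _ClassifierCore(cfg, rng)
        x = core.prepare(bright + dark)
        y = np.concatenate([np.ones(20), np.zeros(20)])
        opt = _nn.MomentumSGD(core.net.params(), lr=0.5, momentum=0.9,
                              weight_decay=1e-4)
        for _ in range(100):
            logits = core.net.forward(x).reshape(-1)
            _, grad = _nn.bce_with_logits(logits, y)
            core.net.backward(grad.reshape(-1, 1))
            opt.step()
        pred = core.scores(x) > 0.5
        assert (pred == y.astype(bool)).mean() == 1.0


def _tiny_training_setup(seed=3, n_pos=4, n_neg=2):
    params = PhantomParams.for_task("chest", grid_size=(48, 48, 48))
    counts = {"initial": (n_pos, n_neg), "retraining1": (0, 0),
              "retraining2": (0, 0), "test": (0, 0)}
    manifest, volumes = generate_dataset(params, seed=seed, counts=counts)
    cases = manifest.subset("initial")
    annotations = {c.case_id: list(c.lesions) for c in cases}
    return cases, annotations, volumes


class TestTrain:
    def test_per_epoch_class_balance(self):
        cases, annotations, volumes = _tiny_training_setup()
        cfg = DetectorConfig.for_task("chest", epochs=3)
        seen = []
        train(cfg, cases, annotations, volumes, seed=1,
              epoch_hook=lambda e, p, n: seen.append((e, p, n)))
        assert len(seen) == 3
        for _, n_pos, n_neg in seen:
            assert n_pos == n_neg

    def test_single_class_error(self):
        cases, annotations, volumes = _tiny_training_setup()
        # claim every candidate is a lesion: huge ROI covering the grid
        all_pos = {
            c.case_id: [SphericalROI(c.case_id, (24, 24, 24), 200, "R1")]
            for c in cases
        }
        cfg = DetectorConfig.for_task("chest", epochs=1)
        with pytest.raises(TrainingError, match="negative"):
            train(cfg, cases, all_pos, volumes, seed=1)

    def test_deterministic_predictions(self):
        cases, annotations, volumes = _tiny_training_setup()
        cfg = DetectorConfig.for_task("chest", epochs=2)
        probe_vol, _ = generate_phantom(
            PhantomParams.for_task("chest", grid_size=(48, 48, 48)), 1, 0, seed=99
        )
        outs = []
        for _ in range(2):
            det = train(cfg, cases, annotations, volumes, seed=5)
            cands = run_cad(det, probe_vol, "probe")
            outs.append([(c.centroid, c.score) for c in cands])
        assert outs[0] == outs[1]

    @pytest.mark.parametrize("kind", ["cnn3d", "cnn_mip"])
    def test_cnn_kinds_train_and_score(self, kind):
        cases, annotations, volumes = _tiny_training_setup(n_pos=2, n_neg=1)
        cfg = DetectorConfig.for_task(
            "chest", classifier=kind, epochs=1, learning_rate=1e-3,
            n_augment=3, cnn_width=2,
        )
        det = train(cfg, cases, annotations, volumes, seed=2)
        vol, _ = generate_phantom(
            PhantomParams.for_task("chest", grid_size=(48, 48, 48)), 1, 0, seed=98
        )
        cands = run_cad(det, vol, "p")
        assert all(0.0 <= c.score <= 1.0 for c in cands)


class TestRunCad:
    def test_scores_in_unit_interval_and_sorted(self):
        cases, annotations, volumes = _tiny_training_setup()
        cfg = DetectorConfig.for_task("chest", epochs=2)
        det = train(cfg, cases, annotations, volumes, seed=1)
        vol, _ = generate_phantom(
            PhantomParams.for_task("chest", grid_size=(48, 48, 48)), 1, 0, seed=44
        )
        cands = run_cad(det, vol, "p")
        assert all(0.0 <= c.score <= 1.0 for c in cands)
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)

    def test_empty_mask_returns_empty(self):
        cases, annotations, volumes = _tiny_training_setup()
        cfg = DetectorConfig.for_task("chest", epochs=1)
        det = train(cfg, cases, annotations, volumes, seed=1)
        flat = Volume(np.zeros((16, 16, 16)), spacing=(1, 1, 1),
                      origin=(0, 0, 0), task=Task.CHEST)
        with pytest.warns(UserWarning, match="empty organ mask"):
            assert run_cad(det, flat, "flat") == []

    def test_top_candidate_hits_lesion_most_seeds(self):
        cases, annotations, volumes = _tiny_training_setup(n_pos=6, n_neg=3)
        cfg = DetectorConfig.for_task("chest", epochs=5)
        det = train(cfg, cases, annotations, volumes, seed=1)
        params = PhantomParams.for_task("chest", grid_size=(48, 48, 48))
        hits = 0
        for seed in range(200, 210):
            vol, rois = generate_phantom(params, 1, 0, seed=seed)
            lesion = rois[0]
            cands = run_cad(det, vol, "p")
            if cands and lesion.distance_to(cands[0].centroid) <= max(
                lesion.radius, 3.0
            ):
                hits += 1
        assert hits >= 8
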