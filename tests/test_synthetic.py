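import numpy as np
import pytest

from posekit.skeleton import load_annotations, save_annotations
from posekit.synthetic import (
    CreatureSpec,
    make_creature,
    make_dataset,
    render,
    rest_pose,
    sample_pose,
    scaled_creature,
    toy_creature,
)


class TestSamplePose:
    def test_zero_jitter_reproduces_rest_pose(self, toy_spec):
        import dataclasses

        spec = dataclasses.replace(toy_spec, jitter_std=np.zeros(5))
        rng = np.random.default_rng(0)
        kp = sample_pose(spec, rng)
        assert np.allclose(kp.coords, rest_pose(spec).coords)

    def test_chain_forward_kinematics(self):
        from posekit.skeleton import Skeleton

        skel = Skeleton(names=["a", "b", "c"], parent=[-1, 0, 1], swap=[0, 1, 2])
        spec = CreatureSpec(
            skeleton=skel,
            lengths=[0.0, 10.0, 10.0],
            rest_angles=[0.0, 0.0, 0.0],
            jitter_std=[0.0, 0.0, 0.0],
            image_size=(64, 64),
            margin=5.0,
        )
        kp = rest_pose(spec)
        c = np.array([31.5, 31.5])
        assert np.allclose(kp.coords[0], c)
        assert np.allclose(kp.coords[1], c + [0, -10])
        assert np.allclose(kp.coords[2], c + [0, -20])

    def test_fixed_seed_reproducible(self, toy_spec):
        a = sample_pose(toy_spec, np.random.default_rng(5)).coords
        b = sample_pose(toy_spec, np.random.default_rng(5)).coords
        assert np.array_equal(a, b)

    def test_rest_pose_must_fit(self):
        from posekit.skeleton import Skeleton

        skel = Skeleton(names=["a", "b"], parent=[-1, 0], swap=[0, 1])
        with pytest.raises(ValueError, match="does not fit"):
            CreatureSpec(
                skeleton=skel,
                lengths=[0.0, 40.0],  # segment longer than the frame allows
                rest_angles=[0.0, 0.0],
                jitter_std=[0.0, 0.0],
                image_size=(64, 64),
                margin=15.0,
            )


class TestRender:
    def test_noise_free_contrast(self, toy_spec):
        import dataclasses

        spec = dataclasses.replace(toy_spec, noise_level=0.0)
        kp = rest_pose(spec)
        img = render(spec, kp)[..., 0]
        head = spec.skeleton.index("head")
        body = spec.skeleton.root
        mid = ((kp.coords[head] + kp.coords[body]) / 2).astype(int)
        assert img[mid[1], mid[0]] == 255
        assert img[2, 2] == 0

    def test_same_pose_differs_only_in_noise(self, toy_spec):
        kp = rest_pose(toy_spec)
        img1 = render(toy_spec, kp, np.random.default_rng(1))
        img2 = render(toy_spec, kp, np.random.default_rng(2))
        assert not np.array_equal(img1, img2)
        assert np.abs(img1.astype(int) - img2.astype(int)).mean() < 30

    def test_limb_brighter_than_background_sweep(self, toy_spec):
        # midpoint of a limb beats a far corner pixel across random poses
        rng = np.random.default_rng(3)
        head = toy_spec.skeleton.index("head")
        body = toy_spec.skeleton.root
        for _ in range(100):
            kp = sample_pose(toy_spec, rng)
            img = render(toy_spec, kp, rng)[..., 0]
            mid = ((kp.coords[head] + kp.coords[body]) / 2).astype(int)
            assert img[mid[1], mid[0]] > img[1, 1]


class TestDatasets:
    @pytest.mark.parametrize(
        "preset,size,k",
        [("fly192", 192, 32), ("locust160", 160, 35), ("zebra160", 160, 9)],
    )
    def test_preset_shapes(self, preset, size, k):
        spec = make_creature(preset)
        ds = make_dataset(spec, 3, seed=0)
        assert ds.images.shape == (3, size, size, 1)
        assert ds.keypoints.shape == (3, k, 2)
        assert ds.annotated.all()

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            make_creature("mouse")

    def test_minimal_dataset_round_trips(self, tmp_path, toy_spec):
        ds = make_dataset(toy_spec, 1, seed=0)
        path = tmp_path / "one.h5"
        save_annotations(ds, path)
        back = load_annotations(path)
        assert back.images.shape == (1, 64, 64, 1)
        assert back.skeleton.names == toy_spec.skeleton.names

    def test_scaled_creature_keeps_topology(self):
        spec = scaled_creature("zebra160", 0.6)
        assert spec.image_size == (96, 96)
        assert spec.skeleton.n_keypoints == 9
        ds = make_dataset(spec, 2, seed=0)
        assert ds.images.shape == (2, 96, 96, 1)


class TestEndToEnd:
    def test_small_model_generalizes_to_held_out_poses(self):
        """Train a small stacked dense model on 50 synthetic images of the
        zebra-skeleton creature (at reduced resolution) and require a held-out
        validation error under 5 px."""
        import posekit as pk
        from posekit.confmaps import render_targets
        from posekit.evaluation import euclidean_error
        from posekit.skeleton import split_train_val
        from posekit.training import TrainSchedule, fit

        spec = scaled_creature("zebra160", 0.6)
        ds = make_dataset(spec, 50, seed=7)
        train, val = split_train_val(ds, 0.1, seed=7)
        stack = render_targets(
            ds.keypoint_set(0), ds.skeleton, spec.image_size, 4, 5.0
        )
        cfg = pk.ModelConfig(
            arch="stacked_densenet", n_stacks=1, output_stride=4,
            n_keypoints=9, n_graph_maps=stack.n_graph_maps,
            input_shape=spec.image_size + (1,),
            growth_rate=8, n_layers_per_block=2, n_down=2, front_filters=16,
            seed=0,
        )
        model = pk.build_stacked_densenet(cfg)
        sched = TrainSchedule(
            learning_rate=2e-3, lr_factor=2.0, lr_min_delta=1e-5,
            lr_patience=15, stop_patience=40, max_epochs=50, seed=0,
        )
        fit(model, train, val, augment_config=None, schedule=sched)
        preds = pk.predict(model, val.images)
        errs = np.concatenate(
            [euclidean_error(p, val.keypoint_set(i)) for i, p in enumerate(preds)]
        )
        assert errs.mean() < 5.0
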