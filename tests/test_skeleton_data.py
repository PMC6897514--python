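import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posekit.skeleton import (
    AnnotationSet,
    Skeleton,
    load_annotations,
    parse_skeleton,
    save_annotations,
    skeleton_to_csv,
    split_train_val,
    validation_size,
)
from posekit.skeleton import SkeletonError
from posekit.synthetic import make_dataset, toy_creature


class TestParseSkeleton:
    def test_minimal_chain(self):
        skel = parse_skeleton("name,parent,swap\nhead,,\nneck,head,\n")
        assert skel.names == ("head", "neck")
        assert skel.parent.tolist() == [-1, 0]
        assert skel.root == 0
        assert skel.edges == [(1, 0)]

    def test_root_may_name_itself(self):
        skel = parse_skeleton("name,parent,swap\nhead,head,\nneck,head,\n")
        assert skel.root == 0
        assert skel.parent.tolist() == [-1, 0]

    def test_swap_involution(self, simple_skeleton):
        swap = simple_skeleton.swap
        assert np.array_equal(swap[swap], np.arange(len(swap)))
        i = simple_skeleton.index("left_arm")
        assert simple_skeleton.names[swap[i]] == "right_arm"

    @pytest.mark.parametrize(
        "csv,match",
        [
            ("name,parent,swap\ntail,nose_typo,\n", "unknown parent"),
            ("name,parent,swap\na,,\na,,\n", "duplicate"),
            ("name,parent,swap\na,b,\nb,a,\n", "root"),
            ("name,parent,swap\na,,\nb,,\n", "root"),
            ("name,parent,swap\na,,\nb,a,c\n", "unknown swap"),
        ],
    )
    def test_malformed_definitions_rejected(self, csv, match):
        with pytest.raises(SkeletonError, match=match):
            parse_skeleton(csv)

    def test_non_involution_swap_rejected(self):
        with pytest.raises(SkeletonError, match="involution"):
            Skeleton(names=["a", "b", "c"], parent=[-1, 0, 0], swap=[0, 2, 0])

    def test_csv_round_trip(self, simple_skeleton):
        again = parse_skeleton(skeleton_to_csv(simple_skeleton))
        assert again.names == simple_skeleton.names
        assert np.array_equal(again.parent, simple_skeleton.parent)
        assert np.array_equal(again.swap, simple_skeleton.swap)


class TestAnnotationContainer:
    def test_round_trip_identity(self, tmp_path, toy_dataset):
        path = tmp_path / "data.h5"
        save_annotations(toy_dataset, path)
        back = load_annotations(path)
        assert np.array_equal(back.images, toy_dataset.images)
        vis = toy_dataset.visible
        assert np.array_equal(back.visible, vis)
        assert np.allclose(
            back.keypoints[vis], toy_dataset.keypoints.astype(np.float32)[vis]
        )
        assert back.skeleton.names == toy_dataset.skeleton.names

    def test_missing_dataset_raises(self, tmp_path, toy_dataset):
        import h5py

        path = tmp_path / "broken.h5"
        save_annotations(toy_dataset, path)
        with h5py.File(path, "a") as f:
            del f["keypoints"]
        with pytest.raises(KeyError, match="keypoints"):
            load_annotations(path)

    def test_shape_contract(self, tmp_path):
        spec = toy_creature(64)
        ds = make_dataset(spec, 5, seed=0)
        path = tmp_path / "d.h5"
        save_annotations(ds, path)
        back = load_annotations(path)
        assert back.images.shape == (5, 64, 64, 1)
        assert back.keypoints.shape == (5, 5, 2)

    def test_mismatched_keypoints_rejected(self, simple_skeleton):
        with pytest.raises(ValueError, match="keypoints shape"):
            AnnotationSet(
                images=np.zeros((2, 8, 8, 1), dtype=np.uint8),
                keypoints=np.zeros((2, 3, 2)),
                visible=np.ones((2, 3), dtype=bool),
                skeleton=simple_skeleton,
            )


class TestSplit:
    def _tiny_set(self, n, skel):
        k = skel.n_keypoints
        return AnnotationSet(
            images=np.zeros((n, 8, 8, 1), dtype=np.uint8),
            keypoints=np.full((n, k, 2), 3.0),
            visible=np.ones((n, k), dtype=bool),
            skeleton=skel,
        )

    @pytest.mark.parametrize("n,frac,expected_val", [(900, 0.1, 90), (10, 0.1, 1)])
    def test_split_sizes(self, simple_skeleton, n, frac, expected_val):
        train, val = split_train_val(self._tiny_set(n, simple_skeleton), frac, seed=0)
        assert len(val) == expected_val
        assert len(train) == n - expected_val

    def test_partition_and_determinism(self, simple_skeleton):
        aset = self._tiny_set(37, simple_skeleton)
        aset.keypoints[:, 0, 0] = np.arange(37)  # tag examples
        t1, v1 = split_train_val(aset, 0.2, seed=5)
        t2, v2 = split_train_val(aset, 0.2, seed=5)
        tags = np.concatenate([t1.keypoints[:, 0, 0], v1.keypoints[:, 0, 0]])
        assert sorted(tags) == list(range(37))  # disjoint and exhaustive
        assert np.array_equal(v1.keypoints, v2.keypoints)
        _, v3 = split_train_val(aset, 0.2, seed=6)
        assert not np.array_equal(v1.keypoints, v3.keypoints)

    def test_size_rule_over_range(self):
        # independent oracle: enumerate the rounding definition directly
        for n in range(2, 1001, 7):
            expected = int(np.floor(n * 0.1 + 0.5))
            assert validation_size(n, 0.1) == expected

    @given(
        n=st.integers(2, 1000),
        frac=st.floats(0.01, 0.99, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_size_rule_properties(self, n, frac):
        v = validation_size(n, frac)
        assert 0 <= v <= n
        # half-up rounding: within half an example of the exact fraction
        assert abs(v - n * frac) <= 0.5 + 1e-9

    def test_too_small_raises(self, simple_skeleton):
        with pytest.raises(ValueError):
            split_train_val(self._tiny_set(3, simple_skeleton), 0.01, seed=0)
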