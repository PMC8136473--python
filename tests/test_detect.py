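from collections import deque
from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

import abtomo as ab
from abtomo.detect import (
    SegmentationParams,
    FilterParams,
    segment,
    label_components,
    measure_object,
    classify,
    detect_ab,
    wadell_sphericity,
)
from abtomo.volume import Volume, project_volume


def flood_fill_components(mask: np.ndarray, connectivity: int) -> set[frozenset]:
    """Brute-force BFS partition of a boolean mask — independent oracle."""
    if connectivity == 6:
        offsets = [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        offsets = [o for o in product((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, o)) <= 2]
    else:
        offsets = [o for o in product((-1, 0, 1), repeat=3) if any(o)]
    todo = set(map(tuple, np.argwhere(mask)))
    components = set()
    while todo:
        seed = todo.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        components.add(frozenset(comp))
    return components


def partition_of(labels: np.ndarray) -> set[frozenset]:
    out = set()
    for lab in range(1, labels.max() + 1):
        out.add(frozenset(map(tuple, np.argwhere(labels == lab))))
    return out


class TestSegment:
    def test_constant_below_window(self):
        vol = Volume(np.full((4, 4, 4), 0.2), 1.0)
        assert not segment(vol, SegmentationParams(0.5, 1.0)).any()

    def test_exact_voxel_selection(self):
        rng = np.random.default_rng(1)
        data = np.full((10, 10, 10), 0.1)
        idx = rng.choice(1000, size=100, replace=False)
        data.ravel()[idx] = 0.9
        mask = segment(Volume(data, 1.0), SegmentationParams(0.5, 1.0))
        assert mask.sum() == 100
        np.testing.assert_array_equal(np.flatnonzero(mask.ravel()), np.sort(idx))

    def test_elementwise_oracle_on_noisy_field(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0.4, 0.2, (20, 20, 20))
        data = np.clip(data, 0, 1)
        params = SegmentationParams(0.55, 0.9)
        mask = segment(Volume(data, 1.0), params)
        oracle = np.zeros_like(mask)
        for i, j, k in product(range(20), repeat=3):
            oracle[i, j, k] = 0.55 <= data[i, j, k] <= 0.9
        np.testing.assert_array_equal(mask, oracle)

    def test_window_widening_is_monotone(self):
        rng = np.random.default_rng(3)
        data = rng.random((12, 12, 12))
        narrow = segment(Volume(data, 1.0), SegmentationParams(0.4, 0.6))
        wide = segment(Volume(data, 1.0), SegmentationParams(0.3, 0.7))
        assert wide.sum() >= narrow.sum()
        assert np.all(wide[narrow])

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            SegmentationParams(0.9, 0.1)


class TestLabelComponents:
    def test_two_separated_cubes(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[0:3, 0:3, 0:3] = True
        mask[5:8, 5:8, 5:8] = True
        _, n = label_components(mask, 26)
        assert n == 2

    def test_corner_sharing_connectivity_semantics(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert label_components(mask, 26)[1] == 1
        assert label_components(mask, 6)[1] == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(4)
        mask = rng.random((20, 20, 20)) < 0.1
        labels, n = label_components(mask, connectivity)
        oracle = flood_fill_components(mask, connectivity)
        assert n == len(oracle)
        assert partition_of(labels) == oracle


class TestMeasureObject:
    def test_axis_aligned_box(self):
        # 90 x 9 x 9 voxels at 0.332 um: hand geometry
        coords = np.argwhere(np.ones((90, 9, 9), bool))
        f = measure_object(coords, 0.332)
        assert f.length_um == pytest.approx(29.88)
        assert f.width_um == pytest.approx(2.988)
        assert f.aspect_ratio == pytest.approx(10.0)
        assert f.sphericity == pytest.approx(0.1)
        assert f.solidity == pytest.approx(1.0)
        assert f.volume_um3 == pytest.approx(90 * 9 * 9 * 0.332**3)

    def test_single_voxel(self):
        f = measure_object(np.array([[4, 5, 6]]), 0.332)
        assert f.length_um == pytest.approx(0.332)
        assert f.width_um == pytest.approx(0.332)
        assert f.aspect_ratio == pytest.approx(1.0)
        assert f.solidity == pytest.approx(1.0)

    def test_digitized_ball(self):
        g = np.indices((27, 27, 27)).reshape(3, -1).T
        coords = g[np.linalg.norm(g - 13, axis=1) <= 12]
        f = measure_object(coords, 0.332)
        assert f.sphericity >= 0.9
        assert f.aspect_ratio <= 1.15
        # corner hull carries a half-voxel halo over the ball surface, which
        # bounds solidity near (r/(r+0.9))^3 from below for r = 12
        assert 0.80 <= f.solidity <= 1.0

    def test_solidity_never_exceeds_one(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            mask = rng.random((8, 8, 8)) < 0.3
            if not mask.any():
                continue
            f = measure_object(np.argwhere(mask), 1.0)
            assert 0 < f.solidity <= 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            measure_object(np.empty((0, 3)), 1.0)

    def test_border_flag(self):
        f = measure_object(np.array([[0, 2, 2], [1, 2, 2]]), 1.0, volume_shape=(5, 5, 5))
        assert f.touches_border
        g = measure_object(np.array([[2, 2, 2]]), 1.0, volume_shape=(5, 5, 5))
        assert not g.touches_border

    def test_wadell_sphericity_of_cube(self):
        # a voxel cube has Wadell sphericity (pi/6)^(1/3) with exact face counting
        f = wadell_sphericity(np.array([[0, 0, 0]]), 1.0)
        assert f == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-9)


class TestClassify:
    def _fibre_features(self):
        coords = np.argwhere(np.ones((90, 9, 9), bool))
        return measure_object(coords, 0.332)

    def test_fibre_accepted(self):
        f = classify(self._fibre_features(), FilterParams())
        assert f.accepted and f.reason == ""

    def test_ball_rejected_by_aspect_ratio_rule(self):
        # with permissive sphericity/solidity, the printed aspect-ratio > 3 rule fires
        g = np.indices((27, 27, 27)).reshape(3, -1).T
        ball = measure_object(g[np.linalg.norm(g - 13, axis=1) <= 12], 0.332)
        f = classify(ball, FilterParams(max_sphericity=1.0, min_solidity=0.01))
        assert not f.accepted
        assert f.reason == "aspect_ratio"

    def test_ball_rejected_by_sphericity_first_in_default_order(self):
        g = np.indices((27, 27, 27)).reshape(3, -1).T
        ball = measure_object(g[np.linalg.norm(g - 13, axis=1) <= 12], 0.332)
        f = classify(ball, FilterParams())
        assert f.reason == "sphericity"

    def test_speck_rejected_by_size(self):
        f = measure_object(np.array([[0, 0, 0], [0, 0, 1]]), 1.0)
        out = classify(f, FilterParams(min_size_vox=20))
        assert out.reason == "size"

    def test_border_policy(self):
        f = self._fibre_features()
        f.touches_border = True
        assert classify(f, FilterParams(border_policy="include")).accepted
        f2 = self._fibre_features()
        f2.touches_border = True
        assert classify(f2, FilterParams(border_policy="exclude")).reason == "border"

    def test_raising_aspect_threshold_never_accepts_more(self):
        feats = [self._fibre_features() for _ in range(1)]
        n_low = sum(classify(f, FilterParams(min_aspect_ratio=3)).accepted for f in feats)
        feats = [self._fibre_features() for _ in range(1)]
        n_high = sum(classify(f, FilterParams(min_aspect_ratio=12)).accepted for f in feats)
        assert n_high <= n_low

    @given(
        min_ar=st.floats(1.0, 6.0),
        delta=st.floats(0.0, 6.0),
    )
    def test_aspect_threshold_monotonicity_property(self, min_ar, delta):
        f = self._fibre_features()
        lo = classify(f, FilterParams(min_aspect_ratio=min_ar)).accepted
        f2 = self._fibre_features()
        hi = classify(f2, FilterParams(min_aspect_ratio=min_ar + delta)).accepted
        assert (not hi) or lo  # hi accepted implies lo accepted

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FilterParams(min_size_vox=0)
        with pytest.raises(ValueError):
            FilterParams(min_size_vox=10, max_size_vox=5)
        with pytest.raises(ValueError):
            FilterParams(connectivity=4)


class TestDetectAB:
    def test_empty_phantom(self):
        spec = ab.PhantomSpec(
            shape=(48, 48, 48), n_fibres=0, n_voids=0,
            n_small_distractors=0, n_large_distractors=0, seed=0,
        )
        vol = ab.render_phantom([], spec)
        table = detect_ab(vol)
        assert table.n_accepted == 0

    def test_clean_phantom_exact_recovery(self, clean_phantom):
        """25 separated fibres: all accepted; every distractor rejected."""
        spec, volume, records = clean_phantom
        table = detect_ab(volume)
        assert table.n_accepted == len(records)
        for obj in table.objects:
            if not obj.accepted:
                assert obj.reason == "size"  # sub-size specks only
        res = ab.match_to_truth(
            np.array([o.centroid_um for o in table.accepted]),
            np.array([o.length_um for o in table.accepted]),
            records,
        )
        assert res.fdr == 0.0
        assert res.sensitivity == 1.0

    def test_accepted_objects_satisfy_invariants(self, clean_phantom):
        _, volume, _ = clean_phantom
        table = detect_ab(volume)
        for o in table.accepted:
            l1, l2, l3 = o.extents_um
            assert l1 >= l2 >= l3 > 0
            assert o.aspect_ratio >= 1
            assert 0 < o.sphericity <= 1
            assert 0 < o.solidity <= 1
            assert o.volume_um3 > 0

    def test_stage_counts_are_decreasing(self, clean_phantom):
        _, volume, _ = clean_phantom
        counts = detect_ab(volume).stage_counts
        seq = [counts["components"], counts["after_size"], counts["after_sphericity"],
               counts["after_solidity"], counts["after_aspect_ratio"],
               counts["after_border"]]
        assert all(a >= b for a, b in zip(seq, seq[1:]))
        assert seq[-1] == counts["accepted"]

    def test_projection_undercounts_dense_phantom(self):
        """2D component count of a max projection <= 3D accepted count."""
        spec = ab.PhantomSpec(
            shape=(128, 128, 128), n_fibres=40, noise_sd=0.0, n_voids=0,
            n_small_distractors=0, n_large_distractors=0, seed=13,
        )
        vol, recs = ab.generate_phantom(spec)
        table = detect_ab(vol)
        img = project_volume(vol, axis=0, mode="max")
        from scipy import ndimage

        labels2d, n2d = ndimage.label(img >= 0.6, structure=np.ones((3, 3), bool))
        assert n2d <= table.n_accepted
        assert n2d < len(recs)  # projection genuinely merges fibres here


class TestChunkedDetection:
    def test_whole_vs_chunked_identical(self, stitch_phantom):
        spec, vol, recs = stitch_phantom
        # precondition: overlap (100 planes = 33.2 um) exceeds the longest fibre
        assert max(r.length_um for r in recs) < 100 * spec.voxel_size
        whole = detect_ab(vol)
        chunked = detect_ab(vol, chunk_planes=150, overlap=100)
        assert chunked.n_accepted == whole.n_accepted
        key = lambda o: o.centroid_um
        for a, b in zip(sorted(whole.accepted, key=key), sorted(chunked.accepted, key=key)):
            np.testing.assert_allclose(a.centroid_um, b.centroid_um, atol=1e-9)
            assert a.length_um == pytest.approx(b.length_um)
            assert a.width_um == pytest.approx(b.width_um)
            assert a.voxel_count == b.voxel_count
            assert a.solidity == pytest.approx(b.solidity)


class TestABTable:
    def test_dataframe_and_csv(self, clean_phantom, tmp_path):
        _, volume, _ = clean_phantom
        table = detect_ab(volume)
        df = table.to_dataframe()
        assert list(df.columns)[:4] == ["id", "status", "reason", "voxel_count"]
        assert (df["status"] == "accepted").sum() == table.n_accepted
        path = tmp_path / "objects.csv"
        table.to_csv(path)
        assert path.exists()
        summary = table.run_summary()
        assert summary["n_accepted"] == table.n_accepted
        assert summary["volume_cm3"] == pytest.approx(volume.physical_volume_cm3)
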