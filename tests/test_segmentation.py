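"""Max-entropy thresholding, nucleus splitting, meshing, cell expansion."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from lobule3d.core import LabelMap, VoxelGrid, binary_map
from lobule3d.segmentation import (
    NoSeedsError,
    SegmentationParams,
    SingleBinHistogramError,
    expand_cells_from_nuclei,
    kapur_threshold,
    mesh_from_labels,
    segment_structure,
    split_nuclei,
)

from conftest import digital_ball, digital_ellipsoid


def brute_force_max_entropy(hist) -> int:
    """Independent exhaustive maximiser of the two-part entropy criterion.

    Evaluates both class entropies from scratch at every cut (no shared
    cumulative sums with the implementation under test).
    """
    hist = np.asarray(hist, float)
    p = hist / hist.sum()

    def entropy(part: np.ndarray) -> float:
        w = part.sum()
        q = part[part > 0] / w
        return float(-(q * np.log(q)).sum())

    best, best_t = -math.inf, None
    for t in range(len(p) - 1):
        lo, hi = p[: t + 1], p[t + 1 :]
        if lo.sum() <= 0 or hi.sum() <= 0:
            continue
        crit = entropy(lo) + entropy(hi)
        if crit > best:
            best, best_t = crit, t
    return best_t


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    kind = rng.integers(3)
    if kind == 0:
        return rng.integers(0, 50, 256)
    if kind == 1:
        h = np.zeros(256, int)
        for c, s, n in ((60, 10, 3000), (180, 25, 1500)):
            v = np.clip(rng.normal(c, s, n).astype(int), 0, 255)
            h += np.bincount(v, minlength=256)
        return h
    h = rng.poisson(5.0, 256)
    if (h > 0).sum() < 2:
        h[0] = h[-1] = 5
    return h


class TestKapur:
    def test_two_delta_masses_separated(self):
        h = np.zeros(256, int)
        h[50], h[200] = 10, 7
        t = kapur_threshold(h)
        assert 50 <= t < 200

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            h = random_histogram(rng)
            assert kapur_threshold(h) == brute_force_max_entropy(h)

    def test_uniform_histogram_matches_brute_force(self):
        h = np.full(256, 4)
        assert kapur_threshold(h) == brute_force_max_entropy(h)

    def test_single_bin_rejected(self):
        h = np.zeros(256, int)
        h[10] = 100
        with pytest.raises(SingleBinHistogramError):
            kapur_threshold(h)


class TestSegmentStructure:
    def test_noise_free_bc_channel_recovered(self, clean_default_lobule):
        """Dice >= 0.95 against the generating mask on a clean channel."""
        img, gt = clean_default_lobule
        mask = segment_structure(img["cd13"])
        inter = (mask.mask & gt.bc.mask).sum()
        dice = 2 * inter / (mask.mask.sum() + gt.bc.mask.sum())
        assert dice >= 0.95

    def test_small_specks_removed(self):
        data = np.zeros((48, 48, 48), np.float32)
        data[5:7, 5:7, 5] = 1.0  # 4 voxels
        data[30, 30, 30] = 1.0  # 1 voxel
        grid = VoxelGrid(data, 0.3)
        params = SegmentationParams(
            min_object_volume_um3=10 * 0.3**3, closing_radius=0
        )
        mask = segment_structure(grid, params)
        assert not mask.mask.any()

    def test_constant_image_empty(self):
        mask = segment_structure(VoxelGrid(np.full((48, 48, 48), 3.0), 0.3))
        assert not mask.mask.any()

    def test_min_volume_monotone_in_component_count(self, small_lobule):
        img, _ = small_lobule
        counts = []
        for mv in (0.0, 0.5, 2.0):
            m = segment_structure(
                img["cd13"], SegmentationParams(min_object_volume_um3=mv)
            )
            counts.append(ndi.label(m.mask, np.ones((3, 3, 3)))[1])
        assert counts[0] >= counts[1] >= counts[2]


class TestSplitNuclei:
    def test_fused_spheres_split_into_two(self):
        r = 6
        vol = np.zeros((40, 40, 60), bool)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in vol.shape), indexing="ij")
        for cx in (20, 20 + int(1.5 * r)):
            vol |= (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - cx) ** 2 <= r**2
        labels = split_nuclei(binary_map(vol, 0.3))
        assert labels.n_labels == 2
        # partition: every foreground voxel labelled, none invented
        np.testing.assert_array_equal(labels.mask, vol)

    def test_single_sphere_one_label(self):
        labels = split_nuclei(binary_map(digital_ball(6), 0.3))
        assert labels.n_labels == 1

    def test_empty_mask_no_labels(self):
        labels = split_nuclei(binary_map(np.zeros((16, 16, 16), bool), 0.3))
        assert labels.n_labels == 0

    def test_random_packings_recover_count(self):
        """>= 18/20 random non-touching packings keep their sphere count."""
        rng = np.random.default_rng(0)
        good = 0
        for _ in range(20):
            n = int(rng.integers(3, 7))
            r = float(rng.uniform(4, 6))
            centers = []
            vol = np.zeros((64, 64, 64), bool)
            zz, yy, xx = np.meshgrid(*(np.arange(64),) * 3, indexing="ij")
            while len(centers) < n:
                c = rng.uniform(r + 1, 63 - r, 3)
                if all(np.linalg.norm(c - q) >= 1.6 * r for q in centers):
                    centers.append(c)
                    vol |= (
                        (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
                        <= r**2
                    )
            labels = split_nuclei(binary_map(vol, 0.3))
            good += labels.n_labels == n
        assert good >= 18


class TestMeshing:
    def test_sphere_volume_within_tolerance(self):
        r = 10
        labels = LabelMap(digital_ball(r).astype(np.int32), 0.3)
        meshes = mesh_from_labels(labels)
        assert len(meshes) == 1
        analytic = (4.0 / 3.0) * np.pi * (r * 0.3) ** 3
        assert meshes[0].volume_um3 == pytest.approx(analytic, rel=0.10)

    def test_cube_area_before_smoothing(self):
        vol = np.zeros((28, 28, 28), np.int32)
        vol[4:24, 4:24, 4:24] = 1
        params = SegmentationParams(mesh_smoothing_iterations=0)
        meshes = mesh_from_labels(LabelMap(vol, 1.0), params)
        assert meshes[0].area_um2 == pytest.approx(6 * 20**2, rel=0.15)

    def test_random_ellipsoids_volume(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            semi = rng.uniform(5, 11, 3)
            vol = digital_ellipsoid(semi).astype(np.int32)
            meshes = mesh_from_labels(LabelMap(vol, 0.3))
            analytic = (4.0 / 3.0) * np.pi * np.prod(semi * 0.3)
            assert meshes[0].volume_um3 == pytest.approx(analytic, rel=0.10)

    def test_empty_labels_empty_list(self):
        assert mesh_from_labels(LabelMap(np.zeros((8, 8, 8), np.int32), 0.3)) == []

    def test_border_touching_object_closed(self):
        vol = np.zeros((16, 16, 16), np.int32)
        vol[0:8, 0:8, 0:8] = 1  # touches three faces
        meshes = mesh_from_labels(LabelMap(vol, 0.3))
        assert meshes[0].volume_um3 > 0


class TestExpandCells:
    def test_single_nucleus_fills_closed_box(self):
        membrane = np.zeros((24, 24, 24), np.float32)
        membrane[4, 4:20, 4:20] = membrane[19, 4:20, 4:20] = 1.0
        membrane[4:20, 4, 4:20] = membrane[4:20, 19, 4:20] = 1.0
        membrane[4:20, 4:20, 4] = membrane[4:20, 4:20, 19] = 1.0
        seeds = np.zeros((24, 24, 24), np.int32)
        seeds[12, 12, 12] = 1
        cells = expand_cells_from_nuclei(
            LabelMap(seeds, 0.3), VoxelGrid(membrane, 0.3),
            merge_low_boundary=False,
        )
        # the basin reaches the walls; interior of the box is one cell
        interior = np.zeros_like(membrane, bool)
        interior[5:19, 5:19, 5:19] = True
        assert (cells.labels[interior] == 1).all()

    def test_no_seeds_rejected(self):
        with pytest.raises(NoSeedsError):
            expand_cells_from_nuclei(
                LabelMap(np.zeros((8, 8, 8), np.int32), 0.3),
                VoxelGrid(np.zeros((8, 8, 8), np.float32), 0.3),
            )

    def test_expansion_covers_allowed_space(self):
        seeds = np.zeros((16, 16, 16), np.int32)
        seeds[4, 4, 4], seeds[12, 12, 12] = 1, 2
        forbidden = np.zeros((16, 16, 16), bool)
        forbidden[:, :, 8] = True
        cells = expand_cells_from_nuclei(
            LabelMap(seeds, 0.3),
            VoxelGrid(np.zeros((16, 16, 16), np.float32), 0.3),
            binary_map(forbidden, 0.3),
            merge_low_boundary=False,
        )
        assert not cells.mask[forbidden].any()
        assert cells.mask[~forbidden].all()
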