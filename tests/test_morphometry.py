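"""Shape descriptors, ploidy, nuclearity, volume fractions, contacts."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from lobule3d.core import LabelMap, VoxelGrid, binary_map
from lobule3d.morphometry import (
    EmptyTissueError,
    NonPositiveContentError,
    OrphanNucleusError,
    assign_nuclearity,
    build_atlas,
    classify_ploidy,
    contact_surface_fractions,
    count_contact_sites,
    distance_distribution,
    dna_content,
    internuclear_distances,
    proximity_fraction,
    sem,
    shape_descriptors,
    volume_fraction,
)

from conftest import digital_ball, digital_ellipsoid


class TestShapeDescriptors:
    def test_sphere_elongation_near_zero(self):
        df = shape_descriptors(LabelMap(digital_ball(10).astype(np.int32), 0.3))
        assert df.loc[0, "elongation"] <= 0.05

    def test_ellipsoid_axis_ratio(self):
        vol = digital_ellipsoid((8, 4, 4)).astype(np.int32)
        df = shape_descriptors(LabelMap(vol, 0.3))
        assert df.loc[0, "elongation"] == pytest.approx(0.5, abs=0.05)

    def test_cube_volume_counting(self):
        vol = np.zeros((24, 24, 24), np.int32)
        vol[2:22, 2:22, 2:22] = 1
        df = shape_descriptors(LabelMap(vol, 0.3))
        assert df.loc[0, "volume_um3"] == pytest.approx(8000 * 0.027)

    def test_rotation_invariance(self):
        """Elongation of an ellipsoid is stable under rotation (tol 0.05)."""
        from scipy.spatial.transform import Rotation

        semi = np.array([9.0, 5.0, 5.0])
        base = 1.0 - semi[2] / semi[0]
        rng = np.random.default_rng(0)
        n = 41
        c = n // 2
        zz, yy, xx = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1).astype(float)
        for _ in range(20):
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            local = pts @ rot
            vol = (np.sum((local / semi) ** 2, axis=-1) <= 1.0).astype(np.int32)
            df = shape_descriptors(LabelMap(vol, 0.3))
            assert df.loc[0, "elongation"] == pytest.approx(base, abs=0.05)

    def test_single_voxel_convention(self):
        vol = np.zeros((8, 8, 8), np.int32)
        vol[4, 4, 4] = 1
        df = shape_descriptors(LabelMap(vol, 0.3))
        assert df.loc[0, "elongation"] == 0.0

    def test_as_printed_variant_negative(self):
        vol = digital_ellipsoid((8, 4, 4)).astype(np.int32)
        df = shape_descriptors(LabelMap(vol, 0.3), "as_printed")
        assert df.loc[0, "elongation"] < 0


class TestDnaContent:
    def test_uniform_intensity_sum(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels[2:7, 2:6, 2:7] = 1  # 100 voxels
        dapi = np.where(labels > 0, 7.0, 0.0)
        df = dna_content(LabelMap(labels, 0.3), VoxelGrid(dapi, 0.3))
        assert df.loc[0, "dna_raw"] == pytest.approx(700.0)
        assert df.loc[0, "dna_corrected"] == pytest.approx(700.0)

    def test_zero_image_zero_content(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[2:4, 2:4, 2:4] = 1
        df = dna_content(LabelMap(labels, 0.3), VoxelGrid(np.zeros((8, 8, 8)), 0.3))
        assert df["dna_raw"].iloc[0] == 0.0

    def test_background_offset_subtracted(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[4:8, 4:8, 4:8] = 1  # 64 voxels
        dapi = np.full((12, 12, 12), 2.0)
        dapi[labels > 0] = 10.0
        df = dna_content(LabelMap(labels, 0.3), VoxelGrid(dapi, 0.3))
        assert df.loc[0, "dna_raw"] == pytest.approx(640.0)
        assert df.loc[0, "dna_corrected"] == pytest.approx(640.0 - 2.0 * 64)

    def test_synthetic_ploidy_ratio(self, clean_small_lobule):
        """Noise-free 4n / equal-class 2n integral ratio ~ 2."""
        img, gt = clean_small_lobule
        df = dna_content(gt.nuclei, img["dapi"], background_correction=False)
        merged = df.merge(
            gt.nucleus_table, left_on="label", right_on="nucleus_id"
        )
        means = merged.groupby("ploidy_class")["dna_raw"].mean()
        if {"2n", "4n"} <= set(means.index):
            jitter = gt.params.dna_jitter
            assert means["4n"] / means["2n"] == pytest.approx(2.0, rel=3 * jitter)


class TestPloidy:
    def test_explicit_reference_log2_rounding(self):
        classes, _, _ = classify_ploidy(np.array([1.0, 2.05, 3.9]), 1.0)
        assert list(classes) == ["2n", "4n", "8n"]

    def test_all_equal_reference_all_diploid(self):
        classes, fr, _ = classify_ploidy(np.full(10, 3.3), 3.3)
        assert all(c == "2n" for c in classes)
        assert fr == {"2n": 1.0, "4n": 0.0, "8n": 0.0, "16n": 0.0}

    def test_integer_multiples_exact(self):
        rng = np.random.default_rng(0)
        mult = rng.choice([1.0, 2.0, 4.0, 8.0], 100)
        classes, _, _ = classify_ploidy(mult * 5.0, "auto")
        expected = {1.0: "2n", 2.0: "4n", 4.0: "8n", 8.0: "16n"}
        assert [expected[m] for m in mult] == list(classes)

    def test_jittered_simulation_recovery(self):
        """500 nuclei at fractions (0.5, 0.4, 0.1), 10 % lognormal jitter."""
        rng = np.random.default_rng(7)
        mult = rng.choice([1.0, 2.0, 4.0], 500, p=[0.5, 0.4, 0.1])
        contents = mult * rng.lognormal(0.0, 0.10, 500)
        _, fr, ref = classify_ploidy(contents, "auto")
        realized = {c: float(np.mean(mult == m)) for c, m in
                    (("2n", 1.0), ("4n", 2.0), ("8n", 4.0))}
        for c in realized:
            assert fr[c] == pytest.approx(realized[c], abs=0.05)
        assert ref == pytest.approx(1.0, rel=0.1)

    def test_non_positive_rejected(self):
        with pytest.raises(NonPositiveContentError):
            classify_ploidy(np.array([1.0, 0.0]), 1.0)


class TestNuclearity:
    def _cells_and_nuclei(self, two_nuclei=False):
        cells = np.zeros((16, 16, 16), np.int32)
        cells[2:14, 2:14, 2:8] = 1
        cells[2:14, 2:14, 8:14] = 2
        nuclei = np.zeros_like(cells)
        nuclei[6:9, 6:9, 3:6] = 1
        if two_nuclei:
            nuclei[3:5, 3:5, 3:5] = 3
        nuclei[6:9, 6:9, 10:13] = 2
        return LabelMap(cells, 0.3), LabelMap(nuclei, 0.3)

    def test_mononucleate_class(self):
        cells, nuclei = self._cells_and_nuclei()
        df = assign_nuclearity(cells, nuclei, {1: "2n", 2: "4n"})
        assert df.set_index("cell_id").loc[1, "nuclearity"] == "1x2n"
        assert df.set_index("cell_id").loc[2, "nuclearity"] == "1x4n"

    def test_binucleate_class(self):
        cells, nuclei = self._cells_and_nuclei(two_nuclei=True)
        df = assign_nuclearity(cells, nuclei, {1: "2n", 2: "2n", 3: "2n"})
        assert df.set_index("cell_id").loc[1, "nuclearity"] == "2x2n"

    def test_mixed_ploidy_flagged(self):
        cells, nuclei = self._cells_and_nuclei(two_nuclei=True)
        df = assign_nuclearity(cells, nuclei, {1: "2n", 2: "2n", 3: "4n"})
        row = df.set_index("cell_id").loc[1]
        assert row["nuclearity"] == "2x4n" and row["mixed"]

    def test_orphan_nucleus_rejected(self):
        cells = LabelMap(np.zeros((8, 8, 8), np.int32), 0.3)
        nuclei = np.zeros((8, 8, 8), np.int32)
        nuclei[2:4, 2:4, 2:4] = 1
        with pytest.raises(OrphanNucleusError):
            assign_nuclearity(cells, LabelMap(nuclei, 0.3), {1: "2n"})

    def test_synthetic_binucleation_recovery(self, default_lobule):
        """Ground-truth cells/nuclei reproduce the generating fraction."""
        _, gt = default_lobule
        ploidy = dict(
            zip(gt.nucleus_table.nucleus_id, gt.nucleus_table.ploidy_class)
        )
        hep_nuc = gt.nucleus_table[gt.nucleus_table.cell_type == "hepatocyte"]
        nuclei = LabelMap(
            np.where(
                np.isin(gt.nuclei.labels, hep_nuc.nucleus_id.to_numpy()),
                gt.nuclei.labels, 0,
            ).astype(np.int32), 0.3,
        )
        df = assign_nuclearity(gt.hepatocytes, nuclei, ploidy)
        frac = (df["n_nuclei"] >= 2).mean()
        true = (
            gt.cell_table[gt.cell_table.cell_type == "hepatocyte"].n_nuclei >= 2
        ).mean()
        assert frac == pytest.approx(true, abs=0.05)


class TestVolumeFraction:
    def test_identity_and_empty(self):
        tissue = binary_map(np.ones((8, 8, 8), bool), 0.3)
        assert volume_fraction(tissue, tissue) == 1.0
        empty = binary_map(np.zeros((8, 8, 8), bool), 0.3)
        assert volume_fraction(empty, tissue) == 0.0
        with pytest.raises(EmptyTissueError):
            volume_fraction(tissue, empty)

    def test_partition_sums_to_one(self, small_lobule):
        _, gt = small_lobule
        tissue = binary_map(~(gt.cv.mask | gt.pv.mask), 0.3)
        parts = [
            gt.sinusoids, gt.bc,
            binary_map(gt.hsc.labels > 0, 0.3),
            binary_map(gt.kc.labels > 0, 0.3),
            binary_map(gt.hepatocytes.labels > 0, 0.3),
        ]
        covered = np.zeros((64, 64, 64), bool)
        for p in parts:
            covered |= p.mask
        rest = binary_map(~covered & tissue.mask, 0.3)
        total = sum(volume_fraction(p, tissue) for p in parts)
        total += volume_fraction(rest, tissue)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_generator_fraction_recovered(self, small_lobule):
        _, gt = small_lobule
        tissue = binary_map(~(gt.cv.mask | gt.pv.mask), 0.3)
        f = volume_fraction(gt.sinusoids, tissue)
        expected = (gt.sinusoids.mask & tissue.mask).sum() / tissue.mask.sum()
        assert f == pytest.approx(expected, abs=1e-12)


class TestContacts:
    def test_fully_shelled_cell_100_percent(self):
        cells = np.zeros((20, 20, 20), np.int32)
        cells[6:14, 6:14, 6:14] = 1
        shell = ndi.binary_dilation(cells > 0) & (cells == 0)
        df = contact_surface_fractions(
            LabelMap(cells, 0.3), {"shell": binary_map(shell, 0.3)},
            include_other_cells=False,
        )
        assert df.loc[0, "contact_pct_shell"] == pytest.approx(100.0)

    def test_isolated_cell_zero_percent(self):
        cells = np.zeros((20, 20, 20), np.int32)
        cells[6:14, 6:14, 6:14] = 1
        empty = binary_map(np.zeros((20, 20, 20), bool), 0.3)
        df = contact_surface_fractions(
            LabelMap(cells, 0.3), {"none": empty}, include_other_cells=False
        )
        assert df.loc[0, "contact_pct_none"] == 0.0

    def test_cube_on_slab_one_sixth(self):
        """One face flush against a slab -> ~ 1/6 of the surface."""
        cells = np.zeros((40, 40, 40), np.int32)
        cells[10:30, 10:30, 10:30] = 1
        slab = np.zeros((40, 40, 40), bool)
        slab[:, :, 8:10] = True  # flush against the x-low face
        df = contact_surface_fractions(
            LabelMap(cells, 0.3), {"slab": binary_map(slab, 0.3)},
            include_other_cells=False,
        )
        assert df.loc[0, "contact_pct_slab"] == pytest.approx(16.7, abs=2.0)

    def test_three_patch_contact_sites(self):
        a = np.zeros((20, 20, 60), np.int32)
        a[8:12, 8:12, 5:55] = 1  # long bar
        b = np.zeros_like(a)
        for x0 in (10, 25, 40):  # three touching patches
            b[8:12, 12:14, x0 : x0 + 4] = 1
        pairs, totals, mean = count_contact_sites(
            LabelMap(a, 0.3), LabelMap(b, 0.3)
        )
        assert pairs["n_sites"].sum() == 3
        assert mean == pytest.approx(3.0)

    def test_disjoint_objects_no_sites(self):
        a = np.zeros((20, 20, 20), np.int32)
        a[2:5, 2:5, 2:5] = 1
        b = np.zeros_like(a)
        b[12:15, 12:15, 12:15] = 1
        pairs, _, mean = count_contact_sites(LabelMap(a, 0.3), LabelMap(b, 0.3))
        assert len(pairs) == 0 and mean == 0.0

    def test_wrapped_object_single_site(self):
        a = np.zeros((24, 24, 24), np.int32)
        a[8:16, 8:16, 8:16] = 1
        b = (ndi.binary_dilation(a > 0) & (a == 0)).astype(np.int32)
        pairs, _, _ = count_contact_sites(LabelMap(a, 0.3), LabelMap(b, 0.3))
        assert len(pairs) == 1 and pairs.loc[0, "n_sites"] == 1

    def test_contact_existence_symmetric(self):
        a = np.zeros((20, 20, 20), np.int32)
        a[4:10, 4:10, 4:10] = 1
        b = np.zeros_like(a)
        b[10:16, 4:10, 4:10] = 1
        ab, _, _ = count_contact_sites(LabelMap(a, 0.3), LabelMap(b, 0.3))
        ba, _, _ = count_contact_sites(LabelMap(b, 0.3), LabelMap(a, 0.3))
        assert (len(ab) > 0) == (len(ba) > 0)


class TestInternuclearDistances:
    def _spheres(self, gap_vox):
        r = 5
        vol = np.zeros((24, 24, 48), np.int32)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in vol.shape), indexing="ij")
        c2 = 12 + 2 * r + gap_vox
        vol[(zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= r**2] = 1
        vol[(zz - 12) ** 2 + (yy - 12) ** 2 + (xx - c2) ** 2 <= r**2] = 2
        return LabelMap(vol, 0.3)

    def test_analytic_gap_recovered(self):
        """Spheres r = 1.5 um with centroids 7 um apart -> 4 um gap."""
        r_vox = 5  # 1.5 um
        gap_vox = 23.33 - 2 * r_vox  # centroid distance 7 um
        nuclei = self._spheres(int(round(gap_vox)))
        df = internuclear_distances(nuclei, {1: "kc", 2: "hsc"})
        d = df[(df["type"] == "kc") & (df["partner_type"] == "hsc")][
            "distance_um"
        ].iloc[0]
        assert d == pytest.approx(4.0, abs=0.6)

    def test_touching_nuclei_zero(self):
        nuclei = self._spheres(0)
        df = internuclear_distances(nuclei, {1: "kc", 2: "hsc"})
        assert (
            df[(df["type"] == "kc") & (df["partner_type"] == "hsc")][
                "distance_um"
            ].iloc[0]
            == 0.0
        )

    def test_self_pair_excluded(self):
        nuclei = self._spheres(5)
        df = internuclear_distances(nuclei, {1: "kc", 2: "kc"})
        # each KC measures to the OTHER one, never to itself
        assert len(df) == 2 and (df["distance_um"] > 0).all()

    def test_proximity_fraction_threshold(self):
        nuclei = self._spheres(3)  # gap ~ 0.9 um < 2 um
        df = internuclear_distances(nuclei, {1: "kc", 2: "hsc"})
        assert proximity_fraction(df, "kc", "hsc") == 1.0
        dist = distance_distribution(df, "kc", "hsc")
        assert dist["density"].sum() * 0.5 == pytest.approx(1.0)


class TestAtlas:
    def test_sem_closed_form(self):
        assert sem(np.array([2.0, 4.0])) == pytest.approx(1.0)
        assert sem(np.array([5.0])) == 0.0

    def test_single_cell_summary(self):
        cells = pd.DataFrame(
            [{"cell_id": 1, "cell_type": "hepatocyte", "volume_um3": 100.0}]
        )
        nuclei = pd.DataFrame(columns=["nucleus_id"])
        atlas = build_atlas(cells, nuclei)
        row = atlas.summary.set_index("parameter").loc["volume_um3"]
        assert row["mean"] == 100.0 and row["sem"] == 0.0 and row["n"] == 1

    def test_edge_objects_excluded(self):
        cells = pd.DataFrame(
            [
                {"cell_id": 1, "cell_type": "hepatocyte", "volume_um3": 10.0,
                 "edge_object": False},
                {"cell_id": 2, "cell_type": "hepatocyte", "volume_um3": 99.0,
                 "edge_object": True},
            ]
        )
        atlas = build_atlas(cells, pd.DataFrame(columns=["nucleus_id"]))
        row = atlas.summary.set_index("parameter").loc["volume_um3"]
        assert row["n"] == 1 and row["mean"] == 10.0

    def test_duplicate_ids_rejected(self):
        cells = pd.DataFrame(
            [
                {"cell_id": 1, "cell_type": "hepatocyte", "volume_um3": 1.0},
                {"cell_id": 1, "cell_type": "hepatocyte", "volume_um3": 2.0},
            ]
        )
        from lobule3d.core import Lobule3DError

        with pytest.raises(Lobule3DError):
            build_atlas(cells, pd.DataFrame(columns=["nucleus_id"]))
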