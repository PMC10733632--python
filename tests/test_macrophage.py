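"""Macrophage classification rules, morphology and uptake."""

import numpy as np
import pandas as pd
import pytest

import oracles
from perimac.geometry import LabeledVolume, RegionMasks, contact_area
from perimac.macrophage import (
    MacrophageRecord,
    assign_segment,
    classify_association,
    classify_identity,
    cohort_table,
    contact_by_class,
    morphology,
    subset_calls,
    uptake,
)
from perimac.vessel_typing import CLASS_CODES, VesselSegmentMap


def ellipsoid_mask(shape, center, radii):
    zz, yy, xx = np.indices(shape)
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


# ------------------------------------------------------------- identity


def region_fixture(shape=(20, 20, 20)):
    soma = np.zeros(shape, bool)
    fiber = np.zeros(shape, bool)
    soma[10:] = True
    fiber[:10] = True
    return RegionMasks(soma_rich=soma, fiber_rich=fiber)


@pytest.mark.parametrize(
    "z_extent,expected",
    [
        ((10, 20), "DRG"),        # fully in soma region
        ((0, 10), "fiber"),       # fully in fiber region
        ((7, 17), "DRG"),         # exactly 30% soma (3 of 10): inclusive
        ((3, 13), "fiber"),       # 30% soma... no: 3 of 10 in soma -> DRG
    ],
)
def test_identity_rules(z_extent, expected):
    regions = region_fixture()
    labels = np.zeros((20, 20, 20), dtype=np.int32)
    labels[z_extent[0]:z_extent[1], 5, 5] = 1
    vol = LabeledVolume(labels, (1, 1, 1))
    lo, hi = z_extent
    n_soma = max(0, hi - 10)
    if n_soma / (hi - lo) >= 0.30:
        expected = "DRG"
    elif (10 - lo if lo < 10 else 0) / (hi - lo) >= 0.30:
        expected = "fiber"
    else:
        expected = "other"
    assert classify_identity(vol, 1, regions) == expected


def test_identity_evaluation_order():
    """An object split evenly across both regions is DRG: the soma rule
    is evaluated first."""
    regions = region_fixture()
    labels = np.zeros((20, 20, 20), dtype=np.int32)
    labels[5:15, 5, 5] = 1  # 50% soma, 50% fiber
    assert classify_identity(LabeledVolume(labels, (1, 1, 1)), 1, regions) == "DRG"


def test_identity_other():
    regions = region_fixture()
    labels = np.zeros((20, 20, 20), dtype=np.int32)
    labels[8:18, 5, 5] = 1  # 8 of 10 soma -> DRG; shrink regions instead
    small = RegionMasks(
        soma_rich=np.zeros((20, 20, 20), bool),
        fiber_rich=np.zeros((20, 20, 20), bool),
    )
    assert classify_identity(LabeledVolume(labels, (1, 1, 1)), 1, small) == "other"


# ---------------------------------------------------------- association


def test_association_threshold_and_boundary():
    assert classify_association(25.0) == "perivascular"
    assert classify_association(0.0) == "parenchymal"
    assert classify_association(9.99) == "parenchymal"
    assert classify_association(10.0) == "perivascular"  # boundary inclusive
    assert classify_association(10.0, threshold_um2=20.0) == "parenchymal"


def test_association_cohort_straddles_threshold():
    """Slabs with constructed contact areas {2, 8, 15, 40} μm² classify
    as {par, par, peri, peri}."""
    spacing = (1.0, 1.0, 1.0)
    vessel = np.zeros((10, 10, 50), bool)
    vessel[0] = True  # floor wall
    for area, expected in [(2, "parenchymal"), (8, "parenchymal"),
                           (15, "perivascular"), (40, "perivascular")]:
        mac = np.zeros_like(vessel)
        placed = 0
        for y in range(10):
            for x in range(50):
                if placed < area:
                    mac[1, y, x] = True
                    placed += 1
        got = contact_area(mac, vessel, spacing)
        assert got == pytest.approx(area)
        assert classify_association(got) == expected


# ------------------------------------------------------------- segment


def segment_fixture():
    """A vein wall and a v-cap wall flanking a macrophage slab."""
    shape = (12, 12, 12)
    classes = np.zeros(shape, dtype=np.uint8)
    classes[:, :, 0] = CLASS_CODES["vein"]
    classes[:, :, 6] = CLASS_CODES["v-cap"]
    return VesselSegmentMap(
        voxel_classes=classes, branch_table=pd.DataFrame(), spacing=(1, 1, 1)
    )


def test_assign_segment_max_contact():
    seg = segment_fixture()
    labels = np.zeros((12, 12, 12), dtype=np.int32)
    labels[0:4, 0:3, 1] = 1   # 12 μm² on the vein wall
    labels[0:1, 0:3, 5] = 1   # 3 μm² on the v-cap wall
    vol = LabeledVolume(labels, (1, 1, 1))
    cls, flag = assign_segment(vol, 1, seg)
    assert (cls, flag) == ("vein", "ok")


def test_assign_segment_single_contact_and_error():
    seg = segment_fixture()
    labels = np.zeros((12, 12, 12), dtype=np.int32)
    labels[2:5, 2:5, 5] = 1  # touches only the v-cap wall
    vol = LabeledVolume(labels, (1, 1, 1))
    assert assign_segment(vol, 1, seg)[0] == "v-cap"
    labels2 = np.zeros_like(labels)
    labels2[5, 5, 3] = 2  # floats free of both walls
    labels2[5, 5, 2] = 2
    labels2[5, 6, 3] = 2
    labels2[6, 5, 3] = 2
    with pytest.raises(ValueError, match="perivascular"):
        assign_segment(LabeledVolume(labels2, (1, 1, 1)), 2, seg)


def test_assign_segment_tie_breaks_by_distance():
    """Equal contact areas: the class whose wall is nearer the centroid
    wins; verified against exhaustive distances."""
    seg = segment_fixture()
    labels = np.zeros((12, 12, 12), dtype=np.int32)
    labels[0:2, 0:2, 1] = 1       # 4 μm² on the vein wall (x=0)
    labels[0:2, 0:2, 5] = 1       # 4 μm² on the v-cap wall (x=6)
    labels[0:2, 0:2, 2:5] = 1     # bridge
    labels[2:5, 0:2, 2] = 1       # extra mass near the vein side (no wall contact)
    vol = LabeledVolume(labels, (1, 1, 1))
    contacts = contact_by_class(labels == 1, seg, (1, 1, 1))
    assert contacts["vein"] == contacts["v-cap"] == 4.0
    c = np.argwhere(labels == 1).mean(axis=0) + 0.5
    d_vein = oracles.min_distance_um(c, seg.class_mask("vein"), (1, 1, 1))
    d_vcap = oracles.min_distance_um(c, seg.class_mask("v-cap"), (1, 1, 1))
    assert d_vein != d_vcap
    cls, flag = assign_segment(vol, 1, seg)
    assert cls == ("vein" if d_vein < d_vcap else "v-cap")
    assert flag == "ok"


# ----------------------------------------------------------- morphology


def test_morphology_sphere_limit():
    mask = ellipsoid_mask((24, 24, 24), (12, 12, 12), (8, 8, 8))
    vol = LabeledVolume(mask.astype(np.int32), (1, 1, 1))
    elong, sparse = morphology(vol, 1)
    assert elong == pytest.approx(1.0, abs=0.05)
    assert sparse == pytest.approx(1.0, abs=0.1)


def test_morphology_ellipsoid_elongation():
    mask = ellipsoid_mask((40, 24, 24), (20, 12, 12), (16, 8, 8))
    vol = LabeledVolume(mask.astype(np.int32), (1, 1, 1))
    elong, sparse = morphology(vol, 1)
    assert elong == pytest.approx(2.0, abs=0.1)
    assert sparse == pytest.approx(1.0, abs=0.1)


def test_morphology_matches_moment_oracle(rng):
    mask = np.zeros((14, 14, 14), bool)
    mask |= ellipsoid_mask((14, 14, 14), (7, 7, 7), (3, 3, 3))
    mask[rng.integers(3, 11, 40), rng.integers(3, 11, 40), rng.integers(3, 11, 40)] = True
    spacing = (0.7, 0.5, 0.5)
    vol = LabeledVolume(mask.astype(np.int32), spacing)
    elong, sparse = morphology(vol, 1)
    o_elong, o_sparse = oracles.ellipsoid_descriptors(mask, spacing)
    assert elong == pytest.approx(o_elong)
    assert sparse == pytest.approx(o_sparse)


def test_morphology_spider_sparser_than_ball(small_tissue):
    """Planted spider shapes have sparseness > 2 and above the
    equal-volume ball's."""
    t = small_tissue
    tm = t.macrophage_truth
    # pristine (parenchymal) spiders: perivascular ones are carved where
    # they hug the vessel, which can clip an arm
    spiders = tm[(tm["shape"] == "spider") & (tm.association == "parenchymal")]
    assert len(spiders) > 0
    balls = tm[tm["shape"] == "sphere"]
    s_spider = [morphology(t.macrophages, int(i))[1] for i in spiders.object_id]
    s_ball = [morphology(t.macrophages, int(i))[1] for i in balls.object_id]
    assert min(s_spider) > 2.0
    assert min(s_spider) > max(s_ball)


def test_morphology_invariance_under_permutation_translation():
    mask = ellipsoid_mask((30, 20, 20), (14, 10, 10), (11, 5, 5))
    vol = LabeledVolume(mask.astype(np.int32), (1, 1, 1))
    e1, s1 = morphology(vol, 1)
    perm = np.transpose(mask, (2, 0, 1))
    e2, s2 = morphology(LabeledVolume(perm.astype(np.int32), (1, 1, 1)), 1)
    rolled = np.roll(mask, (3, -2, 4), axis=(0, 1, 2))
    e3, s3 = morphology(LabeledVolume(rolled.astype(np.int32), (1, 1, 1)), 1)
    assert (e2, s2) == pytest.approx((e1, s1))
    assert (e3, s3) == pytest.approx((e1, s1))


def test_morphology_degenerate_objects_rejected():
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[2, 2, 2] = 1
    with pytest.raises(ValueError, match="voxels"):
        morphology(LabeledVolume(labels, (1, 1, 1)), 1)
    labels[2, 2:6, 2:6] = 2  # planar
    with pytest.raises(ValueError, match="planar"):
        morphology(LabeledVolume(labels, (1, 1, 1)), 2)


# --------------------------------------------------------------- uptake


def test_uptake_fold_and_uniform():
    labels = np.zeros((10, 10, 10), dtype=np.int32)
    labels[4:6, 4:6, 4:6] = 1
    vol = LabeledVolume(labels, (1, 1, 1))
    tissue = np.ones((10, 10, 10), bool)
    ch = np.full((10, 10, 10), 100.0)
    ch[labels == 1] = 500.0
    mfi, fold = uptake(vol, 1, ch, tissue)
    assert (mfi, fold) == (500.0, 5.0)
    uniform = np.full((10, 10, 10), 70.0)
    assert uptake(vol, 1, uniform, tissue)[1] == pytest.approx(1.0)


def test_uptake_background_errors():
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[0, 0, 0] = 1
    labels[0, 0, 1] = 1
    vol = LabeledVolume(labels, (1, 1, 1))
    ch = np.ones((4, 4, 4))
    with pytest.raises(ValueError, match="empty"):
        uptake(vol, 1, ch, np.zeros((4, 4, 4), bool))
    with pytest.raises(ValueError, match="zero"):
        uptake(vol, 1, np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool))


# --------------------------------------------------------------- subset


def test_subset_calls_boundary_and_auto():
    labels = np.zeros((6, 6, 12), dtype=np.int32)
    labels[2:4, 2:4, 1:3] = 1
    labels[2:4, 2:4, 8:10] = 2
    vol = LabeledVolume(labels, (1, 1, 1))
    ch = np.zeros((6, 6, 12))
    ch[labels == 1] = 150.0
    ch[labels == 2] = 5.0
    assert subset_calls(vol, ch, "auto") == {1: "CD163+", 2: "CD163-"}
    # exactly at an absolute threshold: negative (strict)
    assert subset_calls(vol, ch, 150.0)[1] == "CD163-"


# --------------------------------------------------------------- cohort


def test_cohort_table_shapes_and_means():
    records = [
        MacrophageRecord(
            id=i, volume_um3=float(10 + i), centroid_um=(1, 2, 3),
            identity="DRG", association="perivascular" if i < 3 else "parenchymal",
            contact_area_um2=float(i), assigned_segment="vein" if i < 3 else "none",
            subset="CD163+",
        )
        for i in range(5)
    ]
    per_object, per_group = cohort_table(records)
    assert len(per_object) == 5
    assert per_group["n"].sum() == 5
    g = per_group.set_index(["identity", "association", "assigned_segment", "subset"])
    assert g.loc[("DRG", "perivascular", "vein", "CD163+"), "volume_um3_mean"] == \
        pytest.approx(np.mean([10, 11, 12]))


def test_cohort_table_empty():
    per_object, per_group = cohort_table([])
    assert per_object.empty and "volume_um3" in per_object.columns
    assert per_group.empty
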