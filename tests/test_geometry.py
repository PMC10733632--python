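"""Geometry primitives against brute-force oracles and analytic shapes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from perimac.geometry import (
    LabeledVolume,
    boundary_voxels,
    branch_diameters,
    centroid,
    connected_components,
    contact_area,
    distance_to_nearest,
    local_diameter_map,
    object_volume,
    percent_volume,
    region_overlap_fraction,
    surface_coverage,
)


def random_mask(rng, shape=(8, 8, 8), p=0.3):
    return rng.random(shape) < p


def sphere_mask(shape, center_vox, radius_vox):
    zz, yy, xx = np.indices(shape)
    return (
        (zz - center_vox[0]) ** 2
        + (yy - center_vox[1]) ** 2
        + (xx - center_vox[2]) ** 2
    ) <= radius_vox**2


# ------------------------------------------------------- components


@pytest.mark.parametrize("connectivity,n_expected", [(26, 1), (18, 1), (6, 2)])
def test_diagonal_voxel_adjacency(connectivity, n_expected):
    """Two corner-touching voxels are one component under 26/18, two
    under 6-connectivity."""
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[0, 0, 0] = mask[1, 1, 0] = True  # share an edge
    lv = connected_components(mask, connectivity)
    assert lv.labels.max() == n_expected


@pytest.mark.parametrize("connectivity", [6, 18, 26])
@pytest.mark.parametrize("seed", range(5))
def test_components_match_flood_fill(connectivity, seed):
    rng = np.random.default_rng(seed)
    mask = random_mask(rng, (10, 10, 10), 0.35)
    got = connected_components(mask, connectivity).labels
    want = oracles.flood_fill_components(mask, connectivity)
    assert np.array_equal(got, want)


# ------------------------------------------------------ volume / percent


def test_object_volume_arithmetic():
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[0, 0, :2] = 1  # 2 voxels
    vol = LabeledVolume(labels, (1.0, 0.5, 0.5))
    assert object_volume(vol, 1) == pytest.approx(0.5)
    with pytest.raises(KeyError):
        object_volume(vol, 9)


def test_percent_volume_quarter():
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[:1] = 1  # 16 of 64 voxels
    tissue = np.ones((4, 4, 4), dtype=bool)
    assert percent_volume(LabeledVolume(labels, (1, 1, 1)), tissue) == 25.0
    with pytest.raises(ValueError):
        percent_volume(LabeledVolume(labels, (1, 1, 1)), np.zeros((4, 4, 4), bool))


# ------------------------------------------------------------- contact


def test_contact_single_face_and_diagonal():
    a = np.zeros((3, 3, 3), bool)
    b = np.zeros((3, 3, 3), bool)
    a[1, 1, 0] = True
    b[1, 1, 1] = True
    assert contact_area(a, b, (1, 1, 1)) == pytest.approx(1.0)
    b[:] = False
    b[0, 0, 1] = True  # only diagonal
    assert contact_area(a, b, (1, 1, 1)) == 0.0


def test_contact_slab_anisotropy_aware():
    """A 3×3 flat slab face-on to a wall at 0.5 μm isotropic: 9 faces of
    0.25 μm² each."""
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    a[1, :3, :3] = True
    b[2, :3, :3] = True
    assert contact_area(a, b, (0.5, 0.5, 0.5)) == pytest.approx(2.25)


def test_contact_overlap_rejected():
    a = np.ones((2, 2, 2), bool)
    with pytest.raises(ValueError, match="overlap"):
        contact_area(a, a, (1, 1, 1))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_contact_symmetric_and_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    a = random_mask(rng, (6, 6, 6), 0.3)
    b = np.logical_and(random_mask(rng, (6, 6, 6), 0.3), ~a)
    spacing = tuple(rng.uniform(0.3, 1.5, 3))
    ab = contact_area(a, b, spacing)
    assert ab == pytest.approx(contact_area(b, a, spacing))
    assert ab == pytest.approx(oracles.contact_area_um2(a, b, spacing))


def test_contact_scaling_with_spacing(rng):
    a = random_mask(rng, (6, 6, 6), 0.3)
    b = np.logical_and(random_mask(rng, (6, 6, 6), 0.4), ~a)
    base = contact_area(a, b, (1, 1, 1))
    assert contact_area(a, b, (2, 2, 2)) == pytest.approx(4 * base)


# ------------------------------------------------- centroid / distance


def test_centroid_conventions():
    labels = np.zeros((6, 6, 6), dtype=np.int32)
    labels[2, 3, 4] = 1
    got = centroid(LabeledVolume(labels, (0.5, 0.5, 0.5)), 1)
    assert np.allclose(got, [(2 + 0.5) * 0.5, (3 + 0.5) * 0.5, (4 + 0.5) * 0.5])
    labels[1:4, 1:4, 1:4] = 2
    got = centroid(LabeledVolume(labels, (1, 1, 1)), 2)
    assert np.allclose(got, [2.5, 2.5, 2.5])


def test_distance_axis_aligned_and_containment():
    target = np.zeros((8, 8, 8), bool)
    target[:, :, 0] = True
    # point at the centre of voxel (4, 4, 3): 3 voxels from the wall
    assert distance_to_nearest(
        np.array([4.5, 4.5, 3.5]), target, (1, 1, 1)
    ) == pytest.approx(3.0)
    assert distance_to_nearest(np.array([4.5, 4.5, 0.5]), target, (1, 1, 1)) == 0.0
    with pytest.raises(ValueError):
        distance_to_nearest(np.array([0.0, 0, 0]), np.zeros((2, 2, 2), bool), (1, 1, 1))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_distance_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    target = random_mask(rng, (7, 7, 7), 0.1)
    if not target.any():
        target[0, 0, 0] = True
    spacing = tuple(rng.uniform(0.4, 1.2, 3))
    point = rng.uniform(0, 4, 3)
    got = distance_to_nearest(point, target, spacing)
    want = oracles.min_distance_um(point, target, spacing)
    vidx = tuple(int(point[i] // spacing[i]) for i in range(3))
    inside = all(0 <= vidx[i] < 7 for i in range(3)) and target[vidx]
    assert got == pytest.approx(0.0 if inside else want)


# --------------------------------------------------- overlap fraction


def test_region_overlap_fraction_counting():
    labels = np.zeros((5, 5, 5), dtype=np.int32)
    labels[0, 0, :5] = 1
    labels[1, 0, :5] = 1  # 10 voxels
    region = np.zeros((5, 5, 5), bool)
    region[0, 0, :3] = True  # 3 of them inside
    vol = LabeledVolume(labels, (1, 1, 1))
    assert region_overlap_fraction(vol, 1, region) == pytest.approx(0.30)
    assert region_overlap_fraction(vol, 1, np.ones_like(region)) == 1.0
    assert region_overlap_fraction(vol, 1, np.zeros_like(region)) == 0.0


# ----------------------------------------------------------- diameter


@pytest.mark.parametrize("radius_um", [1.0, 2.5, 5.0, 10.0])
def test_cylinder_diameter_within_one_voxel(radius_um):
    """Voxelized straight cylinder: medial-axis diameter within one
    voxel spacing of the analytic value."""
    spacing = (0.5, 0.5, 0.5)
    r_vox = radius_um / 0.5
    n = int(2 * r_vox) + 8
    zz = 40
    yy, xx = np.indices((n, n))
    disc = ((yy - n / 2) ** 2 + (xx - n / 2) ** 2) <= r_vox**2
    mask = np.broadcast_to(disc, (zz, n, n)).copy()
    labels = mask.astype(np.int32)
    d = branch_diameters(LabeledVolume(labels, spacing))[1]
    assert abs(d - 2 * radius_um) <= 0.5 + 1e-9


def test_thin_line_and_sphere_diameter():
    spacing = (0.5, 0.5, 0.5)
    labels = np.zeros((20, 9, 9), dtype=np.int32)
    labels[:, 4, 4] = 1
    d = branch_diameters(LabeledVolume(labels, spacing))[1]
    assert d <= 1.0
    r_vox = 8
    mask = sphere_mask((20, 20, 20), (10, 10, 10), r_vox)
    dm, _ = local_diameter_map(mask, (1, 1, 1))
    assert abs(dm[10, 10, 10] - 2 * r_vox) <= 1.0


# ----------------------------------------------------------- coverage


def test_surface_coverage_limits_and_oracle(rng):
    vessel = sphere_mask((12, 12, 12), (6, 6, 6), 3)
    surface = boundary_voxels(vessel)
    shell = np.logical_and(
        sphere_mask((12, 12, 12), (6, 6, 6), 5), ~vessel
    )
    assert surface_coverage(surface, shell) == 100.0
    assert surface_coverage(surface, np.zeros_like(shell)) == 0.0
    half = shell.copy()
    half[:, :6, :] = False
    got = surface_coverage(surface, half)
    want = oracles.surface_coverage_pct(surface, half)
    assert got == pytest.approx(want)
    assert 25 < got < 75
    with pytest.raises(ValueError):
        surface_coverage(np.zeros_like(shell), shell)


# -------------------------------------------------- randomized battery


@pytest.mark.parametrize("seed", range(8))
def test_random_volume_oracle_battery(seed):
    """Volumes, centroids and overlaps all equal first-principles
    counting on random small volumes."""
    rng = np.random.default_rng(100 + seed)
    mask = random_mask(rng, (9, 9, 9), 0.25)
    if not mask.any():
        mask[4, 4, 4] = True
    spacing = tuple(rng.uniform(0.3, 1.2, 3))
    lv = connected_components(mask, 26, spacing)
    region = random_mask(rng, (9, 9, 9), 0.5)
    for oid in lv.ids[:3]:
        m = lv.labels == oid
        assert object_volume(lv, int(oid)) == pytest.approx(
            oracles.volume_um3(m, spacing)
        )
        assert np.allclose(centroid(lv, int(oid)), oracles.centroid_um(m, spacing))
        assert region_overlap_fraction(lv, int(oid), region) == pytest.approx(
            oracles.overlap_fraction(m, region)
        )
    tissue = random_mask(rng, (9, 9, 9), 0.7)
    if tissue.any():
        assert percent_volume(lv, tissue) == pytest.approx(
            oracles.percent_volume(mask, tissue)
        )
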