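import numpy as np
import pytest

from perimac.simulate import EMSimConfig, TissueSimConfig, generate_em_scene, generate_tissue


def small_tissue_config(seed: int = 11, **overrides) -> TissueSimConfig:
    """A scaled-down tissue (60 μm cube, ~20 macrophages) that still
    realizes all five vessel classes and both regions; fast enough for
    unit tests."""
    base = dict(
        volume_shape=(140, 140, 140),
        n_branches_per_class={
            "artery": 1, "a-cap": 2, "capillary": 2, "v-cap": 2, "vein": 1,
        },
        radius_range_per_class={
            "artery": (5.5, 6.5),
            "a-cap": (1.5, 2.5),
            "capillary": (1.5, 2.5),
            "v-cap": (1.5, 2.5),
            "vein": (5.5, 6.5),
        },
        n_macrophages={
            "DRG/perivascular/CD163+": 5,
            "DRG/perivascular/CD163-": 5,
            "DRG/parenchymal/CD163+": 3,
            "DRG/parenchymal/CD163-": 3,
            "fiber/perivascular/CD163+": 1,
            "fiber/parenchymal/CD163-": 3,
        },
        seed=seed,
    )
    base.update(overrides)
    return TissueSimConfig(**base)


@pytest.fixture(scope="session")
def small_tissue():
    return generate_tissue(small_tissue_config())


@pytest.fixture(scope="session")
def small_tissue_clean():
    """Same layout, zero intensity noise."""
    return generate_tissue(small_tissue_config(noise_sd=0.0))


@pytest.fixture(scope="session")
def em_scene_default():
    return generate_em_scene(EMSimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def expert_annotation(vessel_labels, truth, axis=0):
    """Construct the 2D class annotation an expert would draw over a
    projection: each pixel goes to the branch that most depends on it
    (its column voxel count normalized by the branch's total projected
    footprint), so thin vessels are traced over the large ones they
    cross. Returns (annotation, worst voxel-weighted ownership)."""
    from perimac.vessel_typing import CLASS_CODES

    shape2 = tuple(
        s for i, s in enumerate(vessel_labels.shape) if i != axis
    )
    nb = int(truth.branch_id.max())
    weight = np.zeros((nb + 1,) + shape2, dtype=np.float64)
    counts = np.zeros_like(weight)
    for _, row in truth.iterrows():
        c = (vessel_labels == row.branch_id).sum(axis=axis).astype(float)
        counts[int(row.branch_id)] = c
        weight[int(row.branch_id)] = c / (c > 0).sum()
    owner = weight.argmax(axis=0)
    # fraction of each branch's voxels lying under pixels it owns; the
    # branch majority vote is guaranteed when this exceeds 0.5
    own_frac = min(
        counts[b][owner == b].sum() / counts[b].sum()
        for b in truth.branch_id.astype(int)
    )
    class_of = {
        int(r.branch_id): CLASS_CODES[r.vessel_class] for _, r in truth.iterrows()
    }
    class_of[0] = 0
    ann = np.vectorize(class_of.get)(owner).astype(np.uint8)
    return ann, float(own_frac)


def best_expert_annotation(vessel_labels, truth):
    """Annotate the projection in which the vessels are most
    distinguishable, as an annotator would choose their view. Returns
    (annotation, axis)."""
    best = max(
        (expert_annotation(vessel_labels, truth, axis) + (axis,) for axis in range(3)),
        key=lambda t: t[1],
    )
    return best[0], best[2]
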