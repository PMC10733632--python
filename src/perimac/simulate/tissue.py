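"""Ground-truthed synthetic tissue volumes.

Generates a voxelized vascular network zonated along the arteriovenous
axis, region masks (soma-rich vs fiber-rich), and macrophages of
controlled identity, vascular association, subset and shape — together
with a truth table recording, for every object, the quantity each
downstream classification rule consumes. Vessels are capsule primitives
(straight tubes with hemispherical caps): the downstream rules depend
only on class, diameter, marker status and adjacency, not on realistic
branching topology.

Layout conventions (physical μm, axes (z, y, x)):

* arteries enter from the z = 0 face (the nerve-fiber side) and run
  toward the interior;
* veins run parallel to the far z face (the tissue surface), their
  centrelines within ``surface_margin_um`` of it;
* capillary-calibre branches (a-cap, capillary, v-cap) sit in the
  interior, clear of the surface shell;
* the fiber-rich region occupies the low-z slab, the soma-rich region
  the rest.

Randomness: each stage draws from its own ``default_rng([seed, k])``
stream (k = 0 vessels, 1 macrophages, 2 channel noise), so a stage can
be regenerated independently and the full volume is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..geometry import LabeledVolume, RegionMasks, contact_area
from ..vessel_typing import largest_gap_threshold
from .config import MARKERS, SHAPES, VESSEL_CLASSES, TissueSimConfig

__all__ = [
    "VesselTree",
    "MacrophagePopulation",
    "SyntheticTissue",
    "generate_vessel_tree",
    "generate_regions",
    "generate_macrophages",
    "generate_tissue",
]

# extra clearance (μm) beyond the default 15 μm surface shell so that
# interior branch centrelines are unambiguously not "on the surface"
_INTERIOR_MARGIN_UM = 16.0

_CHANNEL_ORDER = list(MARKERS) + ["tracer", "CD163"]


@dataclass
class VesselTree:
    vessels: LabeledVolume
    truth: pd.DataFrame
    channels: dict[str, np.ndarray]  # marker name -> float volume (noise-free)


@dataclass
class MacrophagePopulation:
    macrophages: LabeledVolume
    truth: pd.DataFrame
    channels: dict[str, np.ndarray]  # "tracer", "CD163" (noise-free)


@dataclass
class SyntheticTissue:
    config: TissueSimConfig
    vessels: LabeledVolume
    vessel_truth: pd.DataFrame
    macrophages: LabeledVolume
    macrophage_truth: pd.DataFrame
    regions: RegionMasks
    tissue_mask: np.ndarray
    channels: dict[str, np.ndarray]  # with noise applied


# ---------------------------------------------------------------- capsules


def _capsule_voxels(shape, spacing, a, b, radius):
    """Binary mask (in a bounding subvolume) of voxels whose centre lies
    within ``radius`` of segment a–b. Returns (lo_index, submask)."""
    sp = np.asarray(spacing, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo_phys = np.minimum(a, b) - radius
    hi_phys = np.maximum(a, b) + radius
    lo = np.maximum(np.floor(lo_phys / sp).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(hi_phys / sp).astype(int) + 2, np.asarray(shape))
    if np.any(lo >= hi):
        return lo, np.zeros((0, 0, 0), dtype=bool)
    grids = np.meshgrid(
        *[(np.arange(lo[i], hi[i]) + 0.5) * sp[i] for i in range(3)],
        indexing="ij",
    )
    p = np.stack(grids, axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        d2 = ((p - a) ** 2).sum(axis=-1)
    else:
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        d2 = ((p - proj) ** 2).sum(axis=-1)
    return lo, d2 <= radius * radius


def _paint(full: np.ndarray, lo, sub: np.ndarray, value) -> None:
    if sub.size == 0:
        return
    sl = tuple(slice(lo[i], lo[i] + sub.shape[i]) for i in range(3))
    full[sl][sub] = value


def _read(full: np.ndarray, lo, sub_shape) -> np.ndarray:
    sl = tuple(slice(lo[i], lo[i] + sub_shape[i]) for i in range(3))
    return full[sl]


# ------------------------------------------------------------ vessel tree


def generate_vessel_tree(
    config: TissueSimConfig, rng: np.random.Generator | None = None
) -> VesselTree:
    """Voxelize a vascular network of all configured classes and paint
    the endothelial/mural marker channels (noise-free).

    Truth rows record, per branch: class, constructed diameter, and the
    marker positivity implied by the configured class-mean profile
    (split by the largest gap over class means, matching the automatic
    thresholding policy of the classifier).
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 0])
    shape = tuple(config.volume_shape)
    sp = np.asarray(config.voxel_spacing)
    extent = np.asarray(shape) * sp  # physical size (μm)

    labels = np.zeros(shape, dtype=np.uint16)
    occupied = np.zeros(shape, dtype=bool)

    # truth marker status from the configured profile
    marker_pos: dict[str, set[str]] = {}
    for marker, prof in config.marker_profile.items():
        means = [prof[c] for c in VESSEL_CLASSES]
        thr = largest_gap_threshold(np.asarray(means))
        marker_pos[marker] = {c for c in VESSEL_CLASSES if prof[c] > thr}

    rows = []
    branch_id = 0
    for cls in VESSEL_CLASSES:
        n = config.n_branches_per_class.get(cls, 0)
        if n == 0:
            continue
        lo_r, hi_r = config.radius_range_per_class[cls]
        for i in range(n):
            radius = float(rng.uniform(lo_r, hi_r))
            placed = False
            for _attempt in range(200):
                a, b = _propose_branch(cls, radius, extent, config, rng)
                lo, sub = _capsule_voxels(shape, config.voxel_spacing, a, b, radius)
                if sub.size == 0 or not sub.any():
                    continue
                occ = _read(occupied, lo, sub.shape)
                if np.logical_and(sub, occ).any():
                    continue
                branch_id += 1
                _paint(labels, lo, sub, branch_id)
                # keep branches non-touching: block a 1-voxel halo
                from scipy import ndimage as _ndi

                halo = _ndi.binary_dilation(
                    sub, _ndi.generate_binary_structure(3, 3)
                )
                occ_view = _read(occupied, lo, sub.shape)
                occ_view |= halo
                rows.append(
                    {
                        "branch_id": branch_id,
                        "vessel_class": cls,
                        "radius_um": radius,
                        "diameter_um": 2.0 * radius,
                        "surface": cls == "vein",
                        "n_voxels": int(sub.sum()),
                        **{
                            f"{m}_pos": cls in marker_pos.get(m, set())
                            for m in config.marker_profile
                        },
                        "axis_a_z": a[0], "axis_a_y": a[1], "axis_a_x": a[2],
                        "axis_b_z": b[0], "axis_b_y": b[1], "axis_b_x": b[2],
                    }
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place {cls} branch {i} (radius {radius:.2f} μm) "
                    "without overlap; volume too small or too crowded"
                )

    channels = {}
    for marker, prof in config.marker_profile.items():
        ch = np.zeros(shape, dtype=np.float64)
        for row in rows:
            ch[labels == row["branch_id"]] = prof[row["vessel_class"]]
        channels[marker] = ch

    truth = pd.DataFrame(rows)
    return VesselTree(
        vessels=LabeledVolume(labels.astype(np.int32), config.voxel_spacing),
        truth=truth,
        channels=channels,
    )


def _propose_branch(cls, radius, extent, config, rng):
    """Random capsule endpoints (physical μm) for one branch of a class."""
    lz, ly, lx = extent
    margin = _INTERIOR_MARGIN_UM + radius + 1.0
    if margin >= ly - margin or margin >= lx - margin:
        raise ValueError(
            f"volume too small for a {cls} branch of radius {radius:.2f} μm: "
            f"lateral extent {ly:.1f}×{lx:.1f} μm cannot hold margin {margin:.1f} μm"
        )
    if cls == "artery":
        # enters from the nerve-fiber face (z = 0), runs into the interior
        y = rng.uniform(margin, ly - margin)
        x = rng.uniform(margin, lx - margin)
        z_end = rng.uniform(0.55, 0.70) * lz
        return np.array([0.0, y, x]), np.array([z_end, y, x])
    if cls == "vein":
        # runs parallel to and just under the far z face (tissue surface)
        z = lz - config.surface_margin_um
        x = rng.uniform(margin, lx - margin)
        y0 = rng.uniform(2.0, 0.25 * ly)
        y1 = rng.uniform(0.75 * ly, ly - 2.0)
        return np.array([z, y0, x]), np.array([z, y1, x])
    # capillary-calibre branch in the interior box
    lo_box = np.full(3, margin)
    hi_box = extent - margin
    for _ in range(50):
        a = rng.uniform(lo_box, hi_box)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = rng.uniform(15.0, 30.0)
        b = a + length * d
        if np.all(b > lo_box) and np.all(b < hi_box):
            return a, b
    # fall back to a shorter axis-aligned segment
    a = rng.uniform(lo_box, hi_box)
    b = a.copy()
    b[1] = min(a[1] + 15.0, hi_box[1])
    return a, b


# ---------------------------------------------------------------- regions


def generate_regions(config: TissueSimConfig) -> RegionMasks:
    """Partition the volume into fiber-rich (low z, the side arteries
    enter from) and soma-rich (high z) slabs, optionally separated by an
    unassigned gap band."""
    shape = tuple(config.volume_shape)
    nz = shape[0]
    split = config.region_split_fraction
    gap = config.region_gap_fraction
    z = np.arange(nz)
    fiber_hi = int(round((split - gap / 2) * nz))
    soma_lo = int(round((split + gap / 2) * nz))
    fiber = np.zeros(shape, dtype=bool)
    soma = np.zeros(shape, dtype=bool)
    fiber[z < fiber_hi] = True
    soma[z >= soma_lo] = True
    return RegionMasks(soma_rich=soma, fiber_rich=fiber)


# ------------------------------------------------------------ macrophages


def _shape_voxels(shape_name, center, r_um, vol_shape, spacing, rng):
    """Rasterize one macrophage body; returns (lo, submask)."""
    sp = np.asarray(spacing)
    if shape_name == "sphere":
        return _capsule_voxels(vol_shape, spacing, center, center, r_um)
    if shape_name == "prolate":
        # cigar: a capsule of half-length ~1.2 r along an axis-aligned
        # direction, tube radius scaled to conserve volume roughly
        axis = np.zeros(3)
        axis[rng.integers(0, 3)] = 1.0
        half = 1.2 * r_um
        rr = 0.8 * r_um
        return _capsule_voxels(
            vol_shape, spacing, center - half * axis, center + half * axis, rr
        )
    if shape_name == "spider":
        # sphere core plus 3–6 thin random-direction arms
        core_r = 0.75 * r_um
        lo, sub = _capsule_voxels(vol_shape, spacing, center, center, core_r)
        pieces = [(lo, sub)]
        n_arms = int(rng.integers(3, 7))
        arm_r = 1.2 * float(np.mean(sp))  # ≲ 1.5 voxels thick
        for _ in range(n_arms):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            tip = center + 2.2 * r_um * d
            pieces.append(
                _capsule_voxels(vol_shape, spacing, center, tip, arm_r)
            )
        # merge pieces into a common bounding box
        los = np.array([p[0] for p in pieces if p[1].size])
        his = np.array(
            [p[0] + np.asarray(p[1].shape) for p in pieces if p[1].size]
        )
        lo_all = los.min(axis=0)
        hi_all = his.max(axis=0)
        merged = np.zeros(hi_all - lo_all, dtype=bool)
        for plo, psub in pieces:
            if psub.size == 0:
                continue
            off = plo - lo_all
            sl = tuple(
                slice(off[i], off[i] + psub.shape[i]) for i in range(3)
            )
            merged[sl] |= psub
        return lo_all, merged
    raise ValueError(f"unknown shape {shape_name!r}")


def _local_contact_by_branch(mac_lo, mac_sub, vessel_labels, spacing):
    """Contact area of a macrophage submask with each vessel branch that
    appears in the (1-voxel expanded) bounding box. Returns dict id→μm²."""
    shape = vessel_labels.shape
    lo = np.maximum(mac_lo - 1, 0)
    hi = np.minimum(mac_lo + np.asarray(mac_sub.shape) + 1, np.asarray(shape))
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    ves = vessel_labels[sl]
    mac = np.zeros(ves.shape, dtype=bool)
    off = mac_lo - lo
    msl = tuple(slice(off[i], off[i] + mac_sub.shape[i]) for i in range(3))
    mac[msl] = mac_sub
    out: dict[int, float] = {}
    for bid in np.unique(ves):
        if bid == 0:
            continue
        out[int(bid)] = contact_area(mac, ves == bid, spacing)
    return out


def place_perivascular(
    vessel_tree: VesselTree,
    target_class: str,
    shape_name: str,
    r_um: float,
    contact_band_um2: tuple[float, float],
    occupied: np.ndarray,
    rng: np.random.Generator,
    region_mask: np.ndarray | None = None,
    region_min_fraction: float = 0.8,
    max_attempts: int = 400,
):
    """Place one macrophage touching a branch of ``target_class`` with a
    realized contact area inside ``contact_band_um2``.

    Constructive placement: pick a random point on the branch axis, push
    the body outward along a perpendicular direction, then search over
    penetration depths; the realized contact area is verified by face
    counting and recorded as-is (discretization makes exact targets
    unattainable). Returns (lo, submask, realized_contact, branch_id)
    or raises after bounded retries.
    """
    cfg_sp = vessel_tree.vessels.spacing
    shape3 = vessel_tree.vessels.labels.shape
    cand = vessel_tree.truth[vessel_tree.truth.vessel_class == target_class]
    if cand.empty:
        raise RuntimeError(f"no branch of class {target_class!r} available")
    lo_c, hi_c = contact_band_um2
    for _attempt in range(max_attempts):
        row = cand.iloc[int(rng.integers(len(cand)))]
        a = np.array([row.axis_a_z, row.axis_a_y, row.axis_a_x])
        b = np.array([row.axis_b_z, row.axis_b_y, row.axis_b_x])
        t = rng.uniform(0.1, 0.9)
        p = a + t * (b - a)
        axis = b - a
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([1.0, 0, 0])
        u = rng.normal(size=3)
        u -= (u @ axis) * axis
        un = np.linalg.norm(u)
        if un < 1e-6:
            continue
        u /= un
        for depth in np.linspace(0.3, 0.8 * r_um, 7):
            center = p + u * (row.radius_um + r_um - depth)
            if np.any(center < 0) or np.any(
                center >= np.asarray(shape3) * np.asarray(cfg_sp)
            ):
                continue
            lo, sub = _shape_voxels(shape_name, center, r_um, shape3, cfg_sp, rng)
            if sub.size == 0 or not sub.any():
                continue
            ves = _read(vessel_tree.vessels.labels, lo, sub.shape)
            body = np.logical_and(sub, ves == 0)  # carve out the vessel
            if body.sum() < 30:
                continue
            occ = _read(occupied, lo, body.shape)
            if np.logical_and(body, occ).any():
                continue  # collision with another macrophage: redraw
            contacts = _local_contact_by_branch(
                lo, body, vessel_tree.vessels.labels, cfg_sp
            )
            others = {k: v for k, v in contacts.items() if k != row.branch_id}
            if any(v > 0 for v in others.values()):
                continue  # touches a second branch: ambiguous, try deeper/new
            realized = contacts.get(int(row.branch_id), 0.0)
            if not (lo_c <= realized <= hi_c):
                continue
            if region_mask is not None:
                reg = _read(region_mask, lo, body.shape)
                frac = np.logical_and(body, reg).sum() / body.sum()
                if frac < region_min_fraction:
                    break  # wrong side of the tissue: new position
            return lo, body, float(realized), int(row.branch_id)
    raise RuntimeError(
        f"failed to place perivascular macrophage on {target_class!r} "
        f"with contact in {contact_band_um2} μm² after {max_attempts} attempts"
    )


def place_parenchymal(
    vessel_distance_um: np.ndarray,
    clearance_um: float,
    shape_name: str,
    r_um: float,
    occupied: np.ndarray,
    spacing,
    rng: np.random.Generator,
    region_mask: np.ndarray | None = None,
    region_min_fraction: float = 0.8,
    max_attempts: int = 200,
):
    """Place one macrophage with every voxel at least ``clearance_um``
    from the vasculature (checked against the precomputed vessel EDT)."""
    shape3 = vessel_distance_um.shape
    extent = np.asarray(shape3) * np.asarray(spacing)
    pad = r_um + 1.0
    for _attempt in range(max_attempts):
        center = rng.uniform([pad] * 3, extent - pad)
        lo, sub = _shape_voxels(shape_name, center, r_um, shape3, spacing, rng)
        if sub.size == 0 or not sub.any():
            continue
        dist = _read(vessel_distance_um, lo, sub.shape)
        if dist[sub].min() < clearance_um:
            continue
        occ = _read(occupied, lo, sub.shape)
        if np.logical_and(sub, occ).any():
            continue
        if region_mask is not None:
            reg = _read(region_mask, lo, sub.shape)
            if np.logical_and(sub, reg).sum() / sub.sum() < region_min_fraction:
                continue
        return lo, sub
    raise RuntimeError(
        f"failed to place parenchymal macrophage (clearance {clearance_um} μm) "
        f"after {max_attempts} attempts"
    )


def generate_macrophages(
    config: TissueSimConfig,
    vessel_tree: VesselTree,
    regions: RegionMasks | None = None,
    rng: np.random.Generator | None = None,
) -> MacrophagePopulation:
    """Place the configured macrophage cohort and paint the tracer and
    CD163 channels (noise-free).

    Perivascular cells are planted touching one branch with a verified
    contact area inside ``contact_target_um2`` and inherit the tracer
    mean of the contacted class (the arteriovenous uptake gradient);
    parenchymal cells keep ``parenchymal_clearance_um`` from all vessels
    and carry the parenchymal uptake level. Identities are controlled by
    placing each body almost entirely inside its target region.
    """
    from scipy import ndimage as _ndi

    rng = rng if rng is not None else np.random.default_rng([config.seed, 1])
    regions = regions if regions is not None else generate_regions(config)
    shape = tuple(config.volume_shape)
    sp = config.voxel_spacing

    labels = np.zeros(shape, dtype=np.int32)
    occupied = vessel_tree.vessels.labels > 0
    # halo so macrophages never touch each other or vessels unintentionally
    vessel_edt = _ndi.distance_transform_edt(
        vessel_tree.vessels.labels == 0, sampling=sp
    )

    tracer = np.full(shape, config.tracer_background, dtype=np.float64)
    cd163 = np.zeros(shape, dtype=np.float64)

    # perivascular target classes cycled per identity; arteries reach the
    # fiber-rich slab (they enter from that face), so fiber-identity
    # perivascular cells are planted on arteries
    peri_cycle = {"DRG": list(VESSEL_CLASSES), "fiber": ["artery"]}
    present = set(vessel_tree.truth.vessel_class.unique())
    peri_cycle = {
        k: [c for c in v if c in present] for k, v in peri_cycle.items()
    }
    cycle_pos = {k: 0 for k in peri_cycle}
    shape_cycle = 0

    rows = []
    mac_id = 0
    # deterministic placement order: perivascular before parenchymal (the
    # space along the vessel walls fills up first) and large-footprint
    # shapes before compact ones, so crowding cannot strand a spider
    cells: list[tuple[str, str]] = []
    for key in sorted(config.n_macrophages):
        for _i in range(config.n_macrophages[key]):
            shape_name = config.shape_repertoire[
                shape_cycle % len(config.shape_repertoire)
            ]
            shape_cycle += 1
            cells.append((key, shape_name))
    shape_rank = {"spider": 0, "prolate": 1, "sphere": 2}
    cells.sort(
        key=lambda c: (
            0 if "/perivascular/" in c[0] else 1,
            shape_rank.get(c[1], 3),
            c[0],
        )
    )
    for key, shape_name in cells:
        identity, assoc, subset = key.split("/")
        region_mask = (
            regions.soma_rich if identity == "DRG" else regions.fiber_rich
        )
        if True:
            r_um = float(rng.uniform(*config.macrophage_radius_range))
            if assoc == "perivascular":
                classes = peri_cycle[identity]
                if not classes:
                    raise RuntimeError(
                        f"no vessel class available for {key!r} placement"
                    )
                cls = classes[cycle_pos[identity] % len(classes)]
                cycle_pos[identity] += 1
                lo, body, realized, bid = place_perivascular(
                    vessel_tree, cls, shape_name, r_um,
                    config.contact_target_um2, occupied, rng,
                    region_mask=region_mask,
                )
                uptake = config.tracer_gradient[cls]
                contacted_class = cls
                clearance = 0.0
            else:
                lo, body = place_parenchymal(
                    vessel_edt, config.parenchymal_clearance_um, shape_name,
                    r_um, occupied, sp, rng, region_mask=region_mask,
                )
                realized, bid, contacted_class = 0.0, 0, ""
                uptake = config.parenchymal_uptake
                dist = _read(vessel_edt, lo, body.shape)
                clearance = float(dist[body].min())
            mac_id += 1
            _paint(labels, lo, body, mac_id)
            halo = _ndi.binary_dilation(
                body, _ndi.generate_binary_structure(3, 3)
            )
            occ_view = _read(occupied, lo, body.shape)
            occ_view |= halo
            _paint(tracer, lo, body, uptake)
            _paint(cd163, lo, body, config.subset_intensity[subset])
            rows.append(
                {
                    "object_id": mac_id,
                    "identity": identity,
                    "association": assoc,
                    "subset": subset,
                    "shape": shape_name,
                    "contact_area_um2": realized,
                    "contacted_branch_id": bid,
                    "contacted_class": contacted_class,
                    "clearance_um": clearance,
                    "tracer_mean": uptake,
                    "volume_um3": float(body.sum()) * float(np.prod(sp)),
                    "n_voxels": int(body.sum()),
                }
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "object_id", "identity", "association", "subset", "shape",
            "contact_area_um2", "contacted_branch_id", "contacted_class",
            "clearance_um", "tracer_mean", "volume_um3", "n_voxels",
        ],
    )
    return MacrophagePopulation(
        macrophages=LabeledVolume(labels, sp),
        truth=truth,
        channels={"tracer": tracer, "CD163": cd163},
    )


# ------------------------------------------------------------- full tissue


def generate_tissue(config: TissueSimConfig) -> SyntheticTissue:
    """Generate the complete synthetic volume: vessels, regions,
    macrophages, and all intensity channels with additive Gaussian noise
    (clipped at zero) applied in a fixed channel order."""
    tree = generate_vessel_tree(config)
    regions = generate_regions(config)
    pop = generate_macrophages(config, tree, regions)

    channels = dict(tree.channels)
    channels.update(pop.channels)
    noise_rng = np.random.default_rng([config.seed, 2])
    if config.noise_sd > 0:
        for name in _CHANNEL_ORDER:
            if name in channels:
                channels[name] = np.clip(
                    channels[name]
                    + noise_rng.normal(0.0, config.noise_sd, channels[name].shape),
                    0.0,
                    None,
                )

    tissue_mask = np.ones(tuple(config.volume_shape), dtype=bool)
    return SyntheticTissue(
        config=config,
        vessels=tree.vessels,
        vessel_truth=tree.truth,
        macrophages=pop.macrophages,
        macrophage_truth=pop.truth,
        regions=regions,
        tissue_mask=tissue_mask,
        channels=channels,
    )
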