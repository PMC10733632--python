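"""Per-macrophage classification and quantification.

Implements the rule set used to type tissue macrophages against the
vasculature and tissue regions:

* identity — a macrophage with ≥ 30% of its volume inside the neuronal
  soma-rich region is a DRG macrophage; otherwise, with ≥ 30% in the
  fiber-rich region, a fiber macrophage; otherwise "other". The DRG
  rule is evaluated first, so a cell straddling both regions is DRG.
* vascular association — perivascular when the contact area with blood
  vessels reaches the threshold (10 μm² by default; the exact-threshold
  boundary is assigned perivascular), parenchymal otherwise.
* segment assignment — a perivascular macrophage belongs to the vessel
  class it shares the most contact area with; ties fall back to the
  class whose medial axis is nearest the cell centroid, and a residual
  tie is flagged unassigned.
* morphology — elongation and sparseness from the object's equivalent
  ellipsoid (second central moments of voxel centres in physical μm,
  radius² = 5 × eigenvalue, the uniform-solid-ellipsoid convention).
* uptake — mean tracer intensity over the object, normalized to the
  median intensity of the surrounding tissue (vessels and macrophages
  excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    LabeledVolume,
    RegionMasks,
    centroid,
    contact_area,
    distance_to_nearest,
    medial_voxels,
    region_overlap_fraction,
)
from .vessel_typing import (
    CLASS_CODES,
    VESSEL_CLASSES,
    VesselSegmentMap,
    resolve_threshold,
)

__all__ = [
    "MacrophageRecord",
    "classify_identity",
    "classify_association",
    "contact_by_class",
    "assign_segment",
    "morphology",
    "uptake",
    "subset_calls",
    "cohort_table",
    "RECORD_COLUMNS",
]


@dataclass
class MacrophageRecord:
    """All per-macrophage quantities emitted by the pipeline."""

    id: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    identity: str  # DRG | fiber | other
    association: str  # perivascular | parenchymal
    contact_area_um2: float
    contact_by_class_um2: dict[str, float] = field(default_factory=dict)
    assigned_segment: str = "none"
    distance_to_vessel_um: float = np.nan
    subset: str = "unknown"  # CD163+ | CD163- | unknown
    elongation: float = np.nan
    sparseness: float = np.nan
    mfi: dict[str, float] = field(default_factory=dict)
    uptake_fold: dict[str, float] = field(default_factory=dict)
    flag: str = "ok"


RECORD_COLUMNS = [
    "object_id", "volume_um3", "centroid_z", "centroid_y", "centroid_x",
    "identity", "association", "contact_area_um2", "assigned_segment",
    "distance_to_vessel_um", "subset", "elongation", "sparseness", "flag",
]


def classify_identity(
    macrophages: LabeledVolume,
    id: int,
    regions: RegionMasks,
    min_fraction: float = 0.30,
) -> str:
    """Region identity of one macrophage: DRG-first, then fiber, else other.

    The ≥ threshold is inclusive: a cell with exactly 30% of its volume
    in the soma-rich region is a DRG macrophage.
    """
    if region_overlap_fraction(macrophages, id, regions.soma_rich) >= min_fraction:
        return "DRG"
    if region_overlap_fraction(macrophages, id, regions.fiber_rich) >= min_fraction:
        return "fiber"
    return "other"


def classify_association(
    contact_area_um2: float, threshold_um2: float = 10.0
) -> str:
    """Perivascular iff the vessel contact area reaches the threshold
    (boundary inclusive), parenchymal otherwise."""
    return "perivascular" if contact_area_um2 >= threshold_um2 else "parenchymal"


def contact_by_class(
    mac_mask: np.ndarray,
    segment_map: VesselSegmentMap,
    spacing: tuple[float, float, float],
) -> dict[str, float]:
    """Contact area (μm²) of one macrophage with each vessel class."""
    return {
        cls: contact_area(mac_mask, segment_map.class_mask(cls), spacing)
        for cls in VESSEL_CLASSES
    }


def assign_segment(
    macrophages: LabeledVolume,
    id: int,
    segment_map: VesselSegmentMap,
    contacts: dict[str, float] | None = None,
) -> tuple[str, str]:
    """Vessel class a perivascular macrophage is most closely associated
    with: the class with maximal contact area; ties break to the class
    whose medial axis lies nearest the cell centroid; a residual tie is
    unassigned. Returns (class, flag).

    Raises when the object has no vessel contact at all — segment
    assignment is only defined for perivascular cells.
    """
    m = macrophages.require(id)
    if contacts is None:
        contacts = contact_by_class(m, segment_map, macrophages.spacing)
    best = max(contacts.values())
    if best <= 0:
        raise ValueError(
            f"object {id} has no vessel contact; segment assignment is "
            "defined for perivascular macrophages only"
        )
    tied = [c for c, v in contacts.items() if v == best]
    if len(tied) == 1:
        return tied[0], "ok"
    # tie-break on distance from the centroid to each class's medial axis
    c = centroid(macrophages, id)
    dists = {}
    for cls in tied:
        cmask = segment_map.class_mask(cls)
        skel = medial_voxels(cmask, macrophages.spacing)
        target = skel if skel.any() else cmask
        dists[cls] = distance_to_nearest(c, target, macrophages.spacing)
    dmin = min(dists.values())
    nearest = [c_ for c_, d in dists.items() if d == dmin]
    if len(nearest) == 1:
        return nearest[0], "ok"
    return "unassigned", "tie"


def morphology(
    macrophages: LabeledVolume, id: int
) -> tuple[float, float]:
    """Elongation and sparseness of one object.

    The equivalent ellipsoid is fitted from the second central moments
    of the voxel centres in physical μm; eigenvalues λ₁ ≥ λ₂ ≥ λ₃ give
    radii a ≥ b ≥ c via radius = √(5λ) (a uniform solid ellipsoid
    reproduces its own radii). Elongation = a/b (cigar-ness ≥ 1);
    sparseness = (4/3)π·a·b·c / object volume (spider-like shapes with
    thin arms give values well above 1).
    """
    m = macrophages.require(id)
    pts = (np.argwhere(m) + 0.5) * np.asarray(macrophages.spacing)
    if pts.shape[0] < 4:
        raise ValueError(
            f"object {id} has {pts.shape[0]} voxels; morphology needs ≥ 4"
        )
    cov = np.cov(pts.T, bias=True)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eig[2] <= 1e-12:
        kind = "linear" if eig[1] <= 1e-12 else "planar"
        raise ValueError(
            f"object {id} is degenerate ({kind}); its equivalent ellipsoid "
            "has a zero radius"
        )
    a, b, c = np.sqrt(5.0 * eig)
    vol = pts.shape[0] * macrophages.voxel_volume
    elongation = float(a / b)
    sparseness = float((4.0 / 3.0) * np.pi * a * b * c / vol)
    return elongation, sparseness


def uptake(
    macrophages: LabeledVolume,
    id: int,
    channel: np.ndarray,
    tissue_mask: np.ndarray,
    exclusion_masks: list[np.ndarray] | None = None,
    background_stat: str = "median",
) -> tuple[float, float]:
    """Tracer uptake of one object: (MFI, fold over tissue background).

    MFI is the mean channel intensity over the object's voxels; the
    background is the median (or mean) over tissue voxels excluding all
    macrophages and every exclusion mask (typically the vasculature).
    """
    if channel.shape != macrophages.labels.shape:
        raise ValueError("channel shape does not match the label volume")
    m = macrophages.require(id)
    mfi = float(channel[m].mean())
    bg_mask = np.logical_and(tissue_mask.astype(bool), macrophages.labels == 0)
    for excl in exclusion_masks or []:
        bg_mask &= ~excl.astype(bool)
    if not bg_mask.any():
        raise ValueError("background region is empty after exclusions")
    if background_stat == "median":
        bg = float(np.median(channel[bg_mask]))
    elif background_stat == "mean":
        bg = float(channel[bg_mask].mean())
    else:
        raise ValueError(f"unknown background statistic {background_stat!r}")
    if bg == 0:
        raise ValueError("tissue background intensity is zero; fold undefined")
    return mfi, mfi / bg


def subset_calls(
    macrophages: LabeledVolume,
    channel: np.ndarray,
    policy: float | str = "auto",
    positive_name: str = "CD163+",
    negative_name: str = "CD163-",
) -> dict[int, str]:
    """Subset call per object: positive iff its MFI strictly exceeds the
    threshold (absolute, or an automatic bimodal split over the object
    population's MFIs)."""
    if channel.shape != macrophages.labels.shape:
        raise ValueError("channel shape does not match the label volume")
    mfis = {
        int(i): float(channel[macrophages.labels == i].mean())
        for i in macrophages.ids
    }
    thr = resolve_threshold(np.array(list(mfis.values())), policy)
    return {
        i: (positive_name if v > thr else negative_name)
        for i, v in mfis.items()
    }


def cohort_table(
    records: list[MacrophageRecord],
    group_keys: tuple[str, ...] = ("identity", "association", "assigned_segment", "subset"),
    channels: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-object table plus grouped summary (mean, sd, n).

    Returns ``(per_object, per_group)``; with no records both tables are
    empty but carry the full header, and group sizes always sum to the
    cohort size.
    """
    rows = []
    for r in records:
        row = {
            "object_id": r.id,
            "volume_um3": r.volume_um3,
            "centroid_z": r.centroid_um[0],
            "centroid_y": r.centroid_um[1],
            "centroid_x": r.centroid_um[2],
            "identity": r.identity,
            "association": r.association,
            "contact_area_um2": r.contact_area_um2,
            "assigned_segment": r.assigned_segment,
            "distance_to_vessel_um": r.distance_to_vessel_um,
            "subset": r.subset,
            "elongation": r.elongation,
            "sparseness": r.sparseness,
            "flag": r.flag,
        }
        for cls in VESSEL_CLASSES:
            row[f"contact_{cls}_um2"] = r.contact_by_class_um2.get(cls, 0.0)
        for ch in channels:
            row[f"mfi_{ch}"] = r.mfi.get(ch, np.nan)
            row[f"uptake_fold_{ch}"] = r.uptake_fold.get(ch, np.nan)
        rows.append(row)
    columns = list(RECORD_COLUMNS)
    columns[8:8] = [f"contact_{cls}_um2" for cls in VESSEL_CLASSES]
    for ch in channels:
        columns += [f"mfi_{ch}", f"uptake_fold_{ch}"]
    per_object = pd.DataFrame(rows, columns=columns)

    value_cols = [
        c
        for c in per_object.columns
        if per_object[c].dtype.kind in "fi" and c != "object_id"
    ]
    if per_object.empty:
        per_group = pd.DataFrame(
            columns=[*group_keys, "n"]
            + [f"{c}_{s}" for c in value_cols for s in ("mean", "sd")]
        )
    else:
        g = per_object.groupby(list(group_keys), dropna=False)
        agg = g[value_cols].agg(["mean", "std"])
        agg.columns = [
            f"{c}_{'sd' if s == 'std' else s}" for c, s in agg.columns
        ]
        agg.insert(0, "n", g.size())
        per_group = agg.reset_index()
    return per_object, per_group
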