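"""Vessel-segment typing along the arteriovenous axis.

Every vessel branch (and voxel) is assigned one of five classes —
artery, a-cap, capillary, v-cap, vein — from mural-marker status
(ACTA2), diameter, position relative to the tissue surface, and
capillary zonation markers (PLVAP, CLDN5). Two pathways are provided:

* :func:`classify_branches` — the rule-based classifier: arteries are
  ACTA2+ vessels thicker than 10 μm away from the tissue surface, veins
  the same on the surface, capillary-calibre ACTA2− vessels are split
  into arterial-side (a-cap) and venous-side (v-cap) capillaries by
  their PLVAP/CLDN5 status;
* :func:`apply_av_annotation` — projection of an expert 2D class
  annotation back onto the 3D vasculature.

Branches no rule covers (for example, exactly 10 μm in diameter, or
carrying contradictory zonation markers) are flagged and reported as
unassigned, never silently resolved: the class thresholds use strict
inequalities, so the boundary case is visible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LabeledVolume, boundary_shell, branch_diameters, local_diameter_map

__all__ = [
    "VESSEL_CLASSES",
    "CLASS_CODES",
    "VesselSegmentMap",
    "largest_gap_threshold",
    "resolve_threshold",
    "marker_status",
    "classify_branches",
    "apply_av_annotation",
    "zonation_profile",
]

VESSEL_CLASSES = ("artery", "a-cap", "capillary", "v-cap", "vein")

#: voxel-class encoding; 0 is unassigned
CLASS_CODES = {c: i + 1 for i, c in enumerate(VESSEL_CLASSES)}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class VesselSegmentMap:
    """Per-voxel and per-branch arteriovenous classes.

    ``voxel_classes`` holds the code of each vessel voxel's class
    (0 = unassigned); ``branch_table`` has one row per branch with its
    class, mean diameter, marker status, surface flag and an audit
    ``flag`` column ∈ {ok, unassigned, conflicted, tie}.
    """

    voxel_classes: np.ndarray
    branch_table: pd.DataFrame
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def class_mask(self, cls: str) -> np.ndarray:
        return self.voxel_classes == CLASS_CODES[cls]


def largest_gap_threshold(values: np.ndarray) -> float:
    """Split a 1D set of values at the midpoint of its largest gap.

    Used as the automatic bimodal threshold for marker positivity over
    per-branch (or per-object) mean intensities.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or v[-1] == v[0]:
        raise ValueError(
            "cannot split a constant set of intensities automatically; "
            "provide an absolute threshold"
        )
    gaps = np.diff(v)
    i = int(np.argmax(gaps))
    return float((v[i] + v[i + 1]) / 2.0)


def resolve_threshold(values: np.ndarray, policy: float | str) -> float:
    """Resolve a threshold policy: a number is used as-is; ``"auto"``
    splits the population at its largest intensity gap."""
    if isinstance(policy, str):
        if policy != "auto":
            raise ValueError(f"unknown threshold policy {policy!r}")
        return largest_gap_threshold(values)
    return float(policy)


def marker_status(
    vessels: LabeledVolume,
    channel: np.ndarray,
    policy: float | str = "auto",
) -> dict[int, bool]:
    """Per-branch marker positivity: positive iff the branch's mean
    voxel intensity strictly exceeds the threshold (a branch mean
    exactly at the threshold is negative)."""
    if channel.shape != vessels.labels.shape:
        raise ValueError("marker channel shape does not match the label volume")
    means = {
        int(i): float(channel[vessels.labels == i].mean()) for i in vessels.ids
    }
    thr = resolve_threshold(np.array(list(means.values())), policy)
    return {i: m > thr for i, m in means.items()}


def _split_capillary(plvap: bool | None, cldn5: bool | None) -> tuple[str, str]:
    """A-cap/v-cap split of an ACTA2− capillary-calibre branch.

    With both markers available: a-cap = PLVAP− & CLDN5+, v-cap =
    PLVAP+ & CLDN5−, neither marker = mid-zone capillary, both =
    conflicted. With a single marker the call is binary (PLVAP
    preferred, CLDN5 as fallback). Returns (class, flag).
    """
    if plvap is not None and cldn5 is not None:
        if plvap and cldn5:
            return "unassigned", "conflicted"
        if plvap:
            return "v-cap", "ok"
        if cldn5:
            return "a-cap", "ok"
        return "capillary", "ok"
    if plvap is not None:
        return ("v-cap" if plvap else "a-cap"), "ok"
    if cldn5 is not None:
        return ("a-cap" if cldn5 else "v-cap"), "ok"
    return "capillary", "ok"


def classify_branches(
    vessels: LabeledVolume,
    markers: dict[str, np.ndarray],
    diameters: dict[int, float] | None = None,
    surface_mask: np.ndarray | None = None,
    tissue_mask: np.ndarray | None = None,
    diameter_threshold_um: float = 10.0,
    surface_depth_um: float = 15.0,
    marker_policy: float | str = "auto",
) -> VesselSegmentMap:
    """Rule-based arteriovenous classification of every branch.

    Rules (strict inequalities, threshold 10 μm by default):

    * artery — ACTA2+, diameter > 10 μm, centreline off the surface;
    * vein — ACTA2+, diameter > 10 μm, centreline on the surface;
    * capillary-calibre — ACTA2−, diameter < 10 μm; split into a-cap /
      v-cap by PLVAP/CLDN5 when those channels are supplied, else left
      as capillary;
    * anything else (including exactly-threshold diameters) —
      unassigned, flagged in the branch table.

    ``surface_mask`` is the boundary shell of the tissue; when omitted
    it is derived from ``tissue_mask`` (default: the whole volume) with
    ``surface_depth_um``. A branch is "on the surface" when the
    majority of its medial-axis voxels fall inside the shell.
    """
    if "ACTA2" not in markers:
        raise ValueError("classification requires an ACTA2 channel")
    if diameters is None:
        diameters = branch_diameters(vessels)
    if surface_mask is None:
        if tissue_mask is None:
            tissue_mask = np.ones(vessels.labels.shape, dtype=bool)
        surface_mask = boundary_shell(
            tissue_mask, surface_depth_um, vessels.spacing
        )

    acta2 = marker_status(vessels, markers["ACTA2"], marker_policy)
    plvap = (
        marker_status(vessels, markers["PLVAP"], marker_policy)
        if "PLVAP" in markers else None
    )
    cldn5 = (
        marker_status(vessels, markers["CLDN5"], marker_policy)
        if "CLDN5" in markers else None
    )

    _, skel = local_diameter_map(vessels.labels > 0, vessels.spacing)

    rows = []
    voxel_classes = np.zeros(vessels.labels.shape, dtype=np.uint8)
    thr = diameter_threshold_um
    for bid in vessels.ids:
        bid = int(bid)
        m = vessels.labels == bid
        medial = np.logical_and(m, skel)
        sel = medial if medial.any() else m
        on_surface = bool(
            surface_mask[sel].sum() * 2 > sel.sum()
        )  # strict majority
        d = float(diameters[bid])
        a_pos = acta2[bid]
        p_pos = plvap[bid] if plvap is not None else None
        c_pos = cldn5[bid] if cldn5 is not None else None

        if a_pos and d > thr:
            cls, flag = ("vein", "ok") if on_surface else ("artery", "ok")
        elif (not a_pos) and d < thr:
            cls, flag = _split_capillary(p_pos, c_pos)
        else:
            cls, flag = "unassigned", "unassigned"

        if cls != "unassigned":
            voxel_classes[m] = CLASS_CODES[cls]
        rows.append(
            {
                "branch_id": bid,
                "vessel_class": cls,
                "diameter_um": d,
                "ACTA2_pos": a_pos,
                "PLVAP_pos": p_pos,
                "CLDN5_pos": c_pos,
                "surface": on_surface,
                "flag": flag,
            }
        )
    return VesselSegmentMap(
        voxel_classes=voxel_classes,
        branch_table=pd.DataFrame(rows),
        spacing=vessels.spacing,
    )


def apply_av_annotation(
    annotation_2d: np.ndarray,
    vessels: LabeledVolume,
    projection_axis: int = 0,
    legend: dict[int, str] | None = None,
) -> VesselSegmentMap:
    """Back-project an expert 2D arteriovenous annotation onto the 3D
    vasculature.

    ``annotation_2d`` is an integer mask over the projection of the
    volume along ``projection_axis`` (default z, matching a maximum
    intensity projection); pixel values map to class names through
    ``legend`` (default: the standard codes, 0 = unannotated). Each 3D
    vessel voxel inherits the class of its projected pixel; each branch
    takes the majority class of its voxels, ties (including with the
    unannotated vote) are reported as unassigned.
    """
    expected = tuple(
        s for i, s in enumerate(vessels.labels.shape) if i != projection_axis
    )
    if annotation_2d.shape != expected:
        raise ValueError(
            f"annotation shape {annotation_2d.shape} does not match the "
            f"projection {expected} along axis {projection_axis}"
        )
    if legend is None:
        code_of = dict(CODE_CLASSES)
    else:
        code_of = {int(k): v for k, v in legend.items()}
    # normalize annotation pixel values onto the standard codes
    remap = np.zeros(int(annotation_2d.max()) + 1, dtype=np.uint8)
    for px, name in code_of.items():
        if px <= annotation_2d.max():
            remap[px] = CLASS_CODES.get(name, 0)
    ann = remap[annotation_2d]

    ann3 = np.expand_dims(ann, axis=projection_axis)
    ann3 = np.broadcast_to(ann3, vessels.labels.shape)
    voxel_classes = np.where(vessels.labels > 0, ann3, 0).astype(np.uint8)

    rows = []
    for bid in vessels.ids:
        bid = int(bid)
        votes = np.bincount(voxel_classes[vessels.labels == bid], minlength=6)
        top = int(votes.max())
        winners = np.flatnonzero(votes == top)
        if len(winners) > 1 or winners[0] == 0:
            cls, flag = "unassigned", ("tie" if len(winners) > 1 else "unassigned")
        else:
            cls, flag = CODE_CLASSES[int(winners[0])], "ok"
        rows.append({"branch_id": bid, "vessel_class": cls, "flag": flag})
    return VesselSegmentMap(
        voxel_classes=voxel_classes,
        branch_table=pd.DataFrame(rows),
        spacing=vessels.spacing,
    )


def zonation_profile(
    channel: np.ndarray,
    segment_map: VesselSegmentMap,
    specimen: str = "specimen",
    channel_name: str = "channel",
) -> pd.DataFrame:
    """Per-segment mean fluorescence intensity, normalized to %max
    within the specimen.

    MFI is the mean over all vessel voxels of a class; the normalized
    value is 100 × MFI / max-over-classes, so the brightest segment is
    100% per specimen and channel. Classes with no voxels are reported
    as missing (NaN), not zero.
    """
    if channel.shape != segment_map.voxel_classes.shape:
        raise ValueError("channel shape does not match the segment map")
    mfis = {}
    for cls, code in CLASS_CODES.items():
        m = segment_map.voxel_classes == code
        mfis[cls] = float(channel[m].mean()) if m.any() else np.nan
    finite = [v for v in mfis.values() if np.isfinite(v)]
    if not finite:
        raise ValueError("segment map contains no classified voxels")
    top = max(finite)
    rows = [
        {
            "specimen": specimen,
            "channel": channel_name,
            "vessel_class": cls,
            "mfi": mfis[cls],
            "pct_max": 100.0 * mfis[cls] / top if np.isfinite(mfis[cls]) else np.nan,
        }
        for cls in VESSEL_CLASSES
    ]
    return pd.DataFrame(rows)
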