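"""Pipeline orchestration: simulate → quantify → report.

The in-memory entry points (:func:`quantify_tissue`,
:func:`quantify_em_scenes`) wire the geometry, vessel-typing,
macrophage and EM modules together; :func:`simulate_dataset`,
:func:`quantify_dataset` and :func:`render_report` are their on-disk
counterparts used by the command line. Every threshold and tie-break
policy in force is echoed into the run metadata, object accounting is
explicit (classified / unassigned / failed all reconciled), and all
table output is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import ndimage

from . import io
from .em import (
    classify_size,
    detect_fenestrae,
    detect_vesicles,
    detections_to_frame,
    fenestrae_fraction,
    restrict_to_endothelium,
    vesicle_metrics,
    EMScene,
)
from .geometry import (
    LabeledVolume,
    RegionMasks,
    branch_diameters,
    contact_area,
    percent_volume,
)
from .macrophage import (
    MacrophageRecord,
    classify_association,
    classify_identity,
    cohort_table,
    morphology,
    subset_calls,
)
from .simulate import EMSimConfig, TissueSimConfig, generate_em_scene, generate_tissue
from .vessel_typing import (
    VESSEL_CLASSES,
    classify_branches,
    zonation_profile,
)

__version__ = "0.1.0"

__all__ = [
    "Thresholds",
    "RunConfig",
    "TissueReport",
    "quantify_tissue",
    "quantify_em_scenes",
    "simulate_dataset",
    "quantify_dataset",
    "render_report",
]


class Thresholds(BaseModel):
    """Every decision threshold of the rule set, echoed into run metadata."""

    model_config = ConfigDict(extra="forbid")

    contact_um2: float = 10.0
    region_fraction: float = 0.30
    diameter_um: float = 10.0
    vesicle_boundary_nm: float = 100.0
    surface_depth_um: float = 15.0
    marker_policy: float | str = "auto"
    subset_policy: float | str = "auto"
    background_stat: str = "median"


class RunConfig(BaseModel):
    """One reproducible pipeline run: simulation settings, thresholds,
    seed. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    tissue: TissueSimConfig = TissueSimConfig()
    em: EMSimConfig = EMSimConfig()
    n_em_scenes: int = 3
    thresholds: Thresholds = Thresholds()
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = self.model_copy(deep=True)
        cfg.seed = seed
        cfg.tissue.seed = seed
        cfg.em.seed = seed + 1000
        return cfg


@dataclass
class TissueReport:
    branch_table: pd.DataFrame
    zonation: pd.DataFrame
    per_object: pd.DataFrame
    per_group: pd.DataFrame
    density: pd.DataFrame
    accounting: dict[str, int] = field(default_factory=dict)
    audit: dict[str, float] = field(default_factory=dict)


def _background_level(channel, tissue_mask, exclusions, stat):
    bg_mask = tissue_mask.astype(bool).copy()
    for m in exclusions:
        bg_mask &= ~m.astype(bool)
    if not bg_mask.any():
        raise ValueError("background region is empty after exclusions")
    bg = (
        float(np.median(channel[bg_mask]))
        if stat == "median"
        else float(channel[bg_mask].mean())
    )
    if bg == 0:
        raise ValueError("tissue background intensity is zero; fold undefined")
    return bg


def quantify_tissue(
    vessels: LabeledVolume,
    macrophages: LabeledVolume,
    regions: RegionMasks,
    tissue_mask: np.ndarray,
    channels: dict[str, np.ndarray],
    thresholds: Thresholds | None = None,
    specimen: str = "specimen",
    truth_vessels: pd.DataFrame | None = None,
    truth_macrophages: pd.DataFrame | None = None,
) -> TissueReport:
    """Run the full light-microscopy quantification on one volume.

    Requires an ACTA2 channel for vessel typing (PLVAP/CLDN5 optional —
    without them capillaries are reported unsplit), a "tracer" channel
    for uptake and a "CD163" channel for subset calls when present.
    When generator truth tables are supplied, the report's audit block
    records the per-rule agreement fractions.
    """
    thr = thresholds or Thresholds()
    markers = {
        k: v
        for k, v in channels.items()
        if k not in ("tracer", "CD163")
    }
    if "ACTA2" not in markers:
        raise ValueError("quantification requires an ACTA2 marker channel")

    diameters = branch_diameters(vessels)
    segmap = classify_branches(
        vessels,
        markers,
        diameters=diameters,
        tissue_mask=tissue_mask,
        diameter_threshold_um=thr.diameter_um,
        surface_depth_um=thr.surface_depth_um,
        marker_policy=thr.marker_policy,
    )

    zon = pd.concat(
        [
            zonation_profile(ch, segmap, specimen=specimen, channel_name=name)
            for name, ch in channels.items()
            if name != "CD163"
        ],
        ignore_index=True,
    )

    vessel_mask = vessels.labels > 0
    spacing = macrophages.spacing
    subset = (
        subset_calls(macrophages, channels["CD163"], thr.subset_policy)
        if "CD163" in channels and len(macrophages.ids)
        else {}
    )
    tracer = channels.get("tracer")
    bg = (
        _background_level(
            tracer, tissue_mask, [vessel_mask, macrophages.labels > 0],
            thr.background_stat,
        )
        if tracer is not None
        else None
    )

    # vessel voxel centres, queried once for all centroid distances
    from scipy.spatial import cKDTree

    ves_centers = (np.argwhere(vessel_mask) + 0.5) * np.asarray(spacing)
    ves_tree = cKDTree(ves_centers) if len(ves_centers) else None

    slices = ndimage.find_objects(macrophages.labels)
    records: list[MacrophageRecord] = []
    n_unassigned = 0
    n_failed = 0
    for mid in macrophages.ids:
        mid = int(mid)
        sl = slices[mid - 1]
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, macrophages.labels.shape)
        )
        sub_mac = macrophages.labels[sl] == mid
        n_vox = int(sub_mac.sum())
        vol_um3 = n_vox * macrophages.voxel_volume
        idx = np.argwhere(sub_mac) + np.array([s.start for s in sl])
        cz, cy, cx = (idx.mean(axis=0) + 0.5) * np.asarray(spacing)

        identity = classify_identity(
            macrophages, mid, regions, thr.region_fraction
        )
        sub_classes = segmap.voxel_classes[sl]
        sub_vessel = vessel_mask[sl]
        contacts = {
            cls: contact_area(sub_mac, sub_classes == code, spacing)
            for cls, code in zip(VESSEL_CLASSES, range(1, 6))
        }
        total_contact = contact_area(sub_mac, sub_vessel, spacing)
        association = classify_association(total_contact, thr.contact_um2)

        flag = "ok"
        if association == "perivascular":
            best = max(contacts.values())
            if best <= 0:
                assigned, flag = "unassigned", "contacts-unclassified-vessel"
                n_unassigned += 1
            else:
                tied = [c for c, v in contacts.items() if v == best]
                if len(tied) == 1:
                    assigned = tied[0]
                else:
                    from .macrophage import assign_segment

                    assigned, flag = assign_segment(
                        macrophages, mid, segmap, contacts
                    )
                    if assigned == "unassigned":
                        n_unassigned += 1
        else:
            assigned = "none"

        dist = (
            float(ves_tree.query([cz, cy, cx])[0]) if ves_tree else np.nan
        )
        if ves_tree is not None:
            vidx = tuple(
                int(c // s) for c, s in zip((cz, cy, cx), spacing)
            )
            if all(0 <= i < d for i, d in zip(vidx, vessel_mask.shape)) and \
                    vessel_mask[vidx]:
                dist = 0.0

        try:
            elong, sparse = morphology(macrophages, mid)
        except ValueError:
            elong, sparse = np.nan, np.nan
            flag = "degenerate-morphology"
            n_failed += 1

        mfi: dict[str, float] = {}
        folds: dict[str, float] = {}
        if tracer is not None:
            m_mfi = float(tracer[sl][sub_mac].mean())
            mfi["tracer"] = m_mfi
            folds["tracer"] = m_mfi / bg

        records.append(
            MacrophageRecord(
                id=mid,
                volume_um3=vol_um3,
                centroid_um=(cz, cy, cx),
                identity=identity,
                association=association,
                contact_area_um2=total_contact,
                contact_by_class_um2=contacts,
                assigned_segment=assigned,
                distance_to_vessel_um=dist,
                subset=subset.get(mid, "unknown"),
                elongation=elong,
                sparseness=sparse,
                mfi=mfi,
                uptake_fold=folds,
                flag=flag,
            )
        )

    chans = ("tracer",) if tracer is not None else ()
    per_object, per_group = cohort_table(records, channels=chans)

    density = pd.DataFrame(
        [
            {
                "structure": "macrophages",
                "region": "tissue",
                "percent_volume": percent_volume(macrophages, tissue_mask)
                if len(macrophages.ids)
                else 0.0,
            },
            {
                "structure": "vessels",
                "region": "tissue",
                "percent_volume": percent_volume(vessels, tissue_mask),
            },
        ]
    )

    accounting = {
        "total": len(records),
        "classified": len(records) - n_unassigned - n_failed,
        "unassigned": n_unassigned,
        "failed": n_failed,
    }

    audit: dict[str, float] = {}
    if truth_macrophages is not None and len(per_object):
        t = truth_macrophages.set_index("object_id")
        p = per_object.set_index("object_id")
        joined = p.join(t, rsuffix="_true")
        audit["identity_agreement"] = float(
            (joined["identity"] == joined["identity_true"]).mean()
        )
        audit["association_agreement"] = float(
            (joined["association"] == joined["association_true"]).mean()
        )
        peri = joined[joined["association_true"] == "perivascular"]
        if len(peri):
            audit["segment_agreement"] = float(
                (peri["assigned_segment"] == peri["contacted_class"]).mean()
            )
        if "subset_true" in joined:
            audit["subset_agreement"] = float(
                (joined["subset"] == joined["subset_true"]).mean()
            )
    if truth_vessels is not None:
        t = truth_vessels.set_index("branch_id")["vessel_class"]
        p = segmap.branch_table.set_index("branch_id")["vessel_class"]
        audit["vessel_class_agreement"] = float((p == t.reindex(p.index)).mean())

    return TissueReport(
        branch_table=segmap.branch_table,
        zonation=zon,
        per_object=per_object,
        per_group=per_group,
        density=density,
        accounting=accounting,
        audit=audit,
    )


def quantify_em_scenes(
    scenes: list[EMScene],
    thresholds: Thresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect, mask-restrict and classify vesicles and measure the
    fenestrae lining fraction for each scene. Returns
    (per-scene summary, per-vesicle detections)."""
    thr = thresholds or Thresholds()
    summaries = []
    detections_all = []
    for i, scene in enumerate(scenes):
        det = detect_vesicles(scene)
        kept, dropped = restrict_to_endothelium(det, scene.endothelium_mask)
        for d in kept:
            d.size_class = classify_size(d.diameter_nm, thr.vesicle_boundary_nm)
        metrics = vesicle_metrics(kept, scene)
        intervals = detect_fenestrae(scene)
        fen = fenestrae_fraction(
            scene.lining_paths, intervals, scene.nm_per_pixel
        )
        summaries.append(
            {
                "scene": i,
                **metrics,
                "n_dropped_outside": float(dropped),
                "fenestrae_pct_lining": fen,
            }
        )
        df = detections_to_frame(kept)
        df.insert(0, "scene", i)
        detections_all.append(df)
    per_scene = pd.DataFrame(summaries)
    per_vesicle = (
        pd.concat(detections_all, ignore_index=True)
        if detections_all
        else pd.DataFrame()
    )
    return per_scene, per_vesicle


# --------------------------------------------------------------- on disk


def simulate_dataset(config: RunConfig, outdir: Path) -> Path:
    """Generate and write a complete synthetic dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tissue = generate_tissue(config.tissue)
    io.write_channels(outdir / "channels.ome.tif", tissue.channels)
    io.write_labels(outdir / "vessels.tif", tissue.vessels.labels)
    io.write_labels(outdir / "macrophages.tif", tissue.macrophages.labels)
    io.write_mask(outdir / "region_soma.tif", tissue.regions.soma_rich)
    io.write_mask(outdir / "region_fiber.tif", tissue.regions.fiber_rich)
    io.write_mask(outdir / "tissue.tif", tissue.tissue_mask)
    io.write_table(outdir / "truth_vessels.csv", tissue.vessel_truth)
    io.write_table(outdir / "truth_macrophages.csv", tissue.macrophage_truth)

    em_dir = outdir / "em"
    em_dir.mkdir(exist_ok=True)
    em_truths = []
    for i in range(config.n_em_scenes):
        cfg = config.em.model_copy(update={"seed": config.em.seed + i})
        scene, truth, frac = generate_em_scene(cfg)
        import tifffile

        tifffile.imwrite(em_dir / f"scene_{i}.tif", scene.image.astype(np.float32))
        io.write_mask(em_dir / f"scene_{i}_mask.tif", scene.endothelium_mask)
        io.write_json(
            em_dir / f"scene_{i}.json",
            {
                "nm_per_pixel": scene.nm_per_pixel,
                "lining_paths": [p.tolist() for p in scene.lining_paths],
                "true_fenestrae_pct": frac,
            },
        )
        truth.insert(0, "scene", i)
        em_truths.append(truth)
    io.write_table(
        outdir / "truth_em.csv", pd.concat(em_truths, ignore_index=True)
    )
    io.write_json(outdir / "config.json", config.model_dump(mode="json"))
    return outdir


def _load_scenes(dataset: Path) -> list[EMScene]:
    import tifffile

    scenes = []
    em_dir = Path(dataset) / "em"
    for i in range(len(sorted(em_dir.glob("scene_*.json")))):
        meta = io.read_json(em_dir / f"scene_{i}.json")
        scenes.append(
            EMScene(
                image=tifffile.imread(em_dir / f"scene_{i}.tif").astype(float),
                nm_per_pixel=float(meta["nm_per_pixel"]),
                endothelium_mask=io.read_mask(em_dir / f"scene_{i}_mask.tif"),
                lining_paths=[np.asarray(p) for p in meta["lining_paths"]],
            )
        )
    return scenes


def quantify_dataset(dataset: Path, outdir: Path, config: RunConfig | None = None) -> Path:
    """Quantify a dataset directory written by :func:`simulate_dataset`
    and write the full report (tables + metadata) to ``outdir``."""
    dataset = Path(dataset)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = RunConfig.model_validate(io.read_json(dataset / "config.json"))
    thr = config.thresholds
    spacing = tuple(config.tissue.voxel_spacing)

    channels = io.read_channels(dataset / "channels.ome.tif")
    vessels = LabeledVolume(io.read_labels(dataset / "vessels.tif"), spacing)
    macrophages = LabeledVolume(io.read_labels(dataset / "macrophages.tif"), spacing)
    regions = RegionMasks(
        soma_rich=io.read_mask(dataset / "region_soma.tif"),
        fiber_rich=io.read_mask(dataset / "region_fiber.tif"),
    )
    tissue_mask = io.read_mask(dataset / "tissue.tif")
    truth_v = (
        pd.read_csv(dataset / "truth_vessels.csv")
        if (dataset / "truth_vessels.csv").exists()
        else None
    )
    truth_m = (
        pd.read_csv(dataset / "truth_macrophages.csv")
        if (dataset / "truth_macrophages.csv").exists()
        else None
    )

    report = quantify_tissue(
        vessels, macrophages, regions, tissue_mask, channels,
        thresholds=thr, truth_vessels=truth_v, truth_macrophages=truth_m,
    )
    per_scene, per_vesicle = quantify_em_scenes(_load_scenes(dataset), thr)

    io.write_table(outdir / "branch_table.csv", report.branch_table)
    io.write_table(outdir / "zonation.csv", report.zonation)
    io.write_table(outdir / "per_object.csv", report.per_object)
    io.write_table(outdir / "per_group.csv", report.per_group)
    io.write_table(outdir / "density.csv", report.density)
    io.write_table(outdir / "em_per_scene.csv", per_scene)
    io.write_table(outdir / "em_per_vesicle.csv", per_vesicle)

    cfg_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    io.write_json(
        outdir / "run_metadata.json",
        {
            "software": "perimac",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "thresholds": thr.model_dump(mode="json"),
            "tie_break": "max contact area; centroid-to-medial-axis distance",
            "accounting": report.accounting,
            "audit": report.audit,
        },
    )
    return outdir


def render_report(report_dir: Path, outdir: Path | None = None) -> list[Path]:
    """Render summary figures from a written report's tables only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report_dir = Path(report_dir)
    outdir = Path(outdir) if outdir else report_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    per_object = pd.read_csv(report_dir / "per_object.csv")
    zonation = pd.read_csv(report_dir / "zonation.csv")
    order = list(VESSEL_CLASSES)

    if per_object.empty:
        print("report is empty; nothing to plot")
        return written

    # uptake by assigned segment
    if "uptake_fold_tracer" in per_object:
        peri = per_object[per_object.association == "perivascular"]
        g = (
            peri[peri.assigned_segment.isin(order)]
            .groupby("assigned_segment")["uptake_fold_tracer"]
            .mean()
            .reindex(order)
        )
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(order, g.values, "o-")
        ax.set_ylabel("uptake (fold over background)")
        ax.set_xlabel("vessel segment")
        fig.tight_layout()
        p = outdir / "uptake_by_segment.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

    # zonation profiles
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for ch, sub in zonation.groupby("channel"):
        sub = sub.set_index("vessel_class").reindex(order)
        ax.plot(order, sub["pct_max"].values, "o-", label=ch)
    ax.set_ylabel("MFI (% max)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "zonation.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    # morphology scatter
    fig, ax = plt.subplots(figsize=(4, 4))
    for ident, sub in per_object.groupby("identity"):
        ax.scatter(sub["elongation"], sub["sparseness"], s=8, label=ident)
    ax.set_xlabel("elongation")
    ax.set_ylabel("sparseness")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "morphology.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)
    return written
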