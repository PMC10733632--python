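"""Simulation configuration models.

The tissue generator emulates the statistical structure the analysis
assumes: a branched vascular network zonated along the arteriovenous
axis (artery → a-cap → capillary → v-cap → vein) in radius, mural and
endothelial marker intensity and macrophage tracer uptake; macrophages
of controlled shape, placement and subset; and EM-scale scenes with
endothelial ribbons containing vesicles and fenestral gaps.

Defaults realise the regimes the classification rules discriminate:
artery/vein radii above 5 μm and capillary radii below 5 μm, so vessel
diameters straddle the 10 μm class boundary; a tracer gradient strictly
increasing from artery to vein; marker class means separated by well
over five noise standard deviations.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

VESSEL_CLASSES = ("artery", "a-cap", "capillary", "v-cap", "vein")

MARKERS = ("ACTA2", "PLVAP", "CLDN5", "CAV1", "MFSD2A")

SHAPES = ("sphere", "prolate", "spider")


def _default_marker_profile() -> dict[str, dict[str, float]]:
    # class means per marker, artery → vein order; chosen so an automatic
    # largest-gap split over branch means recovers the intended ± status
    return {
        "ACTA2": {"artery": 200.0, "a-cap": 5.0, "capillary": 5.0, "v-cap": 5.0, "vein": 180.0},
        "PLVAP": {"artery": 5.0, "a-cap": 10.0, "capillary": 20.0, "v-cap": 150.0, "vein": 200.0},
        "CLDN5": {"artery": 220.0, "a-cap": 180.0, "capillary": 60.0, "v-cap": 40.0, "vein": 30.0},
        "CAV1": {"artery": 20.0, "a-cap": 40.0, "capillary": 80.0, "v-cap": 160.0, "vein": 200.0},
        "MFSD2A": {"artery": 180.0, "a-cap": 150.0, "capillary": 110.0, "v-cap": 60.0, "vein": 30.0},
    }


def _default_counts() -> dict[str, int]:
    # keys "identity/association/subset"; identities via placement region,
    # perivascular spread round-robin over vessel classes
    return {
        "DRG/perivascular/CD163+": 20,
        "DRG/perivascular/CD163-": 20,
        "DRG/parenchymal/CD163+": 15,
        "DRG/parenchymal/CD163-": 15,
        "fiber/perivascular/CD163+": 8,
        "fiber/perivascular/CD163-": 8,
        "fiber/parenchymal/CD163+": 10,
        "fiber/parenchymal/CD163-": 10,
    }


class TissueSimConfig(BaseModel):
    """Configuration of one synthetic light-microscopy tissue volume."""

    model_config = ConfigDict(extra="forbid")

    volume_shape: tuple[int, int, int] = (160, 160, 160)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)

    n_branches_per_class: dict[str, int] = Field(
        default_factory=lambda: {
            "artery": 2, "a-cap": 4, "capillary": 4, "v-cap": 4, "vein": 2,
        }
    )
    radius_range_per_class: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "artery": (6.0, 8.0),
            "a-cap": (1.5, 2.5),
            "capillary": (1.5, 2.5),
            "v-cap": (1.5, 2.5),
            "vein": (6.0, 8.0),
        }
    )
    marker_profile: dict[str, dict[str, float]] = Field(
        default_factory=_default_marker_profile
    )

    # mean tracer uptake painted into macrophages contacting each class;
    # strictly increasing artery → vein realises the arteriovenous gradient
    tracer_gradient: dict[str, float] = Field(
        default_factory=lambda: {
            "artery": 20.0, "a-cap": 40.0, "capillary": 60.0,
            "v-cap": 100.0, "vein": 120.0,
        }
    )
    zonation_enabled: bool = True
    tracer_background: float = 10.0
    parenchymal_uptake: float = 15.0

    n_macrophages: dict[str, int] = Field(default_factory=_default_counts)
    shape_repertoire: tuple[str, ...] = SHAPES
    macrophage_radius_range: tuple[float, float] = (2.0, 3.0)
    contact_target_um2: tuple[float, float] = (15.0, 45.0)
    parenchymal_clearance_um: float = 3.0
    subset_intensity: dict[str, float] = Field(
        default_factory=lambda: {"CD163+": 150.0, "CD163-": 5.0}
    )

    region_split_fraction: float = 0.35  # fiber-rich below, soma-rich above
    region_gap_fraction: float = 0.0
    surface_margin_um: float = 8.0  # how close vein centrelines sit to the far face

    noise_sd: float = 5.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TissueSimConfig":
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive per axis")
        if any(n <= 0 for n in self.volume_shape):
            raise ValueError("volume_shape must be positive per axis")
        for cls, (lo, hi) in self.radius_range_per_class.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid radius range for {cls!r}: ({lo}, {hi})")
        for cls in self.n_branches_per_class:
            if cls not in VESSEL_CLASSES:
                raise ValueError(f"unknown vessel class {cls!r}")
        if self.zonation_enabled:
            vals = [self.tracer_gradient[c] for c in VESSEL_CLASSES]
            if not all(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    "tracer_gradient must be strictly increasing artery → vein"
                )
        for key in self.n_macrophages:
            parts = key.split("/")
            if len(parts) != 3 or parts[0] not in ("DRG", "fiber") or \
                    parts[1] not in ("perivascular", "parenchymal") or \
                    parts[2] not in ("CD163+", "CD163-"):
                raise ValueError(
                    f"n_macrophages key {key!r} must be "
                    "'<DRG|fiber>/<perivascular|parenchymal>/<CD163+|CD163->'"
                )
        for s in self.shape_repertoire:
            if s not in SHAPES:
                raise ValueError(f"unknown shape {s!r}")
        if not 0 < self.region_split_fraction < 1:
            raise ValueError("region_split_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return self


class EMSimConfig(BaseModel):
    """Configuration of one synthetic EM-scale 2D scene.

    The scene is a horizontal endothelial ribbon on a lighter lumen and
    tissue background; the luminal lining is the ribbon's upper
    boundary. Vesicles are dark discs of specified diameter inside the
    ribbon (plus decoys outside); fenestrae are gaps of specified
    length carved through the lining.
    """

    model_config = ConfigDict(extra="forbid")

    image_shape: tuple[int, int] = (400, 600)
    nm_per_pixel: float = 2.0
    ribbon_rows: tuple[int, int] = (150, 250)  # [start, stop) rows of the ribbon

    vesicle_diameters_nm: tuple[float, ...] = (60.0, 70.0, 80.0, 90.0, 120.0, 140.0)
    decoy_diameters_nm: tuple[float, ...] = (60.0, 80.0)
    min_separation_px: float = 6.0

    # fenestrae as (start fraction along the lining, gap length in nm)
    fenestrae: tuple[tuple[float, float], ...] = ((0.25, 60.0), (0.7, 80.0))
    fenestra_depth_px: int = 4

    background_level: float = 190.0
    ribbon_level: float = 120.0
    vesicle_level: float = 30.0
    noise_sd: float = 18.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EMSimConfig":
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be positive")
        r0, r1 = self.ribbon_rows
        if not (0 <= r0 < r1 <= self.image_shape[0]):
            raise ValueError("ribbon_rows must lie inside the image")
        for d in self.vesicle_diameters_nm + self.decoy_diameters_nm:
            if d / self.nm_per_pixel < 2.0:
                raise ValueError(
                    f"vesicle diameter {d} nm is below 2 pixels at "
                    f"{self.nm_per_pixel} nm/px and cannot be resolved"
                )
        for start, _length in self.fenestrae:
            if not 0 <= start < 1:
                raise ValueError("fenestra start fraction must be in [0, 1)")
        return self
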