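# perimac

Quantification of perivascular macrophages and arteriovenous zonation
in 3D microscopy volumes of sensory ganglia, plus EM-scale vesicle and
fenestrae quantification — with a ground-truthed synthetic tissue
generator so the entire rule set is testable without real data.

## The problem

Sensory ganglia (e.g. dorsal root ganglia) have an unusually permeable
vasculature, and their macrophages sit in defined spatial niches:
pressed against vessel walls (perivascular) or free in the parenchyma,
in the neuron-soma-rich core or the nerve-fiber region. Quantifying
these niches from segmented 3D volumes requires a reproducible rule
set:

* **Vessel typing.** Each vessel branch is assigned along the
  arteriovenous axis from mural-marker status, calibre and position:
  arteries are ACTA2⁺ with diameter > 10 μm away from the tissue
  surface, veins the same on the surface, and ACTA2⁻ capillary-calibre
  vessels split into arterial (a-cap: PLVAP⁻ CLDN5⁺) and venous (v-cap:
  PLVAP⁺ CLDN5⁻) capillaries. An expert 2D projection annotation can be
  back-projected onto the 3D vasculature as an alternative pathway.
* **Macrophage classification.** Identity by region overlap (DRG if
  ≥ 30% of the volume lies in the soma-rich region, else fiber by the
  same rule), vascular association by contact area (perivascular iff
  the shared surface with vessels ≥ 10 μm²), and segment assignment to
  the vessel class with maximal contact.
* **Per-cell measurements.** Volume; equivalent-ellipsoid morphology —
  elongation a/b ("cigar-ness") and sparseness V_ellipsoid/V_object
  ("spider-ness"); tracer uptake as MFI normalized to tissue
  background; CD163 subset calls; distance to the nearest vessel.
* **Zonation profiles.** Per-segment mean fluorescence intensity
  normalized to %max per specimen.
* **EM quantification.** Caveolar vesicles detected as dark circular
  blobs, restricted to the endothelium, classified single (< 100 nm) vs
  fused (> 100 nm), with densities per μm² of cytoplasm; fenestrae as
  the percent of the luminal lining length occupied by gaps.

Every threshold and tie-break is explicit, configurable and echoed
into the run metadata; objects no rule covers are flagged, never
silently dropped.

## Worked example

```python
from perimac.simulate import TissueSimConfig, generate_tissue
from perimac.pipeline import quantify_tissue

tissue = generate_tissue(TissueSimConfig(seed=1))   # 160³ voxels, 106 cells
report = quantify_tissue(
    tissue.vessels, tissue.macrophages, tissue.regions,
    tissue.tissue_mask, tissue.channels,
    truth_macrophages=tissue.macrophage_truth,
)

peri = report.per_object[report.per_object.association == "perivascular"]
print(peri.groupby("assigned_segment")["uptake_fold_tracer"].mean().round(2))
```

```
assigned_segment
a-cap         4.00
artery        2.00
capillary     5.99
v-cap         9.99
vein         11.99
```

Mean tracer uptake of perivascular macrophages rises strictly along
the arteriovenous axis (artery 2.0× background → vein 12.0×) and peaks
on the venous side — the generator plants that gradient, and the full
chain (contact areas → segment assignment → background-normalized
uptake) recovers it. The zonation profile of the venous marker channel
shows the complementary pattern:

```python
print(report.zonation[report.zonation.channel == "PLVAP"]
      [["vessel_class", "pct_max"]].round(1).to_string(index=False))
```

```
vessel_class  pct_max
      artery      2.7
       a-cap      5.0
   capillary     10.0
       v-cap     75.0
        vein    100.0
```

With truth tables supplied, `report.audit` carries the agreement of
every classification against the generator's ground truth (1.0 across
the board under the default study conditions).

The same pipeline runs from the shell:

```bash
perimac simulate --seed 1 --out data/
perimac quantify data/ --out report/
perimac report report/
```

`quantify` writes tidy CSVs (`per_object.csv`, `per_group.csv`,
`branch_table.csv`, `zonation.csv`, `em_per_scene.csv`) plus
`run_metadata.json` with every threshold, seed and tie-break; `report`
renders uptake-by-segment, zonation and morphology figures from the
tables alone. Reruns under the same config and seed are byte-identical.

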