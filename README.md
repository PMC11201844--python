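# resectmargin

Quantifies the **resection margin** after sublobar lung cancer surgery —
the closest 3D distance between the surgical cut surface and the tumor —
from a pair of thoracic CT scans (pre-operative and post-operative), for
thoracic surgeons and medical-image-analysis researchers who want an
objective alternative to gross specimen measurement.

The hard part is registration: a wedge of lung is physically gone after
surgery and the remaining tissue collapses into the void, so no smooth
deformation maps one scan onto the other. The package implements a
reconstruction pipeline built around two ideas:

1. **Subvascular-tree matching.** The pulmonary vessel tree is segmented
   (single-scale Frangi filter, σ = 3 mm, 95th-percentile threshold inside
   the lung eroded by 4 mm) and split into *subvascular trees* — 26-connected
   components over 250 voxels. Trees are matched across scans in two phases:
   rigid coherent point drift (CPD) on centerlines with Dice acceptance
   (target ≥ 0.5, 60³ surrounding crop ≥ 0.2), then a relative-positioning
   phase scored by the volume-penalized Dice

   DSCP = DSC / r²,  r = V₁/V₂ (V₁ ≥ V₂) ≥ 1,

   accepted at DSCP ≥ 0.3. Non-rigid CPD on matched centerlines yields
   paired feature points.

2. **Selective-control-point thin-plate splines.** Each voxel gets its own
   TPS control subset: pairs within the candidate radius

   R = 2·d_max · exp(a·(d/d_max − 1)),  a = 3,

   (d = distance to the tumor centroid, d_max = farthest tumor-to-lung-edge
   distance) are clustered by DBSCAN *in displacement space* and only the
   cluster nearest the voxel is used. The resulting displacement field is
   continuous where one motion regime dominates and free to jump across the
   resection — which a classical all-control-point TPS cannot do.

The warped post-operative lung is then overlaid with the pre-operative
tumor mask and the margin is the closest surface-to-surface Euclidean
distance (sub-voxel results print as `<1.00` mm). Registration quality is
evaluated with the target registration error (TRE) at landmark pairs.

No patient data is included: a phantom module generates paired synthetic CT
volumes (lungs, branching vessel trees, tumor, simulated resection with a
known margin, known deformation field) on which every stage is testable.

## Worked example

Generate a phantom pair with a known 10 mm margin and run the pipeline:

```
resectmargin phantom --seed 42 --out phantom/
resectmargin run --pre phantom/pre.nii.gz --post phantom/post.nii.gz \
    --tumor-seed 121,75,112 --landmarks phantom/landmarks.csv --out case01/
```

The `run` command prints the margin and TRE blocks of the report
(`case01/report.json`); on this phantom it prints:

```
{
  "distance_mm": 9.219544,
  "printed": "9.22",
  "overlap": false,
  "resection_voxels": 34381
}
{
  "n": 20,
  "excluded": 0,
  "mean_mm": 0.534793,
  "sd_mm": 0.206504,
  "max_mm": 1.033434,
  "min_mm": 0.149251
}
```

Reading: the reconstructed margin is 9.22 mm against the phantom's true
10 mm (within one voxel of the 1 mm grid), and the deformation field lands
the 20 vessel-bifurcation landmarks within 0.53 mm of their true
pre-operative positions on average (worst case 1.03 mm). The report also
carries the per-phase matching table (all post-operative trees matched;
the tree inside the resected cap correctly stays unmatched) and the
feature-point count.

The same stages are available individually (`segment`, `match`, `register`,
`margin`, `tre`) and as library functions
(`resectmargin.pipeline.run_pipeline_volumes`).

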