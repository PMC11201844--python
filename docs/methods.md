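# Methods

`resectmargin` reconstructs the surgical scene of a sublobar lung resection
from a pair of thoracic CT scans — one taken before surgery, one a few months
after — and quantifies the resection margin: the closest 3D distance between
the cut surface of the remaining lung and the tumor that was removed. The
difficulty is that no smooth transformation maps the post-operative chest
onto the pre-operative one: a wedge of tissue is simply gone, and the
remaining lung collapses into the void. The pipeline therefore estimates a
deformation field that is continuous almost everywhere but *allowed to jump*
near the resection.

## Pipeline model and assumptions

1. **Resampling.** Both scans are resampled to a 1 mm isotropic grid
   (linear interpolation for HU volumes, nearest for masks). All later
   stages assume this grid; distances in millimetres then coincide with
   voxel units. Inputs with spacing above 1.5 mm are accepted with a
   warning — accuracy claims assume thin-slice data.
2. **Lung segmentation.** Gaussian smoothing (σ = 1 mm), threshold at
   −775 HU, discard below-threshold components touching the grid boundary
   (outside air), keep the largest one or two interior components, fill
   holes per axial slice and once volumetrically. The −775 HU threshold
   sits close to aerated-lung HU, so the contour is biased sub-voxel
   inward; disagreement with ground truth stays within a one-voxel band.
3. **Localization.** The post-operative scan is aligned to the
   pre-operative one by registering the binary lung masks: signed distance
   transforms, mean-squares metric, regular-step gradient descent, 4×/2×/1×
   pyramid, moments initialization. The default transform model is a
   *similarity* (rigid + isotropic scale) rather than a full affine: with a
   resected cap missing from one lung, a 12-DOF affine can stretch the
   post-operative lung anisotropically into the void — every overlap metric
   rewards it — which biases the reconstructed cut surface by several
   millimetres while landmark errors elsewhere stay small. The constrained
   model keeps intact anatomy honest and leaves residual anisotropy to the
   deformable stage; `model="affine"` restores the full model. For the same
   reason the pipeline excludes a ball around the tumor (default radius
   50 mm) from the registration metric: the resected volume is missing from
   the post-operative scan and its irreducible mismatch otherwise rewards
   transforms that tilt intact anatomy into the gap. An optional tanh
   saturation of the distance maps (`saturation_mm`) sharpens pure scale
   recovery at the cost of this robustness and is off by default.
4. **Vessel segmentation.** Single-scale Frangi tubularity (σ = 3 mm,
   α = β = 0.5, background sensitivity = half the maximum Hessian norm),
   thresholded at the 95th percentile of the response *inside the lung*,
   restricted to the lung eroded by 4 mm (which removes the hilar vessels).
   26-connected components above 250 voxels are the *subvascular trees*;
   each is reduced to a centerline by topology-preserving 3D thinning.
5. **Two-phase tree matching.**
   - *Phase I*: for each post-operative tree, candidate pre-operative trees
     within 30 mm (centroid gate) are aligned by rigid coherent point drift
     (CPD) on the centerlines; the pair is accepted when the Dice of the
     aligned tree masks is ≥ 0.5 **and** the Dice of 60×60×60-voxel crops
     of the surrounding vasculature is ≥ 0.2. Greedy one-to-one assignment
     by descending target Dice.
   - *Phase II*: each leftover post tree is translated by the mean centroid
     offset of its three nearest matched pairs, dilated by 3 mm (tolerating
     slight bending), and scored against overlapping unmatched pre trees
     with a volume-penalized Dice, DSCP = DSC / r² where r ≥ 1 is the ratio
     of the *undilated* tree volumes; accepted when DSCP ≥ 0.3. Computing r
     from the dilated mask would make the threshold unattainable even for a
     perfect match of a thin tube (dilation multiplies a radius-a tube's
     volume by ≈ (1 + 3/a)²), so the penalty uses the matching objects'
     own volumes while the Dice uses the dilated placement.
   - Matched pairs yield feature points: non-rigid CPD (Gaussian kernel
     β = 2, regularization λ = 3, outlier weight w = 0.1, in normalized
     point-cloud units) maps each post centerline point into pre-operative
     space; points whose posterior confidence falls below 0.5 are dropped.
6. **Displacement field.** For an evaluation voxel at distance d from the
   tumor centroid, a candidate radius R = 2·dmax·exp(a·(d/dmax − 1)) with
   a = 3 selects nearby feature pairs (dmax = farthest distance from tumor
   centroid to the lung surface): small near the tumor, approaching 2·dmax
   far away. DBSCAN (ε = 2 mm, minimum 5 points) clusters the candidates by
   their displacement vectors; noise points are discarded and the cluster
   whose members sit nearest the voxel wins — so control points moving with
   the far side of a resection never steer a near-side voxel. A 3D
   thin-plate spline (kernel U(r) = r, exact interpolation, full affine
   part) fit on the selected subset supplies the voxel displacement. An
   all-control-point TPS is available as the classical continuous baseline.
7. **Margin.** The field (inverted by fixed-point iteration) warps the
   localized post-operative lung into pre-operative space; the resection
   region is the pre-operative lung not covered by it. The margin is the
   minimum Euclidean distance between the warped-lung surface restricted to
   within 2 mm of the resection region (keeping distant chest wall out of
   the search) and the tumor surface, computed via a Euclidean distance
   transform, exact to voxel resolution. Sub-voxel results print as
   "<1.00" mm; a warped lung overlapping the tumor reports 0 with an
   overlap flag (negative margin). TRE (target registration error) at
   landmark pairs is ‖post + u(post) − pre‖ with trilinear field sampling.

## Numerical choices

- **CPD.** Both rigid and non-rigid variants normalize the clouds to zero
  mean and a shared RMS scale; without this the uniform-outlier density
  overwhelms the mixture at initialization and the scale estimate
  collapses. The non-rigid variant starts its annealing at the
  nearest-neighbour distance scale (capped by the classic cloud-scale
  initialization): vessel centerline points are densely spaced, and a
  cloud-scale σ lets a curve slide along itself into an off-by-one local
  optimum. EM stops when σ² changes by < 1e-8 or after 100 iterations.
- **TPS subsets.** Control subsets are capped at 300 points per fit
  (deterministic even thinning) and augmented with nearest pairs whenever
  the selected points are coplanar — a coplanar set leaves the TPS affine
  part unconstrained along the normal and extrapolates wildly. Degenerate
  solves fall back to a 1e-6 ridge with a warning. Outside the control
  points the TPS affine trend extrapolates linearly; each node's
  displacement is therefore clipped to its control points' displacement
  range expanded by half the observed spread (at least 1 mm), which lets a
  saturating motion (the collapse near a cut face) be followed a short way
  past the last vessel while cutting off runaway extrapolation.
- **Field evaluation lattice.** The field is evaluated on a stride-4
  lattice (4 mm on the 1 mm grid) and upsampled nearest within each cell;
  TPS fits are cached by control subset. Exact per-voxel evaluation is
  available (`exact=True`) but costs roughly stride³ more fits.
- **Ties.** Tree labels order by decreasing volume then lexicographic
  smallest voxel index; equally near DBSCAN clusters resolve to the larger
  cluster, then the lower id; nearest-point ties in the margin search take
  the lexicographically smallest index. Every stage is deterministic for
  fixed inputs (SimpleITK metric evaluation is pinned to one thread).

## The phantom: what it emulates, what it does not

No patient data ships with the package; the `phantom` module generates
paired volumes with complete ground truth. A soft-tissue body (~40 HU)
in air holds two ellipsoidal lungs (~−850 HU), six branching tube trees
(~50 HU, radius tapering 3.5 → 2 mm, three per lung in separate axial
slabs, bifurcation coordinates recorded during drawing), and a spherical
tumor (~0 HU). HU values are chosen so the pipeline's fixed thresholds
(−775 HU lung, Frangi at σ = 3 mm) operate in their intended regime, and
the total tube volume stays below the 95th-percentile quota of lung
voxels so the stated threshold can capture whole trees. A
superior cap of the tumor-bearing lung — containing the tumor, with the
cut plane `resection_offset` mm from the tumor surface — is replaced by
soft tissue on the pre volume, and a known displacement field (smooth
global sinusoid, peak 3 mm, plus a collapse of up to 5 mm confined to
within 15 mm of the cut) then produces the post volume by backward
sampling: `post(x) = pre_resected(x + u(x)) + noise`. Because resection
precedes warping, the true field is known exactly on both sides of the
cut, and the true margin equals the construction offset. One tree lies
inside the resected cap and is absent post-operatively, so it must remain
unmatched — the same behavior the two-phase matcher shows on real cases.

What passing the phantom does **not** show: real CT texture and noise
correlation, respiratory-phase differences beyond a smooth warp, airway
structures, fissures and per-lobe mechanics, stapler artifacts, or
scanner-dependent resolution effects. Matching rates on the phantom
(≈ 100% over 5 retained trees) are far above the clinical regime, where
dozens of trees per lung with segmentation differences between visits
yield Phase-I rates near 50–67%. The phantom's ~500 feature pairs are an
order of magnitude below the ≥ 1000 pairs available at clinical scale.

Default problem sizes (160³ voxel phantom, 6 trees, stride-4 field
evaluation) were chosen so a single end-to-end run completes in about two
minutes on one CPU; they are the package's reference configuration for
tests and for `scripts/acceptance.py`.

## Known limitations

- The margin search restricts the cut-surface candidates to within 2 mm of
  the reconstructed resection region; pathological cases where the warped
  lung misses the resection entirely fall back to the full lung surface.
- Lung contours and fissures may show spurious discontinuities, since
  nothing constrains the selective field at boundaries where no vessel
  control points exist.
- Tumor segmentation is a seeded region-growing refinement intended for
  solid tumors ≥ 3 mm radius on a supplied seed; ground-glass lesions and
  tiny nodules should be supplied as ready masks.
- All accuracy statements in the test suite are statements about the
  phantom under its stated conditions, not clinical validation.
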