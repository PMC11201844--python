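"""Subvascular-tree matching: similarity measures, CPD, and the two-phase matcher.

The matcher pairs post-operative subvascular trees (connected vessel
components) with their pre-operative counterparts:

* **Phase I** establishes high-similarity matches: each post tree's centerline
  is rigidly aligned to a candidate pre tree's centerline with rigid coherent
  point drift (CPD); the aligned tree mask and a 60x60x60 crop of the
  surrounding vasculature are compared with the Dice coefficient, and the pair
  is accepted when target Dice >= 0.5 and surrounding Dice >= 0.2.
* **Phase II** places each remaining post tree at a search centre inferred
  from the three nearest already-matched tree pairs, dilates it by 3 mm to
  tolerate slight bending, and accepts the best overlapping pre tree when the
  volume-penalized Dice (DSCP = DSC / r^2, r = volume ratio >= 1) is >= 0.3.

Accepted pairs are converted to matched feature points by mapping each post
centerline point onto the pre centerline with non-rigid CPD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from skimage.morphology import skeletonize as _skeletonize_nd

from .errors import EmptyInputError, GridMismatchError, PipelineError, PreconditionError
from .imaging import BinaryMask, ball_footprint

# ---------------------------------------------------------------------------
# Skeletonization and similarity
# ---------------------------------------------------------------------------


def skeletonize_mask(mask: BinaryMask) -> np.ndarray:
    """Topology-preserving 3D thinning; returns centerline voxel indices.

    Uses iterative deletion of simple border voxels (Lee et al. thinning as
    implemented in scikit-image), which preserves the 26-connected component
    count of the input.  Indices are returned in lexicographic order.
    """
    if not mask.data.any():
        raise EmptyInputError("skeletonize of an empty mask")
    if not mask.is_isotropic():
        raise PreconditionError("skeletonize requires an isotropic grid")
    skel = _skeletonize_nd(mask.data)
    return np.argwhere(skel)


def skeletonize(mask: BinaryMask) -> np.ndarray:
    """Centerline points of ``mask`` in world coordinates (mm, z/y/x)."""
    return mask.index_to_world(skeletonize_mask(mask))


def _dice_counts(na: int, nb: int, ninter: int) -> float:
    if na + nb == 0:
        return 0.0
    return 2.0 * ninter / (na + nb)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 0 when both empty."""
    if not a.same_grid(b):
        raise GridMismatchError("dice requires masks on the same grid")
    return _dice_counts(a.count(), b.count(), int((a.data & b.data).sum()))


def dice_penalized(a: BinaryMask, b: BinaryMask) -> float:
    """Volume-penalized Dice: DSCP = DSC / r^2 with r = max(V)/min(V) >= 1.

    Equals the plain Dice when the volumes are equal; strongly penalizes
    size-mismatched pairs, guarding small trees against spurious matches.
    """
    if not a.same_grid(b):
        raise GridMismatchError("dice_penalized requires masks on the same grid")
    va, vb = a.count(), b.count()
    if va == 0 or vb == 0:
        raise EmptyInputError("dice_penalized of an empty mask")
    r = max(va, vb) / min(va, vb)
    return dice(a, b) / r**2


# ---------------------------------------------------------------------------
# Coherent point drift
# ---------------------------------------------------------------------------


def _cpd_posterior(
    transformed: np.ndarray, fixed: np.ndarray, sigma2: float, w: float
) -> np.ndarray:
    """CPD E-step: posterior P[m, n] that fixed point n arose from moving m."""
    m = transformed.shape[0]
    n = fixed.shape[0]
    d = fixed.shape[1]
    dist2 = cdist(transformed, fixed, "sqeuclidean")
    num = np.exp(-dist2 / (2.0 * sigma2))
    c = (2.0 * np.pi * sigma2) ** (d / 2.0) * (w / max(1.0 - w, 1e-12)) * (m / n)
    den = num.sum(axis=0, keepdims=True) + c
    return num / np.maximum(den, 1e-300)


@dataclass
class RigidCPDResult:
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # (3,)
    scale: float
    sigma2: float
    iterations: int
    degenerate: bool = False

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation


def rigid_cpd(
    moving: np.ndarray,
    fixed: np.ndarray,
    w: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RigidCPDResult:
    """Rigid (similarity) CPD: EM fit of a rotation/translation/scale.

    The moving set is treated as Gaussian-mixture centroids fit to the fixed
    set, with a uniform outlier component of weight ``w``.  Deterministic for
    fixed inputs.
    """
    Y0 = np.atleast_2d(np.asarray(moving, dtype=float))
    X0 = np.atleast_2d(np.asarray(fixed, dtype=float))
    if Y0.shape[0] < 4 or X0.shape[0] < 4:
        raise PreconditionError("rigid_cpd needs >= 4 points in each set")
    d = X0.shape[1]
    degenerate = False
    sv = np.linalg.svd(Y0 - Y0.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        degenerate = True
        warnings.warn("rigid_cpd: moving points are (near) collinear", stacklevel=2)

    # normalize both clouds (zero mean, shared unit RMS scale) so the
    # uniform-outlier density is commensurate with the Gaussian components
    mu_x0 = X0.mean(axis=0)
    mu_y0 = Y0.mean(axis=0)
    norm_scale = max(
        np.sqrt(((X0 - mu_x0) ** 2).sum(axis=1).mean()),
        np.sqrt(((Y0 - mu_y0) ** 2).sum(axis=1).mean()),
        1e-9,
    )
    X = (X0 - mu_x0) / norm_scale
    Y = (Y0 - mu_y0) / norm_scale

    R = np.eye(d)
    t = np.zeros(d)
    s = 1.0
    sigma2 = cdist(X, Y, "sqeuclidean").mean() / d
    it = 0
    for it in range(1, max_iter + 1):
        TY = s * Y @ R.T + t
        P = _cpd_posterior(TY, X, sigma2, w)
        Np = P.sum()
        if Np < 1e-12:
            break
        P1 = P.sum(axis=1)  # (M,)
        Pt1 = P.sum(axis=0)  # (N,)
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y) / Np
        Xh = X - mu_x
        Yh = Y - mu_y
        A = Xh.T @ P.T @ Yh
        U, S, Vt = np.linalg.svd(A)
        C = np.eye(d)
        C[-1, -1] = np.sign(np.linalg.det(U @ Vt))
        R = U @ C @ Vt
        trace_sc = float(np.trace(np.diag(S) @ C))
        denom = float((P1 * (Yh**2).sum(axis=1)).sum())
        s = trace_sc / max(denom, 1e-12)
        t = mu_x - s * R @ mu_y
        sigma2_new = (
            float((Pt1 * (Xh**2).sum(axis=1)).sum()) - s * trace_sc
        ) / (Np * d)
        sigma2_new = max(sigma2_new, 1e-10)
        if abs(sigma2 - sigma2_new) < tol:
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    # undo the normalization: x0 = s R y0 + (mu_x - s R mu_y + scale * t)
    t_world = mu_x0 - s * R @ mu_y0 + norm_scale * t
    return RigidCPDResult(R, t_world, s, sigma2, it, degenerate)


@dataclass
class NonRigidCPDResult:
    displaced: np.ndarray  # moving points carried into fixed space, (M, 3)
    correspondence: np.ndarray  # index of the most probable fixed point, (M,)
    confidence: np.ndarray  # posterior mass of that fixed point per row, (M,)
    sigma2: float
    iterations: int


def nonrigid_cpd(
    moving: np.ndarray,
    fixed: np.ndarray,
    beta: float = 2.0,
    lam: float = 3.0,
    w: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NonRigidCPDResult:
    """Non-rigid CPD with a Gaussian motion-coherence kernel.

    ``beta`` (kernel width) and ``lam`` (regularization weight) are expressed
    in units of the normalized point-cloud scale: both clouds are shifted to
    zero mean and divided by a shared RMS scale before the EM iterations, and
    the displaced points are mapped back afterwards.
    """
    Y0 = np.atleast_2d(np.asarray(moving, dtype=float))
    X0 = np.atleast_2d(np.asarray(fixed, dtype=float))
    if Y0.shape[0] < 5 or X0.shape[0] < 5:
        raise PreconditionError("nonrigid_cpd needs >= 5 points in each set")
    d = X0.shape[1]
    mu_x = X0.mean(axis=0)
    mu_y = Y0.mean(axis=0)
    scale = max(
        np.sqrt(((X0 - mu_x) ** 2).sum(axis=1).mean()),
        np.sqrt(((Y0 - mu_y) ** 2).sum(axis=1).mean()),
        1e-9,
    )
    X = (X0 - mu_x) / scale
    Y = (Y0 - mu_y) / scale

    G = np.exp(-cdist(Y, Y, "sqeuclidean") / (2.0 * beta**2))
    W = np.zeros_like(Y)
    # start the annealing at the scale of the actual residual displacements
    # (nearest-neighbour distances) rather than the whole cloud extent:
    # centerline points are densely spaced, and a cloud-scale sigma lets the
    # curve slide along itself into an off-by-one local optimum
    d2 = cdist(X, Y, "sqeuclidean")
    sigma2 = min(
        d2.mean() / d,
        max(5.0 * 0.5 * (d2.min(axis=0).mean() + d2.min(axis=1).mean()) / d, 1e-8),
    )
    P = None
    it = 0
    for it in range(1, max_iter + 1):
        TY = Y + G @ W
        P = _cpd_posterior(TY, X, sigma2, w)
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = P.sum()
        if Np < 1e-12:
            break
        lhs = G * P1[:, None] + lam * sigma2 * np.eye(Y.shape[0])
        rhs = P @ X - P1[:, None] * Y
        W = np.linalg.solve(lhs, rhs)
        TY = Y + G @ W
        xPx = float((Pt1 * (X**2).sum(axis=1)).sum())
        trPXT = float(((P @ X) * TY).sum())
        yPy = float((P1 * (TY**2).sum(axis=1)).sum())
        sigma2_new = max((xPx - 2.0 * trPXT + yPy) / (Np * d), 1e-10)
        if abs(sigma2 - sigma2_new) < tol:
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    TY = Y + G @ W
    corr = np.argmax(P, axis=1)
    row_mass = P.sum(axis=1)
    conf = P[np.arange(P.shape[0]), corr] / np.maximum(row_mass, 1e-300)
    displaced = TY * scale + mu_x
    return NonRigidCPDResult(displaced, corr, conf, sigma2, it)


# ---------------------------------------------------------------------------
# Match bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class MatchCandidate:
    post_tree_id: int
    pre_tree_id: int
    dsc_target: float
    dsc_surround: float
    dscp: float
    r: float
    phase: str  # "I" or "II"


@dataclass
class MatchResult:
    pairs: list[MatchCandidate] = field(default_factory=list)
    unmatched_post: list[int] = field(default_factory=list)
    unmatched_pre: list[int] = field(default_factory=list)
    unmatched_reasons: dict[int, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def matched_post_ids(self) -> set[int]:
        return {c.post_tree_id for c in self.pairs}

    def matched_pre_ids(self) -> set[int]:
        return {c.pre_tree_id for c in self.pairs}

    def summary(self, total_post: int, total_pre: int) -> dict[str, int]:
        p1 = sum(1 for c in self.pairs if c.phase == "I")
        p2 = sum(1 for c in self.pairs if c.phase == "II")
        return {
            "total_post": total_post,
            "total_pre": total_pre,
            "phase1_matched": p1,
            "phase1_unmatched": total_post - p1,
            "phase2_matched": p1 + p2,
            "phase2_unmatched": total_post - p1 - p2,
        }


@dataclass
class FeaturePointSet:
    """Paired post-operative centerline points and mapped pre-operative points."""

    post_points: np.ndarray  # (N, 3) mm, post-operative localized space
    pre_points: np.ndarray  # (N, 3) mm, pre-operative space
    source_tree: np.ndarray  # (N,) pair ids (post tree id of the source pair)

    def __post_init__(self) -> None:
        self.post_points = np.atleast_2d(np.asarray(self.post_points, dtype=float))
        self.pre_points = np.atleast_2d(np.asarray(self.pre_points, dtype=float))
        self.source_tree = np.asarray(self.source_tree, dtype=int)
        if len(self.post_points) != len(self.pre_points) or len(
            self.post_points
        ) != len(self.source_tree):
            raise PreconditionError("feature point arrays must have equal length")

    def __len__(self) -> int:
        return len(self.post_points)

    @property
    def displacements(self) -> np.ndarray:
        """Per-pair displacement carrying post-operative content to pre space."""
        return self.pre_points - self.post_points

    def to_csv(self, path: str) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "pre_x": self.pre_points[:, 2],
                "pre_y": self.pre_points[:, 1],
                "pre_z": self.pre_points[:, 0],
                "post_x": self.post_points[:, 2],
                "post_y": self.post_points[:, 1],
                "post_z": self.post_points[:, 0],
                "tree_id": self.source_tree,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "FeaturePointSet":
        import pandas as pd

        df = pd.read_csv(path)
        pre = df[["pre_z", "pre_y", "pre_x"]].to_numpy(float)
        post = df[["post_z", "post_y", "post_x"]].to_numpy(float)
        return cls(post, pre, df["tree_id"].to_numpy(int))


# ---------------------------------------------------------------------------
# Phase I
# ---------------------------------------------------------------------------


def _tree_mask_array(tree, shape) -> np.ndarray:
    arr = np.zeros(shape, dtype=bool)
    vox = tree.voxels
    arr[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return arr


def _paint_indices(idx: np.ndarray, shape) -> np.ndarray:
    arr = np.zeros(shape, dtype=bool)
    keep = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    idx = idx[keep]
    arr[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return arr


def _crop(arr: np.ndarray, center_idx: np.ndarray, size: int) -> np.ndarray:
    half = size // 2
    sl = tuple(
        slice(max(0, int(c) - half), min(n, int(c) + half))
        for c, n in zip(center_idx, arr.shape)
    )
    return arr[sl]


def phase1_match(
    pre_trees: list,
    post_trees: list,
    pre_vessels: BinaryMask,
    post_vessels: BinaryMask,
    dsc_target_min: float = 0.5,
    dsc_surround_min: float = 0.2,
    centroid_gate_mm: float = 30.0,
    crop_size: int = 60,
    cpd_w: float = 0.1,
) -> MatchResult:
    """Phase I: high-similarity one-to-one matches via rigid CPD + Dice.

    Both tree sets must live on the same (localized) grid.  For each post
    tree, candidate pre trees are those whose centroid lies within
    ``centroid_gate_mm``; each candidate pair is aligned with rigid CPD on the
    centerlines and scored by target Dice and surrounding-crop Dice.  Accepted
    greedily by descending target Dice with one-to-one enforcement.
    """
    if not pre_vessels.same_grid(post_vessels):
        raise GridMismatchError("phase1_match requires a common grid")
    shape = pre_vessels.shape
    grid = pre_vessels
    pre_masks = {t.id: _tree_mask_array(t, shape) for t in pre_trees}
    post_vessel_world = grid.index_to_world(np.argwhere(post_vessels.data))

    candidates: list[MatchCandidate] = []
    for pt in post_trees:
        for pr in pre_trees:
            if np.linalg.norm(pt.centroid - pr.centroid) > centroid_gate_mm:
                continue
            if len(pt.skeleton) < 4 or len(pr.skeleton) < 4:
                # degenerate (blob-like) centerline: fall back to centroid
                # translation so compact trees can still be scored
                rigid = RigidCPDResult(
                    np.eye(3), pr.centroid - pt.centroid, 1.0, 0.0, 0, True
                )
            else:
                rigid = rigid_cpd(pt.skeleton, pr.skeleton, w=cpd_w)
            # Transform the post tree mask onto the pre grid.
            moved = rigid.apply(grid.index_to_world(pt.voxels))
            moved_idx = np.round(grid.world_to_index(moved)).astype(int)
            moved_mask = _paint_indices(moved_idx, shape)
            pre_mask = pre_masks[pr.id]
            inter = int((moved_mask & pre_mask).sum())
            dsc_t = _dice_counts(int(moved_mask.sum()), int(pre_mask.sum()), inter)
            if dsc_t < dsc_target_min:
                continue
            # Surrounding-area similarity on crops centred at the pre centroid.
            moved_vessel_idx = np.round(
                grid.world_to_index(rigid.apply(post_vessel_world))
            ).astype(int)
            moved_vessels = _paint_indices(moved_vessel_idx, shape)
            center = np.round(grid.world_to_index(pr.centroid)[0]).astype(int)
            ca = _crop(pre_vessels.data, center, crop_size)
            cb = _crop(moved_vessels, center, crop_size)
            dsc_s = _dice_counts(
                int(ca.sum()), int(cb.sum()), int((ca & cb).sum())
            )
            if dsc_s < dsc_surround_min:
                continue
            r = max(pt.volume, pr.volume) / min(pt.volume, pr.volume)
            candidates.append(
                MatchCandidate(pt.id, pr.id, dsc_t, dsc_s, dsc_t / r**2, r, "I")
            )

    candidates.sort(key=lambda c: (-c.dsc_target, c.post_tree_id, c.pre_tree_id))
    result = MatchResult()
    used_post: set[int] = set()
    used_pre: set[int] = set()
    for c in candidates:
        if c.post_tree_id in used_post or c.pre_tree_id in used_pre:
            continue
        result.pairs.append(c)
        used_post.add(c.post_tree_id)
        used_pre.add(c.pre_tree_id)
    result.unmatched_post = [t.id for t in post_trees if t.id not in used_post]
    result.unmatched_pre = [t.id for t in pre_trees if t.id not in used_pre]
    result.counts = result.summary(len(post_trees), len(pre_trees))
    return result


# ---------------------------------------------------------------------------
# Phase II
# ---------------------------------------------------------------------------


def phase2_match(
    result: MatchResult,
    pre_trees: list,
    post_trees: list,
    pre_vessels: BinaryMask,
    dscp_min: float = 0.3,
    dilation_mm: float = 3.0,
) -> MatchResult:
    """Phase II: relative-positioning matches for trees Phase I left over.

    Each unmatched post tree is translated by the mean centroid offset of its
    three nearest matched pairs (the search centre), dilated by
    ``dilation_mm`` to tolerate slight bending, and compared against the
    unmatched pre trees its search mask touches.  The score divides the Dice
    of the dilated placed mask by the squared undilated volume ratio, so a
    small tree cannot buy a match from a much larger one.  Updates and
    returns ``result`` in place.
    """
    post_by_id = {t.id: t for t in post_trees}
    pre_by_id = {t.id: t for t in pre_trees}
    grid = pre_vessels
    shape = pre_vessels.shape
    matched = list(result.pairs)
    pending = [post_by_id[i] for i in list(result.unmatched_post)]

    if len(matched) < 3:
        for t in pending:
            result.unmatched_reasons[t.id] = "insufficient_phase1_matches"
        result.counts = result.summary(len(post_trees), len(pre_trees))
        return result

    anchors_post = np.array([post_by_id[c.post_tree_id].centroid for c in matched])
    anchors_pre = np.array([pre_by_id[c.pre_tree_id].centroid for c in matched])
    offsets = anchors_pre - anchors_post

    fp = ball_footprint(dilation_mm, grid.spacing[0])
    scored: list[MatchCandidate] = []
    for pt in pending:
        near = np.argsort(np.linalg.norm(anchors_post - pt.centroid, axis=1))[:3]
        local_offset = offsets[near].mean(axis=0)
        shift_vox = np.round(local_offset / np.asarray(grid.spacing)).astype(int)
        placed = _paint_indices(pt.voxels + shift_vox, shape)
        if not placed.any():
            result.unmatched_reasons[pt.id] = "placed_outside_grid"
            continue
        from scipy import ndimage as ndi

        placed_dil = ndi.binary_dilation(placed, structure=fp)
        best: MatchCandidate | None = None
        for pr in pre_trees:
            if pr.id in result.matched_pre_ids():
                continue
            pre_mask = _tree_mask_array(pr, shape)
            inter_gate = placed_dil & pre_mask
            if not inter_gate.any():
                continue
            dsc = _dice_counts(
                int(placed_dil.sum()), int(pre_mask.sum()), int(inter_gate.sum())
            )
            r = max(pt.volume, pr.volume) / min(pt.volume, pr.volume)
            dscp = dsc / r**2
            cand = MatchCandidate(pt.id, pr.id, dsc, float("nan"), dscp, r, "II")
            if best is None or cand.dscp > best.dscp:
                best = cand
        if best is not None:
            scored.append(best)
        else:
            result.unmatched_reasons[pt.id] = "no_overlapping_candidate"

    scored.sort(key=lambda c: (-c.dscp, c.post_tree_id, c.pre_tree_id))
    for c in scored:
        if c.dscp < dscp_min:
            result.unmatched_reasons[c.post_tree_id] = "below_dscp_threshold"
            continue
        if c.post_tree_id in result.matched_post_ids() or (
            c.pre_tree_id in result.matched_pre_ids()
        ):
            result.unmatched_reasons[c.post_tree_id] = "one_to_one_conflict"
            continue
        result.pairs.append(c)

    matched_post = result.matched_post_ids()
    matched_pre = result.matched_pre_ids()
    result.unmatched_post = [t.id for t in post_trees if t.id not in matched_post]
    result.unmatched_pre = [t.id for t in pre_trees if t.id not in matched_pre]
    result.counts = result.summary(len(post_trees), len(pre_trees))
    return result


def match_trees(
    pre_trees: list,
    post_trees: list,
    pre_vessels: BinaryMask,
    post_vessels: BinaryMask,
    **kwargs,
) -> MatchResult:
    """Run Phase I followed by Phase II with default thresholds."""
    phase1_kwargs = {
        k: kwargs[k]
        for k in (
            "dsc_target_min",
            "dsc_surround_min",
            "centroid_gate_mm",
            "crop_size",
            "cpd_w",
        )
        if k in kwargs
    }
    phase2_kwargs = {
        k: kwargs[k] for k in ("dscp_min", "dilation_mm") if k in kwargs
    }
    result = phase1_match(pre_trees, post_trees, pre_vessels, post_vessels, **phase1_kwargs)
    return phase2_match(result, pre_trees, post_trees, pre_vessels, **phase2_kwargs)


# ---------------------------------------------------------------------------
# Feature points
# ---------------------------------------------------------------------------


def build_feature_points(
    result: MatchResult,
    pre_trees: list,
    post_trees: list,
    confidence_min: float = 0.5,
    beta: float = 2.0,
    lam: float = 3.0,
    cpd_w: float = 0.1,
) -> FeaturePointSet:
    """Map post centerline points to pre space per accepted pair via non-rigid CPD.

    Points whose maximum CPD posterior falls below ``confidence_min`` are
    dropped as outliers (e.g. branch segments absent from the other scan).
    """
    if not result.pairs:
        raise PipelineError("no accepted tree pairs; registration impossible")
    pre_by_id = {t.id: t for t in pre_trees}
    post_by_id = {t.id: t for t in post_trees}
    posts, pres, src = [], [], []
    for c in result.pairs:
        pt = post_by_id[c.post_tree_id]
        pr = pre_by_id[c.pre_tree_id]
        if len(pt.skeleton) < 5 or len(pr.skeleton) < 5:
            continue  # degenerate centerline (e.g. a blob-like component)
        res = nonrigid_cpd(pt.skeleton, pr.skeleton, beta=beta, lam=lam, w=cpd_w)
        keep = res.confidence >= confidence_min
        if not keep.any():
            continue
        posts.append(pt.skeleton[keep])
        pres.append(res.displaced[keep])
        src.append(np.full(int(keep.sum()), c.post_tree_id, dtype=int))
    if not posts:
        raise PipelineError("all feature points rejected as outliers")
    return FeaturePointSet(
        np.vstack(posts), np.vstack(pres), np.concatenate(src)
    )
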