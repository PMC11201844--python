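"""Discontinuous deformation fields via selective-control-point thin-plate splines.

A classical TPS fit through *all* matched feature points yields a globally
continuous deformation, which cannot represent the displacement jump across a
surgical resection.  Here each evaluation voxel gets its *own* control-point
subset:

1. A candidate radius grows exponentially with distance from the tumor,
   ``R = 2 * dmax * exp(a * (d / dmax - 1))`` — small near the tumor (local
   deformation), approaching ``2 * dmax`` far away (global deformation).
2. Feature pairs whose post-operative point falls inside the radius are
   clustered by DBSCAN *in displacement space*; the cluster whose members sit
   nearest the voxel wins, so control points moving with a different
   displacement regime (the far side of a resection) are excluded.
3. An exact-interpolation 3D TPS (kernel U(r) = r) fit on the selected subset
   supplies the voxel's displacement.

The result is continuous wherever one displacement regime dominates and free
to jump where regimes meet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .errors import EmptyInputError, PreconditionError
from .imaging import BinaryMask, ImageVolume, dilate_mm, surface_mask
from .matching import FeaturePointSet


def candidate_radius(d: float, dmax: float, a: float = 3.0):
    """Candidate sphere radius ``R = 2 * dmax * exp(a * (d/dmax - 1))`` (mm).

    Strictly increasing in ``d``; equals ``2 * dmax`` at ``d = dmax``.
    Accepts scalars or arrays.
    """
    if np.any(np.asarray(dmax) <= 0):
        raise PreconditionError("dmax must be > 0")
    if np.any(np.asarray(d) < 0):
        raise PreconditionError("d must be >= 0")
    return 2.0 * dmax * np.exp(a * (np.asarray(d, dtype=float) / dmax - 1.0))


# ---------------------------------------------------------------------------
# Thin-plate spline (3D, kernel U(r) = r)
# ---------------------------------------------------------------------------


@dataclass
class TPSTransform:
    """Exact-interpolation 3D TPS ``f(x) = affine(x) + sum_i w_i |x - c_i|``."""

    control: np.ndarray  # (n, 3) source points
    weights: np.ndarray  # (n, 3)
    affine: np.ndarray  # (4, 3): rows constant + linear

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        K = cdist(pts, self.control)
        P = np.hstack([np.ones((len(pts), 1)), pts])
        return K @ self.weights + P @ self.affine


def tps_fit(
    control_src: np.ndarray, control_dst: np.ndarray, ridge: float = 0.0
) -> TPSTransform:
    """Fit a 3D thin-plate spline interpolating src -> dst exactly.

    Solves the standard bordered system with kernel ``U(r) = r`` (the 3D
    biharmonic interpolant) and a full affine part.  Degenerate (coplanar)
    control sets fall back to a ridge-regularized solve (1e-6) with a warning.
    """
    src = np.atleast_2d(np.asarray(control_src, dtype=float))
    dst = np.atleast_2d(np.asarray(control_dst, dtype=float))
    if src.shape != dst.shape:
        raise PreconditionError("control point sets must have the same shape")
    n = src.shape[0]
    if n < 4:
        raise PreconditionError("tps_fit needs >= 4 control points")
    K = cdist(src, src)
    P = np.hstack([np.ones((n, 1)), src])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + ridge * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst
    try:
        sol = np.linalg.solve(A, rhs)
        if not np.isfinite(sol).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if ridge == 0.0:
            import warnings

            warnings.warn(
                "degenerate TPS control set; using ridge-regularized solve",
                stacklevel=2,
            )
            return tps_fit(src, dst, ridge=1e-6)
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return TPSTransform(src, sol[:n], sol[n:])


# ---------------------------------------------------------------------------
# Control point selection
# ---------------------------------------------------------------------------


@dataclass
class RegistrationParams:
    """Tunables of the selective-TPS field construction."""

    a: float = 3.0  # candidate-radius growth parameter
    dbscan_eps: float = 2.0  # mm, in displacement space
    dbscan_min_pts: int = 5
    k_fallback: int = 15  # nearest pairs used when clustering is impossible
    stride: int = 4  # evaluation lattice stride, voxels (= mm on a 1 mm grid)
    max_control_points: int = 300  # cap per TPS fit (deterministic thinning)
    exact: bool = False  # evaluate at every voxel instead of the strided lattice


def select_control_points(
    voxel_mm: np.ndarray,
    tumor_centroid: np.ndarray,
    dmax: float,
    fps: FeaturePointSet,
    params: RegistrationParams | None = None,
    tree: cKDTree | None = None,
) -> np.ndarray:
    """Indices of the feature pairs controlling the TPS at ``voxel_mm``.

    Candidates are pairs whose post point lies within the candidate radius;
    DBSCAN groups them by displacement, noise points are discarded, and the
    cluster whose members' mean position is nearest the voxel is returned
    (ties: larger cluster, then lower cluster id).  If there are fewer than
    ``dbscan_min_pts`` candidates or DBSCAN finds no cluster, the
    ``k_fallback`` nearest pairs by position are used instead.
    """
    params = params or RegistrationParams()
    if len(fps) == 0:
        raise EmptyInputError("feature point set is empty")
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    if tree is None:
        tree = cKDTree(fps.post_points)
    d = float(np.linalg.norm(voxel_mm - np.asarray(tumor_centroid, dtype=float)))
    R = float(candidate_radius(d, dmax, params.a))
    cand = np.asarray(sorted(tree.query_ball_point(voxel_mm, R)), dtype=int)

    def _fallback() -> np.ndarray:
        k = min(params.k_fallback, len(fps))
        _, idx = tree.query(voxel_mm, k=k)
        return np.sort(np.atleast_1d(idx).astype(int))

    if len(cand) < params.dbscan_min_pts:
        return _fallback()
    disp = fps.displacements[cand]
    labels = DBSCAN(eps=params.dbscan_eps, min_samples=params.dbscan_min_pts).fit(
        disp
    ).labels_
    cluster_ids = np.unique(labels[labels >= 0])
    if cluster_ids.size == 0:
        return _fallback()
    best = None
    for cid in cluster_ids:
        members = cand[labels == cid]
        dist = float(
            np.linalg.norm(fps.post_points[members].mean(axis=0) - voxel_mm)
        )
        key = (dist, -len(members), cid)
        if best is None or key < best[0]:
            best = (key, members)
    return best[1]


# ---------------------------------------------------------------------------
# Displacement field
# ---------------------------------------------------------------------------


@dataclass
class DisplacementField:
    """Per-voxel displacement (mm) carrying post-operative content to pre space."""

    vectors: np.ndarray  # (nz, ny, nx, 3) float32 mm
    valid: np.ndarray  # (nz, ny, nx) bool
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def sample(self, pts_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear field values at world points; second array flags validity."""
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        idx = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        coords = idx.T
        out = np.stack(
            [
                ndi.map_coordinates(
                    self.vectors[..., c], coords, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=1,
        )
        ok = (
            ndi.map_coordinates(
                self.valid.astype(np.float32), coords, order=0, mode="constant"
            )
            > 0.5
        )
        return out, ok


def _node_lattice(region: np.ndarray, stride: int):
    """Strided node indices covering ``region`` (coarse grid index arrays)."""
    shape = region.shape
    coarse_shape = tuple(int(np.ceil(n / stride)) for n in shape)
    zz, yy, xx = np.meshgrid(
        *[np.arange(c) * stride for c in coarse_shape], indexing="ij"
    )
    return coarse_shape, np.stack([zz, yy, xx], axis=-1)


def compute_dmax(tumor: BinaryMask, lung: BinaryMask) -> float:
    """Furthest distance (mm) from the tumor centroid to the lung surface."""
    c = tumor.centroid_mm()
    surf = np.argwhere(surface_mask(lung).data)
    pts = lung.index_to_world(surf)
    return float(np.linalg.norm(pts - c, axis=1).max())


def build_displacement_field(
    fps: FeaturePointSet,
    tumor: BinaryMask,
    lung: BinaryMask,
    params: RegistrationParams | None = None,
    all_points: bool = False,
) -> DisplacementField:
    """Displacement field on the lung region of the reference grid.

    Per evaluation node (strided lattice, nearest upsampling), a
    control-point subset is selected and an exact TPS supplies the node
    displacement; ``all_points=True`` instead fits one classical TPS through
    every feature pair (the continuous baseline).  TPS fits are cached by
    control subset, so neighbouring nodes sharing a selection reuse one
    solve.
    """
    params = params or RegistrationParams()
    if len(fps) < max(4, params.dbscan_min_pts if not all_points else 4):
        raise PreconditionError("too few feature pairs to build a field")
    if not tumor.data.any() or not lung.data.any():
        raise EmptyInputError("tumor and lung masks must be non-empty")
    grid = lung
    region = dilate_mm(lung, 2.0 * params.stride).data
    tumor_centroid = tumor.centroid_mm()
    dmax = compute_dmax(tumor, lung)
    kdtree = cKDTree(fps.post_points)

    if all_points:
        global_tps = tps_fit(fps.post_points, fps.pre_points)

        def node_displacement(world: np.ndarray) -> np.ndarray:
            return global_tps(world)[0] - world

    else:
        cache: dict = {}

        def _spans_3d(pts: np.ndarray) -> bool:
            if len(pts) < 4:
                return False
            sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
            return sv[2] > 1e-6 * max(sv[0], 1.0)

        def node_displacement(world: np.ndarray) -> np.ndarray:
            sel = select_control_points(
                world, tumor_centroid, dmax, fps, params, kdtree
            )
            if len(sel) > params.max_control_points:
                thin = np.linspace(0, len(sel) - 1, params.max_control_points)
                sel = sel[np.unique(thin.astype(int))]
            # a coplanar control set leaves the TPS affine part unconstrained
            # in the normal direction; augment with nearest pairs until the
            # set spans 3D (or the whole set is exhausted)
            if not _spans_3d(fps.post_points[sel]):
                k = min(len(fps), max(32, 2 * len(sel)))
                _, near = kdtree.query(world, k=k)
                for idx in np.atleast_1d(near):
                    if idx in sel:
                        continue
                    sel = np.sort(np.append(sel, idx))
                    if _spans_3d(fps.post_points[sel]):
                        break
            key = sel.tobytes()
            entry = cache.get(key)
            if entry is None:
                tps = tps_fit(fps.post_points[sel], fps.pre_points[sel])
                d_sel = fps.pre_points[sel] - fps.post_points[sel]
                entry = (tps, d_sel.min(axis=0), d_sel.max(axis=0))
                cache[key] = entry
            tps, d_lo, d_hi = entry
            disp = tps(world)[0] - world
            # beyond the control points the TPS affine trend extrapolates
            # linearly; allow it a limited reach (half the observed spread,
            # at least 1 mm) past the per-component displacement range of the
            # node's own control points so saturating motion is followed but
            # runaway extrapolation is cut off
            slack = np.maximum(0.5 * (d_hi - d_lo), 1.0)
            return np.clip(disp, d_lo - slack, d_hi + slack)

    stride = 1 if params.exact else max(1, int(params.stride))
    coarse_shape, nodes = _node_lattice(region, stride)
    coarse = np.zeros(coarse_shape + (3,), dtype=np.float32)
    node_idx = nodes.reshape(-1, 3)
    # only evaluate nodes whose stride-cell intersects the region
    active = np.zeros(len(node_idx), dtype=bool)
    for i, nidx in enumerate(node_idx):
        cell = tuple(
            slice(nidx[a], min(nidx[a] + stride, region.shape[a])) for a in range(3)
        )
        active[i] = region[cell].any()
    worlds = grid.index_to_world(node_idx)
    flat = coarse.reshape(-1, 3)
    for i in np.nonzero(active)[0]:
        flat[i] = node_displacement(worlds[i])
    # nearest fill of inactive nodes so upsampling has no seams at the border
    if (~active).any() and active.any():
        act3 = active.reshape(coarse_shape)
        _, inds = ndi.distance_transform_edt(~act3, return_indices=True)
        coarse = coarse[inds[0], inds[1], inds[2]]

    if stride == 1:
        vectors = coarse[: region.shape[0], : region.shape[1], : region.shape[2]]
    else:
        up = np.repeat(
            np.repeat(np.repeat(coarse, stride, axis=0), stride, axis=1),
            stride,
            axis=2,
        )
        vectors = up[: region.shape[0], : region.shape[1], : region.shape[2]]
    return DisplacementField(
        vectors.astype(np.float32), region, grid.spacing, grid.origin
    )


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------


def _invert_field(field: DisplacementField, iterations: int = 8) -> np.ndarray:
    """Fixed-point inverse: for each target voxel y find x with x + u(x) = y.

    Returns the source *index* coordinates for every grid voxel.
    """
    shape = field.valid.shape
    sp = np.asarray(field.spacing)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij")
    y_idx = np.stack(grids, axis=0)  # (3, nz, ny, nx)
    u_idx = np.moveaxis(field.vectors, -1, 0) / sp[:, None, None, None]
    x_idx = y_idx.copy()
    for _ in range(iterations):
        u_at_x = np.stack(
            [
                ndi.map_coordinates(u_idx[c], x_idx, order=1, mode="nearest")
                for c in range(3)
            ]
        )
        x_idx = y_idx - u_at_x
    return x_idx


def warp_with_field(
    obj: ImageVolume | BinaryMask, field: DisplacementField
) -> ImageVolume | BinaryMask:
    """Apply the displacement field to post-operative content.

    A voxel at post position ``x`` lands at ``x + u(x)``; warping is realized
    by inverting the field (fixed-point iteration) and back-sampling, nearest
    for masks and linear for volumes.  A zero field is the identity; voxels
    whose source falls outside the validity region become background.
    """
    if obj.shape != field.valid.shape:
        raise PreconditionError("object and field grids differ")
    src_idx = _invert_field(field)
    is_mask = isinstance(obj, BinaryMask)
    out = ndi.map_coordinates(
        obj.data.astype(np.float32),
        src_idx,
        order=0 if is_mask else 1,
        mode="constant",
        cval=0.0 if is_mask else -1000.0,
    )
    inside = np.ones(obj.shape, dtype=bool)
    for c in range(3):
        inside &= (src_idx[c] >= -0.5) & (src_idx[c] <= obj.shape[c] - 0.5)
    if is_mask:
        return BinaryMask((out > 0.5) & inside, obj.spacing, obj.origin)
    data = np.where(inside, out, -1000.0)
    return ImageVolume(data, obj.spacing, obj.origin)


def write_field(field: DisplacementField, path: str) -> None:
    """Serialize as a 4-component NIfTI (3 vector components + validity)."""
    import SimpleITK as sitk

    stacked = np.concatenate(
        [field.vectors, field.valid[..., None].astype(np.float32)], axis=-1
    )
    img = sitk.GetImageFromArray(stacked, isVector=True)
    img.SetSpacing(tuple(reversed(field.spacing)))
    img.SetOrigin(tuple(reversed(field.origin)))
    sitk.WriteImage(img, path)


def read_field(path: str) -> DisplacementField:
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    arr = sitk.GetArrayFromImage(img)
    return DisplacementField(
        arr[..., :3].astype(np.float32),
        arr[..., 3] > 0.5,
        tuple(reversed(img.GetSpacing())),
        tuple(reversed(img.GetOrigin())),
    )
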