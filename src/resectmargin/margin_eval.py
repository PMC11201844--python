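"""Resection-margin measurement, TRE, MIP slabs, and the paired comparison test.

The resection margin is the closest 3D Euclidean distance between the surface
of the deformed post-operative lung mask (the reconstructed cut surface) and
the pre-operative tumor surface, both expressed on the common pre-operative
1 mm grid.  Sub-voxel margins are reported with a "<1.00 mm" sentinel, since
a distance below one voxel is not resolvable on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    GeometryError,
    GridMismatchError,
    PreconditionError,
)
from .imaging import BinaryMask, ImageVolume, surface_mask
from .registration import DisplacementField

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MarginResult:
    distance: float  # mm
    point_on_resection: np.ndarray  # (3,) mm
    point_on_tumor: np.ndarray  # (3,) mm
    resection_region: BinaryMask
    overlap: bool = False

    @property
    def sentinel(self) -> str:
        """Table-style rendering; sub-voxel margins print as ``<1.00``."""
        if self.overlap:
            return "0.00 (overlap)"
        if self.distance < 1.0:
            return "<1.00"
        return f"{self.distance:.2f}"


@dataclass
class LandmarkPair:
    pre_point: np.ndarray  # (3,) mm, pre-operative world
    post_point: np.ndarray  # (3,) mm, post-operative world
    label: str = ""

    def __post_init__(self) -> None:
        self.pre_point = np.asarray(self.pre_point, dtype=float).reshape(3)
        self.post_point = np.asarray(self.post_point, dtype=float).reshape(3)


@dataclass
class TREReport:
    errors: np.ndarray  # per-landmark mm
    excluded: int = 0

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float).reshape(-1)

    @property
    def mean(self) -> float:
        return float(self.errors.mean())

    @property
    def sd(self) -> float:
        return float(self.errors.std(ddof=1)) if len(self.errors) > 1 else 0.0

    @property
    def max(self) -> float:
        return float(self.errors.max())

    @property
    def min(self) -> float:
        return float(self.errors.min())

    def to_dict(self) -> dict:
        return {
            "n": int(len(self.errors)),
            "excluded": int(self.excluded),
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "max_mm": self.max,
            "min_mm": self.min,
        }


def measure_margin(
    warped_post_lung: BinaryMask,
    pre_tumor: BinaryMask,
    pre_lung: BinaryMask,
    resection_band_mm: float = 2.0,
) -> MarginResult:
    """Closest distance between the deformed post-lung surface and the tumor.

    The resection region is the pre-operative lung not covered by the warped
    post-operative lung (largest component near the tumor); the candidate
    "resection edge" is the warped-lung surface within ``resection_band_mm``
    of that region, which keeps distant chest-wall surface points out of the
    search.  Exact to voxel resolution via a Euclidean distance transform;
    ties broken by lexicographically smallest surface index.
    """
    for m in (pre_tumor, pre_lung):
        if not warped_post_lung.same_grid(m):
            raise GridMismatchError("margin masks must share the pre-operative grid")
    if not pre_tumor.data.any():
        raise EmptyInputError("tumor mask is empty")
    if not warped_post_lung.data.any():
        raise EmptyInputError("warped lung mask is empty")
    if not (pre_tumor.data & pre_lung.data).any():
        raise GeometryError("tumor lies entirely outside the pre-operative lung")
    spacing = warped_post_lung.spacing

    resection = pre_lung.data & ~warped_post_lung.data
    labels, n = ndi.label(resection, structure=_CONN26)
    if n > 1:
        # component nearest the tumor; ties -> larger component
        dt_tumor = ndi.distance_transform_edt(~pre_tumor.data, sampling=spacing)
        best_lab, best_key = 0, None
        for lab in range(1, n + 1):
            sel = labels == lab
            key = (float(dt_tumor[sel].min()), -int(sel.sum()), lab)
            if best_key is None or key < best_key:
                best_lab, best_key = lab, key
        resection = labels == best_lab
    resection_mask = warped_post_lung.like(resection)

    if (warped_post_lung.data & pre_tumor.data).any():
        return MarginResult(
            0.0,
            np.full(3, np.nan),
            np.full(3, np.nan),
            resection_mask,
            overlap=True,
        )

    lung_surface = surface_mask(warped_post_lung).data
    if resection.any():
        dt_res = ndi.distance_transform_edt(~resection, sampling=spacing)
        edge = lung_surface & (dt_res <= resection_band_mm)
        if not edge.any():
            edge = lung_surface
    else:
        edge = lung_surface

    tumor_surface = surface_mask(pre_tumor).data
    dt, inds = ndi.distance_transform_edt(
        ~tumor_surface, sampling=spacing, return_indices=True
    )
    edge_idx = np.argwhere(edge)  # lexicographic
    dists = dt[edge_idx[:, 0], edge_idx[:, 1], edge_idx[:, 2]]
    best = int(np.argmin(dists))  # argmin returns the first (lexicographic) tie
    p_res_idx = edge_idx[best]
    p_tum_idx = inds[:, p_res_idx[0], p_res_idx[1], p_res_idx[2]]
    p_res = warped_post_lung.index_to_world(p_res_idx)[0]
    p_tum = warped_post_lung.index_to_world(p_tum_idx)[0]
    return MarginResult(float(dists[best]), p_res, p_tum, resection_mask)


def compute_tre(
    landmarks: list[LandmarkPair], disp_field: DisplacementField
) -> TREReport:
    """Target registration error of the field at landmark pairs.

    Per landmark: ``error = ||(post + u(post)) - pre||`` with the field
    sampled trilinearly at the post-operative point.  Landmarks outside the
    field validity region are excluded and counted.
    """
    if not landmarks:
        raise PreconditionError("at least one landmark is required")
    post = np.array([lm.post_point for lm in landmarks])
    pre = np.array([lm.pre_point for lm in landmarks])
    u, ok = disp_field.sample(post)
    if not ok.any():
        raise PreconditionError("no landmark lies inside the field validity region")
    if not ok.all():
        import warnings

        warnings.warn(
            f"{int((~ok).sum())} landmark(s) outside field validity excluded",
            stacklevel=2,
        )
    errors = np.linalg.norm(post[ok] + u[ok] - pre[ok], axis=1)
    return TREReport(errors, excluded=int((~ok).sum()))


def mip_slab(
    vol: ImageVolume, axis: int, center_index: int, slabs: int = 5
) -> np.ndarray:
    """Maximum intensity projection over ``slabs`` slices centred on an index."""
    half = slabs // 2
    n = vol.shape[axis]
    if not (half <= center_index <= n - 1 - half):
        raise PreconditionError("MIP slab extends outside the volume")
    sl = [slice(None)] * 3
    sl[axis] = slice(center_index - half, center_index + half + 1)
    return np.asarray(vol.data[tuple(sl)]).max(axis=axis)


def significance_stars(p: float) -> str:
    """Conventional significance annotation: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def paired_t_test(errors_a, errors_b) -> tuple[float, float]:
    """Classical paired t statistic on the differences (two-sided p, n-1 df)."""
    a = np.asarray(errors_a, dtype=float).reshape(-1)
    b = np.asarray(errors_b, dtype=float).reshape(-1)
    if len(a) != len(b) or len(a) < 2:
        raise PreconditionError("paired_t_test needs equal-length samples, n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        raise DegenerateInputError("zero-variance nonzero differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Landmark CSV I/O (columns: label, pre_x, pre_y, pre_z, post_x, post_y, post_z)
# ---------------------------------------------------------------------------


def read_landmarks(path: str) -> list[LandmarkPair]:
    import pandas as pd

    df = pd.read_csv(path)
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            LandmarkPair(
                pre_point=(row["pre_z"], row["pre_y"], row["pre_x"]),
                post_point=(row["post_z"], row["post_y"], row["post_x"]),
                label=str(row.get("label", "")),
            )
        )
    return pairs


def write_landmarks(pairs: list[LandmarkPair], path: str) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "label": [p.label for p in pairs],
            "pre_x": [p.pre_point[2] for p in pairs],
            "pre_y": [p.pre_point[1] for p in pairs],
            "pre_z": [p.pre_point[0] for p in pairs],
            "post_x": [p.post_point[2] for p in pairs],
            "post_y": [p.post_point[1] for p in pairs],
            "post_z": [p.post_point[0] for p in pairs],
        }
    )
    df.to_csv(path, index=False)
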