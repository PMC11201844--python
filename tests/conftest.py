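"""Shared fixtures: phantom pairs, pipeline runs, and synthetic tree sets."""

from __future__ import annotations

import numpy as np
import pytest

from resectmargin.imaging import BinaryMask
from resectmargin.phantom import PhantomSpec, bifurcation_landmarks, generate_phantom
from resectmargin.pipeline import PipelineConfig, run_pipeline_volumes
from resectmargin.segmentation import extract_subvascular_trees


@pytest.fixture(scope="session")
def phantom_truth():
    """The default 160-cube paired phantom with a 10 mm-margin resection."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def phantom_landmarks(phantom_truth):
    return bifurcation_landmarks(phantom_truth, 20)


@pytest.fixture(scope="session")
def full_run(phantom_truth, phantom_landmarks):
    """Full pipeline on the default phantom (shared across the suite)."""
    seed = tuple(int(round(c)) for c in phantom_truth.spec.tumor_center)
    return run_pipeline_volumes(
        phantom_truth.pre_volume,
        phantom_truth.post_volume,
        tumor_seed=seed,
        landmarks=phantom_landmarks,
        cfg=PipelineConfig(),
    )


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 112-cube phantom small enough for repeated pipeline runs."""
    base = dict(
        seed=7,
        shape=(112, 112, 112),
        body_center=(56.0, 56.0, 56.0),
        body_semiaxes=(50.0, 46.0, 52.0),
        lung_centers=((56.0, 52.0, 34.0), (56.0, 52.0, 78.0)),
        lung_semiaxes=(38.0, 22.0, 17.0),
        trees_per_lung=2,
        tumor_center=(82.0, 52.0, 78.0),
        tumor_radius=8.0,
        resection_offset=None,
        warp_amplitude=0.0,
        collapse_amplitude=0.0,
        noise_sd=10.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_phantom_spec())


def run_self_pair(truth):
    """Pipeline on an identical pre/post pair (degenerate no-surgery case)."""
    seed = tuple(int(round(c)) for c in truth.spec.tumor_center)
    coincident = [
        type(lm)(lm.pre_point, lm.pre_point.copy(), lm.label)
        for lm in bifurcation_landmarks(truth, 10)
    ]
    return run_pipeline_volumes(
        truth.pre_volume,
        truth.pre_volume,
        tumor_seed=seed,
        landmarks=coincident,
        cfg=PipelineConfig(),
    )


@pytest.fixture(scope="session")
def self_pair_runs(small_phantom):
    """Two independent self-pair runs, for degenerate-case and determinism checks."""
    return run_self_pair(small_phantom), run_self_pair(small_phantom)


# ---------------------------------------------------------------------------
# Two-regime displacement scene (resection-plane discontinuity)
# ---------------------------------------------------------------------------


def box_mask(shape, lo, hi):
    arr = np.zeros(shape, dtype=bool)
    arr[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return BinaryMask(arr, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def sphere_mask(shape, center, radius):
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    arr = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (
        xx - center[2]
    ) ** 2 <= radius**2
    return BinaryMask(arr, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def lattice_feature_points(box=(10, 54), step=4.0, disp_fn=None):
    """Feature pairs on a regular lattice with a per-point displacement."""
    from resectmargin.matching import FeaturePointSet

    ax = np.arange(box[0], box[1], step, dtype=float)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    post = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    disp = np.zeros_like(post) if disp_fn is None else disp_fn(post)
    return FeaturePointSet(post, post + disp, np.zeros(len(post), dtype=int))


@pytest.fixture(scope="session")
def two_regime_scene():
    """Feature pairs with a 6 mm displacement jump across the plane x = 32."""
    shape = (64, 64, 64)
    lung = box_mask(shape, (8, 8, 8), (56, 56, 56))
    tumor = sphere_mask(shape, (32, 32, 20), 4.0)

    def disp(p):
        d = np.zeros_like(p)
        d[p[:, 2] >= 32.0, 2] = 6.0
        return d

    fps = lattice_feature_points(box=(10, 54), step=4.0, disp_fn=disp)
    return fps, tumor, lung


@pytest.fixture(scope="session")
def two_regime_fields(two_regime_scene):
    """Selective and all-control-point fields for the two-regime scene."""
    from resectmargin.registration import build_displacement_field

    fps, tumor, lung = two_regime_scene
    selective = build_displacement_field(fps, tumor, lung)
    baseline = build_displacement_field(fps, tumor, lung, all_points=True)
    return selective, baseline


# ---------------------------------------------------------------------------
# Synthetic tube-tree sets for matching tests
# ---------------------------------------------------------------------------


def paint_tube(arr: np.ndarray, start, direction, length, radius, bend=0.0):
    """Paint a (optionally bent) tube of the given radius into ``arr``."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    perp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(perp, d)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp -= np.dot(perp, d) * d
    perp /= np.linalg.norm(perp)
    shape = np.asarray(arr.shape)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in arr.shape], indexing="ij")
    for t in np.arange(0.0, length, 0.5):
        p = start + t * d + bend * np.sin(np.pi * t / length) * perp
        lo = np.maximum(0, np.floor(p - radius - 1).astype(int))
        hi = np.minimum(shape, np.ceil(p + radius + 2).astype(int))
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        dist2 = (
            (zz[sl] - p[0]) ** 2 + (yy[sl] - p[1]) ** 2 + (xx[sl] - p[2]) ** 2
        )
        arr[sl] |= dist2 <= radius**2
    return arr


def tube_tree_scene(
    n_trees: int = 6,
    shape=(72, 96, 96),
    translate=(0.0, 0.0, 0.0),
    orphan: bool = False,
    drop_last: bool = False,
):
    """Bent parallel tubes (irregular lengths/spacing) as a vessel scene.

    Returns ``(vessels_mask, trees)``; the slight bend keeps centerlines
    non-collinear and irregular geometry breaks translational symmetry so
    surrounding-area crops can disambiguate neighbours.
    """
    arr = np.zeros(shape, dtype=bool)
    lengths = [40, 34, 46, 38, 50, 36][:n_trees]
    xs = np.cumsum([14] + [15, 18, 14, 17, 16][: n_trees - 1])
    zs = [20, 34, 48, 24, 40, 52][:n_trees]
    count = n_trees - 1 if drop_last else n_trees
    for i in range(count):
        start = np.asarray([zs[i], 20.0, float(xs[i])]) + np.asarray(translate)
        paint_tube(arr, start, (0.0, 1.0, 0.0), lengths[i], radius=3.0, bend=2.5)
    if orphan:
        paint_tube(arr, (12.0, 30.0, 80.0), (0.0, 1.0, 0.0), 30, radius=3.0, bend=2.5)
    mask = BinaryMask(arr, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    return mask, extract_subvascular_trees(mask)
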