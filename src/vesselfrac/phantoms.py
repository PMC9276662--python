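"""Synthetic inputs with known ground truth.

Three families of phantoms exercise every stage of the pipeline:

* **Analytic 2D fractals** (line, filled rectangle, Sierpinski triangle,
  Koch curve, random branching tree) whose box-counting dimension is
  known in closed form, for validating the estimator.
* **3D vessel volumes**: bright tubular bifurcating trees on a noisy dark
  background, emulating the bright-blood contrast of time-of-flight MR
  angiography, with the exact centerline returned as ground truth. A
  ``rarefaction`` parameter prunes terminal branches, providing a tunable
  "reduced vascular complexity" axis.
* **Two-group cohort tables** whose dimension distributions follow the
  group means/SDs reported for subjects with and without white-matter
  hyperintensities, with a 10-year cardiovascular risk score (QRISK2)
  negatively rank-coupled to the dimension through a Gaussian copula.

All generators are bit-deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import line as draw_line

from .projection import Volume3D
from .segmentation import BinaryMask

__all__ = [
    "FractalPhantomSpec",
    "VesselVolumeSpec",
    "CohortSpec",
    "make_fractal_phantom",
    "make_vessel_volume",
    "make_cohort",
    "THEORETICAL_DIMENSIONS",
]

#: analytic box-counting dimensions of the deterministic phantom kinds
THEORETICAL_DIMENSIONS = {
    "line": 1.0,
    "filled_rect": 2.0,
    "sierpinski_triangle": math.log(3) / math.log(2),
    "koch_curve": math.log(4) / math.log(3),
}

_KINDS = {"line", "filled_rect", "sierpinski_triangle", "koch_curve",
          "random_branching_tree"}

# ---------------------------------------------------------------------------
# 2D fractal phantoms


@dataclass(frozen=True)
class FractalPhantomSpec:
    """Recipe for a 2D binary fractal phantom.

    ``order`` is the recursion depth where applicable; deterministic
    kinds ignore ``seed`` entirely.
    """

    kind: str
    size_px: int = 512
    order: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unsupported phantom kind {self.kind!r}")
        if self.size_px < 32:
            raise ValueError("size_px must be >= 32")
        if self.order < 0:
            raise ValueError("order must be >= 0")


def _sierpinski(size: int, order: int) -> tuple[np.ndarray, int]:
    """Right-angle Sierpinski gasket by quadrant subdivision.

    Each level splits a square cell into four and keeps three; leaves are
    filled. Returns the image and the number of elementary (leaf)
    triangles, 3**order.
    """
    if size / 2**order < 1:
        raise ValueError(
            f"order {order} too deep for size_px {size}: elementary cell < 1 px"
        )
    img = np.zeros((size, size), dtype=np.uint8)
    n_leaves = 0
    stack = [(0.0, 0.0, float(size), order)]
    while stack:
        r0, c0, s, d = stack.pop()
        if d == 0:
            img[int(round(r0)):int(round(r0 + s)),
                int(round(c0)):int(round(c0 + s))] = 1
            n_leaves += 1
        else:
            h = s / 2
            stack.append((r0, c0, h, d - 1))
            stack.append((r0 + h, c0, h, d - 1))
            stack.append((r0 + h, c0 + h, h, d - 1))
    return img, n_leaves


def _koch_polyline(order: int) -> np.ndarray:
    """Vertices of the order-n Koch curve on the unit interval (complex)."""
    pts = np.array([0.0 + 0j, 1.0 + 0j])
    rot = np.exp(1j * np.pi / 3)
    for _ in range(order):
        new = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            d = (b - a) / 3
            new.extend([a + d, a + d + d * rot, a + 2 * d, b])
        pts = np.array(new)
    return pts


def _rasterize_polyline(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    for i in range(len(rows) - 1):
        rr, cc = draw_line(int(round(rows[i])), int(round(cols[i])),
                           int(round(rows[i + 1])), int(round(cols[i + 1])))
        img[rr, cc] = 1


def _koch(size: int, order: int) -> np.ndarray:
    if (size - 2) / 3**order < 1:
        raise ValueError(
            f"order {order} too deep for size_px {size}: segment < 1 px"
        )
    pts = _koch_polyline(order)
    width = size - 2
    # curve peaks rise to height sqrt(3)/6 of the base; place near the bottom
    cols = 1 + pts.real * width
    rows = size - 2 - pts.imag * width
    img = np.zeros((size, size), dtype=np.uint8)
    _rasterize_polyline(img, rows, cols)
    return img


def _branching_tree_2d(size: int, order: int, seed: int) -> np.ndarray:
    """Seeded recursive bifurcating tree drawn with 1-px strokes."""
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size), dtype=np.uint8)
    depth = order if order > 0 else 6
    length0 = size * 0.30
    angle0 = np.pi / 2  # pointing up (decreasing row)
    stack = [((size - 2.0, size / 2.0), angle0, length0, depth)]
    while stack:
        (r, c), ang, length, d = stack.pop()
        r2 = r - length * np.sin(ang)
        c2 = c + length * np.cos(ang)
        r2 = float(np.clip(r2, 0, size - 1))
        c2 = float(np.clip(c2, 0, size - 1))
        _rasterize_polyline(img, np.array([r, r2]), np.array([c, c2]))
        if d > 1 and length >= 2:
            spread = 0.55 + rng.normal(0, 0.12)
            for sign in (-1.0, 1.0):
                child = ang + sign * spread + rng.normal(0, 0.08)
                stack.append(((r2, c2), child, length * 0.72, d - 1))
    return img


def make_fractal_phantom(spec: FractalPhantomSpec) -> BinaryMask:
    """Render the phantom named by ``spec``.

    The mask's ``meta`` carries the analytic dimension
    (``theoretical_dimension``; None for the random tree) and, for the
    Sierpinski gasket, the number of elementary triangles.
    """
    size = spec.size_px
    meta: dict = {"kind": spec.kind,
                  "theoretical_dimension": THEORETICAL_DIMENSIONS.get(spec.kind)}
    if spec.kind == "line":
        img = np.zeros((size, size), dtype=np.uint8)
        img[size // 2, :] = 1
    elif spec.kind == "filled_rect":
        img = np.ones((size, size), dtype=np.uint8)
    elif spec.kind == "sierpinski_triangle":
        img, n_leaves = _sierpinski(size, spec.order)
        meta["n_elementary_triangles"] = n_leaves
    elif spec.kind == "koch_curve":
        img = _koch(size, spec.order)
    elif spec.kind == "random_branching_tree":
        img = _branching_tree_2d(size, spec.order, spec.seed)
    else:  # pragma: no cover - guarded by the spec validator
        raise ValueError(f"unsupported phantom kind {spec.kind!r}")
    return BinaryMask(img, provenance="phantom", meta=meta)


# ---------------------------------------------------------------------------
# 3D vessel volumes


@dataclass(frozen=True)
class VesselVolumeSpec:
    """Recipe for a bright-vessel 3D volume.

    Geometry: a bifurcating tree grown upward from the volume base;
    branch radius decays geometrically by ``radius_decay`` per
    generation, ``tortuosity`` is the SD (radians) of the per-segment
    angular jitter, and ``rarefaction`` prunes that fraction of terminal
    branches (floor(r * n_terminal) of them, chosen by the seed).
    Contrast: vessel voxels take ``vessel_intensity``; the background is
    additive Gaussian noise clipped at zero, mimicking bright-blood
    angiographic contrast.
    """

    shape_vox: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_generations: int = 5
    radius_root_px: float = 4.0
    radius_decay: float = 0.8
    tortuosity: float = 0.15
    rarefaction: float = 0.0
    vessel_intensity: float = 100.0
    background_noise_sd: float = 5.0
    global_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape_vox) < 8:
            raise ValueError("shape_vox dimensions must be >= 8")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be positive")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.radius_root_px <= 0:
            raise ValueError("radius_root_px must be positive")
        if self.radius_root_px >= min(self.shape_vox) / 2:
            raise ValueError("radius_root_px must be < min(shape_vox)/2")
        if not (0 < self.radius_decay <= 1):
            raise ValueError("radius_decay must be in (0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if not (0 <= self.rarefaction <= 1):
            raise ValueError("rarefaction must be in [0, 1]")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to v."""
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    return (v * np.cos(angle)
            + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1 - np.cos(angle)))


_BRANCH_ANGLE = 0.6  # radians; fixed bifurcation half-angle
_LENGTH_DECAY = 0.75
_SUBSEGMENTS = 4


def _grow_tree(spec: VesselVolumeSpec, rng: np.random.Generator):
    """Build the branch list: dicts with polyline points (float voxel
    coords), radius (px) and generation. Terminals are the leaves."""
    shape = np.array(spec.shape_vox, dtype=float)
    # trunk grows in the projection plane (axis 0), so the tree stays
    # visible in the default axial maximum-intensity projection
    root = np.array([2.0, shape[1] / 2, shape[2] / 2])
    direction = np.array([1.0, 0.0, 0.0])
    # trunk length chosen so the whole tree (sum of generation lengths)
    # roughly spans the volume regardless of depth
    depth_extent = sum(_LENGTH_DECAY**g for g in range(spec.n_generations))
    length0 = 0.8 * (min(spec.shape_vox) - 4) * spec.global_scale / depth_extent
    branches = []

    def grow(start, dirn, length, radius, gen):
        pts = [start.copy()]
        d = dirn.copy()
        p = start.copy()
        for _ in range(_SUBSEGMENTS):
            if spec.tortuosity > 0:
                axis = _perp(d, rng)
                d = _unit(_rotate(d, axis, rng.normal(0, spec.tortuosity)))
            p = p + d * (length / _SUBSEGMENTS)
            p = np.clip(p, 1.0, shape - 2.0)
            pts.append(p.copy())
        branches.append({"points": np.array(pts), "radius": radius,
                         "generation": gen})
        idx = len(branches) - 1
        if gen + 1 < spec.n_generations:
            axis = _perp(d, rng)
            azim = rng.uniform(0, np.pi)
            axis = _unit(_rotate(axis, d, azim))
            for sign in (-1.0, 1.0):
                child_dir = _unit(_rotate(d, axis, sign * _BRANCH_ANGLE))
                grow(p, child_dir, length * _LENGTH_DECAY,
                     radius * spec.radius_decay, gen + 1)
        return idx

    grow(root, direction, length0, spec.radius_root_px, 0)
    return branches


def _rasterize_tree(branches, spec: VesselVolumeSpec):
    """Mark voxels within each branch radius of its centerline; distance
    is Euclidean in mm (anisotropy-corrected). Returns the boolean vessel
    volume and the unique rounded centerline voxels."""
    shape = spec.shape_vox
    vox = np.array(spec.voxel_mm)
    vessel = np.zeros(shape, dtype=bool)
    center_vox = set()
    for br in branches:
        radius_mm = br["radius"] * spec.voxel_mm[0]
        half = np.maximum(np.ceil(radius_mm / vox).astype(int), 0)
        og = np.stack(np.meshgrid(*[np.arange(-h, h + 1) for h in half],
                                  indexing="ij"), axis=-1).reshape(-1, 3)
        keep = (np.linalg.norm(og * vox, axis=1) <= radius_mm + 1e-9)
        ball = og[keep]
        pts = br["points"]
        for a, b in zip(pts[:-1], pts[1:]):
            seg_len = np.linalg.norm(b - a)
            n = max(2, int(np.ceil(seg_len / 0.5)) + 1)
            for t in np.linspace(0.0, 1.0, n):
                p = a + t * (b - a)
                c = np.round(p).astype(int)
                center_vox.add((int(c[0]), int(c[1]), int(c[2])))
                v = ball + c
                ok = np.all((v >= 0) & (v < np.array(shape)), axis=1)
                v = v[ok]
                vessel[v[:, 0], v[:, 1], v[:, 2]] = True
    centerline = np.array(sorted(center_vox), dtype=int)
    return vessel, centerline


def make_vessel_volume(spec: VesselVolumeSpec) -> tuple[Volume3D, np.ndarray]:
    """Generate a bright-tree volume and its ground-truth centerline.

    Returns
    -------
    (Volume3D, ndarray of shape (n, 3))
        The grayscale volume and the sorted integer voxel coordinates of
        the exact centerline used to draw the tubes.

    The tree structure for a given seed is identical at every
    ``rarefaction`` level; pruning only removes terminal branches, so
    increasing rarefaction strictly decreases the centerline voxel count.
    """
    ss = np.random.SeedSequence(spec.seed)
    tree_rng, prune_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(3)]

    branches = _grow_tree(spec, tree_rng)
    terminal_idx = [i for i, b in enumerate(branches)
                    if b["generation"] == spec.n_generations - 1]
    n_prune = int(np.floor(spec.rarefaction * len(terminal_idx)))
    pruned = set()
    if n_prune > 0:
        pruned = set(prune_rng.choice(terminal_idx, size=n_prune, replace=False))
    kept = [b for i, b in enumerate(branches) if i not in pruned]

    vessel, centerline = _rasterize_tree(kept, spec)
    data = np.zeros(spec.shape_vox, dtype=float)
    if spec.background_noise_sd > 0:
        data = np.clip(
            noise_rng.normal(0.0, spec.background_noise_sd, size=spec.shape_vox),
            0.0, None)
    data[vessel] = spec.vessel_intensity
    vol = Volume3D(data, voxel_mm=spec.voxel_mm)
    return vol, centerline


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group subject table.

    Defaults reproduce the reported study conditions: 8 subjects with
    low white-matter-hyperintensity burden (dimension 1.5172 +/- 0.0248)
    vs 14 without (1.5653 +/- 0.0304), a Spearman coupling of -0.656
    between the QRISK2 score and the averaged dimension, and a per-rater
    measurement noise small enough for near-perfect inter-rater
    agreement.
    """

    n_pos: int = 8
    n_neg: int = 14
    mean_pos: float = 1.5172
    sd_pos: float = 0.0248
    mean_neg: float = 1.5653
    sd_neg: float = 0.0304
    qrisk_coupling: float = -0.656
    rater_noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise ValueError("group SDs must be positive")
        if abs(self.qrisk_coupling) > 1:
            raise ValueError("qrisk_coupling must lie in [-1, 1]")
        if self.rater_noise_sd < 0:
            raise ValueError("rater_noise_sd must be >= 0")


# group covariate marginals (WMH+ , WMH-): mean, sd
_AGE = ((47.0, 13.0), (38.0, 11.0))
_BMI = ((26.2, 3.2), (22.6, 3.1))
_SBP = ((139.63, 16.21), (123.14, 11.73))
_TCHDL = ((3.26, 0.49), (3.82, 0.63))
_P_MALE = (2 / 8, 5 / 14)
# pooled QRISK2 marginal (right-skewed): mean, sd
_QRISK_POOLED = (3.11, 4.22)
_DF_EPS = 1e-6


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one subject table.

    The true dimension is a group-specific truncated normal on (1, 2).
    The QRISK2 score is drawn from a pooled lognormal through a Gaussian
    copula with correlation 2 sin(pi * qrisk_coupling / 6) against the
    pooled dimension ranks, so the realized rank correlation converges
    to ``qrisk_coupling``. Two rater columns
    add independent Gaussian measurement noise to the latent true
    dimension; with ``rater_noise_sd=0`` they agree exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    is_pos = np.zeros(n, dtype=bool)
    is_pos[: spec.n_pos] = True

    u = rng.standard_normal(n)
    df_true = np.empty(n)
    for pos, (m, s) in ((True, (spec.mean_pos, spec.sd_pos)),
                        (False, (spec.mean_neg, spec.sd_neg))):
        sel = is_pos == pos
        a, b = (1.0 - m) / s, (2.0 - m) / s
        q = np.clip(stats.norm.cdf(u[sel]), 1e-12, 1 - 1e-12)
        df_true[sel] = stats.truncnorm.ppf(q, a, b, loc=m, scale=s)
    df_true = np.clip(df_true, 1.0 + _DF_EPS, 2.0 - _DF_EPS)

    # Gaussian copula anchored to the *pooled* dimension ranks, so the
    # realized rank correlation converges to qrisk_coupling even though
    # the two groups have different marginal transforms of u
    rho_g = 2.0 * math.sin(math.pi * spec.qrisk_coupling / 6.0)
    pooled_scores = stats.norm.ppf((stats.rankdata(df_true) - 0.5) / n)
    v = rho_g * pooled_scores \
        + math.sqrt(max(0.0, 1.0 - rho_g**2)) * rng.standard_normal(n)

    mu_q, sig_q = _lognorm_params(*_QRISK_POOLED)
    qv = np.clip(stats.norm.cdf(v), 1e-12, 1 - 1e-12)
    qrisk = np.exp(mu_q + sig_q * stats.norm.ppf(qv))

    def _cov(params):
        m = np.where(is_pos, params[0][0], params[1][0])
        s = np.where(is_pos, params[0][1], params[1][1])
        return m + s * rng.standard_normal(n)

    age = np.clip(np.round(_cov(_AGE)), 25, 75).astype(int)
    bmi = np.clip(_cov(_BMI), 14, 45)
    sbp = np.clip(_cov(_SBP), 80, 220)
    tchdl = np.clip(_cov(_TCHDL), 1.0, 10.0)
    p_male = np.where(is_pos, _P_MALE[0], _P_MALE[1])
    sex = np.where(rng.uniform(size=n) < p_male, "M", "F")

    if spec.rater_noise_sd > 0:
        r1 = df_true + rng.normal(0, spec.rater_noise_sd, n)
        r2 = df_true + rng.normal(0, spec.rater_noise_sd, n)
        r1 = np.clip(r1, 1.0 + _DF_EPS, 2.0 - _DF_EPS)
        r2 = np.clip(r2, 1.0 + _DF_EPS, 2.0 - _DF_EPS)
    else:
        r1 = df_true.copy()
        r2 = df_true.copy()

    return pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "group": np.where(is_pos, "WMH_pos", "WMH_neg"),
        "age": age,
        "sex": sex,
        "bmi": np.round(bmi, 2),
        "sbp": np.round(sbp, 2),
        "tchdl": np.round(tchdl, 3),
        "qrisk2": np.round(qrisk, 4),
        "df_rater1": r1,
        "df_rater2": r2,
        "df_mean": 0.5 * (r1 + r2),
    })
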