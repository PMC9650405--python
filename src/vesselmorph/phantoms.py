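"""Ground-truthed tubular phantoms emulating segmented great vessels.

The morphometry stage consumes binary segmentations of the aorta and the
pulmonary artery.  No clinical masks ship with the package, so every phantom
here carries its exact analytic truth: the centerline polyline, the local
tube radius along it, the anchor point marking the "heart-exit"/trunk-origin
end, and (for the bifurcation kind) the branching point.

A phantom voxel is foreground iff its center lies within the local tube
radius of the analytic centerline curve; optional segmentation noise then
flips surface-adjacent voxels independently.  Tube ends are therefore rounded
(capsule-like), which keeps the medial axis of the solid equal to the
analytic curve itself.

Kinds
-----
``cylinder``
    Straight tube of constant radius along an arbitrary unit axis.
``tapered_cylinder``
    Straight tube whose radius varies linearly from ``r_start`` to ``r_end``.
``arc_tube``
    Tube following a circular arc (radius ``arc_radius_mm``, angle
    ``arc_angle_deg``) — the aorta stand-in.
``bifurcation``
    Straight trunk splitting into two equal daughter tubes at a configurable
    opening angle — the pulmonary-artery stand-in.  The anchor is the free
    trunk end (pulmonic-valve side); the truth centerline is the trunk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .io import VolumeMask, write_mask

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "make_vessel_pair"]

_KINDS = ("cylinder", "tapered_cylinder", "arc_tube", "bifurcation")

#: arc-length step (mm) at which analytic centerlines are sampled
_CURVE_STEP_MM = 0.1


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vessel.

    ``tube_radius_mm`` is a scalar, or a ``(r_start, r_end)`` pair for the
    tapered kind.  The radius must be at least 3x the coarsest voxel spacing
    (resolvability floor).
    """

    kind: str
    tube_radius_mm: float | tuple[float, float]
    length_mm: float | None = None
    arc_radius_mm: float | None = None
    arc_angle_deg: float | None = None
    branch_radius_mm: float | None = None
    branch_angle_deg: float = 60.0
    branch_length_mm: float = 20.0
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 1.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_flip_prob: float = 0.0
    seed: int = 0
    margin_voxels: int = 2

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not 0.0 <= self.noise_flip_prob < 1.0:
            raise ValueError("noise_flip_prob must be in [0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.min_radius_mm < 3.0 * max(self.spacing_mm):
            raise ValueError(
                f"unresolvable radius {self.min_radius_mm} mm for spacing "
                f"{self.spacing_mm} (need radius >= 3 x max spacing)"
            )
        if self.kind in ("cylinder", "tapered_cylinder", "bifurcation"):
            if self.length_mm is None or self.length_mm <= 0:
                raise ValueError(f"{self.kind} requires a positive length_mm")
        if self.kind == "arc_tube":
            if not (self.arc_radius_mm and self.arc_angle_deg):
                raise ValueError("arc_tube requires arc_radius_mm and arc_angle_deg")

    @property
    def radii(self) -> tuple[float, float]:
        r = self.tube_radius_mm
        return (float(r[0]), float(r[1])) if np.iterable(r) else (float(r), float(r))

    @property
    def min_radius_mm(self) -> float:
        radii = [min(self.radii)]
        if self.kind == "bifurcation":
            radii.append(self.daughter_radius_mm)
        return min(radii)

    @property
    def daughter_radius_mm(self) -> float:
        if self.branch_radius_mm is not None:
            return float(self.branch_radius_mm)
        return 0.7 * max(self.radii)

    @property
    def unit_axis(self) -> np.ndarray:
        u = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(u)
        if n == 0:
            raise ValueError("axis must be nonzero")
        return u / n


@dataclass(frozen=True)
class PhantomTruth:
    """Exact analytic geometry of a phantom (all coordinates in mm)."""

    centerline_mm: np.ndarray  # (N, 3) main-vessel polyline, anchor end first
    arclen_mm: np.ndarray  # (N,) cumulative arc length from the anchor
    radius_mm: np.ndarray  # (N,) local tube radius
    anchor_mm: np.ndarray  # (3,) measurement anchor (heart-exit / trunk origin)
    bifurcation_mm: np.ndarray | None = None  # (3,) branching point, if any

    @property
    def length_mm(self) -> float:
        return float(self.arclen_mm[-1])

    def diameter_at(self, arclen_from_anchor_mm: float | np.ndarray) -> np.ndarray:
        """True diameter (mm) at arc-length positions measured from the anchor."""
        return 2.0 * np.interp(arclen_from_anchor_mm, self.arclen_mm, self.radius_mm)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "centerline_mm": self.centerline_mm.tolist(),
            "arclen_mm": self.arclen_mm.tolist(),
            "radius_mm": self.radius_mm.tolist(),
            "anchor_mm": self.anchor_mm.tolist(),
            "bifurcation_mm": None
            if self.bifurcation_mm is None
            else self.bifurcation_mm.tolist(),
            "true_diameter_mm": (2.0 * self.radius_mm).tolist(),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _orthonormal(u: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to u (deterministic choice)."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    return v / np.linalg.norm(v)


def _sample_segment(p0, p1, step=_CURVE_STEP_MM):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    length = np.linalg.norm(p1 - p0)
    n = max(2, int(np.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    return p0 + t[:, None] * (p1 - p0)


def _analytic_curves(spec: PhantomSpec):
    """Return (main polyline, main radii, extra polylines, extra radii, bif point)."""
    u = spec.unit_axis
    r0, r1 = spec.radii
    if spec.kind in ("cylinder", "tapered_cylinder"):
        pts = _sample_segment(np.zeros(3), spec.length_mm * u)
        s = np.linalg.norm(pts - pts[0], axis=1)
        radii = r0 + (r1 - r0) * s / s[-1]
        return pts, radii, [], [], None
    if spec.kind == "arc_tube":
        v = _orthonormal(u)
        r_arc = float(spec.arc_radius_mm)
        theta_max = np.deg2rad(float(spec.arc_angle_deg))
        n = max(2, int(np.ceil(r_arc * theta_max / _CURVE_STEP_MM)) + 1)
        theta = np.linspace(0.0, theta_max, n)
        pts = r_arc * (
            np.sin(theta)[:, None] * u + (1.0 - np.cos(theta))[:, None] * v
        )
        radii = np.full(n, r0)
        return pts, radii, [], [], None
    # bifurcation: trunk along u then two daughters opened in the (u, v) plane
    v = _orthonormal(u)
    trunk_end = spec.length_mm * u
    trunk = _sample_segment(np.zeros(3), trunk_end)
    half = np.deg2rad(spec.branch_angle_deg / 2.0)
    d_r = spec.daughter_radius_mm
    extras, extra_radii = [], []
    for sign in (+1.0, -1.0):
        direction = np.cos(half) * u + sign * np.sin(half) * v
        daughter = _sample_segment(
            trunk_end, trunk_end + spec.branch_length_mm * direction
        )
        extras.append(daughter)
        extra_radii.append(np.full(len(daughter), d_r))
    radii = np.full(len(trunk), r0)
    return trunk, radii, extras, extra_radii, trunk_end


def make_phantom(
    spec: PhantomSpec,
    grid_shape: tuple[int, int, int] | None = None,
    grid_origin_mm: tuple[float, float, float] | None = None,
) -> tuple[VolumeMask, PhantomTruth]:
    """Voxelize a phantom and return it with its analytic truth.

    A voxel is foreground iff its center lies within the local tube radius of
    the nearest centerline sample.  When ``noise_flip_prob`` > 0, voxels on
    the mask surface (mixed 6-neighbourhood) are flipped independently with
    that probability under ``spec.seed``.

    ``grid_shape``/``grid_origin_mm`` override the automatic bounding-box
    grid, e.g. to place two phantoms on a shared grid.
    """
    main_pts, main_radii, extras, extra_radii, bif = _analytic_curves(spec)
    all_pts = np.vstack([main_pts] + extras)
    all_radii = np.concatenate([main_radii] + extra_radii)

    spacing = np.asarray(spec.spacing_mm, float)
    rmax = float(all_radii.max())
    if grid_shape is None:
        lo = all_pts.min(axis=0) - rmax - spec.margin_voxels * spacing
        hi = all_pts.max(axis=0) + rmax + spec.margin_voxels * spacing
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / spacing[a])) + 1 for a in range(3))
        origin = tuple(lo)
    else:
        shape = tuple(int(n) for n in grid_shape)
        origin = (0.0, 0.0, 0.0) if grid_origin_mm is None else tuple(grid_origin_mm)
        span = np.asarray(origin) + (np.asarray(shape) - 1) * spacing
        if (all_pts.min(axis=0) - rmax < np.asarray(origin) - 1e-9).any() or (
            all_pts.max(axis=0) + rmax > span + 1e-9
        ).any():
            raise ValueError("phantom geometry exceeds the requested grid")

    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centers = np.asarray(origin) + idx * spacing
    tree = cKDTree(all_pts)
    dist, nearest = tree.query(centers, workers=-1)
    fg = dist <= all_radii[nearest] + 1e-9
    voxels = fg.reshape(shape).astype(np.uint8)

    if spec.noise_flip_prob > 0.0:
        voxels = _flip_surface(voxels, spec.noise_flip_prob, spec.seed)

    mask = VolumeMask(voxels, tuple(spacing), origin)
    arclen = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(main_pts, axis=0), axis=1))]
    )
    truth = PhantomTruth(
        centerline_mm=main_pts,
        arclen_mm=arclen,
        radius_mm=main_radii,
        anchor_mm=main_pts[0].copy(),
        bifurcation_mm=None if bif is None else np.asarray(bif, float),
    )
    return mask, truth


def _flip_surface(voxels: np.ndarray, prob: float, seed: int) -> np.ndarray:
    from scipy import ndimage

    fg = voxels.astype(bool)
    eroded = ndimage.binary_erosion(fg)
    dilated = ndimage.binary_dilation(fg)
    surface = dilated & ~eroded  # voxels adjacent to the boundary, either side
    rng = np.random.default_rng(seed)
    flips = surface & (rng.random(voxels.shape) < prob)
    out = fg ^ flips
    return out.astype(np.uint8)


def make_vessel_pair(
    ao_radius_mm: float = 17.4,
    pa_trunk_radius_mm: float = 13.9,
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 1.0),
    seed: int = 0,
    *,
    ao_arc_radius_mm: float = 40.0,
    ao_arc_length_mm: float = 50.0,
    pa_trunk_length_mm: float = 45.0,
    pa_branch_length_mm: float = 32.0,
    noise_flip_prob: float = 0.0,
) -> tuple[tuple[VolumeMask, PhantomTruth], tuple[VolumeMask, PhantomTruth]]:
    """An arc-tube "aorta" and a bifurcation "pulmonary artery" pair.

    Default radii (17.4 / 13.9 mm) realise the cohort-scale mean PA/Ao
    diameter ratio of 0.8.  The aorta arc must accommodate the 0.5-2.5 cm
    measurement window (length >= 35 mm) and the PA trunk the 0.5-1.5 cm
    window from the branching point (trunk >= 25 mm).
    """
    if ao_arc_length_mm < 35.0:
        raise ValueError(
            "aorta window does not fit: arc length must be >= 35 mm for the "
            "0.5-2.5 cm measurement window"
        )
    if pa_trunk_length_mm < 25.0:
        raise ValueError(
            "PA window does not fit: trunk length must be >= 25 mm for the "
            "0.5-1.5 cm window from the branching point"
        )
    arc_angle = np.rad2deg(ao_arc_length_mm / ao_arc_radius_mm)
    ao_spec = PhantomSpec(
        kind="arc_tube",
        tube_radius_mm=ao_radius_mm,
        arc_radius_mm=ao_arc_radius_mm,
        arc_angle_deg=arc_angle,
        spacing_mm=spacing_mm,
        noise_flip_prob=noise_flip_prob,
        seed=seed,
    )
    pa_spec = PhantomSpec(
        kind="bifurcation",
        tube_radius_mm=pa_trunk_radius_mm,
        length_mm=pa_trunk_length_mm,
        branch_length_mm=pa_branch_length_mm,
        spacing_mm=spacing_mm,
        noise_flip_prob=noise_flip_prob,
        seed=seed + 1,
    )
    return make_phantom(ao_spec), make_phantom(pa_spec)


def write_phantom(
    mask: VolumeMask, truth: PhantomTruth, prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.nii.gz`` plus a ``<prefix>.truth.json`` sidecar."""
    prefix = Path(prefix)
    mask_path = write_mask(mask, prefix.with_suffix(".nii.gz"))
    truth_path = truth.to_json(prefix.parent / (prefix.name + ".truth.json"))
    return mask_path, truth_path
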