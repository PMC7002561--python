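"""Synthetic angiographic volumes with known tubular ground truth.

Vessels are modelled as tubes along piecewise-linear centerlines with a
constant baseline radius and an optional focal narrowing: inside a given
arc-length span the radius is multiplied by a factor in (0, 1], emulating a
vasospastic segment (a 50% diameter narrowing is ``narrowing_factor=0.5``).
Because the volume/length ratio of a tube equals its mean cross-sectional
area, narrowing the diameter by a factor f scales the true ratio by f^2.

Every generated volume carries an analytic ground-truth record (centerline
length, cylinder volume, true ratio, and the exact voxel mask per tube) so
the reconstruction pipeline can be validated end to end without patient
data.  1 mm^3 of voxel volume is 1 uL, the unit identity used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass(frozen=True)
class TubeSpec:
    """One tube: a piecewise-linear centerline with an optional focal narrowing.

    Parameters
    ----------
    control_points
        Ordered (n, 3) world coordinates in mm, n >= 2.
    baseline_radius
        Tube radius in mm outside the narrowed zone.
    narrowing_factor
        Fraction of the baseline *diameter* retained inside ``narrowing_span``,
        in (0, 1].  1.0 means no narrowing.
    narrowing_span
        ``(start, stop)`` arc-length interval in mm along the centerline where
        the narrowing applies, within ``[0, total length]``.  ``None`` with
        ``narrowing_factor < 1`` narrows the whole tube.
    segment_label
        Free-form label carried into the ground truth.
    """

    control_points: tuple[tuple[float, float, float], ...]
    baseline_radius: float
    narrowing_factor: float = 1.0
    narrowing_span: tuple[float, float] | None = None
    segment_label: str = "tube"

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise PhantomError("control_points must be an ordered list of >= 2 3-D points")
        if not self.baseline_radius > 0:
            raise PhantomError("baseline_radius must be > 0")
        if not 0 < self.narrowing_factor <= 1:
            raise PhantomError("narrowing_factor must be in (0, 1]")
        if self.narrowing_span is not None:
            lo, hi = self.narrowing_span
            if not 0 <= lo < hi <= self.length + 1e-9:
                raise PhantomError(
                    f"narrowing_span {self.narrowing_span} outside [0, {self.length:.3f}]"
                )

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.control_points, dtype=float)

    @property
    def length(self) -> float:
        """Total centerline arc length in mm (closed form for a polyline)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        """Local radius (mm) at arc length(s) ``s`` along the centerline."""
        s = np.asarray(s, dtype=float)
        r = np.full(s.shape, self.baseline_radius)
        if self.narrowing_factor < 1.0:
            if self.narrowing_span is None:
                r *= self.narrowing_factor
            else:
                lo, hi = self.narrowing_span
                r[(s >= lo) & (s <= hi)] *= self.narrowing_factor
        return r

    def analytic_volume(self) -> float:
        """Exact tube volume in uL (piecewise cylinders; radius is piecewise constant)."""
        total = self.length
        if self.narrowing_factor >= 1.0 or self.narrowing_span is None:
            narrowed = total if self.narrowing_factor < 1.0 else 0.0
        else:
            lo, hi = self.narrowing_span
            narrowed = hi - lo
        r, f = self.baseline_radius, self.narrowing_factor
        return float(np.pi * r**2 * (total - narrowed) + np.pi * (r * f) ** 2 * narrowed)

    def analytic_ratio(self) -> float:
        """True volume/length ratio in uL/mm (= mean cross-sectional area)."""
        return self.analytic_volume() / self.length


@dataclass(frozen=True)
class PhantomSpec:
    """A full synthetic volume: grid geometry, tubes, intensities, noise."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    tubes: tuple[TubeSpec, ...]
    vessel_intensity: float = 400.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise PhantomError("grid_shape must have 3 components, each >= 8")
        if len(self.spacing) != 3 or any(not s > 0 for s in self.spacing):
            raise PhantomError("spacing components must be > 0")
        if not self.vessel_intensity > self.background_intensity:
            raise PhantomError("vessel_intensity must exceed background_intensity")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if not self.tubes:
            raise PhantomError("at least one tube is required")


@dataclass
class TubeTruth:
    """Analytic ground truth for one rasterized tube."""

    label: str
    length_mm: float
    volume_uL: float
    ratio_uL_per_mm: float
    mask: np.ndarray  # boolean, full grid shape


@dataclass
class PhantomTruth:
    """Ground truth for a whole phantom volume."""

    tubes: list[TubeTruth]
    vessel_mask: np.ndarray  # union of tube masks
    overlap: bool  # any voxel claimed by >= 2 tubes
    overlap_mask: np.ndarray = field(repr=False, default=None)


def resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Densely resample a polyline at <= ``step`` spacing.

    Returns ``(samples, arclengths)``: (m, 3) points and the arc length of
    each sample along the polyline.  Vertices are always included, so the
    resampled path is exact at the control points.
    """
    points = np.asarray(points, dtype=float)
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    samples = [points[0]]
    arcs = [0.0]
    s0 = 0.0
    for p, d, length in zip(points[:-1], seg, seg_len):
        if length == 0:
            continue
        n = max(1, int(np.ceil(length / step)))
        t = np.arange(1, n + 1) / n
        samples.extend(p + t[:, None] * d)
        arcs.extend(s0 + t * length)
        s0 += length
    return np.asarray(samples), np.asarray(arcs)


def _rasterize_tube(tube: TubeSpec, spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of voxels whose center is within the local tube radius.

    The centerline is resampled at 0.1 x min(spacing); a voxel belongs to the
    tube iff its center lies within the radius attached to the *nearest*
    centerline sample.  Deterministic and resolution-controlled.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = np.asarray(spec.grid_shape, dtype=int)
    step = 0.1 * spacing.min()
    samples, arcs = resample_polyline(tube.points, step)
    radii = tube.radius_at(arcs)

    # world extent of voxel centers is [0, (shape-1)*spacing] per axis
    lo = samples - radii[:, None]
    hi = samples + radii[:, None]
    extent = (shape - 1) * spacing
    if (lo < -0.5 * spacing).any() or (hi > extent + 0.5 * spacing).any():
        raise PhantomError(f"tube {tube.segment_label!r} extends outside the grid")

    rmax = radii.max()
    i_lo = np.maximum(np.floor((samples.min(axis=0) - rmax) / spacing).astype(int), 0)
    i_hi = np.minimum(np.ceil((samples.max(axis=0) + rmax) / spacing).astype(int) + 1, shape)
    idx = np.stack(
        np.meshgrid(*(np.arange(a, b) for a, b in zip(i_lo, i_hi)), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = idx * spacing

    tree = cKDTree(samples)
    dist, nearest = tree.query(centers, workers=-1)
    inside = dist <= radii[nearest]

    # flat tube ends: drop the spherical caps the nearest-sample rule would
    # add beyond the first/last centerline point, so the voxelized volume
    # converges to the analytic piecewise-cylinder volume
    for end, sign in ((0, -1.0), (len(samples) - 1, 1.0)):
        sel = nearest == end
        if sel.any():
            tau = samples[-1] - samples[-2] if end else samples[1] - samples[0]
            tau = sign * tau / np.linalg.norm(tau)
            axial = (centers[sel] - samples[end]) @ tau
            inside[sel] &= axial <= 0.5 * step

    mask = np.zeros(tuple(shape), dtype=bool)
    sel = idx[inside]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


def generate_phantom_volume(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterize all tubes into a noisy scalar volume with analytic ground truth.

    Returns the float volume (background + vessel intensities + additive
    Gaussian noise with sd ``noise_sd``) and a :class:`PhantomTruth` listing,
    per tube, the analytic centerline length, cylinder volume, true ratio and
    exact voxel mask.  Overlapping tubes are permitted and flagged.
    """
    masks = [_rasterize_tube(t, spec) for t in spec.tubes]
    counts = np.sum(masks, axis=0)
    union = counts > 0
    overlap_mask = counts > 1

    volume = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    volume[union] = spec.vessel_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        volume += rng.normal(0.0, spec.noise_sd, size=volume.shape)

    truths = [
        TubeTruth(
            label=t.segment_label,
            length_mm=t.length,
            volume_uL=t.analytic_volume(),
            ratio_uL_per_mm=t.analytic_ratio(),
            mask=m,
        )
        for t, m in zip(spec.tubes, masks)
    ]
    truth = PhantomTruth(
        tubes=truths,
        vessel_mask=union,
        overlap=bool(overlap_mask.any()),
        overlap_mask=overlap_mask,
    )
    return volume, truth
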