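"""Seeded 3D image phantoms with known mitotic geometry.

Phantoms emulate the structures seen in multiplexed immunofluorescence of
dividing cells: a chromatin plate (metaphase) or two separating chromatin
masses (segregation) in the DAPI channel, plus antibody channels following
canonical patterns (spindle fibres between the poles, centrosome blobs at
the poles, uniform or cytoplasmic staining).  All geometry is expressed in
micrometres; the ground truth frame is returned alongside the stack so the
registration pipeline can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    METAPHASE,
    SEGREGATION,
    PHASES,
    ImageStack,
    _normalize_axis_sign,
)

PATTERNS = ("chromatin", "spindle", "centrosome", "uniform", "cytoplasmic-shell")


@dataclass
class ChannelPattern:
    channel_name: str
    pattern: str
    amplitude: float = 100.0
    #: Gaussian width (um) of blob/fibre patterns; None picks the pattern
    #: default (1.0 um centrosome blobs, 1.5 um spindle fibre)
    sigma: float | None = None

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class NoiseConfig:
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0  # 0 disables shot noise

    def __post_init__(self):
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class PhantomConfig:
    """Declarative description of one synthetic mitotic cell.

    ``chromatin_half_axes`` (a >= b >= c, um) describe the metaphase plate
    (short axis along ``axis_direction``) or each congruent daughter mass.
    ``centroid_distance`` (um) separates the daughters along the axis and is
    required exactly when ``phase == 'segregation'``.
    """

    phase: str = METAPHASE
    stack_shape: tuple = (48, 64, 64)  # (z, y, x) voxels
    voxel_spacing: tuple = (0.5, 0.5, 0.5)  # um per axis (z, y, x)
    axis_direction: tuple = (1.0, 0.0, 0.0)  # (z, y, x)
    chromatin_half_axes: tuple = (7.0, 6.0, 3.5)
    centroid_distance: float = 0.0
    channel_patterns: list = field(
        default_factory=lambda: [ChannelPattern("DAPI", "chromatin")]
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    background: float = 10.0

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        ax = np.asarray(self.chromatin_half_axes, dtype=float)
        if np.any(ax <= 0):
            raise ValueError("chromatin half axes must be positive")
        if np.any(np.diff(ax) > 0):
            raise ValueError("chromatin half axes must be ordered descending")
        norm = np.linalg.norm(self.axis_direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis_direction must have unit norm")
        if (self.centroid_distance > 0) != (self.phase == SEGREGATION):
            raise ValueError(
                "centroid_distance must be positive iff phase is segregation"
            )
        names = [p.channel_name for p in self.channel_patterns]
        if names.count("DAPI") != 1:
            raise ValueError("exactly one channel must be named 'DAPI'")


@dataclass
class GroundTruthGeometry:
    """The frame a perfect registration should recover."""

    true_center: np.ndarray
    true_axis: np.ndarray
    true_sphere_radius: float
    true_phase: str

    def __post_init__(self):
        if abs(np.linalg.norm(self.true_axis) - 1.0) > 1e-9:
            raise ValueError("true_axis must be a unit vector")
        if self.true_sphere_radius <= 0:
            raise ValueError("radius must be positive")


def _orthonormal_basis(axis: np.ndarray) -> tuple:
    """Two unit vectors orthogonal to ``axis`` (deterministic choice)."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _ellipsoid_level(points, center, axis, half_axes):
    """Normalized ellipsoid radius m (m <= 1 inside) with the *shortest*
    half axis along ``axis``."""
    a, b, c = half_axes
    e1, e2 = _orthonormal_basis(axis)
    rel = points - center
    u = rel @ e1
    v = rel @ e2
    w = rel @ axis
    return np.sqrt((u / a) ** 2 + (v / b) ** 2 + (w / c) ** 2)


def _ellipsoid_soft(points, center, axis, half_axes, edge_um):
    """Solid ellipsoid with a linear ~1-voxel soft edge so that ROI means are
    stable under rotation of the sampling grid.  Returns values in [0, 1];
    exactly 1 strictly inside, 0 outside."""
    m = _ellipsoid_level(points, center, axis, half_axes)
    w = edge_um / float(min(half_axes))  # edge width on the m scale
    return np.clip((1.0 - m) / w + 0.5, 0.0, 1.0)


def _ellipsoid_world_extent(axis, half_axes):
    """Half-extent of the ellipsoid along each world axis (z, y, x)."""
    a, b, c = half_axes
    e1, e2 = _orthonormal_basis(axis)
    basis = np.stack([e1, e2, axis])  # rows paired with (a, b, c)
    return np.sqrt(((np.array([a, b, c])[:, None] * basis) ** 2).sum(axis=0))


def make_phantom(config: PhantomConfig, seed: int) -> tuple:
    """Synthesize one seeded phantom stack and its ground-truth geometry.

    Deterministic: the same ``(config, seed)`` yields a bit-identical stack.
    Raises when a chromatin ellipsoid would exceed the stack bounds, naming
    the offending world axis.
    """
    rng = np.random.default_rng(seed)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    shape = np.asarray(config.stack_shape, dtype=int)
    extent = (shape - 1) * spacing
    center = extent / 2.0
    axis = np.asarray(config.axis_direction, dtype=float)
    half_axes = np.asarray(config.chromatin_half_axes, dtype=float)

    if config.phase == METAPHASE:
        chromatin_centers = [center]
        radius = 1.5 * float(half_axes[0])
        poles = [center - 0.8 * radius * axis, center + 0.8 * radius * axis]
    else:
        offset = config.centroid_distance / 2.0 * axis
        chromatin_centers = [center - offset, center + offset]
        radius = 1.5 * config.centroid_distance / 2.0
        poles = list(chromatin_centers)

    half_extent = _ellipsoid_world_extent(axis, half_axes)
    for c0 in chromatin_centers:
        lo, hi = c0 - half_extent, c0 + half_extent
        for k, name in enumerate("zyx"):
            if lo[k] < 0 or hi[k] > extent[k]:
                raise ValueError(
                    f"chromatin ellipsoid exceeds stack bounds along {name}"
                )

    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    points = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)

    edge = float(np.max(spacing))
    chromatin_soft = np.zeros(points.shape[0])
    for c0 in chromatin_centers:
        np.maximum(
            chromatin_soft,
            _ellipsoid_soft(points, c0, axis, half_axes, edge),
            out=chromatin_soft,
        )
    chromatin = chromatin_soft > 0.5

    rho = np.linalg.norm(points - center, axis=1)
    in_sphere = rho <= radius

    channels = []
    for pat in config.channel_patterns:
        img = np.full(points.shape[0], float(config.background))
        if pat.pattern == "chromatin":
            img += pat.amplitude * chromatin_soft
        elif pat.pattern == "uniform":
            img += pat.amplitude
        elif pat.pattern == "cytoplasmic-shell":
            img[in_sphere & ~chromatin] += pat.amplitude
        elif pat.pattern == "centrosome":
            sigma = pat.sigma or 1.0
            for pole in poles:
                d2 = ((points - pole) ** 2).sum(axis=1)
                img += pat.amplitude * np.exp(-d2 / (2 * sigma**2))
        elif pat.pattern == "spindle":
            sigma = pat.sigma or 1.5
            p0, p1 = poles
            seg = p1 - p0
            t = np.clip((points - p0) @ seg / (seg @ seg), 0.0, 1.0)
            nearest = p0 + t[:, None] * seg
            d2 = ((points - nearest) ** 2).sum(axis=1)
            img += pat.amplitude * np.exp(-d2 / (2 * sigma**2))
        channels.append(img.reshape(shape))

    voxels = np.stack(channels)
    if config.noise.poisson_scale > 0:
        voxels = rng.poisson(voxels * config.noise.poisson_scale) / (
            config.noise.poisson_scale
        )
    if config.noise.gaussian_sd > 0:
        voxels = voxels + rng.normal(0.0, config.noise.gaussian_sd, voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    stack = ImageStack(
        voxels=voxels,
        spacing=tuple(spacing),
        channel_names=[p.channel_name for p in config.channel_patterns],
    )
    truth = GroundTruthGeometry(
        true_center=center,
        true_axis=_normalize_axis_sign(axis.copy()),
        true_sphere_radius=radius,
        true_phase=config.phase,
    )
    return stack, truth
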