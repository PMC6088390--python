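"""Spherical-coordinate registration of single mitotic cells.

A mitotic cell is mapped onto a standardized spherical coordinate system
aligned to its division axis: six concentric shells of equal radial width
crossed with three latitude sectors relative to the division plane
(equatorial, diagonal, polar) give 18 regions of interest (ROIs).  The
mitotic axis is the shortest principal axis of an ellipsoid fitted to the
chromatin (metaphase) or the line through the two daughter chromatin
centroids (segregation).  The sphere radius is anchored so that the outer
edge of the *fourth* shell coincides with the chromatin landmark (longest
half axis, or half the centroid distance), i.e. ``R = 1.5 * landmark``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

METAPHASE = "metaphase"
SEGREGATION = "segregation"
PHASES = (METAPHASE, SEGREGATION)

#: sector names ordered by increasing angle from the mitotic axis
SECTOR_NAMES = ("polar", "diagonal", "equatorial")


@dataclass(frozen=True)
class RoiGrid:
    """The 6-shell x 3-sector partition of the unit sphere.

    ``r_mu`` are the shell eccentricity scores (mid-shell radii on the unit
    scale, ``(mu - 0.5) / 6``) entering the center-of-eccentricity measure;
    ``phi_nu`` are the sector orientation scores in degrees, defined as the
    angle of the sector mid-latitude direction from the mitotic axis
    (polar 15, diagonal 45, equatorial 75), so larger values mean closer to
    the division plane.
    """

    n_shells: int = 6
    n_sectors: int = 3
    sector_names: tuple = SECTOR_NAMES
    #: latitude band edges in degrees of |latitude| from the division plane,
    #: ordered equatorial -> polar
    latitude_edges: tuple = (0.0, 30.0, 60.0, 90.0)

    @property
    def n_rois(self) -> int:
        return self.n_shells * self.n_sectors

    @property
    def r_mu(self) -> np.ndarray:
        return (np.arange(1, self.n_shells + 1) - 0.5) / self.n_shells

    @property
    def phi_nu(self) -> np.ndarray:
        # mid-latitudes of (polar, diagonal, equatorial) are 75/45/15 deg;
        # the orientation score is 90 - mid-latitude
        return np.array([15.0, 45.0, 75.0])

    def shell_edges(self, radius: float) -> np.ndarray:
        return radius * np.arange(self.n_shells + 1) / self.n_shells

    def roi_volume_fractions(self) -> np.ndarray:
        """Analytic volume fraction of each (shell, sector) ROI.

        Shell mu holds (mu^3 - (mu-1)^3)/6^3 of the sphere; a latitude band
        [l1, l2] holds sin(l2) - sin(l1) of it.  Returns a (6, 3) array
        summing to 1, sector order ``SECTOR_NAMES``.
        """
        mu = np.arange(1, self.n_shells + 1)
        shell_frac = (mu**3 - (mu - 1) ** 3) / self.n_shells**3
        lat = np.deg2rad(np.asarray(self.latitude_edges))
        band = np.sin(lat[1:]) - np.sin(lat[:-1])  # equatorial, diagonal, polar
        sector_frac = band[::-1]  # reorder to polar, diagonal, equatorial
        return np.outer(shell_frac, sector_frac)


DEFAULT_GRID = RoiGrid()


@dataclass
class ImageStack:
    """Multi-channel 3D image with physical voxel spacing.

    ``voxels`` has axes (channel, z, y, x); ``spacing`` is micrometres per
    voxel along (z, y, x).  Exactly one channel must be named ``DAPI``.
    """

    voxels: np.ndarray
    spacing: tuple
    channel_names: list

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must have axes (channel, z, y, x)")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.channel_names.count("DAPI") != 1:
            raise ValueError("exactly one channel must be named 'DAPI'")

    @property
    def dapi(self) -> np.ndarray:
        return self.voxels[self.channel_names.index("DAPI")]

    def channel(self, name: str) -> np.ndarray:
        return self.voxels[self.channel_names.index(name)]


@dataclass
class EllipsoidFit:
    """Second-moment ellipsoid of a binary component.

    ``half_axes`` are sorted descending (a1 >= a2 >= a3, micrometres) and
    ``axes[k]`` is the unit direction of ``half_axes[k]``.
    """

    centroid: np.ndarray
    half_axes: np.ndarray
    axes: np.ndarray  # (3, 3), rows are unit vectors

    def __post_init__(self):
        if np.any(self.half_axes <= 0):
            raise ValueError("half axes must be positive")
        if np.any(np.diff(self.half_axes) > 1e-12):
            raise ValueError("half axes must be sorted descending")
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.half_axes))


@dataclass
class MitoticFrame:
    """Registration of one cell: phase, center, mitotic axis, sphere radius."""

    phase: str
    center: np.ndarray
    axis: np.ndarray
    sphere_radius: float

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        if self.sphere_radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class SpheriCellMap:
    """Per-cell 6x3 table of mean ROI intensities and ROI volumes.

    ``intensities`` has axes (channel, shell, sector); empty ROIs carry NaN
    intensity and zero voxel count.  Volumes are voxel count times voxel
    volume in um^3.
    """

    intensities: np.ndarray
    volumes: np.ndarray
    voxel_counts: np.ndarray
    frame: MitoticFrame
    channel_names: list
    cell_id: str = "cell"
    grid: RoiGrid = field(default_factory=RoiGrid)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        expected = (len(self.channel_names), self.grid.n_shells, self.grid.n_sectors)
        if self.intensities.shape != expected:
            raise ValueError(f"intensities must have shape {expected}")

    def channel(self, name: str) -> np.ndarray:
        return self.intensities[self.channel_names.index(name)]


def _normalize_axis_sign(axis: np.ndarray) -> np.ndarray:
    """Flip a sign-arbitrary axis so its first nonzero of (z, y, x) is >= 0."""
    for comp in axis:  # axis stored as (z, y, x)
        if abs(comp) > 1e-12:
            return axis if comp > 0 else -axis
    return axis


def segment_chromatin(stack: ImageStack, min_volume: float = 20.0) -> list:
    """Otsu-threshold the DAPI channel and return chromatin components.

    Components are 26-connected, filtered to at least ``min_volume`` um^3,
    and sorted by volume descending.  Raises ``ValueError`` when nothing
    survives the filter.
    """
    dapi = stack.dapi
    thresh = threshold_otsu(dapi)
    mask = dapi > thresh
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    voxel_volume = float(np.prod(stack.spacing))
    components = []
    for lab in range(1, n + 1):
        comp = labels == lab
        vol = comp.sum() * voxel_volume
        if vol >= min_volume:
            components.append((vol, comp))
    if not components:
        raise ValueError("no chromatin found: no component above min_volume")
    components.sort(key=lambda t: t[0], reverse=True)
    return [comp for _, comp in components]


def fit_ellipsoid(mask: np.ndarray, spacing: tuple) -> EllipsoidFit:
    """Fit a uniform solid ellipsoid to a binary component by second moments.

    The centroid is the mean of voxel centers, principal directions are the
    eigenvectors of the voxel-coordinate covariance, and half axes follow
    the uniform-ellipsoid relation ``a_k = sqrt(5 * eigenvalue_k)``.
    """
    coords = np.argwhere(mask).astype(float) * np.asarray(spacing)
    if coords.shape[0] == 0:
        raise ValueError("empty component")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 1e-12):
        raise ValueError("degenerate component: voxels are (nearly) coplanar")
    order = np.argsort(evals)[::-1]
    half_axes = np.sqrt(5.0 * evals[order])
    axes = evecs[:, order].T
    return EllipsoidFit(centroid=centroid, half_axes=half_axes, axes=axes)


def build_frame(phase: str, fits: list) -> MitoticFrame:
    """Derive the mitotic frame from one (metaphase) or two (segregation) fits.

    Metaphase: axis = shortest principal direction, center = centroid,
    R = 1.5 * longest half axis (the fourth of six shells ends at a1).
    Segregation: axis = centroid-to-centroid direction, center = midpoint,
    R = 1.5 * (centroid distance / 2) (the fourth shell edge passes through
    both daughter centroids).
    """
    if phase == METAPHASE:
        if len(fits) != 1:
            raise ValueError("metaphase requires exactly one ellipsoid fit")
        fit = fits[0]
        axis = _normalize_axis_sign(fit.axes[2].copy())
        return MitoticFrame(
            phase=phase,
            center=fit.centroid.copy(),
            axis=axis / np.linalg.norm(axis),
            sphere_radius=1.5 * float(fit.half_axes[0]),
        )
    if phase == SEGREGATION:
        if len(fits) != 2:
            raise ValueError("segregation requires exactly two ellipsoid fits")
        delta = fits[1].centroid - fits[0].centroid
        dist = float(np.linalg.norm(delta))
        if dist < 1e-9:
            raise ValueError("coincident daughter centroids")
        axis = _normalize_axis_sign(delta / dist)
        return MitoticFrame(
            phase=phase,
            center=(fits[0].centroid + fits[1].centroid) / 2.0,
            axis=axis,
            sphere_radius=1.5 * dist / 2.0,
        )
    raise ValueError(f"unknown phase {phase!r}")


def _assign_rois(points: np.ndarray, frame: MitoticFrame, grid: RoiGrid = DEFAULT_GRID):
    """Vectorized ROI assignment.

    Returns ``(shell, sector)`` integer arrays; shell is 1..6 and sector
    indexes ``SECTOR_NAMES``; both are -1 outside the sphere.  The
    assignment uses |latitude| so it is invariant to the axis sign, and
    latitude bands are lower-inclusive ([0,30) equatorial, [30,60) diagonal,
    [60,90] polar); rho = R lands in shell 6, rho = 0 in shell 1 / polar.
    """
    rel = np.atleast_2d(points) - frame.center
    rho = np.linalg.norm(rel, axis=1)
    inside = rho <= frame.sphere_radius
    shell = np.full(rho.shape, -1, dtype=int)
    sector = np.full(rho.shape, -1, dtype=int)

    shell_in = np.minimum(
        grid.n_shells,
        np.floor(grid.n_shells * rho[inside] / frame.sphere_radius).astype(int) + 1,
    )
    # |cos| of the angle to the axis; rho=0 treated as on-axis (polar)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(rel[inside] @ frame.axis) / np.where(
            rho[inside] > 0, rho[inside], 1.0
        )
    cosang = np.where(rho[inside] > 0, np.clip(cosang, 0.0, 1.0), 1.0)
    lat = 90.0 - np.degrees(np.arccos(cosang))  # |latitude| from division plane
    sec_in = np.where(lat >= 60.0, 0, np.where(lat >= 30.0, 1, 2))
    shell[inside] = shell_in
    sector[inside] = sec_in
    return shell, sector


def assign_roi(point: np.ndarray, frame: MitoticFrame, grid: RoiGrid = DEFAULT_GRID):
    """Assign one physical point (um) to its (shell, sector) ROI.

    Returns ``(shell, sector_name)`` with shell in 1..6, or ``None`` if the
    point lies outside the sphere.
    """
    shell, sector = _assign_rois(np.asarray(point, dtype=float)[None, :], frame, grid)
    if shell[0] < 0:
        return None
    return int(shell[0]), grid.sector_names[sector[0]]


def resample_isotropic(stack: ImageStack) -> ImageStack:
    """Linearly interpolate along z so voxels become isotropic at the
    in-plane spacing.  A no-op for already-isotropic stacks."""
    sz, sy, sx = stack.spacing
    target = float(sx)
    factors = (sz / target, sy / target, 1.0)
    if np.allclose(factors, 1.0):
        return stack
    channels = [
        ndimage.zoom(stack.voxels[c], factors, order=1)
        for c in range(stack.voxels.shape[0])
    ]
    return ImageStack(
        voxels=np.stack(channels),
        spacing=(target, target, target),
        channel_names=list(stack.channel_names),
    )


def bin_stack(
    stack: ImageStack, frame: MitoticFrame, grid: RoiGrid = DEFAULT_GRID,
    cell_id: str = "cell",
) -> SpheriCellMap:
    """Average every in-sphere voxel of every channel into its 18 ROIs.

    The stack is first resampled to isotropic spacing (linear interpolation
    along z), then each voxel center is assigned to exactly one ROI.  Raises
    if the sphere misses the stack entirely; logs a warning if the sphere is
    clipped by the stack boundary.
    """
    iso = resample_isotropic(stack)
    spacing = np.asarray(iso.spacing)
    shape = np.asarray(iso.voxels.shape[1:])
    extent = (shape - 1) * spacing
    lo = frame.center - frame.sphere_radius
    hi = frame.center + frame.sphere_radius
    if np.any(hi < 0) or np.any(lo > extent):
        raise ValueError("sphere lies fully outside the stack")
    clipped = np.any(lo < 0) or np.any(hi > extent)

    # restrict to the sphere's bounding box to keep the point list small
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, shape)
    zz, yy, xx = np.meshgrid(
        *(np.arange(a, b) for a, b in zip(i0, i1)), indexing="ij"
    )
    idx = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    points = idx * spacing
    shell, sector = _assign_rois(points, frame, grid)
    inside = shell > 0
    idx, shell, sector = idx[inside], shell[inside], sector[inside]

    if idx.shape[0] == 0:
        raise ValueError("sphere contains no voxel centers")

    flat_roi = (shell - 1) * grid.n_sectors + sector
    counts = np.bincount(flat_roi, minlength=grid.n_rois)
    voxel_volume = float(np.prod(spacing))
    if clipped:
        sphere_volume = 4.0 / 3.0 * np.pi * frame.sphere_radius**3
        lost = max(0.0, sphere_volume - counts.sum() * voxel_volume)
        logger.warning(
            "sphere clipped by stack boundary (center %s, R %.2f um): "
            "~%.1f um^3 (%.1f%%) of the sphere lies outside",
            np.round(frame.center, 2), frame.sphere_radius, lost,
            100.0 * lost / sphere_volume,
        )
    n_channels = iso.voxels.shape[0]
    intensities = np.full((n_channels, grid.n_rois), np.nan)
    for c in range(n_channels):
        values = iso.voxels[c][idx[:, 0], idx[:, 1], idx[:, 2]]
        sums = np.bincount(flat_roi, weights=values, minlength=grid.n_rois)
        nonzero = counts > 0
        intensities[c, nonzero] = sums[nonzero] / counts[nonzero]

    shape_roi = (grid.n_shells, grid.n_sectors)
    return SpheriCellMap(
        intensities=intensities.reshape((n_channels,) + shape_roi),
        volumes=(counts * voxel_volume).reshape(shape_roi),
        voxel_counts=counts.reshape(shape_roi),
        frame=frame,
        channel_names=list(iso.channel_names),
        cell_id=cell_id,
        grid=grid,
    )


def register_cell(
    stack: ImageStack, phase: str, min_volume: float = 20.0,
    grid: RoiGrid = DEFAULT_GRID, cell_id: str = "cell",
) -> SpheriCellMap:
    """Full per-cell pipeline: segment chromatin, fit ellipsoid(s), build the
    mitotic frame and bin all channels into the 18 spherical ROIs."""
    components = segment_chromatin(stack, min_volume=min_volume)
    n_fits = 1 if phase == METAPHASE else 2
    if len(components) < n_fits:
        raise ValueError(
            f"{phase} needs {n_fits} chromatin component(s), found {len(components)}"
        )
    fits = [fit_ellipsoid(comp, stack.spacing) for comp in components[:n_fits]]
    frame = build_frame(phase, fits)
    return bin_stack(stack, frame, grid=grid, cell_id=cell_id)


def project_map(
    spheri_map: SpheriCellMap,
    normalize: bool = False,
    collection: list | None = None,
    dapi_floor: float | None = None,
) -> np.ndarray:
    """Flatten a SpheriCellMap's first channel (or each channel separately via
    :func:`project_values`) into plot-ready 6x3 values.

    With ``dapi_floor`` set, ROIs whose DAPI mean falls below the floor are
    masked (NaN) to suppress background outside the stained structures.  With
    ``normalize``, values are min-max scaled to [0, 1] over the provided
    ``collection`` of maps (default: this map alone); a constant collection
    maps to 0 everywhere (degenerate min-max).
    """
    return project_values(
        spheri_map, spheri_map.channel_names[0], normalize, collection, dapi_floor
    )


def project_values(
    spheri_map: SpheriCellMap,
    channel: str,
    normalize: bool = False,
    collection: list | None = None,
    dapi_floor: float | None = None,
) -> np.ndarray:
    values = spheri_map.channel(channel).astype(float).copy()
    if dapi_floor is not None:
        values[spheri_map.channel("DAPI") < dapi_floor] = np.nan
    if np.all(np.isnan(values)):
        raise ValueError("all ROIs masked; nothing to project")
    if normalize:
        maps = collection if collection is not None else [spheri_map]
        pool = np.concatenate([m.channel(channel).ravel() for m in maps])
        lo, hi = np.nanmin(pool), np.nanmax(pool)
        if hi - lo < 1e-15:
            values = np.zeros_like(values)
        else:
            values = (values - lo) / (hi - lo)
    return values
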