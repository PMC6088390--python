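"""Model-generated synthetic intensity datasets and statistical fixtures.

Single-cell protein content is log-normally distributed, so per-cell species
totals are drawn log-normal (the default ``mu = 0`` puts the population
median at 1, i.e. already on the normalized fold-change scale the affinity
model consumes).  ROI intensities follow the steady-state affinity model
exactly; optional measurement noise is additive Gaussian with the same
5% + 5%-of-max standard deviation that weights the fit, truncated at zero,
so recovery experiments are self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DEFAULT_GRID,
    METAPHASE,
    SEGREGATION,
    MitoticFrame,
    RoiGrid,
    SpheriCellMap,
)
from .model import (
    ALPHA_BOUNDS,
    BETA_BOUNDS,
    D_BOUNDS,
    InteractionSet,
    ModelParams,
    NormalizedDataset,
    SpeciesSet,
    apply_canonical_gauge,
    canonical_pair,
    predict,
)


@dataclass
class AffinityGroundTruth:
    """True parameters behind a simulated dataset.

    Wraps a :class:`ModelParams` plus per-species log-normal parameters for
    the cell totals.  The beta matrix is symmetric with nonzero entries only
    on the declared interaction pairs.
    """

    params: ModelParams
    lognormal_mu: np.ndarray
    lognormal_sigma: np.ndarray

    def __post_init__(self):
        s = self.params.species.n
        self.lognormal_mu = np.broadcast_to(
            np.asarray(self.lognormal_mu, dtype=float), (s,)
        ).copy()
        self.lognormal_sigma = np.broadcast_to(
            np.asarray(self.lognormal_sigma, dtype=float), (s,)
        ).copy()
        if np.any(self.lognormal_sigma < 0):
            raise ValueError("lognormal sigma must be nonnegative")
        B = self.params.beta_matrix()
        if np.max(np.abs(B - B.T)) != 0:
            raise ValueError("beta must be exactly symmetric")
        for arr, (lo, hi) in (
            (self.params.d_meta, D_BOUNDS),
            (self.params.d_segr, D_BOUNDS),
            (self.params.alpha_meta, ALPHA_BOUNDS),
            (self.params.alpha_segr, ALPHA_BOUNDS),
        ):
            if np.any(arr < lo) or np.any(arr > hi):
                raise ValueError("ground-truth d/alpha outside the allowed box")
        bv = self.params.beta_values
        if bv.size and (np.any(bv < BETA_BOUNDS[0]) or np.any(bv > BETA_BOUNDS[1])):
            raise ValueError("ground-truth beta outside the allowed box")

    @property
    def species(self) -> SpeciesSet:
        return self.params.species


def make_ground_truth(
    species_names: list,
    interaction_pairs: list,
    seed: int,
    n_rois: int = 18,
    beta_range: tuple = (0.2, 1.0),
    alpha_range: tuple = (0.5, 2.0),
    d_range: tuple = (0.5, 2.0),
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 0.5,
) -> AffinityGroundTruth:
    """Draw a random but reproducible ground truth.

    ROI affinities and scalings are log-uniform within moderate ranges;
    planted mutual affinities are strong enough to shape the data yet keep
    the dimerization term a correction to direct recruitment (the regime in
    which treating free concentrations as proportional to cell totals is
    valid, and in which the parameters stay identifiable).  Totals default
    to median 1 with a log-sd of 0.5, a typical cell-to-cell spread for
    protein content.  The drawn parameters are expressed in the canonical
    gauge (geometric mean ROI affinity = 1), the same convention fitted
    parameters are reported in.
    """
    rng = np.random.default_rng(seed)
    species = SpeciesSet(tuple(species_names))
    s = species.n
    pairs = [canonical_pair(*p) for p in interaction_pairs]

    def loguni(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    params = apply_canonical_gauge(
        ModelParams(
            species=species,
            interactions=InteractionSet(pairs),
            d_meta=loguni(*d_range, s),
            d_segr=loguni(*d_range, s),
            alpha_meta=loguni(*alpha_range, (s, n_rois)),
            alpha_segr=loguni(*alpha_range, (s, n_rois)),
            beta_values=loguni(*beta_range, len(pairs)),
        )
    )
    return AffinityGroundTruth(
        params=params,
        lognormal_mu=np.full(s, lognormal_mu),
        lognormal_sigma=np.full(s, lognormal_sigma),
    )


@dataclass
class CellTotals:
    """Per-cell species totals with phase labels."""

    species: SpeciesSet
    totals: np.ndarray  # (n_cells, S)
    phases: np.ndarray  # (n_cells,)


def simulate_cell_totals(
    ground_truth: AffinityGroundTruth,
    n_cells: int,
    phase_fractions: tuple = (0.5, 0.5),
    seed: int = 0,
) -> CellTotals:
    """Draw per-cell species totals log-normally and assign mitotic phases.

    With ``sigma = 0`` every cell carries exactly ``exp(mu)``; otherwise the
    population median per species is ``exp(mu)`` up to sampling error.
    Phases are i.i.d. with the given (metaphase, segregation) fractions.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    fractions = np.asarray(phase_fractions, dtype=float)
    if fractions.min() < 0 or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("phase_fractions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    mu, sigma = ground_truth.lognormal_mu, ground_truth.lognormal_sigma
    totals = np.exp(
        mu[None, :] + sigma[None, :] * rng.standard_normal((n_cells, mu.size))
    )
    phases = rng.choice([METAPHASE, SEGREGATION], size=n_cells, p=fractions)
    return CellTotals(species=ground_truth.species, totals=totals, phases=phases)


def simulate_roi_dataset(
    ground_truth: AffinityGroundTruth,
    totals: CellTotals,
    with_noise: bool = True,
    seed: int = 0,
    grid: RoiGrid = DEFAULT_GRID,
) -> NormalizedDataset:
    """Generate a normalized ROI dataset from the steady-state model.

    The supplied totals are taken as the normalized cell averages; ROI
    values are the exact model prediction, and with noise enabled each value
    receives additive Gaussian noise with sd equal to the 5% + 5%-of-max
    error scale of the clean table (truncated at zero).
    """
    if totals.species.names != ground_truth.species.names:
        raise ValueError("species mismatch between totals and ground truth")
    clean = predict(ground_truth.params, totals.totals, totals.phases)
    roi = clean
    if with_noise:
        rng = np.random.default_rng(seed)
        sd = 0.05 * clean + 0.05 * clean.max(axis=(0, 2))[None, :, None]
        roi = np.clip(clean + rng.normal(0.0, 1.0, clean.shape) * sd, 0.0, None)
    return NormalizedDataset(
        species=ground_truth.species,
        phases=totals.phases.copy(),
        roi=roi,
        totals=totals.totals.copy(),
        medians=np.ones(ground_truth.species.n),
        volumes=grid.roi_volume_fractions().ravel(),
    )


# ---------------------------------------------------------------------------
# fixtures for the spatial statistics layer


@dataclass
class EffectSpec:
    """Planted group-B effect for statistical fixtures.

    ``fold`` multiplies the affected channel; ``shell_shift`` moves a
    fraction of intensity from one shell to another (same sector), pushing
    the center of eccentricity outward when ``to_shell > from_shell``.
    """

    channel: str = "DAPI"
    fold: float = 1.0
    from_shell: int | None = None
    to_shell: int | None = None
    shift_fraction: float = 0.0

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if not 0.0 <= self.shift_fraction <= 1.0:
            raise ValueError("shift_fraction must be in [0, 1]")
        if (self.from_shell is None) != (self.to_shell is None):
            raise ValueError("from_shell and to_shell must be given together")


@dataclass
class FixturePopulation:
    group_a: list
    group_b: list
    effect: EffectSpec


def _template_frame(radius: float = 12.0) -> MitoticFrame:
    return MitoticFrame(
        phase=METAPHASE, center=np.zeros(3), axis=np.array([1.0, 0.0, 0.0]),
        sphere_radius=radius,
    )


def make_roi_fixture_population(
    template: np.ndarray,
    channel_names: list,
    n_cells: int,
    effect: EffectSpec,
    seed: int = 0,
    cell_sigma: float = 0.3,
    roi_sigma: float = 0.1,
    grid: RoiGrid = DEFAULT_GRID,
) -> FixturePopulation:
    """Two groups of SpheriCellMaps around an intensity template.

    Group A cells are the template times a per-cell log-normal factor and
    per-ROI log-normal jitter; group B additionally carries the declared
    effect.  ROI volumes are the analytic sphere fractions.
    """
    template = np.asarray(template, dtype=float)
    if n_cells < 2:
        raise ValueError("need at least 2 cells per group for group statistics")
    rng = np.random.default_rng(seed)
    volumes = grid.roi_volume_fractions() * (4.0 / 3.0) * np.pi * 12.0**3
    counts = np.maximum((volumes / volumes.min()).astype(int), 1)

    template_b = template.copy()
    ci = channel_names.index(effect.channel)
    template_b[ci] *= effect.fold
    if effect.from_shell is not None:
        moved = template_b[ci, effect.from_shell - 1, :] * effect.shift_fraction
        template_b[ci, effect.from_shell - 1, :] -= moved
        template_b[ci, effect.to_shell - 1, :] += moved

    def draw_group(base):
        maps = []
        for k in range(n_cells):
            cell_factor = np.exp(rng.normal(0.0, cell_sigma, base.shape[0]))
            jitter = np.exp(rng.normal(0.0, roi_sigma, base.shape))
            maps.append(
                SpheriCellMap(
                    intensities=base * cell_factor[:, None, None] * jitter,
                    volumes=volumes,
                    voxel_counts=counts,
                    frame=_template_frame(),
                    channel_names=list(channel_names),
                    cell_id=f"cell_{k}",
                    grid=grid,
                )
            )
        return maps

    return FixturePopulation(
        group_a=draw_group(template), group_b=draw_group(template_b), effect=effect
    )
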