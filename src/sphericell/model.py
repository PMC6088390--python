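"""Steady-state affinity model of protein recruitment to mitotic ROIs.

The measured mean intensity of species ``i`` in spherical ROI ``l`` of one
cell is explained by two routes of recruitment: a direct affinity of the
species for the structures in that ROI, and indirect recruitment through
dimerization with a partner species that is itself bound there.  Starting
from mass-action binding kinetics with non-limiting binding sites, the
steady state of the normalized (fold-change) intensities is

    I_il = d_i * alpha_il * T_i * (1 + sum_j alpha_jl * beta_ij * T_j)

where ``T_i`` is the cell's normalized average intensity of species ``i``,
``alpha_il`` the (rescaled, phase-specific) inverse dissociation constant of
species ``i`` for ROI ``l``, ``beta_ij`` the symmetric inverse dissociation
constant of the i-j dimer (phase-independent), and ``d_i`` a per-species,
per-phase scaling factor.  Parameters are estimated by weighted nonlinear
least squares in log10 space with multi-start initialization; new mutual
affinities are discovered by greedy forward selection under a chi-square(1)
likelihood-ratio criterion, and fitted ones are challenged by withdrawal
(contribution) tests.

The per-datapoint uncertainty is 5% of the measured value plus 5% of the
species maximum over all included cells; with this fixed Gaussian error
model the weighted residual sum of squares acts as -2 log-likelihood up to a
constant, so a drop larger than chi2_{0.95}(1) = 3.841 is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .geometry import METAPHASE, SEGREGATION, DEFAULT_GRID, RoiGrid

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)

#: 95% quantile of the chi-square distribution with 1 degree of freedom
CHI2_95_DF1 = 3.8414588206941254

#: box constraints for log-uniform start sampling and fitting, natural scale
ALPHA_BOUNDS = (1e-3, 1e2)
D_BOUNDS = (1e-3, 1e2)
BETA_BOUNDS = (1e-7, 1e2)


# ---------------------------------------------------------------------------
# species / interaction bookkeeping


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered set of measured species (DAPI included)."""

    names: tuple

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("species names must be unique")
        if len(self.names) < 2:
            raise ValueError("need at least two species")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def canonical_pair(i: int, j: int) -> tuple:
    return (i, j) if i <= j else (j, i)


@dataclass
class InteractionSet:
    """Unordered species pairs (homodimers allowed) with provenance."""

    pairs: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        canon = [canonical_pair(*p) for p in self.pairs]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate interaction pairs")
        self.pairs = canon
        for p in self.pairs:
            self.provenance.setdefault(p, "literature")

    def __len__(self):
        return len(self.pairs)

    def __contains__(self, pair):
        return canonical_pair(*pair) in self.pairs

    def with_pair(self, pair, provenance="selected") -> "InteractionSet":
        pair = canonical_pair(*pair)
        return InteractionSet(
            pairs=self.pairs + [pair], provenance={**self.provenance, pair: provenance}
        )

    def without_pair(self, pair) -> "InteractionSet":
        pair = canonical_pair(*pair)
        return InteractionSet(
            pairs=[p for p in self.pairs if p != pair],
            provenance={p: v for p, v in self.provenance.items() if p != pair},
        )


def all_candidate_pairs(
    n_species: int, known: InteractionSet, include_homodimers: bool = True,
    exclude_species: tuple = (),
) -> list:
    """Every unordered pair not already in ``known``."""
    out = []
    for i in range(n_species):
        for j in range(i, n_species):
            if i == j and not include_homodimers:
                continue
            if i in exclude_species or j in exclude_species:
                continue
            if (i, j) not in known:
                out.append((i, j))
    return out


# ---------------------------------------------------------------------------
# dataset


@dataclass
class NormalizedDataset:
    """Fold-change ROI intensities ready for model fitting.

    ``roi`` has axes (cell, species, roi=18); ``totals`` (cell, species) are
    the normalized cell-average intensities that enter the model as inputs;
    ``medians`` are the population medians used for normalization (1.0 for
    data simulated directly on the normalized scale); ``volumes`` are the
    relative ROI volumes used in the cell-average weighting.
    """

    species: SpeciesSet
    phases: np.ndarray  # (n_cells,) of METAPHASE / SEGREGATION
    roi: np.ndarray  # (n_cells, S, L)
    totals: np.ndarray  # (n_cells, S)
    medians: np.ndarray  # (S,)
    volumes: np.ndarray  # (L,)
    cell_ids: list = None

    def __post_init__(self):
        self.roi = np.asarray(self.roi, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        self.phases = np.asarray(self.phases)
        n, s, l = self.roi.shape
        if s != self.species.n:
            raise ValueError("species mismatch between table and species set")
        if self.totals.shape != (n, s):
            raise ValueError("totals shape mismatch")
        if self.volumes.shape != (l,):
            raise ValueError("volumes shape mismatch")
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{k}" for k in range(n)]

    @property
    def n_cells(self) -> int:
        return self.roi.shape[0]

    @property
    def n_rois(self) -> int:
        return self.roi.shape[2]

    def species_max(self) -> np.ndarray:
        """Per-species maximum ROI value over all included cells."""
        return np.nanmax(self.roi, axis=(0, 2))

    def error_scale(self) -> np.ndarray:
        """Per-datapoint uncertainty: 5% of the value + 5% of the species max."""
        eps = 0.05 * self.roi + 0.05 * self.species_max()[None, :, None]
        if np.any(eps <= 0):
            raise ValueError("zero error scale: a species has all-zero values")
        return eps


def normalize_dataset(
    raw_roi: np.ndarray,
    phases,
    species: SpeciesSet,
    volumes: np.ndarray | None = None,
    cell_ids: list | None = None,
    grid: RoiGrid = DEFAULT_GRID,
) -> NormalizedDataset:
    """Turn raw per-cell ROI intensity tables into fold changes.

    Cell averages are the ROI-volume-weighted means of the raw ROI values;
    every species is then divided by the population median of its cell
    averages, so the median normalized cell average is exactly 1.
    """
    raw_roi = np.asarray(raw_roi, dtype=float)
    if volumes is None:
        volumes = grid.roi_volume_fractions().ravel()
    volumes = np.asarray(volumes, dtype=float)
    totals_raw = (raw_roi * volumes[None, None, :]).sum(axis=2) / volumes.sum()
    medians = np.median(totals_raw, axis=0)
    if np.any(medians <= 0):
        raise ValueError("nonpositive population median; cannot normalize")
    return NormalizedDataset(
        species=species,
        phases=np.asarray(phases),
        roi=raw_roi / medians[None, :, None],
        totals=totals_raw / medians[None, :],
        medians=medians,
        volumes=volumes,
        cell_ids=cell_ids,
    )


# ---------------------------------------------------------------------------
# parameters


@dataclass
class ModelParams:
    """Affinity model state: per-phase scalings d, ROI affinities alpha,
    and mutual affinities beta on an explicit interaction set."""

    species: SpeciesSet
    interactions: InteractionSet
    d_meta: np.ndarray
    d_segr: np.ndarray
    alpha_meta: np.ndarray  # (S, L)
    alpha_segr: np.ndarray
    beta_values: np.ndarray  # aligned with interactions.pairs

    def __post_init__(self):
        s = self.species.n
        self.d_meta = np.asarray(self.d_meta, dtype=float)
        self.d_segr = np.asarray(self.d_segr, dtype=float)
        self.alpha_meta = np.asarray(self.alpha_meta, dtype=float)
        self.alpha_segr = np.asarray(self.alpha_segr, dtype=float)
        self.beta_values = np.asarray(self.beta_values, dtype=float)
        if self.alpha_meta.shape[0] != s or self.alpha_segr.shape[0] != s:
            raise ValueError("alpha must have one row per species")
        if len(self.beta_values) != len(self.interactions):
            raise ValueError("one beta value per interaction pair required")

    @property
    def n_rois(self) -> int:
        return self.alpha_meta.shape[1]

    def beta_matrix(self) -> np.ndarray:
        """Dense symmetric S x S matrix; absent pairs are exactly 0."""
        s = self.species.n
        B = np.zeros((s, s))
        for (i, j), val in zip(self.interactions.pairs, self.beta_values):
            B[i, j] = val
            B[j, i] = val
        return B

    def for_phase(self, phase: str) -> tuple:
        if phase == METAPHASE:
            return self.d_meta, self.alpha_meta
        if phase == SEGREGATION:
            return self.d_segr, self.alpha_segr
        raise ValueError(f"unknown phase {phase!r}")


def n_parameters(
    n_species: int, n_rois: int = 18, n_phases: int = 2, n_interactions: int = 0
) -> int:
    """Number of free parameters: per-phase scalings and ROI affinities plus
    one mutual affinity per interaction pair."""
    return n_phases * n_species + n_phases * n_species * n_rois + n_interactions


def n_datapoints(n_cells: int, n_species: int, n_rois: int = 18) -> dict:
    """Dataset size bookkeeping: ROI values, cell-average values, total."""
    roi_values = n_cells * n_species * n_rois
    averages = n_cells * n_species
    return {
        "roi_values": roi_values,
        "cell_averages": averages,
        "total": roi_values + averages,
    }


# ---------------------------------------------------------------------------
# forward model


def _predict_phase(d, alpha, B, totals):
    """Model intensities for one phase: (C, S, L) from d (S,), alpha (S, L),
    symmetric B (S, S) and totals (C, S)."""
    G = 1.0 + np.einsum("ij,jl,cj->cil", B, alpha, totals)
    return d[None, :, None] * alpha[None, :, :] * totals[:, :, None] * G


def predict(params: ModelParams, totals: np.ndarray, phases) -> np.ndarray:
    """Evaluate the steady-state model for every cell.

    ``totals`` (n_cells, S) are normalized cell averages; each cell's phase
    selects the phase-specific d and alpha.  Pairs absent from the
    interaction set contribute exactly zero.
    """
    totals = np.atleast_2d(np.asarray(totals, dtype=float))
    phases = np.asarray(phases)
    B = params.beta_matrix()
    out = np.empty((totals.shape[0], params.species.n, params.n_rois))
    for phase in (METAPHASE, SEGREGATION):
        sel = phases == phase
        if not np.any(sel):
            continue
        d, alpha = params.for_phase(phase)
        out[sel] = _predict_phase(d, alpha, B, totals[sel])
    return out


def objective(params: ModelParams, dataset: NormalizedDataset) -> tuple:
    """Weighted residual vector and residual sum of squares over all 18*S
    ROI values of every cell (cell averages enter only as model inputs)."""
    eps = dataset.error_scale()
    model = predict(params, dataset.totals, dataset.phases)
    residuals = ((dataset.roi - model) / eps).ravel()
    return residuals, float(residuals @ residuals)


def cell_average_consistency(params: ModelParams, dataset: NormalizedDataset):
    """Report how well the volume-weighted average of the modelled ROI values
    reproduces each cell's measured normalized average (a diagnostic, not a
    fitted quantity)."""
    model = predict(params, dataset.totals, dataset.phases)
    v = dataset.volumes
    model_avg = (model * v[None, None, :]).sum(axis=2) / v.sum()
    return model_avg, dataset.totals


# ---------------------------------------------------------------------------
# parameter packing (log10 space)


class _ParamPacker:
    """Maps ModelParams to/from a flat log10 vector.

    Phases with no cells in the dataset are excluded from the vector and kept
    fixed at 1.0 so the optimizer never sees unidentifiable coordinates.
    """

    def __init__(self, species: SpeciesSet, interactions: InteractionSet,
                 n_rois: int, phases_present: tuple):
        self.species = species
        self.interactions = interactions
        self.n_rois = n_rois
        self.phases_present = tuple(phases_present)
        s, l, k = species.n, n_rois, len(interactions)
        self.n_phase_blocks = len(self.phases_present)
        self.n_params = self.n_phase_blocks * (s + s * l) + k
        lo, hi = [], []
        for _ in self.phases_present:
            lo += [np.log10(D_BOUNDS[0])] * s
            hi += [np.log10(D_BOUNDS[1])] * s
        for _ in self.phases_present:
            lo += [np.log10(ALPHA_BOUNDS[0])] * (s * l)
            hi += [np.log10(ALPHA_BOUNDS[1])] * (s * l)
        lo += [np.log10(BETA_BOUNDS[0])] * k
        hi += [np.log10(BETA_BOUNDS[1])] * k
        self.bounds = (np.array(lo), np.array(hi))

    def slices(self):
        s, l = self.species.n, self.n_rois
        nb = self.n_phase_blocks
        d_slices, a_slices = {}, {}
        off = 0
        for p in self.phases_present:
            d_slices[p] = slice(off, off + s)
            off += s
        for p in self.phases_present:
            a_slices[p] = slice(off, off + s * l)
            off += s * l
        beta_slice = slice(off, off + len(self.interactions))
        return d_slices, a_slices, beta_slice

    def unpack(self, x: np.ndarray) -> ModelParams:
        s, l = self.species.n, self.n_rois
        d_sl, a_sl, b_sl = self.slices()
        d = {p: np.ones(s) for p in (METAPHASE, SEGREGATION)}
        alpha = {p: np.ones((s, l)) for p in (METAPHASE, SEGREGATION)}
        for p in self.phases_present:
            d[p] = 10.0 ** x[d_sl[p]]
            alpha[p] = (10.0 ** x[a_sl[p]]).reshape(s, l)
        return ModelParams(
            species=self.species,
            interactions=self.interactions,
            d_meta=d[METAPHASE],
            d_segr=d[SEGREGATION],
            alpha_meta=alpha[METAPHASE],
            alpha_segr=alpha[SEGREGATION],
            beta_values=10.0 ** x[b_sl],
        )

    def pack(self, params: ModelParams) -> np.ndarray:
        d_sl, a_sl, b_sl = self.slices()
        x = np.empty(self.n_params)
        for p in self.phases_present:
            d, alpha = params.for_phase(p)
            x[d_sl[p]] = np.log10(d)
            x[a_sl[p]] = np.log10(alpha).ravel()
        x[b_sl] = np.log10(params.beta_values)
        return np.clip(x, self.bounds[0], self.bounds[1])

    def sample_start(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds
        return rng.uniform(lo, hi)


def _residual_and_jacobian(x, packer: _ParamPacker, dataset: NormalizedDataset,
                           eps: np.ndarray, want_jac: bool):
    """Weighted residuals and (optionally) the analytic Jacobian with respect
    to the log10 parameters."""
    params = packer.unpack(x)
    B = params.beta_matrix()
    d_sl, a_sl, b_sl = packer.slices()
    n, s, l = dataset.roi.shape
    res = np.empty((n, s, l))
    jac = np.zeros((n, s, l, packer.n_params)) if want_jac else None

    for phase in packer.phases_present:
        sel = np.flatnonzero(dataset.phases == phase)
        if sel.size == 0:
            continue
        T = dataset.totals[sel]
        d, alpha = params.for_phase(phase)
        G = 1.0 + np.einsum("ij,jl,cj->cil", B, alpha, T)
        E = d[None, :, None] * alpha[None, :, :] * T[:, :, None]
        P = E * G
        res[sel] = (dataset.roi[sel] - P) / eps[sel]
        if not want_jac:
            continue
        inv_eps = 1.0 / eps[sel]
        jblock = jac[sel]
        # d(log10 d_i): nonzero only on residuals of species i
        dP = -_LN10 * P * inv_eps
        d_cols = np.arange(d_sl[phase].start, d_sl[phase].stop)
        for i in range(s):
            jblock[:, i, :, d_cols[i]] = dP[:, i, :]
        # d(log10 alpha_il): direct term on species i plus partner term on
        # every species k recruited through B[k, i]
        W = np.einsum("ckl,ki,il,ci->ckli", E, B, alpha, T)
        JA = W.copy()
        diag = np.arange(s)
        JA[:, diag, :, diag] += np.transpose(P, (1, 0, 2))
        JA *= -_LN10 * inv_eps[..., None]
        a0 = a_sl[phase].start
        for ll in range(l):
            for i in range(s):
                jblock[:, :, ll, a0 + i * l + ll] = JA[:, :, ll, i]
        # d(log10 beta_q)
        for q, ((i, j), bval) in enumerate(
            zip(params.interactions.pairs, params.beta_values)
        ):
            col = b_sl.start + q
            term_i = E[:, i, :] * alpha[j, :][None, :] * T[:, j, None]
            jblock[:, i, :, col] += -_LN10 * bval * term_i * inv_eps[:, i, :]
            if i != j:
                term_j = E[:, j, :] * alpha[i, :][None, :] * T[:, i, None]
                jblock[:, j, :, col] += -_LN10 * bval * term_j * inv_eps[:, j, :]
        jac[sel] = jblock

    if want_jac:
        return res.ravel(), jac.reshape(-1, packer.n_params)
    return res.ravel()


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    n_starts: int = 50
    seed: int = 0
    max_iter: int = 2000
    tol: float = 1e-6
    include_default_start: bool = False
    warm_starts: list = field(default_factory=list)  # ModelParams to seed from


def apply_canonical_gauge(params: ModelParams, phases: tuple = None) -> ModelParams:
    """Re-express parameters in the canonical gauge.

    The model is exactly invariant under ``(alpha, d, beta) -> (s*alpha,
    d/s, beta/s)`` for any s > 0, so individual affinities are defined only
    up to one global scale.  The canonical convention sets the geometric
    mean of the ROI affinities (over the phases carrying data) to 1 —
    natural for median-normalized fold-change intensities, where alpha is
    interpreted as a typical bound concentration of order one.  The
    transformation leaves every model prediction bit-identical.
    """
    phases = phases or (METAPHASE, SEGREGATION)
    logs = []
    if METAPHASE in phases:
        logs.append(np.log(params.alpha_meta).ravel())
    if SEGREGATION in phases:
        logs.append(np.log(params.alpha_segr).ravel())
    s = np.exp(-np.mean(np.concatenate(logs)))
    return replace(
        params,
        alpha_meta=params.alpha_meta * s,
        alpha_segr=params.alpha_segr * s,
        d_meta=params.d_meta / s,
        d_segr=params.d_segr / s,
        beta_values=params.beta_values / s,
    )


@dataclass
class FitResult:
    params: ModelParams
    rss: float
    n_starts: int
    best_start_index: int
    spread: float
    converged: bool
    seed: int
    start_rss: np.ndarray = None

    def max_single_residual_sq(self, dataset: NormalizedDataset) -> float:
        residuals, _ = objective(self.params, dataset)
        return float(np.max(residuals**2))


def _make_packer(dataset: NormalizedDataset, interactions: InteractionSet):
    phases_present = tuple(
        p for p in (METAPHASE, SEGREGATION) if np.any(dataset.phases == p)
    )
    if not phases_present:
        raise ValueError("dataset contains no cells")
    return _ParamPacker(dataset.species, interactions, dataset.n_rois, phases_present)


def fit_model(
    dataset: NormalizedDataset,
    interactions: InteractionSet,
    config: FitConfig | None = None,
) -> FitResult:
    """Multi-start bounded least squares on log10 parameters.

    Starts are sampled log-uniformly within the parameter boxes (plus any
    warm starts supplied in the config); each start is refined with a
    trust-region-reflective solver using the analytic Jacobian, and the best
    residual sum of squares wins.  ``converged`` records whether the gap
    between the two best starts is below the largest single-datapoint squared
    residual of the winner — i.e. the multi-start spread is within noise.
    The returned parameters are expressed in the canonical gauge
    (:func:`apply_canonical_gauge`).
    """
    config = config or FitConfig()
    packer = _make_packer(dataset, interactions)
    eps = dataset.error_scale()
    rng = np.random.default_rng(config.seed)

    starts = []
    for warm in config.warm_starts:
        warm_aligned = _align_params(warm, packer)
        starts.append(packer.pack(warm_aligned))
    if config.include_default_start:
        x0 = np.zeros(packer.n_params)
        b_lo = packer.bounds[0]
        x0 = np.clip(x0, b_lo, packer.bounds[1])
        starts.append(x0)
    while len(starts) < max(config.n_starts, 1):
        starts.append(packer.sample_start(rng))

    fun = lambda x: _residual_and_jacobian(x, packer, dataset, eps, False)
    jac = lambda x: _residual_and_jacobian(x, packer, dataset, eps, True)[1]

    results = []
    for k, x0 in enumerate(starts):
        try:
            sol = least_squares(
                fun, x0, jac=jac, bounds=packer.bounds, method="trf",
                max_nfev=config.max_iter, xtol=config.tol, ftol=config.tol,
                gtol=config.tol,
            )
            results.append((float(sol.cost * 2.0), sol.x, k))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start %d failed: %s", k, exc)
    if not results:
        raise RuntimeError("all optimization starts failed")

    results.sort(key=lambda t: t[0])
    best_rss, best_x, best_k = results[0]
    spread = results[1][0] - best_rss if len(results) > 1 else 0.0
    params = apply_canonical_gauge(
        packer.unpack(best_x), packer.phases_present
    )
    fit = FitResult(
        params=params,
        rss=best_rss,
        n_starts=len(starts),
        best_start_index=best_k,
        spread=spread,
        converged=True,
        seed=config.seed,
        start_rss=np.array([r[0] for r in results]),
    )
    fit.converged = spread <= fit.max_single_residual_sq(dataset) or len(starts) == 1
    return fit


def _align_params(params: ModelParams, packer: _ParamPacker) -> ModelParams:
    """Project a ModelParams onto the packer's interaction set; pairs new to
    the set start at the lower beta bound."""
    values = []
    lookup = dict(zip(params.interactions.pairs, params.beta_values))
    for pair in packer.interactions.pairs:
        values.append(lookup.get(pair, BETA_BOUNDS[0]))
    return replace(
        params, interactions=packer.interactions, beta_values=np.array(values)
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionStep:
    pair: tuple
    delta_chi2: float
    accepted: bool
    rss_before: float
    rss_after: float


@dataclass
class SelectionTrace:
    steps: list
    final_interactions: InteractionSet
    final_fit: FitResult

    @property
    def accepted_pairs(self) -> list:
        return [s.pair for s in self.steps if s.accepted]


@dataclass
class SelectionConfig:
    n_starts: int = 50
    seed: int = 0
    alpha: float = 0.05
    max_steps: int | None = None
    use_warm_start: bool = True


def forward_select(
    dataset: NormalizedDataset,
    known: InteractionSet,
    candidates: list,
    config: SelectionConfig | None = None,
    base_fit: FitResult | None = None,
) -> SelectionTrace:
    """Greedy likelihood-ratio forward selection of new mutual affinities.

    At each step every remaining candidate pair is added in turn and the
    model refit (multi-start; the incumbent fit additionally seeds a warm
    start).  The best-improving candidate is accepted if its RSS reduction
    exceeds chi2_{0.95}(1) = 3.841; selection stops when no candidate
    passes.  The trace records the RSS drop of each accepted pair.
    """
    config = config or SelectionConfig()
    threshold = _chi2_threshold(config.alpha)
    rng = np.random.default_rng(config.seed)

    current = known
    if base_fit is None:
        base_fit = fit_model(
            dataset, current,
            FitConfig(n_starts=config.n_starts, seed=int(rng.integers(2**31))),
        )
    remaining = [canonical_pair(*p) for p in candidates]
    for p in remaining:
        if p in known:
            raise ValueError(f"candidate {p} already in the known set")
    steps = []
    step_count = 0
    while remaining:
        if config.max_steps is not None and step_count >= config.max_steps:
            break
        trial_results = []
        for pair in remaining:
            trial_set = current.with_pair(pair)
            warm = [base_fit.params] if config.use_warm_start else []
            trial_fit = fit_model(
                dataset, trial_set,
                FitConfig(
                    n_starts=config.n_starts, seed=int(rng.integers(2**31)),
                    warm_starts=warm,
                ),
            )
            trial_results.append((trial_fit.rss, pair, trial_fit))
        trial_results.sort(key=lambda t: t[0])
        best_rss, best_pair, best_fit = trial_results[0]
        delta = base_fit.rss - best_rss
        accepted = delta > threshold
        steps.append(
            SelectionStep(
                pair=best_pair, delta_chi2=float(delta), accepted=accepted,
                rss_before=base_fit.rss, rss_after=best_rss,
            )
        )
        step_count += 1
        if not accepted:
            break
        current = current.with_pair(best_pair)
        base_fit = best_fit
        remaining = [p for p in remaining if p != best_pair]
    return SelectionTrace(steps=steps, final_interactions=current, final_fit=base_fit)


def _chi2_threshold(alpha: float) -> float:
    from scipy.stats import chi2

    if abs(alpha - 0.05) < 1e-12:
        return CHI2_95_DF1
    return float(chi2.ppf(1.0 - alpha, df=1))


@dataclass
class ContributionResult:
    pair: tuple
    delta_chi2: float
    significant: bool
    inconclusive: bool
    rss_with: float
    rss_without: float


def contribution_test(
    dataset: NormalizedDataset,
    fitted: FitResult,
    pair: tuple,
    config: FitConfig | None = None,
) -> ContributionResult:
    """Withdrawal test: refit without one fitted pair and measure the chi^2
    increase.  Significant when the increase exceeds 3.841."""
    pair = canonical_pair(*pair)
    if pair not in fitted.params.interactions:
        raise ValueError(f"pair {pair} not in the fitted interaction set")
    reduced_set = fitted.params.interactions.without_pair(pair)
    config = config or FitConfig(n_starts=10, seed=0)
    config = replace(config, warm_starts=[fitted.params])
    reduced_fit = fit_model(dataset, reduced_set, config)
    delta = reduced_fit.rss - fitted.rss
    return ContributionResult(
        pair=pair,
        delta_chi2=float(delta),
        significant=delta > CHI2_95_DF1,
        inconclusive=not reduced_fit.converged,
        rss_with=fitted.rss,
        rss_without=reduced_fit.rss,
    )


def rescale_roi_affinities(fit: FitResult) -> dict:
    """Report ROI affinities on the measurement scale: alpha rows multiplied
    by their per-species, per-phase scaling d (raw alpha kept alongside)."""
    p = fit.params
    return {
        "alpha_meta": p.alpha_meta.copy(),
        "alpha_segr": p.alpha_segr.copy(),
        "alpha_meta_rescaled": p.alpha_meta * p.d_meta[:, None],
        "alpha_segr_rescaled": p.alpha_segr * p.d_segr[:, None],
    }


# ---------------------------------------------------------------------------
# two-species toy kinetics (independent check of the steady-state algebra)


@dataclass
class ToyKineticSystem:
    """Mass-action binding of two proteins to one compartment plus their
    dimerization inside it; free pools are held constant (non-limiting)."""

    a1: float
    a2: float
    k1_on: float
    k1_off: float
    k2_on: float
    k2_off: float
    kappa_on: float
    kappa_off: float

    def __post_init__(self):
        rates = (self.k1_on, self.k1_off, self.k2_on, self.k2_off,
                 self.kappa_on, self.kappa_off)
        if any(r <= 0 for r in rates):
            raise ValueError("all rate constants must be positive")

    @property
    def K1(self) -> float:
        return self.k1_off / self.k1_on

    @property
    def K2(self) -> float:
        return self.k2_off / self.k2_on

    @property
    def theta(self) -> float:
        return self.kappa_off / self.kappa_on

    def closed_form_equilibrium(self) -> dict:
        """Steady state: bound monomers A_i / K_i and the dimer
        A1 A2 / (K1 K2 theta)."""
        b1 = self.a1 / self.K1
        b2 = self.a2 / self.K2
        return {"A1l": b1, "A2l": b2, "A1l:A2l": self.a1 * self.a2 / (
            self.K1 * self.K2 * self.theta)}


def steady_state_oracle(
    system: ToyKineticSystem, horizon: float = 1e6, tol: float = 1e-10
) -> dict:
    """Integrate the binding/dimerization kinetics to equilibrium.

    Integrates in doubling time windows until the motion stalls — the
    largest time derivative falls below ``tol`` relative to the state —
    and raises if the horizon is exhausted first.
    """

    def rhs(_t, y):
        b1, b2, c = y
        dim_on = system.kappa_on * b1 * b2
        dim_off = system.kappa_off * c
        db1 = system.k1_on * system.a1 - system.k1_off * b1 - dim_on + dim_off
        db2 = system.k2_on * system.a2 - system.k2_off * b2 - dim_on + dim_off
        dc = dim_on - dim_off
        return [db1, db2, dc]

    y = np.zeros(3)
    t0, window = 0.0, 10.0
    while t0 < horizon:
        sol = solve_ivp(
            rhs, (t0, t0 + window), y, method="LSODA", rtol=1e-12, atol=1e-14
        )
        y = sol.y[:, -1]
        t0 += window
        window *= 2.0
        speed = np.max(np.abs(rhs(0.0, y)))
        if speed < tol * max(np.max(np.abs(y)), 1e-30):
            return {"A1l": y[0], "A2l": y[1], "A1l:A2l": y[2]}
    raise RuntimeError("steady state not reached within horizon")
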