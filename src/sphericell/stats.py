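"""Spatially resolved intensity statistics on SpheriCell maps.

Per cell and species, four scalar measures summarize an ROI map: a
concentration-proportional measure ``c`` (volume-weighted mean intensity),
an abundance-proportional measure ``a`` (volume-weighted sum), the center of
eccentricity ``r`` (intensity-weighted mean shell score, larger = farther
from the cell center) and the center of orientation ``phi``
(intensity-weighted mean sector angle, larger = closer to the division
plane).  Groups of cells are compared with Welch's t-tests — on
log-transformed values for c and a, whose population distributions are
log-normal, and on raw values for the bounded location scores r and phi —
with Bonferroni control over a family of comparisons (default 52) and
percentile-bootstrap confidence intervals (default 1,000 resamples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import DEFAULT_GRID, RoiGrid, SpheriCellMap

MEASURES = ("c", "a", "r", "phi")
LOG_MEASURES = ("c", "a")


@dataclass
class CellMeasures:
    """Scalar summary of one channel of one cell's ROI map."""

    cell_id: str
    species: str
    phase: str
    c: float
    a: float
    r: float
    phi: float

    def value(self, measure: str) -> float:
        if measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        return getattr(self, measure)


def cell_measures(
    spheri_map: SpheriCellMap, grid: RoiGrid | None = None
) -> list:
    """Compute (c, a, r, phi) for every channel of a map.

    A channel with any missing ROI, or with zero total intensity (which
    leaves the intensity-weighted location scores undefined), is flagged by
    NaN measures.
    """
    grid = grid or spheri_map.grid
    out = []
    V = np.asarray(spheri_map.volumes, dtype=float)
    r_mu = grid.r_mu[:, None]
    phi_nu = grid.phi_nu[None, :]
    for ci, name in enumerate(spheri_map.channel_names):
        I = spheri_map.intensities[ci]
        if np.any(np.isnan(I)):
            c = a = r = phi = np.nan
        else:
            vw = float((I * V).sum())
            vtot = float(V.sum())
            c = vw / vtot
            a = vw
            itot = float(I.sum())
            if itot <= 0:
                r = phi = np.nan
            else:
                r = float((I * r_mu).sum() / itot)
                phi = float((I * phi_nu).sum() / itot)
        out.append(
            CellMeasures(
                cell_id=spheri_map.cell_id, species=name,
                phase=spheri_map.frame.phase, c=c, a=a, r=r, phi=phi,
            )
        )
    return out


def bonferroni_threshold(alpha: float = 0.05, m: int = 52) -> float:
    """Per-comparison significance level controlling the family-wise error
    over ``m`` comparisons."""
    return alpha / m


@dataclass
class GroupComparison:
    species: str
    measure: str
    effect: float
    p_value: float
    significant: bool
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int


def _extract(measures: list, measure: str) -> np.ndarray:
    vals = np.array([m.value(measure) for m in measures], dtype=float)
    return vals[np.isfinite(vals)]


def compare_groups(
    group_a: list,
    group_b: list,
    measure: str,
    m: int = 52,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    alpha: float = 0.05,
) -> GroupComparison:
    """Welch-test one measure between two groups of cells (B vs A).

    For c and a the test runs on natural-log values and the effect is the
    log2 fold change (difference of log means, i.e. a geometric-mean ratio);
    for r and phi the test runs on raw values and the effect is the additive
    difference mean(B) - mean(A) — positive means toward the periphery (r)
    or toward the division plane (phi).  Significance applies the Bonferroni
    threshold ``alpha / m``; the CI is a seeded percentile bootstrap of the
    effect.
    """
    a = _extract(group_a, measure)
    b = _extract(group_b, measure)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 cells with finite measure per group")
    species = {mm.species for mm in group_a + group_b}
    species_name = species.pop() if len(species) == 1 else "mixed"

    if measure in LOG_MEASURES:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log-scale measures must be positive")
        ta, tb = np.log(a), np.log(b)
        effect_fn = lambda xa, xb: (np.mean(np.log(xb)) - np.mean(np.log(xa))) / np.log(2)
    else:
        ta, tb = a, b
        effect_fn = lambda xa, xb: np.mean(xb) - np.mean(xa)

    if np.ptp(ta) == 0 and np.ptp(tb) == 0:
        p_value = np.nan
    else:
        p_value = float(sps.ttest_ind(tb, ta, equal_var=False).pvalue)
    effect = float(effect_fn(a, b))
    if n_boot > 0:
        ci_low, ci_high = bootstrap_ci(
            (a, b), effect_fn, n_boot=n_boot, level=level, seed=seed
        )
    else:  # CI skipped (n_boot = 0), e.g. in large calibration sweeps
        ci_low = ci_high = float("nan")
    return GroupComparison(
        species=species_name,
        measure=measure,
        effect=effect,
        p_value=p_value,
        significant=bool(np.isfinite(p_value) and p_value < alpha / m),
        ci_low=ci_low,
        ci_high=ci_high,
        n_a=a.size,
        n_b=b.size,
    )


@dataclass
class RoiComparison:
    """Per-ROI effect map between two groups of cells for one channel."""

    effect: np.ndarray  # (6, 3); NaN where not significant (fold_test mode)
    p_values: np.ndarray | None
    significant: np.ndarray | None
    mode: str
    channel: str


def roi_comparisons(
    group_a: list,
    group_b: list,
    channel: str,
    mode: str = "log2diff",
    m: int = 18,
    alpha: float = 0.05,
) -> RoiComparison:
    """Compare two groups of SpheriCellMaps ROI by ROI.

    ``log2diff`` maps the difference of per-group log2 mean intensities
    (the display used for cell-line contrasts); ``fold_test`` additionally
    Welch-tests the log intensities per ROI with Bonferroni over the 18
    ROIs and reports effects only where significant (NaN elsewhere).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 maps per group")
    A = np.stack([mp.channel(channel) for mp in group_a])  # (n, 6, 3)
    B = np.stack([mp.channel(channel) for mp in group_b])
    if np.all(np.isnan(A), axis=0).any() or np.all(np.isnan(B), axis=0).any():
        raise ValueError("an ROI is empty in every cell of a group")

    mean_a = np.nanmean(A, axis=0)
    mean_b = np.nanmean(B, axis=0)
    log2diff = np.log2(mean_b) - np.log2(mean_a)
    if mode == "log2diff":
        return RoiComparison(
            effect=log2diff, p_values=None, significant=None,
            mode=mode, channel=channel,
        )
    if mode != "fold_test":
        raise ValueError("mode must be 'log2diff' or 'fold_test'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.ttest_ind(np.log(B), np.log(A), axis=0, equal_var=False,
                            nan_policy="omit")
    p = np.asarray(res.pvalue)
    significant = p < alpha / m
    effect = np.where(significant, log2diff, np.nan)
    return RoiComparison(
        effect=effect, p_values=p, significant=significant,
        mode=mode, channel=channel,
    )


def bootstrap_ci(
    data,
    statistic,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple:
    """Seeded percentile-bootstrap confidence interval.

    ``data`` is either one array (``statistic(sample)``) or a pair of arrays
    resampled independently (``statistic(sample_a, sample_b)``).
    """
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap samples; interval is unstable")
    rng = np.random.default_rng(seed)
    if isinstance(data, tuple):
        a, b = (np.asarray(x, dtype=float) for x in data)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 observations per group")
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        values = np.array([statistic(a[ia[k]], b[ib[k]]) for k in range(n_boot)])
    else:
        x = np.asarray(data, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        values = np.array([statistic(x[idx[k]]) for k in range(n_boot)])
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, lo)),
        float(np.quantile(values, 1.0 - lo)),
    )
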