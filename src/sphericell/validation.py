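"""Self-validation experiments on synthetic data.

Each function runs one end-to-end study against ground truth known by
construction: equilibrium algebra vs. ODE integration, registration of
phantom geometry, recovery of planted affinity parameters, calibration of
the likelihood-ratio selection step, and calibration of the Welch/Bonferroni
and bootstrap machinery.  They return plain dictionaries of summary numbers
and are the workhorses behind the acceptance checks.

Problem sizes follow the package's standard study conditions: 20 phantoms
per mitotic phase for geometry; 4 species x 18 ROIs x 200 cells with 3
planted mutual affinities and 50 optimization starts for parameter recovery;
200 single-candidate replicates for null calibration of selection.
"""

from __future__ import annotations

import numpy as np

from . import phantom as ph
from .geometry import (
    METAPHASE,
    SEGREGATION,
    build_frame,
    fit_ellipsoid,
    segment_chromatin,
)
from .model import (
    CHI2_95_DF1,
    FitConfig,
    SelectionConfig,
    ToyKineticSystem,
    fit_model,
    forward_select,
    steady_state_oracle,
)
from .simulate import (
    EffectSpec,
    make_ground_truth,
    make_roi_fixture_population,
    simulate_cell_totals,
    simulate_roi_dataset,
)
from .stats import bootstrap_ci, cell_measures, compare_groups

SPECIES4 = ("DAPI", "A", "B", "C")
PLANTED_PAIRS = ((1, 2), (0, 3), (2, 3))


def steady_state_agreement(n_systems: int = 100, seed: int = 0) -> dict:
    """ODE integration of the toy binding/dimerization kinetics vs. the
    closed-form equilibrium, over random-rate systems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_systems):
        rates = 10.0 ** rng.uniform(-1, 1, 6)
        conc = 10.0 ** rng.uniform(np.log10(0.2), np.log10(5.0), 2)
        system = ToyKineticSystem(
            a1=conc[0], a2=conc[1],
            k1_on=rates[0], k1_off=rates[1],
            k2_on=rates[2], k2_off=rates[3],
            kappa_on=rates[4], kappa_off=rates[5],
        )
        ode = steady_state_oracle(system)
        closed = system.closed_form_equilibrium()
        for key in closed:
            rel = abs(ode[key] - closed[key]) / abs(closed[key])
            worst = max(worst, rel)
    return {"max_rel_diff": worst, "n_systems": n_systems}


def _random_unit_axis(rng) -> tuple:
    v = rng.standard_normal(3)
    return tuple(v / np.linalg.norm(v))


def geometry_recovery(n_per_phase: int = 20, seed: int = 0) -> dict:
    """Register noisy seeded phantoms and score axis and radius errors
    against the configured ground truth."""
    rng = np.random.default_rng(seed)
    axis_errors = {METAPHASE: [], SEGREGATION: []}
    radius_errors = {METAPHASE: [], SEGREGATION: []}
    for phase in (METAPHASE, SEGREGATION):
        for k in range(n_per_phase):
            axis = _random_unit_axis(rng)
            if phase == METAPHASE:
                a = rng.uniform(6.5, 7.5)
                half_axes = (a, rng.uniform(5.5, 6.4), rng.uniform(3.0, 3.9))
                dist = 0.0
            else:
                half_axes = (
                    rng.uniform(3.8, 4.2),
                    rng.uniform(3.3, 3.7),
                    rng.uniform(2.8, 3.2),
                )
                dist = rng.uniform(8.0, 10.0)
            cfg = ph.PhantomConfig(
                phase=phase,
                axis_direction=axis,
                chromatin_half_axes=half_axes,
                centroid_distance=dist,
                channel_patterns=[ph.ChannelPattern("DAPI", "chromatin", 100.0)],
                noise=ph.NoiseConfig(gaussian_sd=4.0),
            )
            stack, truth = ph.make_phantom(cfg, seed=int(rng.integers(2**31)))
            components = segment_chromatin(stack)
            n_fits = 1 if phase == METAPHASE else 2
            fits = [
                fit_ellipsoid(c, stack.spacing) for c in components[:n_fits]
            ]
            frame = build_frame(phase, fits)
            cosang = np.clip(abs(frame.axis @ truth.true_axis), 0.0, 1.0)
            axis_errors[phase].append(np.degrees(np.arccos(cosang)))
            radius_errors[phase].append(
                abs(frame.sphere_radius - truth.true_sphere_radius)
                / truth.true_sphere_radius
            )
    return {
        "median_axis_error_deg": float(
            max(np.median(axis_errors[p]) for p in axis_errors)
        ),
        "median_radius_rel_err": float(
            max(np.median(radius_errors[p]) for p in radius_errors)
        ),
        "n_per_phase": n_per_phase,
    }


def affinity_recovery(
    seed: int = 0, n_cells: int = 200, n_starts: int = 50
) -> dict:
    """Fit the affinity model to a noisy synthetic dataset with three
    planted mutual affinities and score parameter recovery.

    Reports the log10 RMSE of the planted beta values (canonical gauge) and
    the median relative error of the gauge-invariant d*alpha products over
    both phases.
    """
    truth = make_ground_truth(list(SPECIES4), list(PLANTED_PAIRS), seed=seed)
    totals = simulate_cell_totals(truth, n_cells, seed=seed + 1)
    dataset = simulate_roi_dataset(truth, totals, with_noise=True, seed=seed + 2)
    fit = fit_model(
        dataset, truth.params.interactions,
        FitConfig(n_starts=n_starts, seed=seed + 3),
    )
    beta_rmse = float(np.sqrt(np.mean(
        (np.log10(fit.params.beta_values) - np.log10(truth.params.beta_values))
        ** 2
    )))
    rel_errors = []
    for phase_tag in ("meta", "segr"):
        true_prod = getattr(truth.params, f"alpha_{phase_tag}") * getattr(
            truth.params, f"d_{phase_tag}"
        )[:, None]
        fit_prod = getattr(fit.params, f"alpha_{phase_tag}") * getattr(
            fit.params, f"d_{phase_tag}"
        )[:, None]
        rel_errors.append((np.abs(fit_prod - true_prod) / true_prod).ravel())
    rel_errors = np.concatenate(rel_errors)
    return {
        "beta_log10_rmse": beta_rmse,
        "product_median_rel_err": float(np.median(rel_errors)),
        "product_p95_rel_err": float(np.quantile(rel_errors, 0.95)),
        "rss": fit.rss,
        "converged": bool(fit.converged),
        "n_cells": n_cells,
        "n_starts": n_starts,
    }


def selection_null_calibration(
    n_replicates: int = 200, seed: int = 0, n_cells: int = 60
) -> dict:
    """False-positive rate of one selection step under the null.

    Data carry only the known interaction; each replicate offers the step a
    single spurious candidate pair (rotating through the non-known pairs),
    so the measured rate is the per-test calibration of the chi-square(1)
    acceptance rule.  With a k-candidate pool the greedy best-of-k step
    accepts at ~1-(1-alpha)^k instead — a property of fixed-threshold
    forward selection, exercised separately by the planted-signal study.
    """
    truth = make_ground_truth(list(SPECIES4), [(0, 1)], seed=seed + 1_000_000)
    known = truth.params.interactions
    spurious = [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    accepted = 0
    deltas = []
    for rep in range(n_replicates):
        rep_seed = seed + 2 * rep
        totals = simulate_cell_totals(
            truth, n_cells, phase_fractions=(1, 0), seed=rep_seed
        )
        dataset = simulate_roi_dataset(
            truth, totals, with_noise=True, seed=rep_seed + 1
        )
        candidate = spurious[rep % len(spurious)]
        trace = forward_select(
            dataset, known, [candidate],
            SelectionConfig(n_starts=2, seed=rep_seed, max_steps=1),
        )
        accepted += trace.steps[0].accepted
        deltas.append(trace.steps[0].delta_chi2)
    return {
        "accept_rate": accepted / n_replicates,
        "n_replicates": n_replicates,
        "median_delta_chi2": float(np.median(deltas)),
    }


def selection_planted_detection(
    n_replicates: int = 30, seed: int = 0, n_cells: int = 60
) -> dict:
    """How often one strongly planted extra interaction is the first pair
    picked (and accepted) from the full candidate pool."""
    first_pick = 0
    planted = (2, 3)
    for rep in range(n_replicates):
        rep_seed = seed + 10_000 + 3 * rep
        truth = make_ground_truth(
            list(SPECIES4), [(0, 1), planted], seed=rep_seed,
            beta_range=(1.0, 2.0),
        )
        known = truth.params.interactions.without_pair(planted)
        totals = simulate_cell_totals(
            truth, n_cells, phase_fractions=(1, 0), seed=rep_seed + 1
        )
        dataset = simulate_roi_dataset(
            truth, totals, with_noise=True, seed=rep_seed + 2
        )
        candidates = [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        trace = forward_select(
            dataset, known, candidates,
            SelectionConfig(n_starts=2, seed=rep_seed, max_steps=1),
        )
        step = trace.steps[0]
        first_pick += step.accepted and step.pair == planted
    return {"first_pick_rate": first_pick / n_replicates,
            "n_replicates": n_replicates}


def welch_bonferroni_fwer(
    n_families: int = 300, seed: int = 0, n_cells: int = 30, m: int = 52
) -> dict:
    """Family-wise error of 52 Welch-on-log comparisons (13 species x 4
    measures) at the Bonferroni threshold, under exchangeable groups."""
    rng = np.random.default_rng(seed)
    n_channels = 13
    template = np.exp(rng.normal(np.log(50.0), 0.3, (n_channels, 6, 3)))
    channels = ["DAPI"] + [f"P{k}" for k in range(1, n_channels)]
    failures = 0
    for fam in range(n_families):
        pop = make_roi_fixture_population(
            template, channels, n_cells=n_cells, effect=EffectSpec(),
            seed=int(rng.integers(2**31)),
        )
        measures_a = [cell_measures(mp) for mp in pop.group_a]
        measures_b = [cell_measures(mp) for mp in pop.group_b]
        any_reject = False
        for ci in range(n_channels):
            group_a = [row[ci] for row in measures_a]
            group_b = [row[ci] for row in measures_b]
            for measure in ("c", "a", "r", "phi"):
                res = compare_groups(
                    group_a, group_b, measure, m=m, n_boot=0, seed=0,
                )
                if res.significant:
                    any_reject = True
                    break
            if any_reject:
                break
        failures += any_reject
    return {"fwer": failures / n_families, "n_families": n_families}


def bootstrap_coverage(
    n_replicates: int = 500, seed: int = 0, n: int = 100, n_boot: int = 1000
) -> dict:
    """Coverage of the seeded percentile bootstrap 95% CI of a mean."""
    rng = np.random.default_rng(seed)
    covered = 0
    for rep in range(n_replicates):
        x = rng.standard_normal(n)
        lo, hi = bootstrap_ci(
            x, np.mean, n_boot=n_boot, seed=int(rng.integers(2**31))
        )
        covered += lo <= 0.0 <= hi
    return {"coverage": covered / n_replicates, "n_replicates": n_replicates}
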