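"""Affinity model: forward evaluation, objective, fitting, selection."""

import numpy as np
import pytest

import sphericell as sc
from sphericell.model import (
    BETA_BOUNDS,
    InteractionSet,
    ModelParams,
    SpeciesSet,
    _make_packer,
    _residual_and_jacobian,
    canonical_pair,
)


def _params(n_species=2, alpha=1.0, d=1.0, pairs=(), beta=()):
    species = SpeciesSet(tuple(f"S{k}" for k in range(n_species)))
    return ModelParams(
        species=species,
        interactions=InteractionSet(list(pairs)),
        d_meta=np.full(n_species, d),
        d_segr=np.full(n_species, d),
        alpha_meta=np.full((n_species, 18), alpha),
        alpha_segr=np.full((n_species, 18), alpha),
        beta_values=np.asarray(beta, dtype=float),
    )


# ---------------------------------------------------------------------------
# forward model


def test_predict_linear_without_interactions():
    params = _params()
    out = sc.predict(params, np.array([[2.0, 3.0]]), [sc.METAPHASE])
    np.testing.assert_allclose(out[0, 0], 2.0)
    np.testing.assert_allclose(out[0, 1], 3.0)


def test_predict_unit_pair():
    params = _params(pairs=[(0, 1)], beta=[1.0])
    out = sc.predict(params, np.array([[1.0, 1.0]]), [sc.METAPHASE])
    np.testing.assert_allclose(out, 2.0)  # 1 * 1 * (1 + 1*1*1)


def test_predict_homodimer():
    params = _params(n_species=2, pairs=[(0, 0)], beta=[1.0])
    out = sc.predict(params, np.array([[2.0, 1.0]]), [sc.METAPHASE])
    np.testing.assert_allclose(out[0, 0], 6.0)  # 2 * (1 + 1*1*2)
    np.testing.assert_allclose(out[0, 1], 1.0)


def test_predict_symmetric_under_pair_relabeling():
    rng = np.random.default_rng(0)
    totals = rng.uniform(0.5, 2.0, (4, 3))
    phases = [sc.METAPHASE, sc.SEGREGATION, sc.METAPHASE, sc.SEGREGATION]
    p12 = _params(n_species=3, pairs=[(1, 2)], beta=[0.7])
    p21 = _params(n_species=3, pairs=[(2, 1)], beta=[0.7])
    np.testing.assert_array_equal(
        sc.predict(p12, totals, phases), sc.predict(p21, totals, phases)
    )


def test_phase_specific_parameters_select_by_phase():
    params = _params()
    params.alpha_segr[:] = 2.0
    out = sc.predict(
        params, np.ones((2, 2)), [sc.METAPHASE, sc.SEGREGATION]
    )
    np.testing.assert_allclose(out[0], 1.0)
    np.testing.assert_allclose(out[1], 2.0)


# ---------------------------------------------------------------------------
# objective


def test_error_scale_five_plus_five_percent(small_truth):
    totals = sc.CellTotals(
        species=SpeciesSet(("S0", "S1")),
        totals=np.ones((1, 2)),
        phases=np.array([sc.METAPHASE]),
    )
    ds = sc.NormalizedDataset(
        species=totals.species,
        phases=totals.phases,
        roi=np.full((1, 2, 18), 2.0),
        totals=totals.totals,
        medians=np.ones(2),
        volumes=sc.DEFAULT_GRID.roi_volume_fractions().ravel(),
    )
    ds.roi[0, 0, 0] = 4.0  # species max becomes 4
    eps = ds.error_scale()
    assert eps[0, 0, 1] == pytest.approx(0.05 * 2.0 + 0.05 * 4.0)  # = 0.3


def test_objective_zero_at_exact_model(small_truth):
    totals = sc.simulate_cell_totals(small_truth, 10, seed=1)
    ds = sc.simulate_roi_dataset(small_truth, totals, with_noise=False)
    _, rss = sc.objective(small_truth.params, ds)
    assert rss == pytest.approx(0.0, abs=1e-18)


def test_objective_matches_loop_oracle(small_truth, small_dataset):
    residuals, rss = sc.objective(small_truth.params, small_dataset)
    eps = small_dataset.error_scale()
    model = sc.predict(
        small_truth.params, small_dataset.totals, small_dataset.phases
    )
    total = 0.0
    for c in range(small_dataset.n_cells):
        for i in range(small_dataset.species.n):
            for l in range(18):
                total += (
                    (small_dataset.roi[c, i, l] - model[c, i, l]) / eps[c, i, l]
                ) ** 2
    assert rss == pytest.approx(total, rel=1e-12)


def test_analytic_jacobian_matches_finite_differences(small_truth, small_dataset):
    packer = _make_packer(small_dataset, small_truth.params.interactions)
    eps = small_dataset.error_scale()
    x0 = packer.sample_start(np.random.default_rng(3))
    _, J = _residual_and_jacobian(x0, packer, small_dataset, eps, True)
    h = 1e-6
    rng = np.random.default_rng(4)
    for k in rng.choice(packer.n_params, size=12, replace=False):
        xp, xm = x0.copy(), x0.copy()
        xp[k] += h
        xm[k] -= h
        num = (
            _residual_and_jacobian(xp, packer, small_dataset, eps, False)
            - _residual_and_jacobian(xm, packer, small_dataset, eps, False)
        ) / (2 * h)
        np.testing.assert_allclose(J[:, k], num, atol=1e-5 * max(1, np.abs(num).max()))


# ---------------------------------------------------------------------------
# normalization


def test_single_cell_normalizes_to_unit_total():
    species = SpeciesSet(("A", "B"))
    rng = np.random.default_rng(5)
    raw = rng.uniform(10, 100, (1, 2, 18))
    ds = sc.normalize_dataset(raw, [sc.METAPHASE], species)
    np.testing.assert_allclose(ds.totals, 1.0)


def test_normalization_median_is_one():
    species = SpeciesSet(("A", "B", "C"))
    rng = np.random.default_rng(6)
    raw = rng.lognormal(3.0, 0.5, (21, 3, 18))
    ds = sc.normalize_dataset(raw, [sc.METAPHASE] * 21, species)
    np.testing.assert_allclose(np.median(ds.totals, axis=0), 1.0, atol=1e-9)


def test_cell_average_matches_volume_weighting_oracle():
    species = SpeciesSet(("A", "B"))
    rng = np.random.default_rng(7)
    raw = rng.uniform(1, 9, (4, 2, 18))
    vols = sc.DEFAULT_GRID.roi_volume_fractions().ravel()
    ds = sc.normalize_dataset(raw, [sc.METAPHASE] * 4, species)
    for c in range(4):
        for i in range(2):
            expected = sum(
                raw[c, i, l] * vols[l] for l in range(18)
            ) / vols.sum()
            assert ds.totals[c, i] * ds.medians[i] == pytest.approx(
                expected, rel=1e-12
            )


# ---------------------------------------------------------------------------
# fitting


def test_linear_limit_matches_closed_form_regression():
    """Without interactions the model is linear in (d * alpha); the fit must
    match the per-(species, ROI) weighted regression estimate."""
    truth = sc.make_ground_truth(["A", "B"], [], seed=21)
    totals = sc.simulate_cell_totals(truth, 40, phase_fractions=(1, 0), seed=22)
    ds = sc.simulate_roi_dataset(truth, totals, with_noise=True, seed=23)
    fit = sc.fit_model(ds, InteractionSet([]), sc.FitConfig(n_starts=3, seed=1))
    eps = ds.error_scale()
    w = 1.0 / eps**2
    # closed form: argmin sum w (y - p T)^2 = sum(w y T) / sum(w T^2)
    T = ds.totals[:, :, None]
    closed = (w * ds.roi * T).sum(axis=0) / (w * T**2).sum(axis=0)
    fitted = fit.params.alpha_meta * fit.params.d_meta[:, None]
    np.testing.assert_allclose(fitted, closed, rtol=1e-6)


def test_warm_start_at_truth_reaches_noise_level(small_truth, small_dataset):
    fit = sc.fit_model(
        small_dataset, small_truth.params.interactions,
        sc.FitConfig(n_starts=1, seed=0, warm_starts=[small_truth.params]),
    )
    # noise-level rss: about one squared unit per datapoint
    n = small_dataset.roi.size
    assert fit.rss < 1.5 * n


def test_canonical_gauge_preserves_rss(small_truth, small_dataset):
    gauged = sc.apply_canonical_gauge(small_truth.params)
    _, rss0 = sc.objective(small_truth.params, small_dataset)
    _, rss1 = sc.objective(gauged, small_dataset)
    assert rss1 == pytest.approx(rss0, rel=1e-12)
    logs = np.concatenate([
        np.log(gauged.alpha_meta).ravel(), np.log(gauged.alpha_segr).ravel()
    ])
    assert abs(logs.mean()) < 1e-12


def test_fit_deterministic_given_seed(small_truth, small_dataset):
    cfg = sc.FitConfig(n_starts=2, seed=9)
    f1 = sc.fit_model(small_dataset, small_truth.params.interactions, cfg)
    f2 = sc.fit_model(small_dataset, small_truth.params.interactions, cfg)
    assert f1.rss == f2.rss
    np.testing.assert_array_equal(f1.params.beta_values, f2.params.beta_values)


# ---------------------------------------------------------------------------
# selection and withdrawal


def test_forward_select_threshold_logic(small_truth, small_dataset):
    """A candidate whose refit cannot beat chi2 threshold is rejected and
    selection stops."""
    known = small_truth.params.interactions
    base = sc.fit_model(
        small_dataset, known,
        sc.FitConfig(n_starts=1, seed=0, warm_starts=[small_truth.params]),
    )
    trace = sc.forward_select(
        small_dataset, known, [(0, 1)],
        sc.SelectionConfig(n_starts=1, seed=1, max_steps=1),
        base_fit=base,
    )
    step = trace.steps[0]
    assert step.accepted == (step.delta_chi2 > sc.CHI2_95_DF1)
    assert step.delta_chi2 >= -1e-6  # nested models, optimizer tolerance


def test_forward_select_finds_planted_pair():
    truth = sc.make_ground_truth(
        ["DAPI", "A", "B"], [(1, 2)], seed=31, beta_range=(1.5, 2.0)
    )
    totals = sc.simulate_cell_totals(truth, 60, phase_fractions=(1, 0), seed=32)
    ds = sc.simulate_roi_dataset(truth, totals, with_noise=True, seed=33)
    trace = sc.forward_select(
        ds, InteractionSet([]), [(0, 1), (0, 2), (1, 2)],
        sc.SelectionConfig(n_starts=2, seed=3, max_steps=1),
    )
    assert trace.steps[0].pair == (1, 2)
    assert trace.steps[0].accepted


def test_contribution_test_on_planted_and_inactive_pairs(small_truth, small_dataset):
    interactions = small_truth.params.interactions.with_pair((0, 1))
    import dataclasses

    params = dataclasses.replace(
        small_truth.params,
        interactions=interactions,
        beta_values=np.append(small_truth.params.beta_values, BETA_BOUNDS[0]),
    )
    fit = sc.fit_model(
        small_dataset, interactions,
        sc.FitConfig(n_starts=1, seed=0, warm_starts=[params]),
    )
    cfg = sc.FitConfig(n_starts=1, seed=0)
    planted = sc.contribution_test(small_dataset, fit, (1, 2), cfg)
    assert planted.significant
    inactive = sc.contribution_test(small_dataset, fit, (0, 1), cfg)
    assert abs(inactive.delta_chi2) < sc.CHI2_95_DF1
    assert not inactive.significant


def test_rescaled_affinities_are_rowwise_products(small_truth):
    fake_fit = sc.FitResult(
        params=small_truth.params, rss=0.0, n_starts=1, best_start_index=0,
        spread=0.0, converged=True, seed=0,
    )
    out = sc.rescale_roi_affinities(fake_fit)
    p = small_truth.params
    for i in range(p.species.n):
        np.testing.assert_allclose(
            out["alpha_meta_rescaled"][i], p.alpha_meta[i] * p.d_meta[i]
        )
        np.testing.assert_allclose(
            out["alpha_segr_rescaled"][i], p.alpha_segr[i] * p.d_segr[i]
        )


# ---------------------------------------------------------------------------
# counting helpers


def test_parameter_count_identities():
    assert sc.n_parameters(13, 18, 2, 19) == 513
    assert sc.n_parameters(13, 18, 2, 35) == 529


def test_datapoint_count_identities():
    counts = sc.n_datapoints(205, 13, 18)
    assert counts["roi_values"] == 47_970
    assert counts["cell_averages"] == 2_665
    assert counts["total"] == 50_635
    screen = sc.n_datapoints(1_217, 13, 18)
    assert screen["roi_values"] == 284_778


# ---------------------------------------------------------------------------
# toy kinetics


def test_steady_state_unit_case():
    system = sc.ToyKineticSystem(
        a1=1.0, a2=1.0, k1_on=1.0, k1_off=1.0, k2_on=1.0, k2_off=1.0,
        kappa_on=1.0, kappa_off=1.0,
    )
    eq = sc.steady_state_oracle(system)
    assert eq["A1l:A2l"] == pytest.approx(1.0, rel=1e-6)


def test_steady_state_closed_form_example():
    # A1=2, A2=3, K1=0.5, K2=1, theta=2 -> dimer = 2*3/(0.5*1*2) = 6
    system = sc.ToyKineticSystem(
        a1=2.0, a2=3.0, k1_on=2.0, k1_off=1.0, k2_on=1.0, k2_off=1.0,
        kappa_on=0.5, kappa_off=1.0,
    )
    assert system.closed_form_equilibrium()["A1l:A2l"] == pytest.approx(6.0)
    eq = sc.steady_state_oracle(system)
    assert eq["A1l:A2l"] == pytest.approx(6.0, rel=1e-6)


def test_steady_state_depends_only_on_ratios():
    kwargs = dict(a1=1.5, a2=0.8, kappa_on=2.0, kappa_off=3.0)
    s1 = sc.ToyKineticSystem(k1_on=1.0, k1_off=2.0, k2_on=3.0, k2_off=1.5, **kwargs)
    s2 = sc.ToyKineticSystem(k1_on=2.0, k1_off=4.0, k2_on=6.0, k2_off=3.0, **kwargs)
    e1, e2 = sc.steady_state_oracle(s1), sc.steady_state_oracle(s2)
    for key in e1:
        assert e1[key] == pytest.approx(e2[key], rel=1e-6)


def test_nonpositive_rates_rejected():
    with pytest.raises(ValueError):
        sc.ToyKineticSystem(
            a1=1, a2=1, k1_on=0.0, k1_off=1, k2_on=1, k2_off=1,
            kappa_on=1, kappa_off=1,
        )
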