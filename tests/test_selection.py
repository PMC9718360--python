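"""Exhaustive subset selection: enumeration, fitting, constraints, F tests."""

import numpy as np
import pytest
from scipy import integrate, stats

from conespec.dataset import SpectralDataset
from conespec.model import ModelParams, predict_log
from conespec.selection import (
    FitOptions,
    compare_models_F,
    cross_fit,
    enumerate_models,
    fit_model,
    select,
    spec_from_id,
    vm_significance,
)
from conespec.synth import (
    SimulationScenario,
    normalize_truth,
    simulate_cumulative,
    wt_larva_like,
)
from conespec.templates import ConeCatalog, ConeEntry, GovardovskiiTemplate


def model_id_of(subset, catalog):
    return sum(1 << catalog.index(lbl) for lbl in subset)


class TestEnumeration:
    def test_eight_cone_catalog_yields_255_models(self, catalog):
        specs = enumerate_models(catalog)
        assert len(specs) == 255

    def test_three_cone_catalog_yields_seven(self):
        t = GovardovskiiTemplate()
        cat = ConeCatalog(
            entries=(
                ConeEntry("a", 400.0, 0.0, t),
                ConeEntry("b", 500.0, 0.1, t),
                ConeEntry("c", 600.0, 0.2, t),
            )
        )
        assert len(enumerate_models(cat)) == 7

    def test_no_duplicate_subsets(self, catalog):
        specs = enumerate_models(catalog)
        assert len({frozenset(s.subset) for s in specs}) == 255

    def test_bitmask_id_subset_bijection(self, catalog):
        for spec in enumerate_models(catalog):
            assert model_id_of(spec.subset, catalog) == spec.model_id
        # hand-checked examples of the documented convention
        assert spec_from_id(111, catalog).subset == ("UV", "B1", "B2", "G1", "G4", "R2")
        assert spec_from_id(192, catalog).subset == ("R2", "R1")
        assert spec_from_id(255, catalog).n_cones == 8

    def test_out_of_range_id_rejected(self, catalog):
        with pytest.raises(ValueError):
            spec_from_id(0, catalog)
        with pytest.raises(ValueError):
            spec_from_id(256, catalog)


class TestVmSignificance:
    def test_zero_estimate_has_p_one(self):
        assert vm_significance(0.0, 0.1, 100) == 1.0

    def test_negative_estimate_never_significant(self):
        assert vm_significance(-0.5, 0.01, 100) == 1.0

    def test_zero_se_convention(self):
        assert vm_significance(0.5, 0.0, 100) == 0.0
        assert vm_significance(0.0, 0.0, 100) == 1.0

    def test_large_t_gives_astronomically_small_p(self):
        # a strong cone signal: t ~ 17.8 on ~1800 df
        p = vm_significance(17.8e-2, 1e-2, 1822)
        assert 1e-70 < p < 1e-60

    @pytest.mark.parametrize("t_val,df", [(2.3, 8), (1.1, 30), (3.7, 150)])
    def test_matches_quadrature_of_t_density(self, t_val, df):
        p = vm_significance(t_val * 0.01, 0.01, df)
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, df), t_val, np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-8)

    def test_one_sided_option_halves_positive_tail(self):
        two = vm_significance(0.02, 0.01, 50)
        one = vm_significance(0.02, 0.01, 50, one_sided=True)
        assert one == pytest.approx(two / 2)


class TestCompareModelsF:
    def test_equal_variances_large_df(self):
        out = compare_models_F(1.0, 2000, 1.0, 2000)
        assert out["F"] == 1.0
        assert out["cdf"] == pytest.approx(0.5, abs=0.01)
        assert out["p_two_sided"] == pytest.approx(1.0, abs=0.02)

    def test_near_unity_ratio_reports_equivalence_scale_p(self):
        # a variance ratio of 0.9992 on ~1900 df: cdf ~ 0.49, two-sided p ~ 0.99
        out = compare_models_F(0.9992, 1939, 1.0, 1940)
        assert out["cdf"] == pytest.approx(0.493, abs=0.01)
        assert out["p_two_sided"] == pytest.approx(0.986, abs=0.02)
        assert out["p_two_sided"] >= 0.95  # declared equivalent

    @pytest.mark.parametrize("f,d1,d2", [(1.5, 20, 25), (0.7, 40, 35), (2.5, 10, 12)])
    def test_matches_quadrature_of_f_density(self, f, d1, d2):
        out = compare_models_F(f, d1, 1.0, d2)
        upper, _ = integrate.quad(lambda x: stats.f.pdf(x, d1, d2), f, np.inf)
        assert out["p_one_sided"] == pytest.approx(upper, abs=1e-8)
        assert out["cdf"] == pytest.approx(1 - upper, abs=1e-8)

    def test_zero_denominator_conventions(self):
        assert compare_models_F(0.5, 10, 0.0, 10)["p_two_sided"] == 0.0
        assert compare_models_F(0.0, 10, 0.0, 10)["p_two_sided"] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_models_F(-1.0, 10, 1.0, 10)
        with pytest.raises(ValueError):
            compare_models_F(1.0, 0, 1.0, 10)


@pytest.fixture(scope="module")
def small_truth():
    from conespec import build_default_catalog, default_protocol

    catalog = build_default_catalog()
    protocol = default_protocol()
    truth = normalize_truth(
        ModelParams(
            subset=("UV", "G1", "R2"),
            vm={"UV": 0.5, "G1": 0.3, "R2": 0.8},
            log_k_uv=4.3,
        ),
        catalog,
        protocol,
    )
    return SimulationScenario(truth=truth, catalog=catalog, protocol=protocol)


class TestFitModel:
    def test_noiseless_round_trip_recovers_truth(self, catalog, small_truth):
        scn = SimulationScenario(
            truth=small_truth.truth,
            catalog=catalog,
            protocol=small_truth.protocol,
            noise_sd=0.0,
            n_datasets=3,
            seed=7,
        )
        cum = simulate_cumulative(scn)
        spec = spec_from_id(model_id_of(scn.truth.subset, catalog), catalog)
        res = fit_model(cum, spec, catalog)
        assert res.converged
        assert res.log_k_uv == pytest.approx(scn.truth.log_k_uv, abs=1e-4)
        for lbl, v in scn.truth.vm.items():
            assert res.vm[lbl] == pytest.approx(v, abs=1e-4)
        assert res.r2 > 1 - 1e-10

    def test_all_zero_amplitudes_yield_insignificant_vm(self, catalog, protocol):
        conds = protocol.conditions()
        ds = SpectralDataset(
            wavelength_nm=[c.wavelength_nm for c in conds],
            log_irradiance=[c.log_irradiance for c in conds],
            amplitude=np.zeros(len(conds)),
        )
        res = fit_model(ds, spec_from_id(7, catalog), catalog)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in res.vm.values())
        assert not res.constraint_flags["all_vm_significant"]

    def test_single_cone_fit_matches_grid_search_oracle(self, catalog, protocol, rng):
        truth = ModelParams(subset=("R2",), vm={"R2": 0.7}, log_k_uv=4.4)
        scn = SimulationScenario(
            truth=truth, catalog=catalog, protocol=protocol, noise_sd=0.02, seed=3
        )
        ds = simulate_cumulative(scn)
        spec = spec_from_id(model_id_of(("R2",), catalog), catalog)
        res = fit_model(ds, spec, catalog)

        vm_grid = np.linspace(0.4, 1.1, 141)  # 0.005 steps
        k_grid = np.linspace(3.9, 4.9, 201)  # 0.005 steps
        y = ds.amplitude
        best = (np.inf, None, None)
        for lk in k_grid:
            p = ModelParams(subset=("R2",), vm={"R2": 1.0}, log_k_uv=lk)
            h = np.asarray(predict_log(p, catalog, ds.wavelength_nm, ds.log_irradiance))
            for vm in vm_grid:
                sse = float(np.sum((vm * h - y) ** 2))
                if sse < best[0]:
                    best = (sse, vm, lk)
        assert res.vm["R2"] == pytest.approx(best[1], abs=0.005)
        assert res.log_k_uv == pytest.approx(best[2], abs=0.005)

    def test_insufficient_points_rejected(self, catalog):
        ds = SpectralDataset(
            wavelength_nm=[490.0, 490.0],
            log_irradiance=[4.0, 5.0],
            amplitude=[0.1, 0.2],
        )
        with pytest.raises(ValueError, match="few points"):
            fit_model(ds, spec_from_id(7, catalog), catalog)


class TestSelect:
    def test_noiseless_single_cone_truth_selected_exactly(self, catalog, protocol):
        truth = normalize_truth(
            ModelParams(subset=("R2",), vm={"R2": 1.0}, log_k_uv=4.4),
            catalog,
            protocol,
        )
        scn = SimulationScenario(
            truth=truth, catalog=catalog, protocol=protocol,
            noise_sd=0.0, n_datasets=2, seed=1,
        )
        cum = simulate_cumulative(scn)
        report = select(cum, catalog)
        assert report.best is not None
        assert report.best.spec.subset == ("R2",)

    def test_empty_amplitudes_give_no_admissible_model(self, catalog, protocol):
        conds = protocol.conditions()
        n = len(conds)
        ds = SpectralDataset(
            wavelength_nm=[c.wavelength_nm for c in conds] * 2,
            log_irradiance=[c.log_irradiance for c in conds] * 2,
            amplitude=np.zeros(2 * n),
        )
        report = select(ds, catalog)
        assert report.no_admissible_model
        assert report.best is None

    def test_selection_invariant_to_row_order(self, catalog, small_truth):
        scn = SimulationScenario(
            truth=small_truth.truth, catalog=catalog, protocol=small_truth.protocol,
            noise_sd=0.02, n_datasets=3, seed=11,
        )
        cum = simulate_cumulative(scn)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cum.n_points)
        shuffled = SpectralDataset(
            cum.wavelength_nm[perm], cum.log_irradiance[perm], cum.amplitude[perm],
            cum.is_replicate[perm], cum.eye_id[perm],
        )
        a = select(cum, catalog)
        b = select(shuffled, catalog)
        assert a.best.spec.model_id == b.best.spec.model_id
        assert a.best.r2 == pytest.approx(b.best.r2, rel=1e-9)

    def test_full_model_r2_not_below_any_subset(self, catalog, small_truth):
        scn = SimulationScenario(
            truth=small_truth.truth, catalog=catalog, protocol=small_truth.protocol,
            noise_sd=0.02, n_datasets=2, seed=5,
        )
        cum = simulate_cumulative(scn)
        report = select(cum, catalog)
        full = next(r for r in report.results if r.spec.model_id == 255)
        tol = 1e-9
        for r in report.results:
            assert full.r2 >= r.r2 - tol

    def test_vm_bias_shrinks_with_noise(self, catalog, small_truth):
        errs = []
        for noise in (0.04, 0.01, 0.0025):
            scn = SimulationScenario(
                truth=small_truth.truth, catalog=catalog,
                protocol=small_truth.protocol,
                noise_sd=noise, n_datasets=4, seed=17,
            )
            cum = simulate_cumulative(scn)
            spec = spec_from_id(model_id_of(small_truth.truth.subset, catalog), catalog)
            res = fit_model(cum, spec, catalog)
            errs.append(
                max(
                    abs(res.vm[l] - v)
                    for l, v in small_truth.truth.vm.items()
                )
            )
        assert errs[2] < errs[0]
        assert errs[2] < 0.01

    def test_amplitude_cap_excludes_degenerate_fits(self, catalog, protocol):
        # near-flat dim data at a single wavelength family drives Vm to the
        # cap with huge uncertainty; such fits must be flagged inadmissible
        conds = protocol.conditions()
        wl = np.array([c.wavelength_nm for c in conds])
        li = np.array([c.log_irradiance for c in conds]) - 4.0  # very dim
        amp = np.full(wl.size, 0.02)
        ds = SpectralDataset(wl, li, amp)
        report = select(ds, catalog, FitOptions())
        for r in report.results:
            if not r.constraint_flags["all_vm_below_cap"]:
                assert not r.admissible


class TestCrossFit:
    def test_self_comparison_is_unity(self, catalog, small_truth):
        scn = SimulationScenario(
            truth=small_truth.truth, catalog=catalog, protocol=small_truth.protocol,
            noise_sd=0.02, n_datasets=3, seed=21,
        )
        cum = simulate_cumulative(scn)
        spec = spec_from_id(model_id_of(small_truth.truth.subset, catalog), catalog)
        own = fit_model(cum, spec, catalog)
        res, cmp = cross_fit(cum, spec, catalog, best_b=own)
        assert cmp["F"] == pytest.approx(1.0, rel=1e-12)
        assert cmp["p_two_sided"] == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_truth_spec_lands_in_inferiority_tail(self, catalog, protocol):
        truth_b = normalize_truth(
            ModelParams(subset=("UV",), vm={"UV": 1.0}, log_k_uv=4.0),
            catalog, protocol,
        )
        scn = SimulationScenario(
            truth=truth_b, catalog=catalog, protocol=protocol,
            noise_sd=0.02, n_datasets=3, seed=2,
        )
        cum = simulate_cumulative(scn)
        own = fit_model(cum, spec_from_id(model_id_of(("UV",), catalog), catalog), catalog)
        spec_a = spec_from_id(model_id_of(("R1",), catalog), catalog)
        res, cmp = cross_fit(cum, spec_a, catalog, best_b=own)
        assert cmp["F"] > 1.5
        assert cmp["p_two_sided"] < 0.001

    def test_reproducible_across_runs(self, catalog, small_truth):
        scn = SimulationScenario(
            truth=small_truth.truth, catalog=catalog, protocol=small_truth.protocol,
            noise_sd=0.02, n_datasets=2, seed=9,
        )
        cum = simulate_cumulative(scn)
        spec = spec_from_id(7, catalog)
        r1, c1 = cross_fit(cum, spec, catalog, best_b=fit_model(cum, spec_from_id(69, catalog), catalog))
        r2, c2 = cross_fit(cum, spec, catalog, best_b=fit_model(cum, spec_from_id(69, catalog), catalog))
        assert r1.ss_res == r2.ss_res
        assert c1 == c2


def test_selection_invariant_to_catalog_label_permutation(protocol):
    """Relabelling cones permutes model ids consistently but not the winner."""
    from conespec import build_default_catalog

    catalog = build_default_catalog()
    truth = normalize_truth(
        ModelParams(subset=("UV", "R2"), vm={"UV": 0.6, "R2": 0.9}, log_k_uv=4.3),
        catalog, protocol,
    )
    scn = SimulationScenario(
        truth=truth, catalog=catalog, protocol=protocol,
        noise_sd=0.02, n_datasets=2, seed=4,
    )
    cum = simulate_cumulative(scn)
    renamed = ConeCatalog(
        entries=tuple(
            ConeEntry(f"c{i}", e.wlmax_nm, e.delta_log_k, e.template)
            for i, e in enumerate(catalog.entries)
        ),
        floor=catalog.floor,
        domain=catalog.domain,
    )
    a = select(cum, catalog)
    b = select(cum, renamed)
    assert a.best.spec.model_id == b.best.spec.model_id
    assert a.best.r2 == pytest.approx(b.best.r2, rel=1e-9)
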