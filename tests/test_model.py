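"""Cascade dynamics: Laplacian, derivatives, Euler integration, oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import samcascade as sc
from samcascade.model import (
    BASELINE,
    DivergenceError,
    ModelError,
    SimulationConfig,
    StabilityError,
    StateField,
    integrate_euler_many,
    single_cell_steady_state,
)
from samcascade.template import CORPUS, L1, L2

from conftest import FAST_CONFIG, make_pair_template

#: Parameters with diffusion switched off: each cell evolves independently.
NO_DIFFUSION = BASELINE.replace(D_mir171=0.0)


def _uniform_field(template, value, label="test"):
    return sc.MLpField(values=np.full(template.n_cells, float(value)), label=label)


class TestDiscreteLaplacian:
    def test_two_cell_hand_example(self):
        pair = make_pair_template()
        out = sc.discrete_laplacian(np.array([0.0, 2.0]), pair)
        assert out.tolist() == [2.0, -2.0]

    def test_constant_field_maps_to_zero(self, small_template):
        out = sc.discrete_laplacian(np.full(small_template.n_cells, 3.7), small_template)
        assert np.allclose(out, 0.0, atol=1e-12)

    @given(seed=st.integers(0, 1000))
    def test_conservation_any_field_sums_to_zero(self, small_template, seed):
        field = np.random.default_rng(seed).uniform(0, 10, small_template.n_cells)
        assert sc.discrete_laplacian(field, small_template).sum() == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_raises(self, small_template):
        with pytest.raises(ModelError):
            sc.discrete_laplacian(np.zeros(3), small_template)


class TestDerivatives:
    def test_zero_state_production_only(self, small_template):
        state = StateField.zeros(small_template.n_cells)
        ml1p = sc.make_ml1p_wildtype(small_template)
        d = sc.derivatives(state, ml1p, BASELINE, small_template)
        l1 = small_template.layer_mask(L1)
        assert np.allclose(d.mir171[l1], BASELINE.k_mirp)
        assert np.allclose(d.mir171[~l1], 0.0)
        assert np.allclose(d.ham_mrna, BASELINE.k_hrp)
        assert np.allclose(d.gfp_mrna[l1], BASELINE.k_grp)
        assert np.allclose(d.ham_protein, 0.0)
        assert np.allclose(d.gfp_protein, 0.0)

    def test_closed_form_fixed_point_has_zero_derivative(self, small_template):
        """With [ML1p] = 0 the spatially uniform closed form is a fixed point."""
        n = small_template.n_cells
        ss = single_cell_steady_state(0.0, BASELINE)
        state = StateField(*(np.full(n, v) for v in ss))
        d = sc.derivatives(state, _uniform_field(small_template, 0.0), BASELINE, small_template)
        assert np.max(np.abs(d.stack())) < 1e-12

    def test_no_diffusion_decouples_cells(self, small_template):
        """With D = 0, perturbing cell j leaves every other derivative unchanged."""
        n = small_template.n_cells
        rng = np.random.default_rng(1)
        state = StateField(*(rng.uniform(0, 2, n) for _ in range(5)))
        ml1p = sc.make_ml1p_wildtype(small_template)
        d0 = sc.derivatives(state, ml1p, NO_DIFFUSION, small_template).stack()
        bumped = state.stack().copy()
        bumped[0, n // 2] += 5.0  # miR171 in one cell
        d1 = sc.derivatives(StateField.from_stack(bumped), ml1p, NO_DIFFUSION, small_template).stack()
        changed = np.nonzero(np.any(d0 != d1, axis=0))[0]
        assert changed.tolist() == [n // 2]

    def test_length_mismatch_raises(self, small_template):
        with pytest.raises(ModelError):
            sc.derivatives(
                StateField.zeros(3),
                sc.make_ml1p_wildtype(small_template),
                BASELINE,
                small_template,
            )


class TestSingleCellSteadyState:
    def test_no_input_limit(self):
        ss = single_cell_steady_state(0.0, BASELINE)
        assert ss.mir171 == 0.0
        assert ss.ham_mrna == pytest.approx(BASELINE.k_hrp / BASELINE.k_hrnh)
        assert ss.gfp_protein == 0.0

    def test_all_rates_half_arithmetic(self):
        p = sc.ModelParameters(**{k: 0.5 for k in sc.PARAM_NAMES})
        ss = single_cell_steady_state(1.0, p)
        assert ss.mir171 == pytest.approx(1.0)
        assert ss.ham_mrna == pytest.approx(0.5 / (0.5 * 1.0 + 0.5))  # = 0.5
        assert ss.ham_protein == pytest.approx(0.5)
        assert ss.gfp_mrna == pytest.approx(1.0)

    def test_ham_mrna_decreases_monotonically_in_input(self):
        values = [single_cell_steady_state(m, BASELINE).ham_mrna for m in (0, 0.5, 1, 5, 50)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 0.02  # -> 0 for large input

    def test_zero_degradation_rejected(self):
        with pytest.raises(ModelError):
            BASELINE.replace(k_mirn=0.0)


class TestIntegrateEuler:
    def test_one_step_from_zero_is_exact(self, small_template):
        config = SimulationConfig(dt=0.01, t_max=0.01, steady_tol=0.0)
        ml1p = sc.make_ml1p_wildtype(small_template)
        with pytest.warns(UserWarning):
            res = sc.integrate_euler(ml1p, BASELINE, small_template, config)
        l1 = small_template.layer_mask(L1)
        assert np.all(res.final_state.mir171[l1] == 0.01 * BASELINE.k_mirp)
        assert np.all(res.final_state.mir171[~l1] == 0.0)
        assert np.all(res.final_state.ham_mrna == 0.01 * BASELINE.k_hrp)

    def test_no_input_reaches_closed_form_steady_state(self, small_template):
        res = sc.integrate_euler(
            _uniform_field(small_template, 0.0), BASELINE, small_template, FAST_CONFIG
        )
        assert res.converged
        ss = single_cell_steady_state(0.0, BASELINE)
        assert np.allclose(res.final_state.mir171, 0.0, atol=1e-6)
        assert np.allclose(res.final_state.ham_mrna, ss.ham_mrna, atol=1e-5)
        assert np.allclose(res.final_state.ham_protein, ss.ham_protein, atol=1e-5)
        assert np.allclose(res.final_state.gfp_protein, 0.0, atol=1e-6)

    def test_steady_state_is_a_fixed_point_under_longer_t_max(self, small_template):
        ml1p = sc.make_ml1p_wildtype(small_template)
        a = sc.integrate_euler(ml1p, BASELINE, small_template, FAST_CONFIG)
        longer = SimulationConfig(
            dt=FAST_CONFIG.dt, t_max=2 * FAST_CONFIG.t_max, steady_tol=FAST_CONFIG.steady_tol
        )
        b = sc.integrate_euler(ml1p, BASELINE, small_template, longer)
        assert np.allclose(a.final_state.stack(), b.final_state.stack(), atol=1e-5)

    def test_matches_single_cell_oracle_without_diffusion(self, small_template):
        """Acceptance-grade oracle: D = 0 steady state equals the closed form."""
        config = SimulationConfig(steady_tol=1e-10, t_max=1000.0)
        ml1p = sc.make_ml1p_ectopic(small_template, 1.1, 0.4)
        res = sc.integrate_euler(ml1p, NO_DIFFUSION, small_template, config)
        assert res.converged
        for i in (0, small_template.n_cells // 2, small_template.n_cells - 1):
            ss = single_cell_steady_state(ml1p.values[i], NO_DIFFUSION)
            for k, species in enumerate(sc.SPECIES):
                assert getattr(res.final_state, species)[i] == pytest.approx(
                    ss[k], abs=1e-8
                )

    def test_matches_linear_algebra_oracle_with_diffusion(self, small_template, small_wt_result):
        """Independent cross-check: sparse linear solve of the miR171 fixed point."""
        lin = sc.steady_state_linear(sc.make_ml1p_wildtype(small_template), BASELINE, small_template)
        assert np.allclose(small_wt_result.final_state.mir171, lin.mir171, atol=1e-6)
        assert np.allclose(small_wt_result.final_state.ham_mrna, lin.ham_mrna, atol=1e-6)

    def test_nonnegative_throughout(self, small_template):
        config = SimulationConfig(steady_tol=1e-6, t_max=600.0, record_every=500)
        res = sc.integrate_euler(
            sc.make_ml1p_wildtype(small_template), BASELINE, small_template, config
        )
        assert all(np.min(state.stack()) >= 0.0 for _, state in res.trajectory)
        assert np.min(res.final_state.stack()) >= 0.0

    def test_monotone_repression(self, small_template):
        """Pointwise-larger [ML1p] never increases any cell's steady HAM mRNA."""
        rng = np.random.default_rng(4)
        n = small_template.n_cells
        for _ in range(3):
            base = rng.uniform(0.0, 1.5, n)
            extra = base + rng.uniform(0.0, 0.8, n)
            res_lo, res_hi = integrate_euler_many(
                [sc.MLpField(base, "lo"), sc.MLpField(extra, "hi")],
                BASELINE,
                small_template,
                FAST_CONFIG,
            )
            assert np.all(
                res_hi.final_state.ham_mrna <= res_lo.final_state.ham_mrna + 1e-9
            )

    def test_gfp_reporter_does_not_feed_back(self, small_template):
        ml1p = sc.make_ml1p_wildtype(small_template)
        full = sc.integrate_euler(ml1p, BASELINE, small_template, FAST_CONFIG)
        no_gfp = sc.integrate_euler(
            ml1p, BASELINE.replace(k_grp=0.0, k_gpp=0.0), small_template, FAST_CONFIG
        )
        for species in ("mir171", "ham_mrna", "ham_protein"):
            assert np.array_equal(
                getattr(full.final_state, species), getattr(no_gfp.final_state, species)
            )
        assert np.all(no_gfp.final_state.gfp_protein == 0.0)

    def test_steady_ham_mrna_linear_in_production_rate(self, small_template):
        ml1p = sc.make_ml1p_wildtype(small_template)
        config = SimulationConfig(steady_tol=1e-9, t_max=1000.0)
        a = sc.integrate_euler(ml1p, BASELINE, small_template, config)
        b = sc.integrate_euler(ml1p, BASELINE.scale("k_hrp", 3.0), small_template, config)
        assert np.allclose(
            b.final_state.ham_mrna, 3.0 * a.final_state.ham_mrna, rtol=1e-7
        )

    def test_step_size_robustness(self, small_template):
        ml1p = sc.make_ml1p_wildtype(small_template)
        coarse = sc.integrate_euler(
            ml1p, BASELINE, small_template, SimulationConfig(dt=0.01, steady_tol=1e-8)
        )
        fine = sc.integrate_euler(
            ml1p, BASELINE, small_template, SimulationConfig(dt=0.005, steady_tol=1e-8)
        )
        total_coarse = coarse.final_state.ham_mrna.sum()
        total_fine = fine.final_state.ham_mrna.sum()
        assert abs(total_coarse - total_fine) / total_fine < 1e-3

    def test_stability_guard_refuses_coarse_step(self, small_template):
        config = SimulationConfig(dt=2.5)
        with pytest.raises(StabilityError):
            sc.integrate_euler(
                sc.make_ml1p_wildtype(small_template), BASELINE, small_template, config
            )

    def test_divergence_detected_when_guard_overridden(self, small_template):
        config = SimulationConfig(dt=25.0, t_max=2000.0, allow_unstable=True)
        with pytest.raises(DivergenceError):
            sc.integrate_euler(
                sc.make_ml1p_wildtype(small_template), BASELINE, small_template, config
            )

    def test_volume_scaled_diffusion_mode(self, small_template):
        """The optional per-edge mode conserves material and reduces to the
        uniform operator when all cells share one volume."""
        from dataclasses import replace as dc_replace

        from samcascade.model import transport_operators

        # heterogeneous volumes: weighted Laplacian still sums to zero
        adj, deg = transport_operators(small_template, volume_scaled=True)
        field = np.random.default_rng(2).uniform(0, 5, small_template.n_cells)
        assert (field @ adj - field * deg).sum() == pytest.approx(0.0, abs=1e-9)

        # equal volumes: both modes integrate to the identical state
        n = small_template.n_cells
        uniform_tpl = dc_replace(
            small_template,
            radii=np.full(n, small_template.radii.mean()),
            volumes=np.full(n, small_template.volumes.mean()),
        )
        ml1p = sc.make_ml1p_wildtype(uniform_tpl)
        plain = sc.integrate_euler(ml1p, BASELINE, uniform_tpl, FAST_CONFIG)
        scaled_cfg = SimulationConfig(
            dt=FAST_CONFIG.dt, t_max=FAST_CONFIG.t_max,
            steady_tol=FAST_CONFIG.steady_tol, volume_scaled_diffusion=True,
        )
        scaled = sc.integrate_euler(ml1p, BASELINE, uniform_tpl, scaled_cfg)
        assert np.allclose(plain.final_state.stack(), scaled.final_state.stack(), atol=1e-12)

    def test_batch_matches_single_runs_bitwise(self, small_template):
        fields = [
            sc.make_ml1p_wildtype(small_template),
            sc.make_ml1p_ectopic(small_template, 1.1, 0.4),
            sc.make_ml1p_ectopic(small_template, 1.3, 0.5),
        ]
        batch = integrate_euler_many(fields, BASELINE, small_template, FAST_CONFIG)
        for field, from_batch in zip(fields, batch):
            single = sc.integrate_euler(field, BASELINE, small_template, FAST_CONFIG)
            assert np.array_equal(single.final_state.stack(), from_batch.final_state.stack())
            assert single.t_final == from_batch.t_final


class TestLayerMeans:
    def test_constant_field_gives_equal_means(self, small_template):
        n = small_template.n_cells
        state = StateField(*(np.full(n, 2.5) for _ in range(5)))
        means = sc.layer_means(state, small_template, "ham_mrna")
        assert means == {L1: 2.5, L2: 2.5, CORPUS: 2.5}

    def test_wildtype_gradient_low_apical_high_basal(self, small_wt_result, small_template):
        means = sc.layer_means(small_wt_result.final_state, small_template, "ham_mrna")
        assert means[L1] < means[L2] < means[CORPUS]

    def test_empty_layer_rejected(self, micro_template):
        state = StateField.zeros(micro_template.n_cells)
        with pytest.raises(ModelError):  # two-shell dome has no corpus
            sc.layer_means(state, micro_template, "ham_mrna")

    def test_unknown_species_rejected(self, small_template):
        state = StateField.zeros(small_template.n_cells)
        with pytest.raises(ModelError):
            sc.layer_means(state, small_template, "ham")


class TestParameterIO:
    def test_csv_roundtrip(self, tmp_path):
        from samcascade.model import read_params_csv, write_params_csv

        sets = [BASELINE, BASELINE.scale("k_mirp", 0.5)]
        write_params_csv(sets, tmp_path / "p.csv")
        back = read_params_csv(tmp_path / "p.csv")
        assert back == sets

    def test_negative_parameter_rejected(self):
        with pytest.raises(ModelError):
            BASELINE.replace(k_mirp=-0.1)

    def test_as_array_roundtrip(self):
        assert sc.ModelParameters.from_array(BASELINE.as_array()) == BASELINE
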