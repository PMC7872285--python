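"""Wilson-Cowan model: steady states, linearization, stability."""

import numpy as np
import pytest

from gnfields import (
    GenericGraphField,
    GraphWilsonCowan,
    LineGraphSpec,
    SteadyState,
    build_mode_system,
    eigendecompose,
    find_steady_state,
    make_line_graph,
    mode_jacobian,
    noise_matrix,
    sigmoid,
    stability_analysis,
    wc_drift,
    wc_filters,
    weighted_laplacian,
)


class TestSigmoid:
    def test_midpoint_and_saturation(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(40.0) == pytest.approx(1.0)
        assert sigmoid(-40.0) == pytest.approx(0.0, abs=1e-15)

    def test_symmetry(self):
        x = np.linspace(-700, 700, 101)
        assert np.allclose(sigmoid(x) + sigmoid(-x), 1.0)

    def test_stable_at_extreme_arguments(self):
        assert np.isfinite(sigmoid(-700.0)) and np.isfinite(sigmoid(700.0))


class TestParamsFile:
    def test_round_trip(self, tmp_path, coupled_params):
        p = tmp_path / "params.txt"
        coupled_params.to_file(p)
        loaded = type(coupled_params).from_file(p)
        assert loaded == coupled_params

    def test_validation(self, coupled_params):
        with pytest.raises(ValueError):
            coupled_params.replace(tau_e=0.0)
        with pytest.raises(ValueError):
            coupled_params.replace(alpha_ee=-1.0)


class TestSteadyState:
    def test_decoupled_midpoint(self, decoupled_params):
        st = find_steady_state(decoupled_params)
        assert st.e_star == pytest.approx(0.5, abs=1e-10)
        assert st.i_star == pytest.approx(0.5, abs=1e-10)
        assert st.a == pytest.approx(0.25, abs=1e-12)
        assert st.b == pytest.approx(0.25, abs=1e-12)

    def test_gain_identity(self, coupled_params):
        st = find_steady_state(coupled_params)
        de = coupled_params.d_e * st.e_star
        assert st.a == pytest.approx(de * (1 - de), abs=1e-12)

    def test_roots_have_zero_drift(self, coupled_params, line60):
        spec = eigendecompose(weighted_laplacian(line60))
        filters = wc_filters(coupled_params, spec)
        _, roots = find_steady_state(coupled_params, return_all=True)
        n = line60.n_vertices
        for st in roots:
            de, di = wc_drift(np.full(n, st.e_star), np.full(n, st.i_star),
                              coupled_params, filters)
            assert np.abs(de).max() < 1e-8
            assert np.abs(di).max() < 1e-8

    def test_independent_of_graph_topology(self, coupled_params):
        ring = make_line_graph(LineGraphSpec(n_vertices=10, spacing=1e-4, periodic=True))
        line = make_line_graph(LineGraphSpec(n_vertices=40, spacing=2e-4))
        # the homogeneous fixed point is a property of the parameters alone
        m1 = GraphWilsonCowan(ring, coupled_params).steady_state()
        m2 = GraphWilsonCowan(line, coupled_params).steady_state()
        assert m1.e_star == pytest.approx(m2.e_star, abs=1e-10)
        assert m1.i_star == pytest.approx(m2.i_star, abs=1e-10)


class TestDrift:
    def test_decoupled_closed_form(self, decoupled_params, ring24, ring24_spectrum):
        filters = wc_filters(decoupled_params, ring24_spectrum)
        rng = np.random.default_rng(0)
        e = rng.uniform(0.1, 0.9, ring24.n_vertices)
        i = rng.uniform(0.1, 0.9, ring24.n_vertices)
        de, di = wc_drift(e, i, decoupled_params, filters)
        assert np.allclose(de, (-e + 0.5) / decoupled_params.tau_e)
        assert np.allclose(di, (-i + 0.5) / decoupled_params.tau_i)

    def test_constant_state_gives_constant_drift(self, coupled_params, ring24_spectrum):
        filters = wc_filters(coupled_params, ring24_spectrum)
        n = ring24_spectrum.n_vertices
        de, di = wc_drift(np.full(n, 0.3), np.full(n, 0.6), coupled_params, filters)
        assert np.ptp(de) < 1e-10
        assert np.ptp(di) < 1e-10

    def test_shape_mismatch(self, coupled_params, ring24_spectrum):
        filters = wc_filters(coupled_params, ring24_spectrum)
        with pytest.raises(ValueError):
            wc_drift(np.zeros(24), np.zeros(23), coupled_params, filters)


class TestModeJacobian:
    def test_zero_couplings_diagonal(self, decoupled_params):
        st = find_steady_state(decoupled_params)
        j = mode_jacobian(decoupled_params, st, 0.0)
        pr = decoupled_params
        assert np.allclose(j, np.diag([-pr.d_e / pr.tau_e, -pr.d_i / pr.tau_i]))

    def test_large_negative_eigenvalue_limit(self, coupled_params):
        st = find_steady_state(coupled_params)
        j = mode_jacobian(coupled_params, st, -1e12)
        pr = coupled_params
        assert np.allclose(j, np.diag([-pr.d_e / pr.tau_e, -pr.d_i / pr.tau_i]))

    def test_matches_finite_difference_of_spectral_drift(self, coupled_params,
                                                         ring24, ring24_spectrum):
        """J_k from the closed form vs numeric differentiation of the drift
        projected onto eigenmode k about the homogeneous steady state."""
        st = find_steady_state(coupled_params)
        filters = wc_filters(coupled_params, ring24_spectrum)
        n = ring24.n_vertices
        u = ring24_spectrum.eigenvectors
        for k in (0, 3, 11):
            jk = mode_jacobian(coupled_params, st, ring24_spectrum.eigenvalues[k])
            eps = 1e-7
            num = np.zeros((2, 2))
            for col, (de_pert, di_pert) in enumerate([(eps, 0.0), (0.0, eps)]):
                e = np.full(n, st.e_star) + de_pert * u[:, k]
                i = np.full(n, st.i_star) + di_pert * u[:, k]
                de, di = wc_drift(e, i, coupled_params, filters)
                num[0, col] = (u[:, k] @ de) / eps
                num[1, col] = (u[:, k] @ di) / eps
            assert np.abs(jk - num).max() < 1e-4 * max(1.0, np.abs(jk).max())

    def test_linearization_is_first_order_accurate(self, coupled_params,
                                                   ring24, ring24_spectrum):
        st = find_steady_state(coupled_params)
        filters = wc_filters(coupled_params, ring24_spectrum)
        modes = build_mode_system(coupled_params, ring24_spectrum.eigenvalues, st)
        n = ring24.n_vertices
        rng = np.random.default_rng(5)
        direction = rng.standard_normal((2, n))
        direction /= np.linalg.norm(direction)
        errs = []
        for eps in (1e-3, 1e-4):
            e = np.full(n, st.e_star) + eps * direction[0]
            i = np.full(n, st.i_star) + eps * direction[1]
            de, di = wc_drift(e, i, coupled_params, filters)
            # linear prediction, assembled mode by mode
            dhat = np.stack([ring24_spectrum.gft(eps * direction[0]),
                             ring24_spectrum.gft(eps * direction[1])])
            lin = np.einsum("kij,jk->ik", modes.jacobians, dhat)
            lin_vertex = np.stack([ring24_spectrum.igft(lin[0]),
                                   ring24_spectrum.igft(lin[1])])
            errs.append(np.linalg.norm(np.stack([de, di]) - lin_vertex))
        order = np.log10(errs[0] / errs[1])
        assert order >= 1.9


class TestNoiseMatrix:
    def test_values_and_scaling(self, coupled_params):
        b = noise_matrix(coupled_params)
        pr = coupled_params
        assert b[0, 0] == pytest.approx(pr.sigma_noise**2 / pr.tau_e**2)
        assert b[1, 1] == pytest.approx(pr.sigma_noise**2 / pr.tau_i**2)
        b2 = noise_matrix(coupled_params.replace(sigma_noise=2 * pr.sigma_noise))
        assert np.allclose(b2, 4.0 * b)
        assert np.allclose(noise_matrix(coupled_params.replace(sigma_noise=0.0)), 0.0)


class TestStability:
    def test_decoupled_all_stable(self, decoupled_params):
        st = find_steady_state(decoupled_params)
        modes = build_mode_system(decoupled_params, -np.linspace(0, 100, 11), st)
        rep = stability_analysis(modes)
        assert rep.stable
        assert rep.max_real_parts.max() == pytest.approx(-min(
            decoupled_params.d_e / decoupled_params.tau_e,
            decoupled_params.d_i / decoupled_params.tau_i))

    def test_positive_trace_means_unstable(self):
        from gnfields import ModeSystem

        j = np.array([[[1.0, -2.0], [3.0, -0.5]]])
        modes = ModeSystem(jacobians=j, noise_power=np.eye(2),
                           eigenvalues=np.zeros(1))
        assert not stability_analysis(modes).stable

    def test_routh_hurwitz_equivalence(self):
        """Stable verdict iff trace < 0 and det > 0, per mode (2x2)."""
        from gnfields import ModeSystem

        rng = np.random.default_rng(21)
        jac = rng.normal(scale=5.0, size=(200, 2, 2))
        modes = ModeSystem(jacobians=jac, noise_power=np.eye(2),
                           eigenvalues=np.zeros(200))
        rep = stability_analysis(modes)
        tr = jac[:, 0, 0] + jac[:, 1, 1]
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        assert np.array_equal(rep.max_real_parts < 0, (tr < 0) & (det > 0))


class TestGenericField:
    def test_wilson_cowan_as_type2_instance(self, coupled_params, ring24,
                                            ring24_spectrum):
        model = GraphWilsonCowan(ring24_spectrum, coupled_params)
        field = model.as_generic_field()
        rng = np.random.default_rng(9)
        e = rng.uniform(0.2, 0.8, ring24.n_vertices)
        i = rng.uniform(0.2, 0.8, ring24.n_vertices)
        du = field.drift(np.stack([e, i]))
        de, di = model.drift(e, i)
        assert np.allclose(du[0], de, atol=1e-12)
        assert np.allclose(du[1], di, atol=1e-12)

    def test_type1_places_nonlinearity_inside_sum(self, ring24_spectrum):
        from gnfields import KernelSpec, build_filter

        filt = build_filter(ring24_spectrum, KernelSpec("gaussian", 2.0))
        n = ring24_spectrum.n_vertices
        f1 = GenericGraphField(kind=1, tau=[1.0], decay=[1.0],
                               weights=np.array([[2.0]]), filters=[[filt]],
                               drives=[0.3])
        rng = np.random.default_rng(2)
        u = rng.standard_normal((1, n))
        expected = (-u[0] + 2.0 * filt.apply(sigmoid(u[0])) + 0.3)
        assert np.allclose(f1.drift(u)[0], expected, atol=1e-12)

    def test_degenerate_gain_is_flagged(self):
        st = SteadyState(e_star=1.0, i_star=0.5, a=0.0, b=0.25, degenerate=True)
        assert st.degenerate and st.a == 0.0
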