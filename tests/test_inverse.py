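"""Gauss-Newton inversion: Jacobian, anatomical prior, iteration behaviour."""

import numpy as np
import pytest

from livereit.errors import ParameterError
from livereit.forward import (
    ConductivityField,
    Frame,
    StimulationPattern,
    make_skip_pattern,
    solve_forward,
)
from livereit.inverse import (
    GammaWeights,
    ReconstructionResult,
    Regularization,
    build_gamma,
    fit_homogeneous,
    gn_step,
    jacobian,
    liver_conductivity,
    reconstruct,
)
from livereit.mesh import PhantomSpec, TriMesh, build_phantom, circle_polygon

from conftest import make_crisscross_mesh


def fd_jacobian(mesh, sigvals, pat, model):
    J = np.zeros((sum(len(f.measurement_pairs) for f in pat.frames), mesh.n_elements))
    for e in range(mesh.n_elements):
        d = 1e-6 * sigvals[e]
        for s, w in ((+d, 0.5 / d), (-d, -0.5 / d)):
            v = sigvals.copy()
            v[e] += s
            ms = solve_forward(mesh, ConductivityField.from_values(mesh, v), pat, model)
            J[:, e] += w * ms.as_vector()
    return J


class TestJacobian:
    @pytest.mark.parametrize("model", ["point", "complete"])
    def test_adjoint_matches_central_differences(self, coarse_disk, model):
        rng = np.random.default_rng(0)
        sigvals = 0.5 * (1.0 + 0.3 * rng.random(coarse_disk.n_elements))
        sig = ConductivityField.from_values(coarse_disk, sigvals)
        pat = make_skip_pattern(8, 2, 2.0)
        J = jacobian(coarse_disk, sig, pat, model).entries
        Jfd = fd_jacobian(coarse_disk, sigvals, pat, model)
        assert np.linalg.norm(J - Jfd) / np.linalg.norm(Jfd) < 1e-4

    def test_row_sum_identity_at_homogeneous(self, coarse_disk):
        """V ∝ 1/σ under uniform scaling forces Σ_e J(k,e) = −V_k/σ₀."""
        s0 = 0.4
        sig = ConductivityField.homogeneous(coarse_disk, s0)
        pat = make_skip_pattern(8, 2, 2.0)
        J = jacobian(coarse_disk, sig, pat, "point").entries
        V = solve_forward(coarse_disk, sig, pat, "point").as_vector()
        scale = np.max(np.abs(V / s0))
        assert np.max(np.abs(J.sum(axis=1) + V / s0)) / scale < 1e-6

    def test_mirror_symmetry(self):
        """On a mirror-symmetric mesh, the Jacobian row of the mirrored
        drive/measure configuration equals the original after reflecting
        elements across the symmetry axis."""
        mesh = make_crisscross_mesh(4)
        sig = ConductivityField.homogeneous(mesh, 1.0)
        # electrodes: 0=A(+y), 1=B=mirror(A), 2=C(+y), 3=D=mirror(C)
        pat = StimulationPattern(
            (
                Frame((0, 2), 2.0, ((1, 3),)),
                Frame((1, 3), 2.0, ((0, 2),)),
            ),
            4,
        )
        J = jacobian(mesh, sig, pat, "point").entries
        # element reflection map via mirrored centroids
        cent = mesh.element_centroids()
        mirrored = cent * np.array([1.0, -1.0])
        idx = [
            int(np.argmin(np.hypot(*(cent - m).T))) for m in mirrored
        ]
        assert np.allclose(J[1, idx], J[0], rtol=1e-10, atol=1e-18)


class TestGamma:
    def test_annihilates_constants(self, abdomen_recovery):
        mesh = abdomen_recovery["mesh"]
        G = build_gamma(mesh, GammaWeights(1.0, 0.1))
        assert np.max(np.abs(G @ np.ones(mesh.n_elements))) < 1e-12

    def test_zero_cross_weight_annihilates_region_constants(self, abdomen_recovery):
        mesh = abdomen_recovery["mesh"]
        G = build_gamma(mesh, GammaWeights(1.0, 0.0))
        v = np.where(mesh.element_region == "liver", 0.3, 0.45)
        assert np.max(np.abs(G @ v)) < 1e-12

    def test_four_element_mesh_matches_explicit_laplacian(self):
        """Crisscross cell: 4 triangles around a centre node form an adjacency
        ring, whose unweighted Laplacian is circulant(2, -1, 0, -1)."""
        mesh = make_crisscross_mesh(1)
        G = build_gamma(mesh, GammaWeights(1.0, 1.0)).toarray()
        expected = np.array(
            [
                [2.0, -1.0, 0.0, -1.0],
                [-1.0, 2.0, -1.0, 0.0],
                [0.0, -1.0, 2.0, -1.0],
                [-1.0, 0.0, -1.0, 2.0],
            ]
        )
        assert np.allclose(G, expected)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ParameterError):
            GammaWeights(within=1.0, cross=2.0)
        with pytest.raises(ParameterError):
            GammaWeights(within=0.0)


class TestGNStep:
    def _setup(self):
        spec = PhantomSpec(outline=circle_polygon(1.0, 96), n_electrodes=16)
        mesh = build_phantom(spec, 0.15)
        sig = ConductivityField.homogeneous(mesh, 0.4)
        pat = make_skip_pattern(16, 4, 2.0)
        data = solve_forward(mesh, sig, pat, "complete")
        J = jacobian(mesh, sig, pat, "complete")
        return mesh, sig, data, J

    def test_zero_residual_is_fixed_point(self):
        mesh, sig, data, J = self._setup()
        new, phi, ok = gn_step(mesh, sig, data, J, Regularization())
        assert ok and np.array_equal(new.values, sig.values)

    def test_huge_lambda_suppresses_all_structure(self):
        """In the regularization-dominated limit the update retains only the
        prior's nullspace (spatial constants for a Laplacian Γ): the iterate
        stays spatially uniform and barely moves."""
        mesh, sig, data, J = self._setup()
        # perturb the data so the residual is non-zero
        noisy = data.with_vector(data.as_vector() * 1.05)
        lam = 1e12 * float(np.linalg.norm(J.entries.T @ J.entries, ord=2))
        new, phi, ok = gn_step(
            mesh, sig, noisy, J, Regularization(lam=lam), line_search=False
        )
        assert np.ptp(new.values) < 1e-9            # no non-constant component
        assert np.max(np.abs(new.values - sig.values)) < 0.1 * 0.4


class TestReconstruct:
    def test_homogeneous_disk_recovery(self):
        spec = PhantomSpec(outline=circle_polygon(1.0, 96), n_electrodes=16)
        mesh = build_phantom(spec, 0.12)
        truth = ConductivityField.homogeneous(mesh, 0.4)
        pat = make_skip_pattern(16, 4, 2.0)
        data = solve_forward(mesh, truth, pat, "complete")
        res = reconstruct(mesh, data, sigma0=0.2, tol=1e-3)
        assert res.converged
        assert np.mean(res.sigma.values) == pytest.approx(0.4, rel=0.02)

    def test_homogeneous_fit_fixes_absolute_scale(self):
        spec = PhantomSpec(outline=circle_polygon(1.0, 96), n_electrodes=16)
        mesh = build_phantom(spec, 0.15)
        truth = ConductivityField.homogeneous(mesh, 0.37)
        pat = make_skip_pattern(16, 4, 2.0)
        data = solve_forward(mesh, truth, pat, "complete")
        assert fit_homogeneous(mesh, data) == pytest.approx(0.37, rel=0.01)

    def test_inclusion_recovery(self, abdomen_recovery):
        """Liver mean within 10 % of truth and below the background mean on
        the noisy reference abdomen phantom."""
        assert abdomen_recovery["liver_mean"] == pytest.approx(0.30, rel=0.10)
        assert abdomen_recovery["liver_mean"] < abdomen_recovery["bg_mean"]

    def test_objective_trace_non_increasing(self, abdomen_recovery):
        trace = abdomen_recovery["result"].objective_trace
        assert all(b <= a * (1 + 1e-9) for a, b in zip(trace[1:], trace[2:]))
        assert trace[-1] <= trace[0]
        res = abdomen_recovery["result"]
        assert np.linalg.norm(res.residual) <= res.objective_trace[0] + 1e-15

    def test_positive_everywhere(self, abdomen_recovery):
        assert np.all(abdomen_recovery["result"].sigma.values > 0)

    def test_infinite_tol_returns_after_one_iteration(self, abdomen_recovery):
        mesh, data = abdomen_recovery["mesh"], abdomen_recovery["data"]
        res = reconstruct(mesh, data, sigma0=0.4, tol=np.inf, max_iter=25)
        assert res.iterations == 1 and res.converged

    def test_monotone_response_to_liver_conductivity(self, liver_sweep):
        values, means = liver_sweep
        assert np.all(np.diff(means) > 0)

    def test_lambda_robustness_two_decades(self, abdomen_recovery):
        """Liver-mean estimate varies < 15 % over a two-decade sweep of the
        regularization weight around the default."""
        mesh, data = abdomen_recovery["mesh"], abdomen_recovery["data"]
        means = [abdomen_recovery["liver_mean"]]
        for alpha in (0.1, 10.0):
            res = reconstruct(mesh, data, reg=Regularization(alpha=alpha))
            means.append(liver_conductivity(res, mesh)[0])
        assert (max(means) - min(means)) / min(means) < 0.15


class TestLiverConductivity:
    def _two_element_liver_mesh(self, v0, v1):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        elements = np.array([[0, 1, 2], [0, 2, 3]])  # equal areas
        mesh = TriMesh(
            nodes,
            elements,
            np.array([[0, 1], [1, 2], [2, 3], [3, 0]]),
            np.array(["liver", "liver"], dtype=object),
            [],
        )
        res = ReconstructionResult(
            sigma=ConductivityField.from_values(mesh, np.array([v0, v1])),
            objective_trace=[0.0],
            iterations=0,
            converged=True,
            lam_used=0.0,
            sigma0=0.35,
            residual=np.zeros(1),
        )
        return mesh, res

    def test_constant_field(self):
        mesh, res = self._two_element_liver_mesh(0.35, 0.35)
        assert liver_conductivity(res, mesh) == (0.35, 0.0)

    def test_equal_area_mean(self):
        mesh, res = self._two_element_liver_mesh(0.3, 0.4)
        mean, sd = liver_conductivity(res, mesh)
        assert mean == pytest.approx(0.35)
        assert sd == pytest.approx(0.05)

    def test_no_liver_raises(self, coarse_disk):
        res = ReconstructionResult(
            sigma=ConductivityField.homogeneous(coarse_disk, 0.4),
            objective_trace=[0.0], iterations=0, converged=True,
            lam_used=0.0, sigma0=0.4, residual=np.zeros(1),
        )
        with pytest.raises(KeyError):
            liver_conductivity(res, coarse_disk)
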