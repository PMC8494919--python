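"""FEM forward model: stimulation patterns, assembly, solves, noise, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from livereit.errors import InputError, ParameterError, PatternError
from livereit.forward import (
    ConductivityField,
    Frame,
    MeasurementSet,
    NoiseModel,
    StimulationPattern,
    add_noise,
    assemble_system,
    load_measurements,
    make_skip_pattern,
    save_measurements,
    solve_forward,
)
from livereit.mesh import PhantomSpec, TriMesh, build_phantom, circle_polygon


def brute_force_pairs(n, skip, drive):
    """Independent enumeration of offset-(skip+1) pairs avoiding the drive."""
    out = []
    for m in range(n):
        p = (m, (m + skip + 1) % n)
        if drive[0] not in p and drive[1] not in p:
            out.append(p)
    return out


class TestSkipPattern:
    def test_study_pattern_32_skip4(self):
        pat = make_skip_pattern(32, 4, 2.0)
        assert len(pat.frames) == 32
        for e, f in enumerate(pat.frames):
            assert f.drive == (e, (e + 5) % 32)  # separated by 5 positions
            assert list(f.measurement_pairs) == brute_force_pairs(32, 4, f.drive)

    def test_adjacent_pattern_8_skip0(self):
        pat = make_skip_pattern(8, 0, 2.0)
        f0 = pat.frames[0]
        assert f0.drive == (0, 1)
        assert f0.measurement_pairs == ((2, 3), (3, 4), (4, 5), (5, 6), (6, 7))

    def test_degenerate_skip_raises(self):
        with pytest.raises(PatternError):
            make_skip_pattern(4, 3, 2.0)

    def test_current_outside_study_range_warns(self):
        with pytest.warns(UserWarning):
            make_skip_pattern(16, 4, 8.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        n=st.integers(8, 40).filter(lambda v: v % 2 == 0),
        skip=st.integers(0, 6),
    )
    def test_pattern_properties(self, n, skip):
        pat = make_skip_pattern(n, skip, 2.0)
        for f in pat.frames:
            assert f.drive[0] != f.drive[1]
            for p in f.measurement_pairs:
                assert f.drive[0] not in p and f.drive[1] not in p
            # injected current sums to zero per frame by construction
            cur = np.zeros(n)
            cur[f.drive[0]] += f.current_ma
            cur[f.drive[1]] -= f.current_ma
            assert cur.sum() == 0.0


def two_element_square_mesh():
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    elements = np.array([[0, 1, 2], [0, 2, 3]])
    bnd = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
    labels = np.array(["background", "background"], dtype=object)
    electrodes = [np.array([0]), np.array([2])]
    return TriMesh(nodes, elements, bnd, labels, electrodes)


class TestAssembly:
    def test_stiffness_row_sums_vanish_before_grounding(self, coarse_disk):
        sig = ConductivityField.homogeneous(coarse_disk, 0.7)
        sys_ = assemble_system(coarse_disk, sig, "point")
        r = np.abs(sys_.K @ np.ones(coarse_disk.n_nodes))
        assert np.max(r) < 1e-12 * np.abs(sys_.K.data).max()

    def test_stiffness_linear_in_sigma(self, coarse_disk):
        s1 = assemble_system(coarse_disk, ConductivityField.homogeneous(coarse_disk, 0.5), "point")
        s2 = assemble_system(coarse_disk, ConductivityField.homogeneous(coarse_disk, 1.0), "point")
        assert np.allclose(2.0 * s1.K.toarray(), s2.K.toarray())

    def test_two_element_square_matches_hand_assembly(self):
        mesh = two_element_square_mesh()
        sig = ConductivityField.homogeneous(mesh, 1.0)
        K = assemble_system(mesh, sig, "point").K.toarray()
        # P1 stiffness of the unit square split along the (0,0)-(1,1) diagonal
        expected = np.array(
            [
                [1.0, -0.5, 0.0, -0.5],
                [-0.5, 1.0, -0.5, 0.0],
                [0.0, -0.5, 1.0, -0.5],
                [-0.5, 0.0, -0.5, 1.0],
            ]
        )
        assert np.allclose(K, expected)

    def test_nonpositive_sigma_rejected(self, coarse_disk):
        with pytest.raises(ParameterError):
            ConductivityField.homogeneous(coarse_disk, -1.0)


class TestSolveForward:
    def test_disk_matches_analytic_dipole(self, fine_disk):
        """Point-electrode potentials on a homogeneous disk follow the
        closed-form logarithmic solution u = (I/πσ)·(ln|x−x_sink| − ln|x−x_src|)."""
        sigma0 = 0.5
        sig = ConductivityField.homogeneous(fine_disk, sigma0)
        pat = make_skip_pattern(16, 4, 2.0)
        data = solve_forward(fine_disk, sig, pat, "point")
        sys_ = assemble_system(fine_disk, sig, "point")
        rep = sys_.rep
        worst = 0.0
        for f, volts in zip(pat.frames[:4], data.voltages[:4]):
            I = f.current_ma * 1e-3
            src, snk = fine_disk.nodes[rep[f.drive[0]]], fine_disk.nodes[rep[f.drive[1]]]

            def u(x):
                return (I / (np.pi * sigma0)) * (
                    np.log(np.linalg.norm(x - snk)) - np.log(np.linalg.norm(x - src))
                )

            for (a, b), v in zip(f.measurement_pairs, volts):
                exact = u(fine_disk.nodes[rep[a]]) - u(fine_disk.nodes[rep[b]])
                worst = max(worst, abs(v - exact) / abs(exact))
        assert worst < 0.01

    @pytest.mark.parametrize("model", ["point", "complete"])
    def test_reciprocity(self, fine_disk, model):
        sig = ConductivityField.homogeneous(fine_disk, 0.5)
        sys_ = assemble_system(fine_disk, sig, model)

        def vpair(drive, meas):
            cur = np.zeros(16)
            cur[drive[0]], cur[drive[1]] = 2e-3, -2e-3
            U = sys_.electrode_potentials(sys_.solve(sys_.electrode_rhs(cur)))
            return U[meas[0]] - U[meas[1]]

        a, b = vpair((0, 5), (8, 13)), vpair((8, 13), (0, 5))
        assert abs(a - b) / abs(a) < 1e-10

    def test_sigma_scaling_inverse(self, coarse_disk):
        pat = make_skip_pattern(8, 2, 2.0)
        v1 = solve_forward(
            coarse_disk, ConductivityField.homogeneous(coarse_disk, 0.5), pat, "point"
        ).as_vector()
        v2 = solve_forward(
            coarse_disk, ConductivityField.homogeneous(coarse_disk, 1.5), pat, "point"
        ).as_vector()
        assert np.linalg.norm(v1 - 3.0 * v2) / np.linalg.norm(v1) < 1e-12

    def test_discretization_cauchy_convergence(self):
        spec = PhantomSpec(outline=circle_polygon(1.0, 256), n_electrodes=16)
        pat = make_skip_pattern(16, 4, 2.0)
        prev, changes = None, []
        for h in (0.24, 0.12, 0.06):
            mesh = build_phantom(spec, h)
            v = solve_forward(
                mesh, ConductivityField.homogeneous(mesh, 0.5), pat, "complete"
            ).as_vector()
            if prev is not None:
                changes.append(np.linalg.norm(v - prev) / np.linalg.norm(prev))
            prev = v
        assert changes[-1] < 0.01  # two finest levels agree to < 1 %

    def test_complete_model_approaches_point_limit(self):
        """Narrow pads + small contact impedance reproduce point electrodes."""
        spec = PhantomSpec(
            outline=circle_polygon(1.0, 256), n_electrodes=16, electrode_width=0.004
        )
        mesh = build_phantom(spec, 0.08)
        sig = ConductivityField.homogeneous(mesh, 0.5)
        pat = make_skip_pattern(16, 4, 2.0)
        vp = solve_forward(mesh, sig, pat, "point").as_vector()
        vc = solve_forward(mesh, sig, pat, "complete", 1e-2).as_vector()
        assert np.linalg.norm(vc - vp) / np.linalg.norm(vp) < 0.01


def _fake_measurements(n_electrodes=36, seed=0):
    pat = make_skip_pattern(n_electrodes, 4, 2.0)
    rng = np.random.default_rng(seed)
    volts = [rng.normal(0.0, 1e-3, len(f.measurement_pairs)) for f in pat.frames]
    return MeasurementSet(pat, volts)


class TestNoise:
    def test_zero_sd_is_identity(self):
        data = _fake_measurements()
        out = add_noise(data, NoiseModel("additive", 0.0), seed=1)
        assert np.array_equal(out.as_vector(), data.as_vector())

    def test_same_seed_bit_identical(self):
        data = _fake_measurements()
        a = add_noise(data, NoiseModel("additive", 1e-4), seed=9)
        b = add_noise(data, NoiseModel("additive", 1e-4), seed=9)
        assert np.array_equal(a.as_vector(), b.as_vector())

    def test_sample_sd_matches_model(self):
        data = _fake_measurements(36)  # 36 frames x 33 pairs = 1188 >= 1000
        s = 2.5e-4
        out = add_noise(data, NoiseModel("additive", s), seed=3)
        diff = out.as_vector() - data.as_vector()
        assert len(diff) >= 1000
        assert np.std(diff) == pytest.approx(s, rel=0.10)

    def test_negative_sd_rejected(self):
        with pytest.raises(ParameterError):
            NoiseModel("additive", -1.0)


class TestMeasurementIO:
    def test_csv_roundtrip_exact(self, tmp_path):
        data = add_noise(_fake_measurements(16), NoiseModel("additive", 1e-4), seed=5)
        save_measurements(data, tmp_path / "m.csv", tmp_path / "m.json")
        back = load_measurements(tmp_path / "m.csv", tmp_path / "m.json")
        assert np.array_equal(back.as_vector(), data.as_vector())
        assert back.pattern == data.pattern
        assert back.seed == data.seed and back.noise_model == data.noise_model

    def test_truncated_csv_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("frame,drive_pos\n0,1\n")
        with pytest.raises(InputError):
            load_measurements(tmp_path / "bad.csv")

    def test_voltage_shape_mismatch_rejected(self):
        pat = make_skip_pattern(8, 0, 2.0)
        with pytest.raises(InputError):
            MeasurementSet(pat, [np.zeros(3)] * len(pat.frames))
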