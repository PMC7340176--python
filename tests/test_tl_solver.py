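import numpy as np
import pytest

from padpulse.arterial_tree import ArterialTree, SegmentGeometry
from padpulse import tl_solver as tl
from conftest import make_toy_tree


def dc_resistance_oracle(tree: ArterialTree) -> float:
    """Independent brute-force resistor network: nodal analysis.

    Each segment is a series Poiseuille resistor between its inlet node and
    outlet node; terminal loads connect leaf outlets to ground.  Inject a
    unit flow at the root inlet and solve the node equations directly.
    """
    # node 0 = ground; node ids: inlet of root, outlet of every segment
    nodes = {("in", tree.root): 1}
    for sid in tree.segments:
        nodes[("out", sid)] = len(nodes) + 1
    n = len(nodes)
    G = np.zeros((n + 1, n + 1))  # conductance matrix incl. ground

    def add(a, b, resistance):
        g = 1.0 / resistance
        G[a, a] += g
        G[b, b] += g
        G[a, b] -= g
        G[b, a] -= g

    for sid, geom in tree.segments.items():
        r_seg = 8.0 * tree.viscosity * geom.length / (np.pi * geom.radius**4)
        parent = tree.parent[sid]
        a = nodes[("in", tree.root)] if parent is None else nodes[("out", parent)]
        add(a, nodes[("out", sid)], r_seg)
    for sid, r_t in tree.terminal_load.items():
        add(nodes[("out", sid)], 0, r_t)

    rhs = np.zeros(n + 1)
    rhs[nodes[("in", tree.root)]] = 1.0  # unit flow source
    # ground node fixed at zero potential
    keep = [i for i in range(n + 1) if i != 0]
    v = np.linalg.solve(G[np.ix_(keep, keep)], rhs[keep])
    return v[keep.index(nodes[("in", tree.root)])]


def single_segment_tree(length=10.0, radius=0.4, thickness=0.05, E=8e6, r_t=1e5):
    return ArterialTree(
        segments={1: SegmentGeometry(length, radius, thickness, E)},
        parent={1: None},
        names={1: "line"},
        terminal_load={1: r_t},
        site_map={"end": (1, "outlet")},
    )


class TestWaveConstants:
    def test_inviscid_speed_matches_moens_korteweg(self):
        geom = SegmentGeometry(10.0, 0.5, 0.05, 4e6)
        rho = 1.05
        w = tl.segment_wave_constants(geom, rho, 0.0, 1.25, 10, wall_loss_tangent=0.0)
        c_mk = tl.moens_korteweg_velocity(geom, rho)
        for k in range(1, 11):
            gamma = w.gamma[k]
            assert abs(gamma.real) < 1e-12 * abs(gamma)  # lossless: pure phase
            c_phase = 2 * np.pi * 1.25 * k / gamma.imag
            assert c_phase == pytest.approx(c_mk, rel=0.01)

    def test_doubling_elasticity_scales_speed_by_sqrt2(self):
        g1 = SegmentGeometry(10.0, 0.5, 0.05, 4e6)
        g2 = SegmentGeometry(10.0, 0.5, 0.05, 8e6)
        assert tl.moens_korteweg_velocity(g2, 1.05) == pytest.approx(
            np.sqrt(2) * tl.moens_korteweg_velocity(g1, 1.05)
        )

    def test_attenuation_branch(self):
        geom = SegmentGeometry(10.0, 0.3, 0.04, 8e6)
        w = tl.segment_wave_constants(geom, 1.05, 0.04, 1.25, 30)
        assert np.all(w.gamma[1:].real >= 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            tl.segment_wave_constants(
                SegmentGeometry(10.0, -0.3, 0.04, 8e6), 1.05, 0.04, 1.25, 5
            )


class TestInputImpedance:
    def test_matched_line_has_zero_reflection(self):
        tree = single_segment_tree()
        # first pass to learn Z_C at k=1, then terminate with that value
        imap = tl.input_impedance(tree, n_harmonics=1)
        zc1 = imap.wave[1].zc[1]
        # a matched line needs a complex load; check the algebra directly
        gamma_l = imap.wave[1].gamma[1] * tree.segments[1].length
        refl = (zc1 - zc1) / (zc1 + zc1)
        z_in = zc1 * (np.exp(gamma_l) + refl * np.exp(-gamma_l)) / (
            np.exp(gamma_l) - refl * np.exp(-gamma_l)
        )
        assert z_in == pytest.approx(zc1)

    def test_zero_length_line_is_transparent(self):
        tree = single_segment_tree(length=1e-12)
        imap = tl.input_impedance(tree, n_harmonics=5)
        for k in range(1, 6):
            assert imap.z_in[1][k] == pytest.approx(imap.z_load[1][k], rel=1e-6)
        assert imap.z_in[1][0] == pytest.approx(tree.terminal_load[1], rel=1e-9)

    def test_dc_impedance_matches_resistor_network_oracle(self, toy_tree):
        imap = tl.input_impedance(toy_tree, n_harmonics=2)
        oracle = dc_resistance_oracle(toy_tree)
        assert abs(imap.z_in[toy_tree.root][0].real - oracle) / oracle < 1e-6

    def test_dc_oracle_on_default_tree(self, default_tree):
        imap = tl.input_impedance(default_tree, n_harmonics=2)
        oracle = dc_resistance_oracle(default_tree)
        assert abs(imap.z_in[default_tree.root][0].real - oracle) / oracle < 1e-6

    def test_passivity_of_reflections(self, toy_tree):
        imap = tl.input_impedance(toy_tree, n_harmonics=30)
        for sid in toy_tree.segments:
            assert np.all(np.abs(imap.refl[sid][1:]) <= 1.0 + 1e-12)

    def test_reflection_definition_holds_exactly(self, toy_tree):
        imap = tl.input_impedance(toy_tree, n_harmonics=10)
        for sid in toy_tree.segments:
            zc = imap.wave[sid].zc[1:]
            zl = imap.z_load[sid][1:]
            expected = (zl - zc) / (zl + zc)
            np.testing.assert_allclose(imap.refl[sid][1:], expected, rtol=1e-12)


class TestPropagate:
    @staticmethod
    def _run(tree, k=30):
        q = tl.inflow_waveform()
        inflow = tl.analyze(q, tl.DEFAULT_F0, k)
        imap = tl.input_impedance(tree, n_harmonics=k)
        return inflow, imap, tl.propagate(tree, inflow, imap)

    def test_flow_conserved_at_every_junction(self, toy_tree):
        _, _, spectra = self._run(toy_tree)
        for sid in toy_tree.segments:
            kids = toy_tree.children(sid)
            if not kids:
                continue
            q_out = spectra[sid]["q_out"].coeffs
            q_kids = sum(spectra[c]["q_in"].coeffs for c in kids)
            np.testing.assert_allclose(q_out, q_kids, rtol=1e-10, atol=1e-12)

    def test_flow_conserved_on_default_tree(self, default_tree):
        _, _, spectra = self._run(default_tree)
        for sid in default_tree.segments:
            kids = default_tree.children(sid)
            if not kids:
                continue
            q_out = spectra[sid]["q_out"].coeffs
            q_kids = sum(spectra[c]["q_in"].coeffs for c in kids)
            scale = np.abs(q_out) + np.abs(q_kids) + 1e-12
            assert np.max(np.abs(q_out - q_kids) / scale) < 1e-10

    def test_zero_length_segment_transfers_identically(self):
        tree = single_segment_tree(length=1e-14)
        _, _, spectra = self._run(tree, k=10)
        np.testing.assert_allclose(
            spectra[1]["p_out"].coeffs, spectra[1]["p_in"].coeffs, rtol=1e-8
        )
        np.testing.assert_allclose(
            spectra[1]["q_out"].coeffs, spectra[1]["q_in"].coeffs, rtol=1e-8
        )

    def test_root_inlet_pressure_is_flow_times_impedance(self, toy_tree):
        inflow, imap, spectra = self._run(toy_tree)
        np.testing.assert_allclose(
            spectra[toy_tree.root]["p_in"].coeffs,
            inflow.coeffs * imap.z_in[toy_tree.root],
            rtol=1e-12,
        )

    def test_lossless_matched_line_preserves_amplitude(self):
        # inviscid, elastic wall, load = Z_C at every harmonic: |p_out| = |p_in|
        tree = single_segment_tree()
        tree.viscosity = 0.0
        k = 5
        imap = tl.input_impedance(tree, n_harmonics=k, wall_loss_tangent=0.0)
        zc = imap.wave[1].zc
        gamma = imap.wave[1].gamma
        l = tree.segments[1].length
        for kk in range(1, k + 1):
            refl = 0.0  # matched by construction
            transfer = (1 + refl) / np.exp(gamma[kk] * l)
            assert abs(abs(transfer) - 1.0) < 1e-10

    def test_linearity_in_inflow(self, toy_tree):
        q = tl.inflow_waveform()
        k = 10
        imap = tl.input_impedance(toy_tree, n_harmonics=k)
        s1 = tl.propagate(toy_tree, tl.analyze(q, tl.DEFAULT_F0, k), imap)
        s2 = tl.propagate(toy_tree, tl.analyze(3.0 * q, tl.DEFAULT_F0, k), imap)
        a, b = s2[7]["p_out"].coeffs, 3.0 * s1[7]["p_out"].coeffs
        # exact up to FFT rounding; tolerance relative to the spectrum scale
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9 * np.abs(b).max())

    def test_mismatched_harmonics_rejected(self, toy_tree):
        q = tl.inflow_waveform()
        imap = tl.input_impedance(toy_tree, n_harmonics=10)
        with pytest.raises(ValueError):
            tl.propagate(toy_tree, tl.analyze(q, tl.DEFAULT_F0, 20), imap)


class TestInflowAndSynthesis:
    def test_stroke_volume_normalisation(self):
        period = 0.8
        q = tl.inflow_waveform(period=period, stroke_volume=70.0, n_samples=4096)
        integral = q.sum() * period / q.size
        assert integral == pytest.approx(70.0, rel=1e-4)

    def test_diastolic_flow_is_zero(self):
        q = tl.inflow_waveform(ejection_fraction=0.3, n_samples=256)
        assert np.all(q[int(0.3 * 256) + 1 :] == 0.0)

    def test_fourier_round_trip_error_below_1pc_of_peak(self):
        q = tl.inflow_waveform(n_samples=256)
        spec = tl.analyze(q, tl.DEFAULT_F0, 30)
        back = tl.synthesize(spec, 256)
        assert np.max(np.abs(back - q)) < 0.01 * q.max()

    def test_single_harmonic_synthesis(self):
        spec = tl.HarmonicSpectrum(1.0, [0.0, 1.0])
        x = tl.synthesize(spec, 16)
        np.testing.assert_allclose(x, 2.0 * np.cos(2 * np.pi * np.arange(16) / 16), atol=1e-12)

    def test_dc_only_synthesis_is_constant(self):
        x = tl.synthesize(tl.HarmonicSpectrum(1.0, [5.0, 0.0]), 32)
        np.testing.assert_allclose(x, 5.0)

    def test_analyze_synthesize_round_trip(self):
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=31) + 1j * rng.normal(size=31)
        coeffs[0] = coeffs[0].real
        spec = tl.HarmonicSpectrum(1.25, coeffs)
        x = tl.synthesize(spec, 256)
        back = tl.analyze(x, 1.25, 30)
        np.testing.assert_allclose(back.coeffs, spec.coeffs, atol=1e-10)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError):
            tl.synthesize(tl.HarmonicSpectrum(1.0, np.ones(31)), 32)

    def test_invalid_inflow_params_rejected(self):
        with pytest.raises(ValueError):
            tl.inflow_waveform(ejection_fraction=1.5)
        with pytest.raises(ValueError):
            tl.inflow_waveform(stroke_volume=-1.0)


class TestSimulatePatient:
    def test_healthy_ankle_systolic_exceeds_brachial(self, default_tree):
        rec = tl.simulate_patient(default_tree)
        assert rec.ankle_bp.max() >= rec.brachial_bp.max()

    def test_record_shapes_and_units(self, default_tree):
        rec = tl.simulate_patient(default_tree)
        assert rec.brachial_bp.shape == (tl.DEFAULT_N,)
        assert 60 < rec.brachial_bp.min() < rec.brachial_bp.max() < 200  # mmHg range
        assert rec.stacked().shape == (2, 2, tl.DEFAULT_N)
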