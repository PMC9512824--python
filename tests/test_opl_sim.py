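import numpy as np
import pytest
from dataclasses import replace

from csretina import opl_sim, stimuli
from csretina.opl_sim import CircuitParams


@pytest.fixture(scope="module")
def params():
    return CircuitParams()


class TestSpatialKernel:
    def test_peak_is_one(self, params):
        k = opl_sim.spatial_kernel(300.0, 10.0, 150)
        assert np.all(np.diag(k) == 1.0)

    def test_normalized_fwhm_half_max_at_half_fwhm(self):
        k = opl_sim.spatial_kernel(300.0, 10.0, 150, "normalized_fwhm")
        # offset of 150 µm = 15 cells
        assert k[0, 15] == pytest.approx(0.5)

    def test_literal_matches_printed_arithmetic(self):
        k = opl_sim.spatial_kernel(300.0, 10.0, 150, "literal")
        assert k[0, 1] == pytest.approx(np.exp(-100.0 / (300.0 / 11.09) ** 2))

    def test_literal_kernel_is_much_narrower(self):
        kn = opl_sim.spatial_kernel(300.0, 10.0, 150, "normalized_fwhm")
        kl = opl_sim.spatial_kernel(300.0, 10.0, 150, "literal")
        assert kl[0, 15] < 1e-6 < kn[0, 15]


class TestPhotoreceptorDrive:
    def test_rest_gives_zero(self, params):
        n = params.n_cells
        d = opl_sim.photoreceptor_drive(np.zeros(n), np.zeros(n), params)
        np.testing.assert_array_equal(d, 0.0)

    def test_light_only_arithmetic(self, params):
        n = params.n_cells
        vs = np.ones(n)
        d = opl_sim.photoreceptor_drive(vs, np.zeros(n), params)
        # g * E_VS * VS / (VS + 1) = 0.5 * (-10) / 2
        np.testing.assert_allclose(d, -2.5)

    def test_light_always_hyperpolarizes_without_feedback(self, params, rng):
        vs = rng.uniform(0.1, 1.0, params.n_cells)
        d = opl_sim.photoreceptor_drive(vs, np.zeros(params.n_cells), params)
        assert np.all(d < 0)


class TestPhotoreceptorKinetics:
    def test_sustained_drive_settles_at_one_fifth(self, params):
        a = b = np.zeros(1)
        drive = np.full(1, -2.0)
        for _ in range(12000):
            a, b, ph = opl_sim.photoreceptor_step(a, b, drive, params)
        assert ph[0] == pytest.approx(0.2 * -2.0, abs=1e-6)

    def test_zero_drive_stays_zero(self, params):
        a, b, ph = opl_sim.photoreceptor_step(
            np.zeros(3), np.zeros(3), np.zeros(3), params
        )
        assert np.all(ph == 0)

    def test_step_response_is_biphasic_and_matches_oracle(self, params):
        # independent scalar integration of the two first-order stages
        a = b = 0.0
        trace = []
        for _ in range(2000):
            a += (-1.0 - a) / 60.0
            b += (-1.0 - b) / 400.0
            trace.append(a - 0.8 * b)
        trace = np.array(trace)
        trough = trace.min()
        t_trough = trace.argmin()
        av = bv = np.zeros(1)
        got = []
        for _ in range(2000):
            av, bv, ph = opl_sim.photoreceptor_step(av, bv, np.full(1, -1.0), params)
            got.append(ph[0])
        got = np.array(got)
        assert got.argmin() == t_trough
        assert got.min() == pytest.approx(trough, abs=1e-12)
        # relaxes from the trough toward the sustained level -0.2
        assert trough < -0.2 and got[-1] == pytest.approx(-0.2, abs=6e-3)


class TestHorizontalCell:
    def test_uniform_photoreceptor_gives_uniform_target(self, params):
        ph = np.full(params.n_cells, -1.3)
        _, hc_inf = opl_sim.hc_step(ph, np.zeros(params.n_cells), params)
        np.testing.assert_allclose(hc_inf, -1.3, rtol=1e-12)

    def test_saturating_fixed_point(self, params):
        # held hc_inf = -2 drives hc to E_Ph*(-2)/(-2+E_Ph) = -2.5
        hc = np.zeros(1)
        ph = np.full(1, -2.0)  # single cell: hc_inf = ph
        single = replace(params, n_cells=1)
        for _ in range(6000):
            hc, _ = opl_sim.hc_step(ph, hc, single, np.ones((1, 1)))
        assert hc[0] == pytest.approx(10 * (-2) / (-2 + 10), abs=1e-6)

    def test_zero_input_stays_zero(self, params):
        hc, hc_inf = opl_sim.hc_step(
            np.zeros(params.n_cells), np.zeros(params.n_cells), params
        )
        assert np.all(hc == 0) and np.all(hc_inf == 0)


class TestBipolarSynapse:
    def test_baseline_subtraction_gives_zero_at_rest(self, params):
        out = opl_sim.bc_synaptic_input(np.zeros(params.n_cells), params, "transient")
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_single_cell_transient_arithmetic(self, params):
        single = replace(params, n_cells=1)
        out = opl_sim.bc_synaptic_input(
            np.full(1, -5.0), single, "transient", np.ones((1, 1))
        )
        expected = -(1 / (1 + np.exp(1.1 * 9)) - 1 / (1 + np.exp(4.4)))
        assert out[0] == pytest.approx(expected, rel=1e-9)
        assert out[0] == pytest.approx(0.0122, abs=2e-4)

    def test_hyperpolarization_yields_monotone_positive_drive(self, params):
        single = replace(params, n_cells=1)
        levels = np.array([-0.5, -1.0, -2.0, -4.0])
        outs = [
            opl_sim.bc_synaptic_input(np.array([v]), single, "transient", np.ones((1, 1)))[0]
            for v in levels
        ]
        assert np.all(np.array(outs) > 0)
        assert np.all(np.diff(outs) > 0)

    def test_bc_vm_arithmetic(self, params):
        assert opl_sim.bc_vm(1.0, 0.0, params) == pytest.approx(100 / 11)
        assert opl_sim.bc_vm(0.0, 0.0, params) == 0.0

    def test_ac_shunts_bc_vm(self, params):
        vms = [opl_sim.bc_vm(1.0, ac, params) for ac in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(np.abs(vms)) < 0)


class TestAmacrine:
    def test_gain_zero_matches_disabled(self, circuit_battery):
        movie = circuit_battery["full"]
        off = opl_sim.run_simulation(
            movie, CircuitParams(ac_enabled=False), record=("bc_vm_transient",)
        )
        zero = opl_sim.run_simulation(
            movie,
            CircuitParams(ac_enabled=True, ac_syn_gain=0.0),
            record=("bc_vm_transient",),
        )
        np.testing.assert_array_equal(
            off["bc_vm_transient"].values, zero["bc_vm_transient"].values
        )

    def test_wide_spot_recruits_more_ac_drive_than_narrow(self):
        extent, dx = 1500.0, 10.0
        p = CircuitParams(ac_enabled=True)
        drives = {}
        for width in (100.0, 500.0):
            spot = stimuli.make_static_flash(
                stimuli.BarSpec(bar_length=width, contrast=1.0, flash_duration=1000.0),
                extent=extent,
                dx=dx,
            )
            tr = opl_sim.run_simulation(spot, p, record=("ac",))
            drives[width] = np.abs(tr["ac"].values[75]).max()
        assert drives[500.0] > drives[100.0]


class TestRunSimulation:
    def test_quiescence(self, params):
        movie = stimuli.StimulusMovie(np.zeros((150, 300)), dx=10.0, dt=1.0)
        traces = opl_sim.run_simulation(movie, params)
        for ts in traces.values():
            assert np.all(ts.values == 0.0)

    def test_geometry_mismatch_rejected(self, params):
        movie = stimuli.StimulusMovie(np.zeros((100, 50)), dx=10.0, dt=1.0)
        with pytest.raises(ValueError):
            opl_sim.run_simulation(movie, params)

    def test_no_hc_photoreceptor_drive_is_light_only(self, circuit_battery):
        movie = circuit_battery["emerging"]
        tr = opl_sim.run_simulation(
            movie, CircuitParams(hc_enabled=False), record=("ph_drive",)
        )
        # drive = g * E_VS * VS / (VS + 1) wherever the bar covers a cell
        expected = 0.5 * (-10.0) * movie.frames / (movie.frames + 1.0)
        np.testing.assert_allclose(tr["ph_drive"].values, expected, atol=1e-12)

    def test_without_hc_photoreceptor_peaks_equal_across_conditions(
        self, circuit_battery
    ):
        peaks = []
        for movie in circuit_battery.values():
            tr = opl_sim.run_simulation(
                movie, CircuitParams(hc_enabled=False), record=("ph",)
            )
            peaks.append(np.abs(tr["ph"].values[75]).max())
        peaks = np.array(peaks)
        assert np.ptp(peaks) / peaks.mean() <= 0.01

    def test_mirror_symmetry(self, params):
        spec = stimuli.BarSpec(bar_length=1000.0, speed=0.5, contrast=1.0)
        right = stimuli.apply_mask(
            stimuli.make_moving_bar(spec, extent=1500.0, dx=10.0), (0.0, 300.0)
        )
        left = right.mirrored()
        a = opl_sim.run_simulation(right, params, record=("bc_vm_transient",))
        b = opl_sim.run_simulation(left, params, record=("bc_vm_transient",))
        np.testing.assert_allclose(
            a["bc_vm_transient"].values,
            b["bc_vm_transient"].values[::-1, :],
            atol=1e-10,
        )


class TestFixedPoints:
    def test_bc_relaxation_reaches_steady_state_within_five_taus(self, params):
        target = np.full(1, 0.03)
        syn = np.zeros(1)
        for _ in range(int(5 * params.tau_bc * 3)):
            syn = opl_sim.bc_step(syn, target, params)
        assert syn[0] == pytest.approx(0.03, abs=1e-6)


class TestHCLeadTime:
    def test_flash_gives_near_zero_lead(self, circuit_traces, circuit_battery):
        leads, _ = opl_sim.hc_lead_time(
            circuit_traces["flash"], circuit_battery["flash"]
        )
        interior = leads[30:120]
        assert np.nanmax(np.abs(interior)) <= 60.0

    def test_motion_lead_strictly_positive_in_interior(
        self, circuit_traces, circuit_battery
    ):
        leads, max_lead = opl_sim.hc_lead_time(
            circuit_traces["full"], circuit_battery["full"]
        )
        assert np.all(leads[30:120] > 0)
        assert max_lead > 0

    def test_halving_hc_fwhm_reduces_max_lead(self, circuit_battery):
        movie = circuit_battery["full"]
        leads = {}
        for fwhm in (150.0, 300.0):
            tr = opl_sim.run_simulation(
                movie, CircuitParams(fwhm_hc=fwhm), record=("hc",)
            )
            _, leads[fwhm] = opl_sim.hc_lead_time(tr, movie)
        assert leads[150.0] < leads[300.0]

    def test_lead_collapses_at_emergence_boundary(
        self, circuit_traces, circuit_battery
    ):
        em_leads, _ = opl_sim.hc_lead_time(
            circuit_traces["emerging"], circuit_battery["emerging"]
        )
        _, full_max = opl_sim.hc_lead_time(
            circuit_traces["full"], circuit_battery["full"]
        )
        # first cells past the occluder edge: HC engages with (or after) light
        assert np.nanmax(em_leads[30:33]) < 0.25 * full_max
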