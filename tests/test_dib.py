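"""Osmotic transport model and permeability estimators."""

import math

import numpy as np
import pytest

from memphys import dib, synthetic
from memphys.constants import WATER_MOLAR_VOLUME, nacl_osmolarity_mol_m3
from memphys.dib import (DropletPairState, TransportParams, aggregate_runs,
                         estimate_pf_ode, estimate_pf_slope, osmolarity,
                         simulate_pair)
from memphys.exceptions import (DomainError, SchemaError, UnidentifiableError)

V_100UM_DROPLET = 4.0 / 3.0 * math.pi * (50e-6) ** 3  # 5.236e-13 m^3


class TestOsmolarity:
    def test_pure_water_droplet_is_zero(self):
        assert osmolarity(0.0, V_100UM_DROPLET) == 0.0

    def test_saline_droplet_hand_division(self):
        # 0.1 M NaCl with vant-Hoff x osmotic-coefficient multiplier 1.864
        # in a 100 um droplet: n = 186.4 osmol/m^3 * V
        n = nacl_osmolarity_mol_m3(0.1) * V_100UM_DROPLET
        assert osmolarity(n, V_100UM_DROPLET) == pytest.approx(186.4)
        assert osmolarity(9.77e-11, 5.236e-13) == pytest.approx(
            9.77e-11 / 5.236e-13)

    def test_halving_volume_doubles_concentration(self):
        n, v = 3.2e-12, 4.1e-13
        assert osmolarity(n, v / 2) == pytest.approx(2 * osmolarity(n, v))

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            osmolarity(1e-12, 0.0)
        with pytest.raises(DomainError):
            osmolarity(1e-12, -1e-15)


class TestSimulatePair:
    def test_zero_gradient_keeps_volumes_constant(self, control_params, t_grid):
        st = DropletPairState.from_radii_um(50, 50, n1=1e-11, n2=1e-11)
        traj = simulate_pair(st, control_params, t_grid)
        r1 = traj.data["R1_um"].to_numpy()
        assert np.allclose(r1, r1[0], rtol=1e-9)

    def test_zero_permeability_keeps_volumes_constant(self, control_state,
                                                      t_grid):
        traj = simulate_pair(control_state, TransportParams(pf_um_s=0.0),
                             t_grid)
        assert np.allclose(traj.data["R1_um"], 50.0, rtol=1e-9)
        assert np.allclose(traj.data["R2_um"], 50.0, rtol=1e-9)

    def test_constant_gradient_matches_linear_closed_form(
            self, control_state, control_params, t_grid):
        """With A_b and the osmolarity difference clamped the model is
        linear: V1(t) = V1(0) - P_f A_b v_w dc t, to 0.1%."""
        ab, dc = 2.2e-9, 186.4
        traj = simulate_pair(control_state, control_params, t_grid,
                             fixed_ab_m2=ab, fixed_dc_osm_m3=dc)
        v1, _ = traj.volumes_m3()
        t = traj.data["t_s"].to_numpy()
        expected = control_state.v1 - 73e-6 * ab * WATER_MOLAR_VOLUME * dc * t
        assert np.max(np.abs(v1 - expected) / expected) < 1e-3

    def test_water_flows_toward_salty_droplet(self, control_state,
                                              control_params, t_grid):
        # droplet 1 is pure water: it must shrink, droplet 2 swell
        traj = simulate_pair(control_state, control_params, t_grid)
        r1 = traj.data["R1_um"].to_numpy()
        r2 = traj.data["R2_um"].to_numpy()
        assert np.all(np.diff(r1) <= 0) and r1[-1] < r1[0]
        assert np.all(np.diff(r2) >= 0) and r2[-1] > r2[0]

    def test_total_volume_conserved_to_1e6(self, control_state,
                                           control_params, t_grid):
        traj = simulate_pair(control_state, control_params, t_grid)
        v1, v2 = traj.volumes_m3()
        tot0 = control_state.v1 + control_state.v2
        assert np.max(np.abs(v1 + v2 - tot0)) / tot0 < 1e-6

    def test_stop_rule_truncates_table(self, control_state):
        params = TransportParams(pf_um_s=500.0, stop_volume_fraction=0.5)
        t = np.arange(0.0, 2000.0, 5.0)
        traj = simulate_pair(control_state, params, t)
        assert len(traj) < len(t)
        v1, _ = traj.volumes_m3()
        assert np.all(v1 >= 0.5 * control_state.v1 * (1 - 1e-6))

    def test_bad_time_grid_rejected(self, control_state, control_params):
        with pytest.raises(DomainError):
            simulate_pair(control_state, control_params, [0.0, 0.0, 1.0])

    @pytest.mark.parametrize("mode", ["sphere", "truncated_sphere"])
    def test_geometry_modes_round_trip(self, mode):
        v = dib.volume_from_radius(47e-6, mode, theta_deg=32.41)
        r = dib.radius_from_volume(v, mode, theta_deg=32.41)
        assert r == pytest.approx(47e-6, rel=1e-12)

    def test_truncated_volume_smaller_than_sphere(self):
        assert (dib.volume_from_radius(50e-6, "truncated_sphere", 32.41)
                < dib.volume_from_radius(50e-6, "sphere"))


class TestEstimators:
    def test_slope_round_trip_noise_free(self, noise_free_trajectory):
        est = estimate_pf_slope(noise_free_trajectory)
        assert est.pf_um_s == pytest.approx(73.0, rel=0.01)

    def test_ode_round_trip_noise_free(self, noise_free_trajectory):
        est = estimate_pf_ode(noise_free_trajectory)
        assert est.pf_um_s == pytest.approx(73.0, rel=0.01)

    def test_estimators_agree_noise_free(self, noise_free_trajectory):
        a = estimate_pf_slope(noise_free_trajectory)
        b = estimate_pf_ode(noise_free_trajectory)
        assert abs(a.pf_um_s - b.pf_um_s) / b.pf_um_s < 0.005

    def test_constant_radii_give_zero_pf(self):
        import pandas as pd
        n = 50
        df = pd.DataFrame({"t_s": np.arange(n, dtype=float),
                           "R1_um": np.full(n, 50.0),
                           "R2_um": np.full(n, 50.0)})
        traj = dib.TrajectoryTable(df, {"n1_osmol": 0.0, "n2_osmol": 9.77e-11,
                                        "theta_deg": 32.41})
        est = estimate_pf_slope(traj)
        assert est.pf_um_s == pytest.approx(0.0, abs=1e-9)

    def test_zero_gradient_unidentifiable(self):
        import pandas as pd
        df = pd.DataFrame({"t_s": [0.0, 1.0, 2.0, 3.0],
                           "R1_um": [50.0, 50.1, 50.2, 50.3],
                           "R2_um": [50.0, 49.9, 49.8, 49.7]})
        traj = dib.TrajectoryTable(df, {"n1_osmol": 0.0, "n2_osmol": 0.0})
        with pytest.raises(UnidentifiableError):
            estimate_pf_slope(traj)

    def test_too_few_rows_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"t_s": [0.0], "R1_um": [50.0], "R2_um": [50.0]})
        traj = dib.TrajectoryTable(df, {"n1_osmol": 0.0, "n2_osmol": 1e-11})
        with pytest.raises(SchemaError):
            estimate_pf_slope(traj)
        with pytest.raises(SchemaError):
            estimate_pf_ode(traj)

    def test_negative_initial_guess_rejected(self):
        with pytest.raises(DomainError):
            TransportParams(pf_um_s=-5.0)

    def test_zero_initial_guess_rejected(self, noise_free_trajectory):
        with pytest.raises(DomainError):
            estimate_pf_ode(noise_free_trajectory,
                            TransportParams(pf_um_s=0.0))

    def test_noisy_single_run_is_finite_and_positive(self):
        traj = synthetic.gen_trajectory(synthetic.TrajectoryConfig(seed=5))
        est = estimate_pf_slope(traj)
        assert np.isfinite(est.pf_um_s) and est.pf_um_s > 0


class TestAggregateRuns:
    def test_single_run_has_undefined_sd(self):
        mean, sd, n = aggregate_runs([73.0])
        assert mean == 73.0 and n == 1 and math.isnan(sd)

    def test_two_runs_hand_arithmetic(self):
        mean, sd, n = aggregate_runs([70.0, 76.0])
        assert mean == pytest.approx(73.0)
        assert sd == pytest.approx(math.sqrt(18.0), rel=1e-12)  # 4.2426
        assert n == 2

    def test_permutation_invariance(self):
        vals = [68.0, 77.0, 73.0, 75.0]
        assert aggregate_runs(vals) == aggregate_runs(list(reversed(vals)))

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            aggregate_runs([])
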