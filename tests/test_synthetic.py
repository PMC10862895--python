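import numpy as np
import pytest

from switchscope.errors import ConstructionError, SpecValidationError
from switchscope.synthetic import (
    KineticGenSpec,
    MeltGenSpec,
    STDGenSpec,
    ToyTrajectorySpec,
    generate_kinetic_trace,
    generate_melting_curves,
    generate_std_table,
    generate_toy_trajectories,
    make_toy_topology,
    read_spec_json,
    write_spec_json,
)
from switchscope.thermostability import fit_melting_curve

from oracles import closest_proton_scan, grid_search_tm


class TestMeltingGenerator:
    def test_midpoint_value(self):
        spec = MeltGenSpec(tm_true=50.0, slope_true=2.0)
        [curve] = generate_melting_curves(spec)
        i = int(np.argmax(curve.temperature == 50.0))
        assert curve.signal[i] == pytest.approx(0.5)

    def test_asymptote_reaches_top(self):
        spec = MeltGenSpec(tm_true=30.0, slope_true=1.0)
        [curve] = generate_melting_curves(spec)
        assert curve.signal[-1] == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_recovery_with_grid_oracle(self):
        spec = MeltGenSpec(tm_true=65.2, slope_true=2.0, noise_sd=0.02, seed=7)
        [curve] = generate_melting_curves(spec)
        fit = fit_melting_curve(curve)
        assert abs(fit.v50 - 65.2) < 0.5
        v50_oracle, _ = grid_search_tm(curve.temperature, curve.signal)
        assert abs(v50_oracle - 65.2) < 0.5

    def test_replicates_differ_only_by_noise(self):
        spec = MeltGenSpec(tm_true=55.0, slope_true=2.0, noise_sd=0.0, replicates=3)
        curves = generate_melting_curves(spec)
        for c in curves[1:]:
            np.testing.assert_array_equal(c.signal, curves[0].signal)

    def test_seed_determinism(self):
        spec = MeltGenSpec(tm_true=55.0, slope_true=2.0, noise_sd=0.02,
                           replicates=2, seed=42)
        a = generate_melting_curves(spec)
        b = generate_melting_curves(spec)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.signal, cb.signal)

    def test_invalid_tm_names_field(self):
        with pytest.raises(SpecValidationError) as exc:
            MeltGenSpec(tm_true=20.0, slope_true=2.0)
        assert exc.value.field == "tm_true"

    def test_noise_free_recovery_six_digits(self):
        spec = MeltGenSpec(tm_true=61.25, slope_true=3.5)
        [curve] = generate_melting_curves(spec)
        fit = fit_melting_curve(curve)
        assert fit.v50 == pytest.approx(61.25, rel=1e-6)
        assert fit.slope == pytest.approx(3.5, rel=1e-6)


class TestKineticGenerator:
    def test_y0_at_time_zero(self):
        trace = generate_kinetic_trace(
            KineticGenSpec(y0=123.0, plateau=300.0, k_true=0.05))
        assert trace.time[0] == 0.0
        assert trace.intensity[0] == pytest.approx(123.0)

    def test_plateau_asymptote(self):
        trace = generate_kinetic_trace(
            KineticGenSpec(y0=100.0, plateau=300.0, k_true=0.5))
        assert trace.intensity[-1] == pytest.approx(300.0, rel=1e-9)

    def test_seed_determinism(self):
        spec = KineticGenSpec(y0=100.0, plateau=300.0, k_true=0.05,
                              noise_sd=2.0, seed=5)
        np.testing.assert_array_equal(generate_kinetic_trace(spec).intensity,
                                      generate_kinetic_trace(spec).intensity)

    def test_sampling_cadence(self):
        trace = generate_kinetic_trace(
            KineticGenSpec(y0=1.0, plateau=2.0, k_true=0.05))
        assert np.all(np.diff(trace.time) == pytest.approx(12.0))
        assert trace.time[-1] == pytest.approx(200.0 * 60.0)


class TestSTDGenerator:
    def test_zero_weight_no_transfer(self):
        spec = STDGenSpec(epitope_weights={"a": 0.0}, i0={"a": 1.0},
                          snr={"a": 1e12})
        [rec] = generate_std_table(spec).records
        assert rec.isat == pytest.approx(1.0, abs=1e-9)

    def test_forward_model_arithmetic(self):
        # w=0.02 at 50-fold excess gives a_std exactly 1.0 without noise
        spec = STDGenSpec(epitope_weights={"a": 0.02}, i0={"a": 1.0},
                          snr={"a": 1e15}, ligand_conc=50.0, protein_conc=1.0)
        table = generate_std_table(spec)
        rec = table.records[0]
        a_std = ((rec.i0 - rec.isat) / rec.i0) * table.context.excess
        assert a_std == pytest.approx(1.0, abs=1e-9)

    def test_noise_scales_with_snr(self):
        isats = []
        for seed in range(400):
            spec = STDGenSpec(epitope_weights={"a": 0.0}, i0={"a": 1.0},
                              snr={"a": 20.0}, seed=seed)
            isats.append(generate_std_table(spec).records[0].isat)
        assert np.std(isats) == pytest.approx(1.0 / 20.0, rel=0.2)


class TestToyTrajectories:
    def test_always_formed_hbond(self, toy_topology):
        spec = ToyTrajectorySpec(topology=toy_topology,
                                 hbond_schedule={(201, 226): 1.0},
                                 n_frames=100, n_replicas=1, seed=0)
        from switchscope.traj import default_switch_regions, hbond_occupancy
        [traj] = generate_toy_trajectories(spec)
        m = hbond_occupancy(traj, default_switch_regions())
        assert m.entries[(201, 226)] == 1.0

    def test_proximity_fraction_by_brute_force(self, toy_topology):
        spec = ToyTrajectorySpec(topology=toy_topology,
                                 proximity_schedule={("a", 52): 0.9},
                                 n_frames=200, n_replicas=1, seed=1)
        [traj] = generate_toy_trajectories(spec)
        proton_id = toy_topology.nucleotide_protons["a"][0]
        hits = sum(
            closest_proton_scan(traj.coords[f], toy_topology, proton_id) == 52
            for f in range(traj.n_frames))
        assert hits / traj.n_frames == pytest.approx(0.90)

    def test_jitter_rmsf_limit(self, toy_topology):
        # Monte-Carlo convergence of per-atom RMSF to sd*sqrt(3)
        from switchscope.traj import compute_rmsf
        spec = ToyTrajectorySpec(topology=toy_topology, jitter_sd=0.3,
                                 n_frames=5000, n_replicas=1, seed=2)
        [traj] = generate_toy_trajectories(spec)
        profile = compute_rmsf(traj)
        mean_rmsf = np.mean(list(profile.per_residue.values()))
        assert mean_rmsf == pytest.approx(0.3 * np.sqrt(3.0), rel=0.05)

    def test_unsatisfiable_schedule_lists_conflict(self, toy_topology):
        # three proton atoms claim residue 52, which has two side hydrogens
        spec = ToyTrajectorySpec(
            topology=toy_topology,
            proximity_schedule={("a", 52): 1.0, ("b", 52): 1.0, ("c", 52): 1.0},
            n_frames=10, n_replicas=1, seed=0)
        with pytest.raises(ConstructionError) as exc:
            generate_toy_trajectories(spec)
        assert exc.value.conflicts

    def test_conflicting_hbond_donor_rejected(self, toy_topology):
        spec = ToyTrajectorySpec(
            topology=toy_topology,
            hbond_schedule={(201, 226): 0.5, (201, 259): 0.5},
            n_frames=10, n_replicas=1, seed=0)
        with pytest.raises(ConstructionError):
            generate_toy_trajectories(spec)

    def test_fraction_sum_validation(self, toy_topology):
        with pytest.raises(SpecValidationError) as exc:
            ToyTrajectorySpec(topology=toy_topology,
                              proximity_schedule={("a", 52): 0.7, ("a", 173): 0.5})
        assert exc.value.field == "proximity_schedule"

    def test_seed_determinism_across_replicas(self, toy_topology):
        spec = ToyTrajectorySpec(topology=toy_topology,
                                 proximity_schedule={("a", 52): 0.5},
                                 jitter_sd=0.1, n_frames=20, n_replicas=3, seed=7)
        a = generate_toy_trajectories(spec)
        b = generate_toy_trajectories(spec)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.coords, tb.coords)
        assert not np.array_equal(a[0].coords, a[1].coords)


def test_spec_json_round_trip(tmp_path):
    spec = MeltGenSpec(tm_true=55.0, slope_true=2.0, noise_sd=0.02, seed=3)
    path = tmp_path / "spec.json"
    write_spec_json(spec, path)
    assert read_spec_json(path) == spec
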