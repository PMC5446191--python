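"""Network construction, update rule, plasticity rules and stepping."""

import copy

import numpy as np
import pytest

from sorncrit.core import (
    NetworkParams,
    NetworkState,
    NoiseModel,
    PlasticityFlags,
    RecordOptions,
    SUPRATHRESHOLD,
    clone_state,
    init_network,
    intrinsic_plasticity,
    istdp_update,
    make_streams,
    prune_nonpositive,
    simulate,
    stdp_update,
    step,
    structural_plasticity,
    synaptic_normalization,
    update_states,
)

SILENT = NoiseModel(kind="none")


def _tiny_state(n_e=6, n_i=2):
    """Minimal consistent state with hand-settable weights."""
    return NetworkState(
        x=np.zeros(n_e), y=np.zeros(n_i),
        w_ee=np.zeros((n_e, n_e)),
        w_ei=np.zeros((n_e, n_i)),
        mask_ei=np.zeros((n_e, n_i), dtype=bool),
        w_ie=np.zeros((n_i, n_e)),
        t_e=np.full(n_e, 0.5), t_i=np.full(n_i, 0.5),
        h_ip=np.full(n_e, 0.1),
    )


class TestParams:
    def test_inhibitory_count_is_fifth_of_excitatory(self):
        assert NetworkParams(n_e=200).n_i == 40
        assert NetworkParams(n_e=110).n_i == 22

    def test_sp_probability_scales_quadratically(self):
        assert np.isclose(NetworkParams(n_e=200).p_sp, 0.1)
        assert np.isclose(NetworkParams(n_e=400).p_sp,
                          400 * 399 / (200 * 199) * 0.1)

    def test_tiny_network_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(n_e=4)

    @pytest.mark.parametrize("kw", [
        {"eta_stdp": -0.01}, {"mu_ip": 1.5}, {"p_ee_init": -0.1},
    ])
    def test_out_of_range_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            NetworkParams(**kw)


class TestInit:
    def test_shapes_and_ranges(self, rng):
        p = NetworkParams(n_e=200)
        s = init_network(p, rng)
        assert s.x.shape == (200,) and s.y.shape == (40,)
        assert not s.x.any() and not s.y.any()
        assert np.all(s.t_e >= 0) and np.all(s.t_e <= 0.5)
        assert np.all(s.t_i >= 0) and np.all(s.t_i <= 1.0)
        assert np.allclose(s.h_ip, 0.1)
        assert np.diagonal(s.w_ee).sum() == 0

    def test_rows_are_normalized(self, rng):
        s = init_network(NetworkParams(n_e=100), rng)
        for w in (s.w_ee, s.w_ei, s.w_ie):
            sums = w.sum(axis=1)
            nz = sums > 0
            assert np.allclose(sums[nz], 1.0)

    def test_connection_fractions_match_probabilities(self):
        fracs_ee, fracs_ei = [], []
        for seed in range(20):
            s = init_network(NetworkParams(n_e=200), np.random.default_rng(seed))
            fracs_ee.append(s.connection_fraction())
            fracs_ei.append((s.w_ei > 0).mean())
        assert abs(np.mean(fracs_ee) - 0.1) < 0.02
        assert abs(np.mean(fracs_ei) - 0.2) < 0.02

    def test_per_unit_target_rates_can_vary(self, rng):
        p = NetworkParams(n_e=200, sigma_ip_sq=0.01)
        s = init_network(p, rng)
        assert s.h_ip.std() > 0
        assert abs(s.h_ip.mean() - 0.1) < 0.05


class TestUpdateStates:
    def test_suprathreshold_external_drive_fires_isolated_unit(self):
        s = _tiny_state()
        u = np.zeros(6)
        u[3] = SUPRATHRESHOLD
        x, _ = update_states(s, u, SILENT, None)
        assert x[3] == 1 and x.sum() == 1

    def test_silent_network_with_positive_thresholds_stays_silent(self):
        s = _tiny_state()
        x, y = update_states(s, None, SILENT, None)
        assert not x.any() and not y.any()

    def test_drive_equal_to_threshold_fires(self):
        # theta(0) = 1 convention
        s = _tiny_state()
        u = np.zeros(6)
        u[0] = s.t_e[0]
        x, _ = update_states(s, u, SILENT, None)
        assert x[0] == 1

    def test_inhibitory_units_follow_previous_excitatory_state(self):
        s = _tiny_state()
        s.w_ie[:, 3] = 1.0
        u = np.zeros(6)
        u[3] = SUPRATHRESHOLD
        # default: y(t+1) reads x(t), so the forced spike is not seen yet
        _, y_lagged = update_states(s, u, SILENT, None)
        assert not y_lagged.any()
        _, y_instant = update_states(s, u, SILENT, None, instant_inhibition=True)
        assert y_instant.all()


class TestSTDP:
    def test_causal_pair_potentiates_by_learning_rate(self):
        w = np.zeros((2, 2))
        w[1, 0] = 0.3                     # synapse 0 -> 1
        x_prev = np.array([1.0, 0.0])     # pre fired first
        x_now = np.array([0.0, 1.0])      # post fired after
        stdp_update(w, x_now, x_prev, 0.004)
        assert np.isclose(w[1, 0], 0.304)

    def test_anticausal_pair_depresses(self):
        w = np.zeros((2, 2))
        w[1, 0] = 0.3
        x_prev = np.array([0.0, 1.0])
        x_now = np.array([1.0, 0.0])
        stdp_update(w, x_now, x_prev, 0.004)
        assert np.isclose(w[1, 0], 0.296)

    def test_coincident_firing_cancels(self):
        w = np.zeros((2, 2))
        w[1, 0] = 0.3
        both = np.array([1.0, 1.0])
        stdp_update(w, both, both, 0.004)
        assert np.isclose(w[1, 0], 0.3)

    def test_absent_synapses_are_never_created(self):
        w = np.zeros((2, 2))
        both = np.array([1.0, 1.0])
        stdp_update(w, both, np.array([1.0, 0.0]), 0.004)
        assert w[0, 1] == 0

    def test_pruning_removes_depressed_synapse(self):
        w = np.zeros((2, 2))
        w[1, 0] = 0.004
        stdp_update(w, np.array([1.0, 0.0]), np.array([0.0, 1.0]), 0.004)
        prune_nonpositive(w)
        assert w[1, 0] == 0


class TestISTDP:
    def test_failed_inhibition_strengthens_by_eta_over_mu(self):
        w = np.full((1, 1), 0.5)
        mask = np.ones((1, 1), dtype=bool)
        istdp_update(w, mask, np.array([1.0]), np.array([1.0]), 0.001, 0.1)
        assert np.isclose(w[0, 0], 0.51)      # +eta_inh/mu_ip = +0.01

    def test_successful_inhibition_weakens_by_eta(self):
        w = np.full((1, 1), 0.5)
        mask = np.ones((1, 1), dtype=bool)
        istdp_update(w, mask, np.array([0.0]), np.array([1.0]), 0.001, 0.1)
        assert np.isclose(w[0, 0], 0.499)

    def test_silent_presynaptic_unit_gates_rule(self):
        w = np.full((1, 1), 0.5)
        mask = np.ones((1, 1), dtype=bool)
        istdp_update(w, mask, np.array([1.0]), np.array([0.0]), 0.001, 0.1)
        assert w[0, 0] == 0.5

    def test_weights_floor_at_zero_but_slot_survives(self):
        w = np.full((1, 1), 0.0005)
        mask = np.ones((1, 1), dtype=bool)
        istdp_update(w, mask, np.array([0.0]), np.array([1.0]), 0.001, 0.1)
        assert w[0, 0] == 0.0
        istdp_update(w, mask, np.array([1.0]), np.array([1.0]), 0.001, 0.1)
        assert w[0, 0] > 0                     # the slot can recover

    def test_zero_target_rate_rejected(self):
        with pytest.raises(ValueError):
            istdp_update(np.ones((1, 1)), np.ones((1, 1), dtype=bool),
                         np.array([1.0]), np.array([1.0]), 0.001, 0.0)


class TestNormalization:
    @pytest.mark.parametrize("row,expected", [
        ([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]),
        ([2.0, 2.0, 0.0], [0.5, 0.5, 0.0]),
        ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]),
    ])
    def test_row_cases(self, row, expected):
        w = np.array([row])
        synaptic_normalization(w)
        assert np.allclose(w[0], expected)


class TestStructuralPlasticity:
    def test_created_synapse_has_seed_weight(self):
        p = NetworkParams(n_e=200, p_sp_200=1.0)   # p_sp(200) = 1: fires every step
        w = np.zeros((200, 200))
        rng = np.random.default_rng(0)
        for _ in range(5):
            structural_plasticity(w, p, rng)
        created = w[w > 0]
        assert len(created) == 5
        assert np.all(created == 0.001)
        assert np.diagonal(w).sum() == 0

    def test_full_graph_is_noop(self):
        p = NetworkParams(n_e=200, p_sp_200=1.0)
        w = np.ones((200, 200)) - np.eye(200)
        before = w.copy()
        structural_plasticity(w, p, np.random.default_rng(1))
        assert np.array_equal(w, before)


class TestIntrinsicPlasticity:
    def test_firing_raises_threshold(self):
        t = np.array([0.2])
        intrinsic_plasticity(t, np.array([1.0]), np.array([0.1]), 0.01)
        assert np.isclose(t[0], 0.209)

    def test_silence_lowers_threshold(self):
        t = np.array([0.2])
        intrinsic_plasticity(t, np.array([0.0]), np.array([0.1]), 0.01)
        assert np.isclose(t[0], 0.199)

    def test_zero_rate_leaves_thresholds(self):
        t = np.array([0.2, -0.1])
        intrinsic_plasticity(t, np.array([1.0, 0.0]), np.array([0.1, 0.1]), 0.0)
        assert np.array_equal(t, [0.2, -0.1])


class TestStep:
    def test_all_flags_off_touches_only_states_and_clock(self):
        p = NetworkParams(n_e=30)
        streams = make_streams(5)
        s = init_network(p, streams["init"])
        w_ee, w_ei = s.w_ee.copy(), s.w_ei.copy()
        t_e = s.t_e.copy()
        step(s, None, NoiseModel(), PlasticityFlags.all_off(), streams, params=p)
        assert np.array_equal(s.w_ee, w_ee)
        assert np.array_equal(s.w_ei, w_ei)
        assert np.array_equal(s.t_e, t_e)
        assert s.t == 1

    def test_rows_sum_to_one_after_any_plastic_step(self):
        p = NetworkParams(n_e=40)
        streams = make_streams(6)
        s = init_network(p, streams["init"])
        for _ in range(50):
            step(s, None, NoiseModel(), PlasticityFlags.all_on(), streams, params=p)
            for w in (s.w_ee, s.w_ei):
                sums = w.sum(axis=1)
                assert np.all(np.abs(sums[sums > 0] - 1.0) < 1e-9)

    def test_identical_seeds_give_identical_trajectories(self):
        p = NetworkParams(n_e=40)
        rasters = []
        for _ in range(2):
            streams = make_streams(11)
            s = init_network(p, streams["init"])
            rec = simulate(s, 500, p, NoiseModel(), PlasticityFlags.all_on(),
                           streams, record=RecordOptions(raster=True))
            rasters.append(rec.raster)
        assert all(np.array_equal(a, b) for a, b in zip(*rasters))


class TestSimulate:
    def test_single_step_run(self):
        p = NetworkParams(n_e=20)
        streams = make_streams(3)
        s = init_network(p, streams["init"])
        rec = simulate(s, 1, p, NoiseModel(), PlasticityFlags.all_on(), streams)
        assert rec.activity.shape == (1,)
        assert s.t == 1

    def test_zero_steps_rejected(self):
        p = NetworkParams(n_e=20)
        streams = make_streams(3)
        s = init_network(p, streams["init"])
        with pytest.raises(ValueError):
            simulate(s, 0, p, NoiseModel(), PlasticityFlags.all_on(), streams)

    def test_fast_path_matches_reference_ops_exactly(self):
        """The compiled batch kernel and the composable reference step
        produce identical spike rasters when fed the same noise draws
        (structural plasticity off: its stream consumption differs)."""
        p = NetworkParams(n_e=80)
        noise = NoiseModel()
        flags = PlasticityFlags(sp=False)

        streams_f = make_streams(21)
        s_f = init_network(p, streams_f["init"])
        rec = simulate(s_f, 2000, p, noise, flags, streams_f,
                       record=RecordOptions(raster=True))

        streams_r = make_streams(21)
        s_r = init_network(p, streams_r["init"])
        rng = streams_r["noise"]
        rasters = []
        done = 0
        while done < 2000:
            batch = min(1024, 2000 - done)
            xi_e = noise.draw(rng, p.n_e, batch)
            xi_i = noise.draw_inhibitory(rng, p.n_i, batch)
            for b in range(batch):
                step(s_r, None, noise, flags, streams_r, params=p,
                     xi=(xi_e[b], xi_i[b]))
                rasters.append(np.flatnonzero(s_r.x))
            done += batch
        assert all(np.array_equal(a, b) for a, b in zip(rec.raster, rasters))
        assert np.allclose(s_f.w_ee, s_r.w_ee, atol=1e-12)
        assert np.allclose(s_f.t_e, s_r.t_e, atol=1e-12)

    def test_no_self_connections_and_no_negative_weights_ever(self):
        p = NetworkParams(n_e=60)
        streams = make_streams(8)
        s = init_network(p, streams["init"])
        for _ in range(10):
            simulate(s, 2000, p, NoiseModel(), PlasticityFlags.all_on(), streams)
            assert np.diagonal(s.w_ee).sum() == 0
            assert s.w_ee.min() >= 0 and s.w_ei.min() >= 0

    def test_clone_and_stream_copy_reproduce_bitwise(self):
        p = NetworkParams(n_e=60)
        streams = make_streams(9)
        s = init_network(p, streams["init"])
        simulate(s, 1000, p, NoiseModel(), PlasticityFlags.all_on(), streams)
        s2 = clone_state(s)
        streams2 = copy.deepcopy(streams)
        rec1 = simulate(s, 1000, p, NoiseModel(), PlasticityFlags.all_on(),
                        streams, record=RecordOptions(raster=True))
        rec2 = simulate(s2, 1000, p, NoiseModel(), PlasticityFlags.all_on(),
                        streams2, record=RecordOptions(raster=True))
        assert all(np.array_equal(a, b) for a, b in zip(rec1.raster, rec2.raster))
        assert np.array_equal(s.w_ee, s2.w_ee)

    def test_exhausted_input_source_rejected(self):
        class Exhausted:
            subsets = np.zeros((1, 1), dtype=np.int64)
            amplitude = 1.0

            def next_ids(self, n, rng):
                raise ValueError("input stream shorter than the run")

        p = NetworkParams(n_e=20)
        streams = make_streams(3)
        s = init_network(p, streams["init"])
        with pytest.raises(ValueError):
            simulate(s, 10, p, SILENT, PlasticityFlags.all_off(), streams,
                     input_source=Exhausted())


class TestIndependentNeuronLimit:
    def test_decoupled_units_with_spike_noise_give_binomial_activity(self):
        """With all couplings removed and random-spike noise p_s = 0.1,
        the activity count must follow Binomial(N_E, 0.1) -- the
        high-noise reference curve for statistically independent units."""
        from scipy import stats

        p = NetworkParams(n_e=200)
        streams = make_streams(77)
        s = init_network(p, streams["init"])
        s.w_ee[:] = 0
        s.w_ei[:] = 0
        noise = NoiseModel(kind="random_spike", p_s=0.1)
        flags = PlasticityFlags(stdp=False, istdp=False, sn=False, sp=False,
                                ip=True)
        rec = simulate(s, 200_000, p, noise, flags, streams)
        vals, counts = np.unique(rec.activity, return_counts=True)
        emp = np.zeros(p.n_e + 1)
        emp[vals] = counts / rec.activity.size
        ref = stats.binom.pmf(np.arange(p.n_e + 1), p.n_e, 0.1)
        total_variation = 0.5 * np.abs(emp - ref).sum()
        assert total_variation < 0.03
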