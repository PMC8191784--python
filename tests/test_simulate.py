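"""Generator correctness: Gillespie statistics, rendering, determinism."""

import numpy as np
import pytest
from scipy import stats

from fretfold import (
    AcquisitionModel,
    Condition,
    KineticScheme,
    compute_fret,
    render_intensity_trace,
    simulate_dataset,
    simulate_state_path,
    two_state_scheme,
)
from fretfold.scheme import StateEvent
from fretfold.simulate import frame_occupancy, path_dwells


def one_state_scheme():
    return KineticScheme(
        state_names=("U",),
        fret_mean=np.array([0.5]),
        fret_sd=np.array([0.0]),
        rates=np.zeros((1, 1)),
    )


class TestScheme:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(("A",), [1.5], [0.05], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            KineticScheme(
                ("A", "B"), [0.2, 0.8], [0.05, 0.05],
                np.array([[0.0, -1.0], [1.0, 0.0]]),
            )
        with pytest.raises(ValueError):
            KineticScheme(
                ("A", "B"), [0.2, 0.8], [0.05, 0.05], np.zeros((2, 2)),
                initial_probs=[0.6, 0.6],
            )

    def test_stationary_distribution_solves_balance(self):
        scheme = two_state_scheme(2.0, 1.0)
        pi = scheme.stationary_distribution()
        np.testing.assert_allclose(pi @ scheme.generator_matrix(), 0, atol=1e-12)
        np.testing.assert_allclose(pi, [1 / 3, 2 / 3])


class TestStatePath:
    def test_one_state_never_exits(self):
        path = simulate_state_path(one_state_scheme(), 10.0, seed=0)
        assert [(e.state, e.entry_time) for e in path] == [("U", 0.0)]

    def test_symmetric_two_state_occupancy_half(self):
        scheme = two_state_scheme(1.0, 1.0)
        path = simulate_state_path(scheme, 5000.0, seed=1)
        t_u = sum(
            d for s, d, _ in path_dwells(path, 5000.0) if s == "U"
        )
        assert t_u / 5000.0 == pytest.approx(0.5, abs=0.03)

    def test_dwell_mean_matches_inverse_exit_rate(self):
        # exit rate 2.7/s from state 1: mean dwell must equal 1/2.7 within 1%
        scheme = two_state_scheme(2.7, 2.7)
        dur = 80000.0  # ~ 1e5 dwells per state
        path = simulate_state_path(scheme, dur, seed=2)
        dwells = [
            d for s, d, cens in path_dwells(path, dur)
            if s == "U" and not cens
        ]
        assert len(dwells) >= 1e5
        assert np.mean(dwells) == pytest.approx(1 / 2.7, rel=0.01)

    def test_dwells_are_exponential(self):
        scheme = two_state_scheme(2.0, 2.0)
        path = simulate_state_path(scheme, 10000.0, seed=3)
        dwells = np.array(
            [d for s, d, c in path_dwells(path, 10000.0) if s == "U" and not c]
        )
        assert len(dwells) > 1e4
        # KS against the known generating exponential
        _, p = stats.kstest(dwells, "expon", args=(0, 1 / 2.0))
        assert p > 0.01

    def test_occupancy_matches_stationary_distribution(self):
        scheme = two_state_scheme(1.6, 0.4)
        pi = scheme.stationary_distribution()
        path = simulate_state_path(scheme, 20000.0, seed=4)
        occ = {"U": 0.0, "F": 0.0}
        for s, d, _ in path_dwells(path, 20000.0):
            occ[s] += d
        assert occ["U"] / 20000.0 == pytest.approx(pi[0], abs=0.02)

    def test_absorbing_state_truncates(self):
        rates = np.array([[0.0, 5.0], [0.0, 0.0]])  # F absorbing
        scheme = KineticScheme(
            ("U", "F"), [0.3, 0.9], [0.05, 0.05], rates,
            initial_probs=[1.0, 0.0],
        )
        path = simulate_state_path(scheme, 100.0, seed=5)
        assert path[-1].state == "F"
        assert len(path) == 2


class TestRender:
    def test_noiseless_single_state_splits_intensity(self):
        scheme = one_state_scheme()
        acq = AcquisitionModel(total_intensity=1000.0, n_frames=50)
        path = [StateEvent("U", 0.0)]
        tr = render_intensity_trace(path, scheme, acq, seed=0)
        np.testing.assert_allclose(tr.donor, 500.0)
        np.testing.assert_allclose(tr.acceptor, 500.0)

    def test_forward_inverse_identity(self):
        scheme = KineticScheme(
            ("F",), [0.92], [0.0], np.zeros((1, 1))
        )
        acq = AcquisitionModel(total_intensity=1000.0, n_frames=40)
        tr = render_intensity_trace([StateEvent("F", 0.0)], scheme, acq, seed=0)
        e = tr.acceptor / (tr.acceptor + tr.donor)
        np.testing.assert_allclose(e, 0.92, rtol=0, atol=1e-12)

    def test_split_frame_time_weighted_average(self):
        scheme = KineticScheme(
            ("A", "B"), [0.2, 1.0], [0.0, 0.0],
            np.zeros((2, 2)), initial_probs=[1.0, 0.0],
        )
        acq = AcquisitionModel(
            frame_interval=0.1, total_intensity=1000.0, n_frames=1
        )
        path = [StateEvent("A", 0.0), StateEvent("B", 0.05)]
        occ = frame_occupancy(path, scheme, 1, 0.1)
        np.testing.assert_allclose(occ, [[0.5, 0.5]])
        tr = render_intensity_trace(path, scheme, acq, seed=0)
        assert tr.acceptor[0] / (tr.acceptor[0] + tr.donor[0]) == pytest.approx(0.6)

    def test_bleaching_drops_both_channels_to_background(self):
        scheme = one_state_scheme()
        acq = AcquisitionModel(
            total_intensity=1000.0, n_frames=400, bleach_lifetime=1.0,
            donor_background=50.0, acceptor_background=80.0,
        )
        tr = render_intensity_trace([StateEvent("U", 0.0)], scheme, acq, seed=1)
        bf = tr.provenance["true_bleach_frame"]
        assert bf is not None
        np.testing.assert_allclose(tr.donor[bf + 1 :], 50.0)
        np.testing.assert_allclose(tr.acceptor[bf + 1 :], 80.0)

    def test_noiseless_trace_inverts_to_state_means(self):
        scheme = two_state_scheme(0.5, 0.5, fret_sd=0.0)
        acq = AcquisitionModel(n_frames=200)
        path = simulate_state_path(scheme, acq.duration, seed=6)
        tr = render_intensity_trace(path, scheme, acq, seed=6)
        ft = compute_fret(tr)
        # frames fully inside one state hit the state mean exactly
        occ = frame_occupancy(path, scheme, 200, acq.frame_interval)
        pure = occ.max(axis=1) > 1 - 1e-12
        states = occ.argmax(axis=1)
        np.testing.assert_allclose(
            ft.efret[pure], scheme.fret_mean[states[pure]], atol=1e-12
        )


class TestDataset:
    def test_fixed_seed_is_bitwise_reproducible(self):
        scheme = two_state_scheme(1.0, 1.0)
        acq = AcquisitionModel(n_frames=100, channel_noise_sd=20.0)
        a = simulate_dataset(scheme, acq, Condition(), 3, seed=9)
        b = simulate_dataset(scheme, acq, Condition(), 3, seed=9)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)

    def test_manifest_lists_unique_ids(self):
        scheme = two_state_scheme(1.0, 1.0)
        acq = AcquisitionModel(n_frames=20)
        ds = simulate_dataset(scheme, acq, Condition(), 200, seed=0)
        ids = ds.manifest()["traces"]
        assert len(ids) == 200 and len(set(ids)) == 200

    def test_dwell_census_matches_exit_rates(self):
        # exits per unit occupancy time is an unbiased census of the exit
        # rate even with window truncation (complete-dwell means are not)
        scheme = two_state_scheme(1.5, 0.75)
        acq = AcquisitionModel(n_frames=400)
        ds = simulate_dataset(scheme, acq, Condition(), 150, seed=10)
        time_in = {"U": 0.0, "F": 0.0}
        exits = {"U": 0, "F": 0}
        for path in ds.paths:
            census = path_dwells(path, acq.duration)
            for s, d, _ in census:
                time_in[s] += d
            for s, _, _ in census[:-1]:  # every dwell but the last exits
                exits[s] += 1
        for state, k_true in (("U", 1.5), ("F", 0.75)):
            k_hat = exits[state] / time_in[state]
            se = k_true / np.sqrt(exits[state])
            assert abs(k_hat - k_true) < 3 * se
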