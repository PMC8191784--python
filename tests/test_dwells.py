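"""Dwell extraction, exponential fits and folding/unfolding rate recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretfold import (
    AcquisitionModel,
    Condition,
    FretHMM,
    compute_fret,
    extract_dwells,
    fit_exponential,
    folding_unfolding_rates,
    simulate_dataset,
    two_state_scheme,
)
from fretfold.dwells import Dwell, ExponentialDwellFit
from fretfold.hmm import HmmModel, StatePath
from fretfold.simulate import dominant_state_per_frame


def make_path(states, dt=0.05, frame_index=None, k=None):
    states = np.asarray(states, dtype=int)
    k = k if k is not None else int(states.max()) + 1
    model = HmmModel(
        k=k,
        means=np.linspace(0.3, 0.9, k),
        sds=np.full(k, 0.05),
        trans=np.full((k, k), 1.0 / k),
        initial=np.full(k, 1.0 / k),
        log_likelihood=0.0,
        n_iterations=1,
        converged=True,
    )
    return StatePath(
        trace_id="t",
        states=states,
        frame_index=(
            np.arange(len(states)) if frame_index is None
            else np.asarray(frame_index)
        ),
        frame_interval=dt,
        model=model,
    )


class TestExtractDwells:
    def test_direct_counting_with_censoring(self):
        # U,U,F,F,F,U,U at 50 ms
        path = make_path([0, 0, 1, 1, 1, 0, 0])
        dwells = extract_dwells(path, state_names=["U", "F"])
        assert [(d.state, round(d.duration, 3), d.censored) for d in dwells] == [
            ("U", 0.10, True),
            ("F", 0.15, False),
            ("U", 0.10, True),
        ]

    def test_lumping_merges_adjacent(self):
        # U,I,I,F lumped {U,I}->u, F->f
        path = make_path([0, 1, 1, 2], k=3)
        dwells = extract_dwells(
            path,
            lump_map={"U": "u", "I": "u", "F": "f"},
            state_names=["U", "I", "F"],
        )
        assert [(d.state, round(d.duration, 3), d.censored) for d in dwells] == [
            ("u", 0.15, True),
            ("f", 0.05, True),
        ]

    def test_masked_gap_censors_both_sides(self):
        path = make_path([0, 0, 0, 0], frame_index=[0, 1, 5, 6], k=1)
        dwells = extract_dwells(path, state_names=["U"])
        assert len(dwells) == 2
        assert all(d.censored for d in dwells)

    def test_matches_simulator_ground_truth(self):
        scheme = two_state_scheme(1.0, 0.8)
        acq = AcquisitionModel(n_frames=400)
        ds = simulate_dataset(scheme, acq, Condition(), 5, seed=3)
        for path in ds.paths:
            truth = dominant_state_per_frame(
                path, scheme, acq.n_frames, acq.frame_interval
            )
            sp = make_path(truth)
            dwells = extract_dwells(sp, state_names=["U", "F"])
            # frame-discretized census: durations sum to the trace length
            assert sum(d.duration for d in dwells) == pytest.approx(
                acq.duration
            )
            # runs of the discretized truth equal the dwell count
            n_runs = 1 + int(np.sum(np.diff(truth) != 0))
            assert len(dwells) == n_runs

    def test_empty_path_errors(self):
        path = make_path([0])
        path.states = np.array([], dtype=int)
        path.frame_index = np.array([], dtype=int)
        with pytest.raises(ValueError):
            extract_dwells(path, state_names=["U"])

    def test_lump_map_must_cover_states(self):
        path = make_path([0, 1])
        with pytest.raises(KeyError):
            extract_dwells(path, lump_map={"U": "u"}, state_names=["U", "F"])


class TestDwellProperties:
    @given(
        st.lists(st.integers(min_value=0, max_value=2), min_size=1,
                 max_size=60)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_durations_partition_the_path(self, states):
        path = make_path(states, k=3)
        dwells = extract_dwells(path, state_names=["U", "I", "F"])
        assert sum(d.duration for d in dwells) == pytest.approx(
            len(states) * path.frame_interval
        )
        # first/last dwells carry the boundary flags
        assert dwells[0].left_censored and dwells[-1].right_censored
        # lumping U and I can only merge dwells, never split them
        lumped = extract_dwells(
            path,
            lump_map={"U": "u", "I": "u", "F": "f"},
            state_names=["U", "I", "F"],
        )
        assert len(lumped) <= len(dwells)
        assert sum(d.duration for d in lumped) == pytest.approx(
            len(states) * path.frame_interval
        )


class TestFitExponential:
    def test_constant_dwells_rate_is_inverse_mean(self):
        est = fit_exponential([0.5] * 100)
        assert est.rate == pytest.approx(2.0)
        assert est.n_dwells == 100

    def test_known_rate_within_two_stderr(self, rng):
        d = rng.exponential(1 / 2.7, 500)
        est = fit_exponential(d)
        assert abs(est.rate - 2.7) < 2 * est.stderr

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fit_exponential([])

    def test_too_few_dwells_errors_with_count(self):
        with pytest.raises(ValueError, match="3"):
            fit_exponential([0.5, 0.4, 0.3])

    def test_censored_mle_counts_survival_time(self):
        dwells = [
            Dwell("t", "U", 1.0, False, False) for _ in range(10)
        ] + [Dwell("t", "U", 2.0, False, True) for _ in range(5)]
        est = fit_exponential(dwells, censor_policy="mle_censored")
        # 10 events over 10*1 + 5*2 = 20 s
        assert est.rate == pytest.approx(0.5)
        assert est.method == "mle_censored"

    def test_histogram_lsq_agrees_with_mle(self, rng):
        d = rng.exponential(0.5, 4000)
        mle = fit_exponential(d)
        lsq = fit_exponential(d, method="histogram_lsq", frame_interval=0.05)
        assert lsq.rate == pytest.approx(mle.rate, rel=0.10)

    def test_estimator_consistency(self):
        # bias shrinks as n grows
        errors = []
        for n in (50, 500, 5000):
            rates = []
            for seed in range(8):
                rng = np.random.default_rng(1000 * n + seed)
                rates.append(fit_exponential(rng.exponential(0.5, n)).rate)
            errors.append(abs(np.mean(rates) - 2.0))
        assert errors[2] < errors[0]
        assert errors[2] < 0.05

    def test_censored_mle_beats_drop_on_truncated_data(self):
        # trace length ~ 2/k: heavy right-censoring
        k_true, window = 1.0, 2.0
        drop_err, cens_err = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dwells = []
            for _ in range(300):
                t, left = 0.0, True
                while t < window:
                    d = rng.exponential(1 / k_true)
                    end = min(t + d, window)
                    dwells.append(
                        Dwell("t", "U", end - t, left, t + d >= window)
                    )
                    t += d
                    left = False
            drop = ExponentialDwellFit(censor_policy="drop").fit(dwells)
            cens = ExponentialDwellFit(censor_policy="mle_censored").fit(dwells)
            drop_err.append(abs(drop.rate_ - k_true))
            cens_err.append(abs(cens.rate_ - k_true))
        assert np.mean(cens_err) < np.mean(drop_err)


class TestFoldingUnfoldingRates:
    @pytest.mark.parametrize(
        "k_fold,k_unfold,seed",
        [(0.19, 0.84, 21), (2.7, 0.64, 22)],
    )
    def test_endpoint_rates_recovered_within_10pct(
        self, k_fold, k_unfold, seed
    ):
        # reduced-size version of the full recovery (acceptance runs n=300)
        from fretfold import recover_two_state_rates

        res = recover_two_state_rates(
            k_fold, k_unfold, n_traces=80, seed=seed, n_init=4
        )
        assert res["k_fold"].rate == pytest.approx(k_fold, rel=0.10)
        assert res["k_unfold"].rate == pytest.approx(k_unfold, rel=0.10)

    def test_rate_ratio_matches_occupancy_ratio(self):
        from fretfold import recover_two_state_rates

        res = recover_two_state_rates(1.0, 0.5, n_traces=80, seed=23, n_init=4)
        # detailed balance: k_fold/k_unfold = occupancy(folded)/occupancy(unfolded)
        scheme = two_state_scheme(1.0, 0.5)
        acq = AcquisitionModel(n_frames=600)
        ds = simulate_dataset(scheme, acq, Condition(), 80, seed=23)
        t_f = t_u = 0.0
        from fretfold.simulate import path_dwells

        for path in ds.paths:
            for s, d, _ in path_dwells(path, acq.duration):
                if s == "F":
                    t_f += d
                else:
                    t_u += d
        ratio_est = res["k_fold"].rate / res["k_unfold"].rate
        assert ratio_est == pytest.approx(t_f / t_u, rel=0.15)

    def test_too_few_dwells_errors(self):
        path = make_path([0, 1] * 10)
        with pytest.raises(ValueError, match="dwells"):
            folding_unfolding_rates([path], min_dwells=50)
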