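"""Background correction, FRET computation, bleach detection and QC."""

import numpy as np
import pytest

from fretfold import (
    IntensityTrace,
    QCRules,
    compute_fret,
    correct_background,
    detect_bleach,
    qc_select,
)
from fretfold.fret import detect_bleach_steps


def make_trace(donor, acceptor, dt=0.05, trace_id="t", bleach_frame=None):
    donor = np.asarray(donor, dtype=float)
    return IntensityTrace(
        time_s=np.arange(len(donor)) * dt,
        donor=donor,
        acceptor=np.asarray(acceptor, dtype=float),
        frame_interval=dt,
        trace_id=trace_id,
        bleach_frame=bleach_frame,
    )


class TestBackground:
    def test_constant_offsets_subtracted(self):
        tr = make_trace([600.0] * 20, [600.0] * 20)
        out = correct_background(
            tr, "constant", {"donor_offset": 100, "acceptor_offset": 100}
        )
        np.testing.assert_allclose(out.donor, 500.0)
        np.testing.assert_allclose(out.acceptor, 500.0)
        assert out.provenance["background"]["donor_offset"] == 100

    def test_zero_offsets_identity(self):
        tr = make_trace([10.0, 20.0], [30.0, 40.0])
        out = correct_background(tr, "constant", {})
        np.testing.assert_array_equal(out.donor, tr.donor)

    def test_post_bleach_mean_recovers_known_backgrounds(self):
        rng = np.random.default_rng(4)
        n, bleach = 600, 400
        donor = np.where(np.arange(n) < bleach, 500.0, 0.0) + 80.0
        acceptor = np.where(np.arange(n) < bleach, 400.0, 0.0) + 120.0
        sd = 10.0
        donor = donor + rng.normal(0, sd, n)
        acceptor = acceptor + rng.normal(0, sd, n)
        tr = make_trace(donor, acceptor, bleach_frame=bleach)
        out = correct_background(tr, "post_bleach_mean")
        tol = 2 * sd / np.sqrt(n - bleach - 1)
        assert out.provenance["background"]["donor_offset"] == pytest.approx(80, abs=tol)
        assert out.provenance["background"]["acceptor_offset"] == pytest.approx(120, abs=tol)

    def test_post_bleach_requires_bleach_frame(self):
        tr = make_trace([500.0] * 30, [500.0] * 30)
        with pytest.raises(ValueError, match="bleach"):
            correct_background(tr, "post_bleach_mean")


class TestComputeFret:
    @pytest.mark.parametrize(
        "ia,id_,expected", [(500, 500, 0.5), (920, 80, 0.92)]
    )
    def test_direct_arithmetic(self, ia, id_, expected):
        ft = compute_fret(make_trace([id_] * 3, [ia] * 3))
        np.testing.assert_allclose(ft.efret, expected)

    def test_zero_total_masked_not_nan_propagated(self):
        ft = compute_fret(make_trace([0.0, 500.0], [0.0, 500.0]))
        assert not ft.valid_mask[0] and ft.valid_mask[1]
        assert ft.efret[1] == 0.5

    def test_artifact_window_masks_outliers(self):
        # E = 2.0 (artifact) must be masked, not clipped
        ft = compute_fret(make_trace([-500.0, 500.0], [1000.0, 500.0]))
        assert not ft.valid_mask[0]

    def test_post_bleach_frames_masked(self):
        tr = make_trace([500.0] * 30, [500.0] * 30, bleach_frame=10)
        ft = compute_fret(tr)
        assert ft.n_valid == 10

    def test_masking_never_changes_unmasked_values(self):
        tr = make_trace([500.0, 0.0, 250.0], [500.0, 0.0, 750.0])
        ft = compute_fret(tr)
        np.testing.assert_allclose(
            ft.efret[ft.valid_mask], [0.5, 0.75]
        )


class TestBleach:
    def test_step_found_within_one_frame(self, rng):
        n, step = 600, 400
        total = np.where(np.arange(n) < step, 1000.0, 200.0)
        half = total / 2 + rng.normal(0, 30, n)
        tr = make_trace(half, total - half + rng.normal(0, 30, n))
        found = detect_bleach(tr)
        assert found is not None and abs(found - step) <= 1

    def test_constant_trace_returns_none(self):
        tr = make_trace([500.0] * 100, [500.0] * 100)
        assert detect_bleach(tr) is None

    def test_two_steps_flagged_multi(self, rng):
        n = 600
        total = np.select(
            [np.arange(n) < 200, np.arange(n) < 400], [1200.0, 700.0], 200.0
        )
        half = total / 2 + rng.normal(0, 20, n)
        tr = make_trace(half, total - half + rng.normal(0, 20, n))
        steps = detect_bleach_steps(tr)
        assert len(steps) == 2
        assert abs(steps[0] - 200) <= 1 and abs(steps[1] - 400) <= 1

    def test_requires_20_frames(self):
        with pytest.raises(ValueError):
            detect_bleach(make_trace([1.0] * 10, [1.0] * 10))


class TestQC:
    def test_clean_static_trace_accepted(self):
        n = 600
        donor = np.full(n, 500.0)
        acceptor = np.full(n, 500.0)
        donor[400:] = 0.0
        acceptor[400:] = 0.0
        res = qc_select([make_trace(donor, acceptor, trace_id="good")])
        assert res.n_accepted == 1
        assert res.reasons["good"] == ""

    def test_short_trace_rejected(self):
        res = qc_select([make_trace([500.0] * 50, [500.0] * 50, trace_id="s")])
        assert res.reasons["s"] == "too_short"

    def test_common_mode_drift_rejected(self, rng):
        n = 600
        drift = np.linspace(200.0, 800.0, n)
        donor = drift + rng.normal(0, 5, n)
        acceptor = drift + rng.normal(0, 5, n)
        res = qc_select([make_trace(donor, acceptor, trace_id="drift")])
        assert res.reasons["drift"] == "not_anticorrelated"

    def test_genuine_fret_dynamics_accepted(self, small_two_state_dataset):
        res = qc_select(small_two_state_dataset.traces)
        # defaults pass nearly all synthetic traces at realistic SNR
        assert res.n_accepted >= 0.95 * len(small_two_state_dataset.traces)

    def test_qc_is_idempotent(self, small_two_state_dataset):
        first = qc_select(small_two_state_dataset.traces)
        second = qc_select(first.accepted)
        assert second.n_accepted == first.n_accepted
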