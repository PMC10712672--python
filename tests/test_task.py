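"""Press-without-break task: geometry, state machine, block structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoloop.controller import ControllerConfig
from myoloop.emg import InvalidParameterError
from myoloop.task import (
    BlockSpec,
    TrialMonitor,
    TrialSpec,
    default_target_catalog,
    force_window,
    index_of_difficulty,
)


@pytest.mark.parametrize("D, W, bits", [(1.0, 1.0, 1.0), (2.0, 1.0, 2.0),
                                        (8.0, 1.0, 4.0), (3.0, 3.0, 1.0)])
def test_index_of_difficulty(D, W, bits):
    assert index_of_difficulty(D, W) == pytest.approx(bits)


def test_index_of_difficulty_rejects_nonpositive():
    with pytest.raises(InvalidParameterError):
        index_of_difficulty(0.0, 1.0)
    with pytest.raises(InvalidParameterError):
        index_of_difficulty(1.0, -2.0)


def test_force_window_geometry():
    assert force_window(2.0, 1.0, 1.0) == (1.5, 2.5)
    f_min, f_max = force_window(3.0, 0.5, 1.0)
    assert 0.5 * (f_min + f_max) == pytest.approx(3.0)  # center = gain*D


def test_force_window_rejects_break_zone_overlap():
    with pytest.raises(InvalidParameterError):
        force_window(4.4, 0.5, 1.0)


def test_catalog_spans_ids_and_respects_break_margin():
    """Six targets, increasing difficulty; the hardest window's top is ~30%
    below the 4.4 N break threshold (4.4 / 1.3)."""
    catalog = default_target_catalog()
    assert len(catalog) == 6
    ids = [index_of_difficulty(d, w) for d, w in catalog]
    assert ids == sorted(ids)
    assert ids[0] == pytest.approx(1.5)
    assert ids[-1] == pytest.approx(4.0)
    tops = [force_window(d, w)[1] for d, w in catalog]
    assert all(t < 4.4 for t in tops)
    assert tops[-1] == pytest.approx(4.4 / 1.3, abs=0.01)


def test_trial_spec_invariants():
    with pytest.raises(InvalidParameterError):
        TrialSpec(D=2.0, W=1.0, f_min=2.5, f_max=1.5)
    with pytest.raises(InvalidParameterError):
        TrialSpec(D=4.0, W=1.0, f_min=3.5, f_max=4.5)
    spec = TrialSpec.from_geometry(2.0, 1.0)
    assert spec.id_bits == pytest.approx(2.0)
    assert (spec.f_min, spec.f_max) == (1.5, 2.5)


# ---------------------------------------------------------------------------
# trial state machine on scripted force traces
# ---------------------------------------------------------------------------

SPEC = TrialSpec.from_geometry(2.0, 1.0)  # window (1.5, 2.5), ID 2


def run_script(forces, spec=SPEC):
    mon = TrialMonitor(spec, control_rate=100.0)
    for f in forces:
        out = mon.update(float(f))
        if out is not None:
            return mon
    raise AssertionError("trial did not terminate")


def test_scripted_success_timing():
    """Contact at t=0.5 s, window entry at t=1.0 s, then hold: success with
    mt = 0.5 and ct = (entry - mt) + dwell = 1.5 s."""
    t = np.arange(1, 1501) * 0.01
    forces = np.where(t < 0.5, 0.0, np.where(t < 1.0, 1.0, 2.0))
    mon = run_script(forces)
    assert mon.outcome == "success"
    assert mon.mt == pytest.approx(0.5)
    assert mon.ct == pytest.approx(1.5, abs=0.011)


def test_scripted_break_is_immediate_and_threshold_inclusive():
    forces = [0.0] * 79 + [4.5]
    mon = run_script(forces)
    assert mon.outcome == "break"
    assert mon.peak_force >= 4.4
    exact = run_script([0.0, 4.4])
    assert exact.outcome == "break"
    below = TrialMonitor(SPEC)
    assert below.update(4.39) is None  # below threshold: trial continues


def test_break_preempts_final_dwell_tick():
    """Breaking on what would be the 100th in-window tick fails the trial."""
    forces = [2.0] * 99 + [4.6]
    mon = run_script(forces)
    assert mon.outcome == "break"


def test_scripted_oscillation_times_out():
    """In/out every 0.5 s: the dwell timer resets on each excursion and the
    trial times out at 15 s."""
    t = np.arange(1, 1501) * 0.01
    forces = np.where((t // 0.5) % 2 == 0, 2.0, 3.0)  # 3.0 is out of window
    mon = run_script(forces)
    assert mon.outcome == "timeout"
    assert math.isnan(mon.ct)


def test_dwell_requires_continuous_run():
    # 99 in-window ticks, one excursion, then 99 more: no success yet
    mon = TrialMonitor(SPEC)
    for f in [2.0] * 99 + [1.0] + [2.0] * 99:
        assert mon.update(f) is None
    assert mon.update(2.0) == "success"  # the 100th consecutive tick


@given(st.lists(st.floats(0.0, 6.0), min_size=1, max_size=200))
@settings(max_examples=60, deadline=None)
def test_outcome_trichotomy(forces):
    """Every terminated trial ends in exactly one outcome, with the outcome's
    defining evidence present in the trace."""
    spec = TrialSpec.from_geometry(2.0, 1.0, timeout=1.0)
    mon = TrialMonitor(spec, control_rate=100.0)
    outcome = None
    for f in forces:
        outcome = mon.update(f)
        if outcome is not None:
            break
    if outcome is None:
        return  # trial still running; nothing to assert
    assert outcome in ("success", "break", "timeout")
    if outcome == "break":
        assert mon.peak_force >= spec.break_threshold
    if outcome == "success":
        # ct and mt are sample timestamps: when the very first contact
        # sample is already in-window, ct = dwell - dt
        assert mon.ct >= spec.dwell - 0.01 - 1e-9


# ---------------------------------------------------------------------------
# block structure
# ---------------------------------------------------------------------------


def test_block_order_is_seeded_permutation_of_ids_times_reps():
    block = BlockSpec(condition=ControllerConfig("linear", "proportional"),
                      seed=11)
    order = block.trial_order()
    assert len(order) == 36
    counts = {i: order.count(i) for i in range(6)}
    assert all(c == 6 for c in counts.values())
    assert order == block.trial_order()  # deterministic
    other = BlockSpec(condition=block.condition, seed=12).trial_order()
    assert other != order  # different seed, different permutation
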