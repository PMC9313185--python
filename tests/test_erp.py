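"""Epoch conditioning, component amplitudes and electrode selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from erpstate.erp import (
    DEFAULT_WINDOWS,
    ComponentWindow,
    EpochSet,
    SelectionResult,
    amplitude_table,
    average_trials,
    baseline_correct,
    component_amplitudes,
    region_tally,
    rereference_average,
    select_electrodes,
)


def make_epochs(trials, fs=1000.0, t0=-200.0, channels=None):
    trials = np.asarray(trials, dtype=float)
    channels = channels or [f"c{i}" for i in range(trials.shape[1])]
    return EpochSet("s0", "comfort", trials, fs, t0, channels)


def test_rereference_zeroes_channel_mean():
    rng = np.random.default_rng(0)
    ep = make_epochs(rng.normal(size=(4, 3, 300)))
    out = rereference_average(ep)
    assert np.allclose(out.trials.mean(axis=1), 0.0, atol=1e-12)
    # idempotent
    again = rereference_average(out)
    assert np.allclose(again.trials, out.trials, atol=1e-12)


def test_rereference_hand_example():
    ep = make_epochs(np.array([[[3.0], [1.0]]]), t0=-0.5)
    out = rereference_average(ep)
    assert np.allclose(out.trials[0, :, 0], [1.0, -1.0])


def test_rereference_needs_two_channels():
    with pytest.raises(ValueError):
        rereference_average(make_epochs(np.zeros((1, 1, 10))))


def test_baseline_correct_definition():
    rng = np.random.default_rng(1)
    ep = make_epochs(rng.normal(size=(3, 2, 300)))
    out = baseline_correct(ep)
    t = out.times_ms
    base = out.trials[:, :, (t >= -200) & (t < 0)]
    assert np.allclose(base.mean(axis=2), 0.0, atol=1e-12)
    # constant signal vanishes entirely
    const = make_epochs(np.full((2, 2, 300), 7.0))
    assert np.allclose(baseline_correct(const).trials, 0.0, atol=1e-12)


def test_baseline_hand_example():
    # two baseline samples 1 and 3, one post-onset sample 10 -> 10 - 2 = 8
    ep = make_epochs(np.array([[[1.0, 3.0, 10.0]]] ).repeat(2, axis=1), fs=1000.0, t0=-2.0)
    out = baseline_correct(ep)
    assert np.allclose(out.trials[0, :, 2], 8.0)


def test_baseline_window_must_be_prestim():
    ep = make_epochs(np.zeros((1, 2, 300)))
    with pytest.raises(ValueError):
        baseline_correct(ep, baseline_start_ms=-500.0)


def test_average_trials():
    ep = make_epochs(np.stack([np.full((2, 10), 2.0), np.full((2, 10), 4.0)]), t0=-2.0)
    erp = average_trials(ep)
    assert np.allclose(erp.erp, 3.0)
    same = make_epochs(np.repeat(np.arange(20.0).reshape(1, 2, 10), 3, axis=0), t0=-2.0)
    assert np.allclose(average_trials(same).erp, same.trials[0])


def test_preprocessing_invariant_to_trial_order():
    rng = np.random.default_rng(2)
    trials = rng.normal(size=(6, 3, 300))
    a = average_trials(baseline_correct(rereference_average(make_epochs(trials))))
    b = average_trials(
        baseline_correct(rereference_average(make_epochs(trials[::-1].copy())))
    )
    assert np.allclose(a.erp, b.erp, atol=1e-12)


def test_component_window_sample_count():
    """fs=1000, window [90, 130) -> exactly the 40 samples at 90..129 ms."""
    ep = make_epochs(np.zeros((1, 1, 1200)), fs=1000.0, t0=-200.0)
    erp = average_trials(ep)
    erp.erp[0, :] = 0.0
    t = erp.times_ms
    erp.erp[0, (t >= 90) & (t < 130)] = 1.0
    amps = component_amplitudes(erp, [ComponentWindow("P1", 90.0, 130.0)])
    assert np.isclose(amps[("c0", "P1")], 1.0)
    assert int(((t >= 90) & (t < 130)).sum()) == 40


def test_component_amplitudes_constant_and_linearity():
    ep = make_epochs(np.full((1, 2, 600), 3.14), fs=1000.0)
    amps = component_amplitudes(average_trials(ep))
    assert np.allclose(amps.to_numpy(), 3.14)
    rng = np.random.default_rng(3)
    e1 = average_trials(make_epochs(rng.normal(size=(1, 2, 600)), fs=1000.0))
    e2 = average_trials(make_epochs(rng.normal(size=(1, 2, 600)), fs=1000.0))
    a1, a2 = component_amplitudes(e1), component_amplitudes(e2)
    e3 = average_trials(
        make_epochs((2.0 * e1.erp - 0.5 * e2.erp)[None], fs=1000.0)
    )
    a3 = component_amplitudes(e3)
    assert np.allclose(a3.to_numpy(), 2.0 * a1.to_numpy() - 0.5 * a2.to_numpy(), atol=1e-10)


def test_window_without_samples_rejected():
    ep = make_epochs(np.zeros((1, 1, 300)), fs=10.0, t0=-200.0)
    erp = average_trials(ep)
    with pytest.raises(ValueError, match="no samples"):
        component_amplitudes(erp, [ComponentWindow("x", 90.0, 91.0)])


def _amp_tables(diff_channel=None, shift=0.0, n_subjects=20, seed=4):
    """Paired amplitude tables with a known shift on one channel's P1."""
    rng = np.random.default_rng(seed)
    channels = [f"c{i}" for i in range(5)]
    cols = pd.MultiIndex.from_product(
        [channels, [w.name for w in DEFAULT_WINDOWS]], names=["channel", "window"]
    )
    base = rng.normal(size=(n_subjects, len(cols)))
    a = pd.DataFrame(base + rng.normal(0, 1, size=base.shape), columns=cols,
                     index=[f"s{i}" for i in range(n_subjects)])
    b = pd.DataFrame(base + rng.normal(0, 1, size=base.shape), columns=cols,
                     index=a.index)
    if diff_channel is not None:
        b[(diff_channel, "P1")] += shift
    return a, b


def test_select_no_effect_and_identical_tables():
    a, _ = _amp_tables()
    res = select_electrodes(a, a.copy(), alpha=0.05)
    assert res.selected == []
    assert (res.per_window["flag"] if "flag" in res.per_window else ~res.per_window["selected"]).all()


def test_select_detects_large_shift():
    # shift of 5 between-subject sds on c2's P1 window
    a, b = _amp_tables(diff_channel="c2", shift=5.0 * np.sqrt(2.0))
    res = select_electrodes(a, b, alpha=0.05)
    assert "c2" in res.selected
    d = (a - b)[("c2", "P1")].to_numpy()
    t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    row = res.per_window.loc[("c2", "P1")]
    assert np.isclose(row["t"], t_manual, atol=1e-10)
    assert abs(t_manual) > sps.t.ppf(0.975, len(d) - 1)


def test_select_requires_matching_subjects():
    a, b = _amp_tables()
    with pytest.raises(ValueError, match="subject"):
        select_electrodes(a, b.iloc[::-1], alpha=0.05)


def test_region_tally_counts_and_partition():
    sel = SelectionResult(
        selected=["c0", "c1", "c2", "c3", "c4"],
        per_window=pd.DataFrame(),
        alpha=0.05,
    )
    rm = {"c0": "F", "c1": "F", "c2": "F", "c3": "P", "c4": "O", "c5": "T"}
    counts = region_tally(sel, rm)
    assert counts == {"F": 3, "P": 1, "O": 1, "T": 0}
    assert sum(counts.values()) == len(sel.selected)
    empty = SelectionResult(selected=[], per_window=pd.DataFrame(), alpha=0.05)
    assert sum(region_tally(empty, rm).values()) == 0
    with pytest.raises(ValueError, match="region"):
        region_tally(SelectionResult(["zz"], pd.DataFrame(), 0.05), rm)


def test_amplitude_table_stacks_subjects():
    rng = np.random.default_rng(5)
    erps = {
        f"s{i}": average_trials(make_epochs(rng.normal(size=(2, 3, 600)), fs=1000.0))
        for i in range(4)
    }
    tab = amplitude_table(erps)
    assert tab.shape == (4, 3 * 4)
    assert list(tab.index) == ["s0", "s1", "s2", "s3"]
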