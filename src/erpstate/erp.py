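"""Epoch conditioning, trial averaging and ERP component analysis.

An epoch is a channels x time slice around a stimulus, an ERP its
trial average.  Component amplitudes are means over fixed post-stimulus
latency windows (P1, early N1, late N1, P3 by default); electrodes whose
amplitudes differ between two conditions in any window (paired t-test
across subjects, uncorrected) form the channel subset passed to the
state model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "ERPSet",
    "ComponentWindow",
    "DEFAULT_WINDOWS",
    "SelectionResult",
    "rereference_average",
    "baseline_correct",
    "average_trials",
    "component_amplitudes",
    "select_electrodes",
    "region_tally",
]


@dataclass
class EpochSet:
    """Single-subject, single-condition stack of trial epochs.

    trials : (n_trials, M, T) array; t0_ms is the time of the first sample
    relative to stimulus onset (negative = pre-stimulus).
    """

    subject: str
    condition: str
    trials: np.ndarray
    fs: float
    t0_ms: float
    channels: list[str]

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, M, T)")
        if self.trials.shape[1] != len(self.channels):
            raise ValueError("channel labels do not match trial channel axis")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.t0_ms + self.trials.shape[2] * 1000.0 / self.fs <= 0:
            raise ValueError("epoch must span past stimulus onset (0 ms)")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.trials.shape[2]) * 1000.0 / self.fs


@dataclass
class ERPSet:
    """Trial-averaged response: erp is (M, T)."""

    subject: str
    condition: str
    erp: np.ndarray
    fs: float
    t0_ms: float
    channels: list[str]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.erp.shape[1]) * 1000.0 / self.fs


@dataclass(frozen=True)
class ComponentWindow:
    """Post-stimulus latency window [start_ms, end_ms) for one ERP component."""

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not (0 <= self.start_ms < self.end_ms):
            raise ValueError("need 0 <= start_ms < end_ms")


#: The classical visual components: P1, early N1, late N1, P3.
DEFAULT_WINDOWS = (
    ComponentWindow("P1", 90.0, 130.0),
    ComponentWindow("earlyN1", 100.0, 140.0),
    ComponentWindow("lateN1", 180.0, 220.0),
    ComponentWindow("P3", 280.0, 320.0),
)


@dataclass
class SelectionResult:
    selected: list[str]  # channel labels, input order
    per_window: pd.DataFrame  # index (channel, window): t, p, selected
    alpha: float


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference every sample to the instantaneous mean across channels."""
    if epochs.trials.shape[1] < 2:
        raise ValueError("average reference needs at least 2 channels")
    ref = epochs.trials.mean(axis=1, keepdims=True)
    return replace(epochs, trials=epochs.trials - ref)


def baseline_correct(
    epochs: EpochSet,
    baseline_start_ms: float | None = None,
    baseline_end_ms: float = 0.0,
) -> EpochSet:
    """Subtract each trial's and channel's mean over the pre-stimulus
    baseline window [baseline_start_ms, baseline_end_ms)."""
    start = epochs.t0_ms if baseline_start_ms is None else baseline_start_ms
    t = epochs.times_ms
    if start < epochs.t0_ms - 1e-9 or baseline_end_ms > 1e-9:
        raise ValueError("baseline window must lie within [t0_ms, 0]")
    mask = (t >= start - 1e-9) & (t < baseline_end_ms - 1e-9)
    if not np.any(mask):
        raise ValueError("baseline window contains no samples")
    base = epochs.trials[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, trials=epochs.trials - base)


def average_trials(epochs: EpochSet) -> ERPSet:
    """The ERP: element-wise mean across the trial axis."""
    if epochs.trials.shape[0] < 1:
        raise ValueError("empty trial stack")
    return ERPSet(
        subject=epochs.subject,
        condition=epochs.condition,
        erp=epochs.trials.mean(axis=0),
        fs=epochs.fs,
        t0_ms=epochs.t0_ms,
        channels=list(epochs.channels),
    )


def component_amplitudes(erp: ERPSet, windows=DEFAULT_WINDOWS) -> pd.Series:
    """Mean ERP amplitude per channel per component window.

    Returns a Series indexed by (channel, window name).  A window's samples
    are those with start_ms <= t < end_ms, t = t0_ms + index * 1000 / fs.
    """
    t = erp.times_ms
    out = {}
    for w in windows:
        mask = (t >= w.start_ms - 1e-9) & (t < w.end_ms - 1e-9)
        if not np.any(mask):
            raise ValueError(f"window {w.name} ({w.start_ms}-{w.end_ms} ms) has no samples")
        vals = erp.erp[:, mask].mean(axis=1)
        for ch, v in zip(erp.channels, vals):
            out[(ch, w.name)] = v
    idx = pd.MultiIndex.from_tuples(out.keys(), names=["channel", "window"])
    return pd.Series(list(out.values()), index=idx, name="amplitude")


def amplitude_table(erps: dict, windows=DEFAULT_WINDOWS) -> pd.DataFrame:
    """Stack per-subject component amplitudes: rows = subjects, columns =
    (channel, window).  ``erps`` maps subject -> ERPSet (one condition)."""
    rows = {s: component_amplitudes(e, windows) for s, e in erps.items()}
    return pd.DataFrame(rows).T.sort_index()


def select_electrodes(
    amps_a: pd.DataFrame, amps_b: pd.DataFrame, alpha: float = 0.05
) -> SelectionResult:
    """Electrodes with a significant condition difference in any window.

    amps_a / amps_b: subject x (channel, window) amplitude tables for the
    two conditions, identical indexing.  Per cell a two-sided paired t-test
    across subjects is run on a - b; a channel is selected if any of its
    windows has p < alpha.  No multiple-comparison correction is applied.
    Cells with identically zero differences are flagged degenerate and
    never selected.
    """
    if not amps_a.index.equals(amps_b.index):
        raise ValueError("subject sets of the two amplitude tables differ")
    if not amps_a.columns.equals(amps_b.columns):
        raise ValueError("channel/window columns of the two tables differ")
    if len(amps_a) < 3:
        raise ValueError("need at least 3 subjects for the paired t-test")
    diff = amps_a - amps_b
    records = []
    channels = list(dict.fromkeys(amps_a.columns.get_level_values(0)))
    for col in amps_a.columns:
        d = diff[col].to_numpy()
        if np.allclose(d, 0.0):
            logger.warning("degenerate cell %s: all paired differences are zero", col)
            records.append((*col, 0.0, 1.0, False))
            continue
        t, p = sps.ttest_rel(amps_a[col], amps_b[col])
        records.append((*col, float(t), float(p), bool(p < alpha)))
    per_window = pd.DataFrame(
        records, columns=["channel", "window", "t", "p", "selected"]
    ).set_index(["channel", "window"])
    sel_set = set(per_window.index[per_window["selected"]].get_level_values(0))
    selected = [ch for ch in channels if ch in sel_set]
    return SelectionResult(selected=selected, per_window=per_window, alpha=alpha)


def region_tally(selection: SelectionResult, region_map: dict) -> dict:
    """Counts of selected electrodes per scalp region (e.g. F/T/P/O).

    Every region in the map appears in the output, including zero counts;
    a selected channel missing from the map is an error.
    """
    counts = {r: 0 for r in dict.fromkeys(region_map.values())}
    for ch in selection.selected:
        if ch not in region_map:
            raise ValueError(f"selected channel {ch!r} has no region assignment")
        counts[region_map[ch]] += 1
    return counts
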