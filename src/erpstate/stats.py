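"""Within-subject group inference for the two-condition state analysis.

Everything here reduces to one-sample t-tests on per-subject contrasts,
which is exact for all-within designs with two levels per factor: a
2x2x2 repeated-measures ANOVA effect with 1 numerator df is the squared
paired t of the corresponding contrast, so each of the seven effects
(three mains, three two-way interactions, one three-way interaction) and
every simple effect is computed in closed form.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TTestResult",
    "paired_t",
    "exclude_incomplete",
    "rm_anova_222",
    "simple_effect",
    "simple_effects",
    "EFFECT_NAMES",
]

FACTORS = ("condition", "state", "period")
EFFECT_NAMES = (
    "condition",
    "state",
    "period",
    "condition x state",
    "condition x period",
    "state x period",
    "condition x state x period",
)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int
    flag: str = ""  # "", "degenerate-zero", "degenerate-infinite"

    @property
    def F(self) -> float:
        return self.t**2


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y.

    Zero-variance differences are flagged rather than raised: all-zero d
    gives t = 0, p = 1 ("degenerate-zero"); constant nonzero d gives an
    infinite t with p = 0 ("degenerate-infinite").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays (paired by subject)")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    m = d.mean()
    s = d.std(ddof=1)
    df = n - 1
    if s == 0.0:
        if m == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0, n, "degenerate-zero")
        return TTestResult(np.inf if m > 0 else -np.inf, df, 0.0, m, n, "degenerate-infinite")
    t = m / (s / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), float(m), n)


def exclude_incomplete(
    metrics: pd.DataFrame, required_states, per_period: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Drop subjects lacking any required state, mirroring the exclusion of
    subjects that never exhibit a state of interest.

    By default a subject is dropped when a required state is absent
    (``present`` False, i.e. never visited) in either condition; with
    ``per_period=True`` the stricter rule applies: absence from either the
    early or the late period of any condition also excludes the subject.
    Returns (filtered table, excluded subject list).
    """
    required = list(required_states)
    excluded = []
    for subj, grp in metrics.groupby("subject", sort=False):
        bad = False
        for k in required:
            sub = grp[grp["state"] == k]
            if not sub["present"].all():
                bad = True
            if per_period and ((sub["fraction_early"] == 0).any() or (sub["fraction_late"] == 0).any()):
                bad = True
        if bad:
            excluded.append(subj)
            logger.info("excluding subject %s: required state(s) %s not exhibited", subj, required)
    out = metrics[~metrics["subject"].isin(excluded)].reset_index(drop=True)
    if required and out["subject"].nunique() < 3:
        raise ValueError("fewer than 3 subjects remain after exclusion")
    return out, excluded


def _contrast(cells: np.ndarray, effect_factors: tuple[int, ...]) -> np.ndarray:
    """Per-subject contrast score for an effect of a 2x2x2 within design.

    cells is (n, 2, 2, 2) ordered (condition, state, period).  Factors in
    the effect get weights (+1, -1); the others are averaged (1/2, 1/2).
    """
    w = np.ones((2, 2, 2))
    for axis in range(3):
        sign = np.array([1.0, -1.0]) if axis in effect_factors else np.array([0.5, 0.5])
        shape = [1, 1, 1]
        shape[axis] = 2
        w = w * sign.reshape(shape)
    return np.einsum("nijk,ijk->n", cells, w)


def rm_anova_222(cells: np.ndarray, factor_names=FACTORS) -> pd.DataFrame:
    """All seven effects of a 2x2x2 all-within repeated-measures ANOVA.

    cells : (n_subjects, 2, 2, 2), axes ordered as ``factor_names``.
    Each effect is the squared paired t of its within-subject contrast:
    F = t^2 with df (1, n-1).  Returns a DataFrame with columns effect,
    F, df1, df2, p, t, flag.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 4 or cells.shape[1:] != (2, 2, 2):
        raise ValueError("cells must be (n_subjects, 2, 2, 2)")
    if np.isnan(cells).any():
        bad = np.argwhere(np.isnan(cells))[0]
        raise ValueError(f"missing cell for subject {bad[0]}, cell index {tuple(bad[1:])}")
    n = cells.shape[0]
    rows = []
    for r in range(1, 4):
        for combo in itertools.combinations(range(3), r):
            c = _contrast(cells, combo)
            res = paired_t(c, np.zeros(n))
            name = " x ".join(factor_names[i] for i in combo)
            F = res.t**2 if np.isfinite(res.t) else np.inf
            rows.append(
                {
                    "effect": name,
                    "F": F,
                    "df1": 1,
                    "df2": res.df,
                    "p": res.p,
                    "t": res.t,
                    "flag": res.flag,
                }
            )
    order = {name: i for i, name in enumerate(EFFECT_NAMES)}
    df = pd.DataFrame(rows)
    df["__o"] = df["effect"].map(lambda e: order.get(e, 99))
    return df.sort_values("__o").drop(columns="__o").reset_index(drop=True)


def simple_effect(cells: np.ndarray, factor: str, fixed: dict, factor_names=FACTORS) -> TTestResult:
    """Paired comparison of the two levels of ``factor`` with the other two
    factors held at the levels given in ``fixed`` (factor name -> level
    index 0/1).  Reported downstream as F = t^2 with df (1, n-1)."""
    cells = np.asarray(cells, dtype=float)
    axes = {name: i for i, name in enumerate(factor_names)}
    if factor not in axes:
        raise ValueError(f"unknown factor {factor!r}")
    if set(fixed) != set(factor_names) - {factor}:
        raise ValueError(f"fixed must give levels for exactly the other two factors")
    idx_hi = [slice(None)] * 4
    idx_lo = [slice(None)] * 4
    idx_hi[1 + axes[factor]] = 0
    idx_lo[1 + axes[factor]] = 1
    for name, lev in fixed.items():
        idx_hi[1 + axes[name]] = lev
        idx_lo[1 + axes[name]] = lev
    return paired_t(cells[tuple(idx_hi)], cells[tuple(idx_lo)])


def simple_effects(cells: np.ndarray, factor_names=FACTORS) -> pd.DataFrame:
    """All 12 simple effects (each factor at each combination of the other
    two factors' levels), as F = t^2 rows."""
    rows = []
    for factor in factor_names:
        others = [f for f in factor_names if f != factor]
        for lev_a in (0, 1):
            for lev_b in (0, 1):
                fixed = {others[0]: lev_a, others[1]: lev_b}
                res = simple_effect(cells, factor, fixed, factor_names)
                rows.append(
                    {
                        "factor": factor,
                        **{f"{k}_level": v for k, v in fixed.items()},
                        "F": res.t**2 if np.isfinite(res.t) else np.inf,
                        "df1": 1,
                        "df2": res.df,
                        "p": res.p,
                        "t": res.t,
                        "mean_diff": res.mean_diff,
                        "flag": res.flag,
                    }
                )
    return pd.DataFrame(rows)
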