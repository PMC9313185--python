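"""End-to-end orchestration: simulate/load -> ERP -> select -> HMM per
condition -> match states -> temporal metrics -> group statistics.

The two conditions are fitted separately with the same restart seeds, the
second fit's states are relabelled onto the first's by connectivity
similarity, and the "weak"/"strong" connectivity states are identified on
the reference (comfort) fit as the states with the smallest / largest mean
absolute off-diagonal correlation.  All randomness derives from the single
configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import erp as erp_mod
from . import metrics as met
from . import stats as st
from .erp import DEFAULT_WINDOWS, ComponentWindow, SelectionResult
from .hmm import FitResult, fc_matrix, fit_hmm
from .io import TrialDataset
from .synth import ComponentEffect, SynthConfig, build_ground_truth, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report", "truth_from_config"]


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the reference analysis values
    (K=4 states, 20 restarts, alpha=0.05, 1100 ms split, 512 Hz epochs
    from -200 to +3000 ms)."""

    seed: int = 0
    # preprocessing
    rereference: bool = True
    baseline_start_ms: float | None = None  # None = epoch start
    baseline_end_ms: float = 0.0
    # electrode selection
    alpha: float = 0.05
    windows: tuple = DEFAULT_WINDOWS
    region_map: dict | None = None
    # hmm
    n_states: int = 4
    n_restarts: int = 20
    tol: float = 1e-6
    max_iter: int = 500
    post_onset_only: bool = True
    standardize: bool = True
    # metrics
    split_ms: float = 1100.0
    timecourse_mode: str = "posterior-mean"
    # synthesis (used when no dataset is supplied)
    synth: SynthConfig = field(default_factory=SynthConfig)
    truth: dict = field(default_factory=lambda: {"K": 4, "M": 8, "seed": 0})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "windows" in d:
            d["windows"] = tuple(
                ComponentWindow(w["name"], w["start_ms"], w["end_ms"]) for w in d["windows"]
            )
        if "synth" in d and not isinstance(d["synth"], SynthConfig):
            d["synth"] = SynthConfig(**d["synth"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = [dataclasses.asdict(w) for w in self.windows]
        return d


def truth_from_config(config: PipelineConfig):
    """Ground-truth model from the config's ``truth`` block (K, M, seed plus
    any keyword accepted by :func:`erpstate.synth.build_ground_truth`)."""
    t = dict(config.truth)
    if "component_effect" in t and isinstance(t["component_effect"], dict):
        t["component_effect"] = ComponentEffect(**t["component_effect"])
    K = t.pop("K", 4)
    M = t.pop("M", 8)
    seed = t.pop("seed", config.seed)
    return build_ground_truth(K, M, seed, **t)


@dataclass
class PipelineResult:
    config: PipelineConfig
    selection: SelectionResult
    region_counts: dict | None
    fits: dict  # condition -> FitResult
    matching: met.StateMatching
    weak_state: int
    strong_state: int
    metrics: pd.DataFrame
    timecourses: dict  # condition -> (K, T) array, reference labels
    anova: pd.DataFrame
    simple: pd.DataFrame
    ttests: pd.DataFrame
    excluded: list
    n_used: int
    conditions: list
    hmm_channels: list
    truth_bundle: dict | None = None
    warnings_log: list = field(default_factory=list)


def _prepare_sequences(erps, subjects, condition, channels_sel, config, fs):
    """Selected-channel, optionally post-onset, optionally z-scored ERP
    sequences in a fixed subject order."""
    seqs = []
    for subj in subjects:
        e = erps[(subj, condition)]
        idx = [e.channels.index(ch) for ch in channels_sel]
        Y = e.erp[idx]
        if config.post_onset_only:
            Y = Y[:, e.times_ms >= -1e-9]
        if config.standardize:
            sd = Y.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                raise ValueError(f"subject {subj}: constant channel cannot be standardized")
            Y = (Y - Y.mean(axis=1, keepdims=True)) / sd
        seqs.append(Y)
    return seqs


def run_pipeline(config: PipelineConfig, dataset: TrialDataset | None = None) -> PipelineResult:
    """Run every stage on ``dataset`` (simulated from the config when None)."""
    truth_bundle = None
    if dataset is None:
        truth = truth_from_config(config)
        dataset, truth_bundle = generate_study(config.synth, truth)
        logger.info("simulated study: %d subjects, %d channels", config.synth.n_subjects, truth.M)

    conditions = list(dataset.conditions)
    if len(conditions) != 2:
        raise ValueError(f"pipeline expects exactly 2 conditions, got {conditions}")
    ref_cond, alt_cond = conditions
    subjects = list(dataset.subjects)

    # --- ERP stage ------------------------------------------------------
    erps = {}
    for key, ep in dataset.epochs.items():
        if config.rereference:
            ep = erp_mod.rereference_average(ep)
        ep = erp_mod.baseline_correct(ep, config.baseline_start_ms, config.baseline_end_ms)
        erps[key] = erp_mod.average_trials(ep)

    tabs = {
        cond: erp_mod.amplitude_table(
            {s: erps[(s, cond)] for s in subjects}, config.windows
        )
        for cond in conditions
    }
    selection = erp_mod.select_electrodes(tabs[ref_cond], tabs[alt_cond], config.alpha)
    if len(selection.selected) < 2:
        raise RuntimeError(
            f"electrode selection found {len(selection.selected)} channel(s); the "
            "connectivity analysis needs at least 2. Raise alpha or increase the "
            "effect size / subject count"
        )
    region_counts = (
        erp_mod.region_tally(selection, config.region_map) if config.region_map else None
    )

    # --- HMM stage (per condition, shared restart seeds) ----------------
    fs = dataset.fs
    t_origin = 0.0 if config.post_onset_only else dataset.t0_ms
    fits: dict[str, FitResult] = {}
    for cond in conditions:
        seqs = _prepare_sequences(erps, subjects, cond, selection.selected, config, fs)
        fits[cond] = fit_hmm(
            seqs,
            K=config.n_states,
            n_restarts=config.n_restarts,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=config.seed,
        )

    # --- state identity across fits -------------------------------------
    ref_params = fits[ref_cond].params
    offdiag = [
        np.abs(fc_matrix(ref_params, k, "correlation"))[~np.eye(ref_params.M, dtype=bool)].mean()
        for k in range(ref_params.K)
    ]
    weak_state = int(np.argmin(offdiag))
    strong_state = int(np.argmax(offdiag))
    matching = met.match_states(ref_params, fits[alt_cond].params)

    paths = {}
    gammas = {}
    for i, subj in enumerate(subjects):
        paths[(subj, ref_cond)] = fits[ref_cond].paths[i]
        g = fits[ref_cond].posteriors.gammas[i]
        gammas[(subj, ref_cond)] = g
        p_alt = matching.relabel(fits[alt_cond].paths[i])
        paths[(subj, alt_cond)] = p_alt
        g_alt = fits[alt_cond].posteriors.gammas[i]
        g_re = np.empty_like(g_alt)
        g_re[:, matching.perm] = g_alt
        gammas[(subj, alt_cond)] = g_re

    # --- temporal metrics ------------------------------------------------
    metrics = met.state_metrics_table(paths, config.n_states, config.split_ms, fs, t_origin)
    timecourses = {}
    for cond in conditions:
        if config.timecourse_mode == "posterior-mean":
            items = [gammas[(s, cond)] for s in subjects]
        else:
            items = [paths[(s, cond)] for s in subjects]
        timecourses[cond] = met.occupancy_timecourse(
            items, config.timecourse_mode, K=config.n_states
        )

    # --- group statistics -------------------------------------------------
    kept, excluded = st.exclude_incomplete(metrics, [strong_state, weak_state])
    kept_subjects = [s for s in subjects if s not in excluded]
    n = len(kept_subjects)
    cells = np.empty((n, 2, 2, 2))
    tab = kept.set_index(["subject", "condition", "state"])
    for i, subj in enumerate(kept_subjects):
        for ci, cond in enumerate(conditions):
            for si, state in enumerate((strong_state, weak_state)):
                row = tab.loc[(subj, cond, state)]
                cells[i, ci, si, 0] = row["fraction_early"]
                cells[i, ci, si, 1] = row["fraction_late"]
    anova = st.rm_anova_222(cells)
    simple = st.simple_effects(cells)

    trows = []
    overall = kept.set_index(["subject", "condition", "state"])
    for state in range(config.n_states):
        for col in ("fraction", "dwell_samples"):
            x = np.array([overall.loc[(s, ref_cond, state), col] for s in kept_subjects])
            y = np.array([overall.loc[(s, alt_cond, state), col] for s in kept_subjects])
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            res = st.paired_t(x[ok], y[ok])
            trows.append(
                {
                    "measure": col,
                    "state": state,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "mean_diff": res.mean_diff,
                    "n": res.n,
                    "flag": res.flag,
                }
            )
    ttests = pd.DataFrame(trows)

    return PipelineResult(
        config=config,
        selection=selection,
        region_counts=region_counts,
        fits=fits,
        matching=matching,
        weak_state=weak_state,
        strong_state=strong_state,
        metrics=metrics,
        timecourses=timecourses,
        anova=anova,
        simple=simple,
        ttests=ttests,
        excluded=excluded,
        n_used=n,
        conditions=conditions,
        hmm_channels=list(selection.selected),
        truth_bundle=truth_bundle,
    )


def _fit_to_json(fit: FitResult, channels, fs) -> dict:
    p = fit.params
    return {
        "K": p.K,
        "M": p.M,
        "pi": p.pi.tolist(),
        "A": p.A.tolist(),
        "mu": p.mu.tolist(),
        "Sigma": p.Sigma.tolist(),
        "loglik_trace": np.asarray(fit.loglik_trace).tolist(),
        "restart_index": int(fit.restart_index),
        "seed": int(fit.seed_used),
        "channels": list(channels),
        "fs": fs,
    }


def write_report(result: PipelineResult, out_dir) -> dict:
    """Write the report bundle; returns {artifact name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    sel = result.selection.per_window.reset_index()
    if result.config.region_map:
        sel["region"] = sel["channel"].map(result.config.region_map)
    files["selection.csv"] = out / "selection.csv"
    sel.to_csv(files["selection.csv"], index=False)

    for cond in result.conditions:
        name = f"fit_{cond}.json"
        files[name] = out / name
        files[name].write_text(
            json.dumps(_fit_to_json(result.fits[cond], result.hmm_channels, None))
        )

    files["matching.json"] = out / "matching.json"
    files["matching.json"].write_text(
        json.dumps(
            {
                "perm": result.matching.perm.tolist(),
                "similarity": result.matching.similarity.tolist(),
                "weak_state": result.weak_state,
                "strong_state": result.strong_state,
                "reference_condition": result.conditions[0],
            },
            indent=1,
        )
    )

    files["metrics.csv"] = out / "metrics.csv"
    result.metrics.to_csv(files["metrics.csv"], index=False)

    tc_frames = []
    for cond, tc in result.timecourses.items():
        df = pd.DataFrame(tc.T, columns=[f"{cond}_state{k}" for k in range(tc.shape[0])])
        tc_frames.append(df)
    files["timecourse.tsv"] = out / "timecourse.tsv"
    pd.concat(tc_frames, axis=1).to_csv(files["timecourse.tsv"], sep="\t", index_label="t_index")

    rows = []
    for _, r in result.anova.iterrows():
        rows.append(
            {
                "analysis": "anova",
                "effect": r["effect"],
                "statistic": r["F"],
                "df1": r["df1"],
                "df2": r["df2"],
                "p": r["p"],
                "n": result.n_used,
                "flag": r["flag"],
            }
        )
    level_names = {
        "state": {0: "strong", 1: "weak"},
        "condition": {0: result.conditions[0], 1: result.conditions[1]},
        "period": {0: "early", 1: "late"},
    }
    for _, r in result.simple.iterrows():
        fixed = {k[:-6]: int(v) for k, v in r.items() if k.endswith("_level") and pd.notna(v)}
        desc = ", ".join(f"{k}={level_names[k][v]}" for k, v in fixed.items())
        rows.append(
            {
                "analysis": "simple",
                "effect": f"{r['factor']} | {desc}",
                "statistic": r["F"],
                "df1": r["df1"],
                "df2": r["df2"],
                "p": r["p"],
                "n": result.n_used,
                "flag": r["flag"],
            }
        )
    for _, r in result.ttests.iterrows():
        rows.append(
            {
                "analysis": "ttest",
                "effect": f"{r['measure']} state {int(r['state'])}",
                "statistic": r["t"],
                "df1": np.nan,
                "df2": r["df"],
                "p": r["p"],
                "n": r["n"],
                "flag": r["flag"],
            }
        )
    files["stats.csv"] = out / "stats.csv"
    pd.DataFrame(rows).to_csv(files["stats.csv"], index=False)

    files["run_log.json"] = out / "run_log.json"
    files["run_log.json"].write_text(
        json.dumps(
            {
                "config": result.config.echo(),
                "excluded_subjects": result.excluded,
                "n_used": result.n_used,
                "hmm_channels": result.hmm_channels,
                "weak_state": result.weak_state,
                "strong_state": result.strong_state,
                "region_counts": result.region_counts,
                "restart_logliks": {
                    c: np.asarray(result.fits[c].restart_logliks).tolist()
                    for c in result.conditions
                },
                "warnings": result.warnings_log,
            },
            indent=1,
            default=str,
        )
    )
    return files
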