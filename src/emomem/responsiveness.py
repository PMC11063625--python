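"""Event responsiveness: baseline-vs-stimulus spike-count permutation tests.

A unit is "event responsive" for a trial type when its spike count in the
post-stimulus window (0.2-1.5 s) differs from the baseline window (-1.5 to
-0.2 s) more than expected under exchangeability.  Because baseline and
stimulus counts are paired within a trial, the default null is generated by
independently swapping the two labels within each trial (a paired
sign-flip); an unpaired pooled shuffle is available behind a flag.  The
p-value uses the add-one convention p = (1 + #{|T*| >= |T|}) / (n_perm + 1),
so it is never exactly zero and is floored at 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TrialRecord, UnitSpikeData
from .psth import BASELINE_WINDOW, STIMULUS_WINDOW, unit_window_counts

ENCODING_TRIAL_TYPES = ("e", "n", "eR", "nR", "eF", "nF")
RECOGNITION_TRIAL_TYPES = ("eRHit", "nRHit", "eMiss", "nMiss", "eCR", "nCR")


@dataclass
class ResponsivenessResult:
    unit_id: str
    region: str
    trial_type: str
    statistic: float       # mean stimulus count - mean baseline count
    p: float
    n_perm: int
    n_trials: int
    direction: str         # "increase" | "decrease"


def _select_trials(
    unit: UnitSpikeData, trials_by_id: dict[int, TrialRecord], trial_type: str
) -> np.ndarray:
    """Indices of the unit's trials belonging to a trial type.

    Pooled types 'e'/'n' select every trial of that emotion; outcome types
    (eR, nMiss, ...) match the trial's derived outcome label exactly.
    """
    idx = []
    for i, tid in enumerate(unit.trial_ids):
        t = trials_by_id.get(tid)
        if t is None:
            continue
        if trial_type == "e" and t.emotion == "emotional":
            idx.append(i)
        elif trial_type == "n" and t.emotion == "neutral":
            idx.append(i)
        elif t.outcome == trial_type:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def permutation_response_test(
    unit: UnitSpikeData,
    trials: list[TrialRecord],
    trial_type: str,
    baseline: tuple[float, float] = BASELINE_WINDOW,
    stimulus: tuple[float, float] = STIMULUS_WINDOW,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    paired: bool = True,
) -> ResponsivenessResult:
    """Two-sided permutation test of stimulus vs baseline spike counts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_id = {t.trial_id: t for t in trials}
    sel = _select_trials(unit, by_id, trial_type)
    if sel.size < 2:
        raise ValueError(
            f"unit {unit.unit_id}: fewer than 2 trials of type {trial_type!r}"
        )
    base = unit_window_counts(unit, baseline).astype(float)[sel]
    stim = unit_window_counts(unit, stimulus).astype(float)[sel]
    t_obs = stim.mean() - base.mean()

    if paired:
        d = stim - base
        signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
        t_perm = (signs * d).mean(axis=1)
    else:
        pooled = np.concatenate([base, stim])
        n = d_len = sel.size
        t_perm = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm[b] = perm[d_len:].mean() - perm[:d_len].mean()

    exceed = int(np.count_nonzero(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + exceed) / (n_perm + 1)
    return ResponsivenessResult(
        unit_id=unit.unit_id, region=unit.region, trial_type=trial_type,
        statistic=float(t_obs), p=float(p), n_perm=n_perm,
        n_trials=int(sel.size),
        direction="increase" if t_obs >= 0 else "decrease",
    )


def run_responsiveness(
    units: list[UnitSpikeData],
    trials: list[TrialRecord],
    phase: str,
    trial_types: tuple[str, ...] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    paired: bool = True,
) -> pd.DataFrame:
    """Permutation tests for every (unit, trial type); skips types with < 2
    trials for a unit."""
    if trial_types is None:
        trial_types = (
            ENCODING_TRIAL_TYPES if phase == "encoding" else RECOGNITION_TRIAL_TYPES
        )
    root = np.random.SeedSequence(seed)
    rows = []
    for u, useed in zip(units, root.spawn(len(units))):
        rng = np.random.default_rng(useed)
        for tt in trial_types:
            try:
                r = permutation_response_test(
                    u, trials, tt, n_perm=n_perm, seed=rng, paired=paired
                )
            except ValueError:
                continue
            rows.append(
                (r.unit_id, r.region, r.trial_type, r.statistic, r.p,
                 r.n_perm, r.n_trials, r.direction)
            )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "region", "trial_type", "statistic", "p",
                 "n_perm", "n_trials", "direction"],
    )


def responsiveness_summary(
    results: pd.DataFrame, alpha: float = 0.05, by_region: bool = False
) -> pd.DataFrame:
    """Percentage of units with p < alpha, per trial type (and region)."""
    if results.empty:
        cols = ["trial_type", "n_units", "n_significant", "pct_significant"]
        if by_region:
            cols.insert(0, "region")
        return pd.DataFrame(columns=cols)
    keys = ["region", "trial_type"] if by_region else ["trial_type"]
    out = (
        results.assign(sig=results["p"] < alpha)
        .groupby(keys, sort=True)
        .agg(n_units=("unit_id", "count"), n_significant=("sig", "sum"))
        .reset_index()
    )
    out["pct_significant"] = 100.0 * out["n_significant"] / out["n_units"]
    return out
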