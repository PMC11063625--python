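"""Firing-rate estimation: smoothed PSTHs, window counts, abs(z) scores, and
the population tensor feeding the mixed model and demixed PCA.

PSTHs are kernel rate estimates: each spike contributes a unit-area Gaussian
(sigma = 50 ms by default) evaluated at 10 ms bin centers, giving per-trial
firing-rate vectors in Hz.  Kernel mass falling outside the analysis window
is truncated, not renormalized, so the integral of the rate over the window
matches the spike count only up to edge losses.

The abs(z) measure summarizes a unit's stimulus-evoked rate change per
trial: z = (x - mu) / sigma with x the trial's stimulus-window rate and
mu, sigma the mean and SD of the per-trial baseline-window rates over all
trials.  Units that *decrease* their rate would otherwise cancel units that
increase it in a population average, so when the mean z over all trials is
negative every z is multiplied by -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TrialRecord, UnitSpikeData

BASELINE_WINDOW = (-1.5, -0.2)
STIMULUS_WINDOW = (0.2, 1.5)

ENCODING_MEMORY_LEVELS = ("R", "F")
RECOGNITION_MEMORY_LEVELS = ("RHit", "Miss", "CR")

_ENC_MEMORY = {"eR": "R", "nR": "R", "eF": "F", "nF": "F"}
_REC_MEMORY = {
    "eRHit": "RHit", "nRHit": "RHit",
    "eMiss": "Miss", "nMiss": "Miss",
    "eCR": "CR", "nCR": "CR",
}


@dataclass
class PSTHMatrix:
    """Per-trial smoothed firing-rate vectors for one unit."""

    unit_id: str
    trial_ids: list[int]
    bin_centers: np.ndarray   # s
    rates: np.ndarray         # (n_trials, n_bins), Hz
    kernel_sigma: float       # s


@dataclass
class PopulationTensor:
    """Trial-averaged rates over (unit x emotion x memory x time) plus the
    retained single-trial rates per condition cell."""

    unit_ids: list[str]
    regions: list[str]
    patient_ids: list[str]
    emotions: tuple[str, ...]
    memory_levels: tuple[str, ...]
    time: np.ndarray                       # (T,) bin centers, s
    avg: np.ndarray                        # (N, E, M, T), Hz
    trial_rates: list                      # [u][e][m] -> (n_trials, T)
    counts: np.ndarray                     # (N, E, M) ints
    dropped_units: list[str]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def padded_trials(self) -> np.ndarray:
        """Single trials as (N, E, M, max_trials, T) with NaN padding."""
        maxn = int(self.counts.max())
        N, E, M, T = self.avg.shape
        out = np.full((N, E, M, maxn, T), np.nan)
        for u in range(N):
            for e in range(E):
                for m in range(M):
                    r = self.trial_rates[u][e][m]
                    out[u, e, m, : r.shape[0]] = r
        return out

    def subset(self, keep: np.ndarray) -> "PopulationTensor":
        idx = np.flatnonzero(keep)
        return PopulationTensor(
            unit_ids=[self.unit_ids[i] for i in idx],
            regions=[self.regions[i] for i in idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            emotions=self.emotions,
            memory_levels=self.memory_levels,
            time=self.time,
            avg=self.avg[idx],
            trial_rates=[self.trial_rates[i] for i in idx],
            counts=self.counts[idx],
            dropped_units=list(self.dropped_units),
        )


def gaussian_rate(
    spikes: np.ndarray, bin_centers: np.ndarray, sigma: float
) -> np.ndarray:
    """Sum of unit-area Gaussians centered on the spikes, in Hz."""
    if spikes.size == 0:
        return np.zeros_like(bin_centers)
    d = bin_centers[None, :] - np.asarray(spikes, dtype=float)[:, None]
    k = np.exp(-0.5 * (d / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return k.sum(axis=0)


def compute_psth(
    unit: UnitSpikeData,
    window: tuple[float, float] = (-1.5, 2.5),
    sigma: float = 0.05,
    bin_width: float = 0.01,
) -> PSTHMatrix:
    lo, hi = window
    if bin_width > hi - lo:
        raise ValueError("bin width exceeds window length")
    centers = np.arange(lo + bin_width / 2, hi, bin_width)
    rates = np.stack([gaussian_rate(s, centers, sigma) for s in unit.spikes])
    return PSTHMatrix(
        unit_id=unit.unit_id, trial_ids=list(unit.trial_ids),
        bin_centers=centers, rates=rates, kernel_sigma=sigma,
    )


def window_spike_count(
    spikes: np.ndarray, window: tuple[float, float]
) -> int:
    """Number of spikes with window[0] <= t < window[1] (half-open)."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must satisfy lo < hi")
    s = np.asarray(spikes)
    return int(np.count_nonzero((s >= lo) & (s < hi)))


def unit_window_counts(
    unit: UnitSpikeData, window: tuple[float, float]
) -> np.ndarray:
    return np.array([window_spike_count(s, window) for s in unit.spikes])


def memory_level(trial: TrialRecord) -> str | None:
    """Primary-analysis memory level of a labeled trial, or None."""
    if trial.outcome is None or trial.excluded_primary:
        return None
    if trial.phase == "encoding":
        return _ENC_MEMORY.get(trial.outcome)
    return _REC_MEMORY.get(trial.outcome)


def compute_abs_z(
    unit: UnitSpikeData,
    trials: list[TrialRecord],
    baseline: tuple[float, float] = BASELINE_WINDOW,
    stimulus: tuple[float, float] = STIMULUS_WINDOW,
) -> pd.DataFrame:
    """Per-trial sign-corrected z-scores for one unit.

    Raises ``ZeroDivisionError`` when the baseline SD is zero (the caller
    logs and excludes such units from the mixed model).  Rows are emitted
    only for primary-analysis trials, but mu/sigma and the sign flip use all
    trials of the unit.
    """
    by_id = {t.trial_id: t for t in trials}
    base_dur = baseline[1] - baseline[0]
    stim_dur = stimulus[1] - stimulus[0]
    base_rates = unit_window_counts(unit, baseline) / base_dur
    stim_rates = unit_window_counts(unit, stimulus) / stim_dur
    mu = base_rates.mean()
    sd = base_rates.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError(
            f"unit {unit.unit_id}: zero baseline variance; cannot z-score"
        )
    z = (stim_rates - mu) / sd
    if z.mean() < 0:
        z = -z
    rows = []
    for tid, zval in zip(unit.trial_ids, z):
        t = by_id.get(tid)
        if t is None:
            continue
        lvl = memory_level(t)
        if lvl is None:
            continue
        rows.append(
            (unit.patient_id, unit.unit_id, unit.region, tid, t.emotion, lvl,
             float(zval))
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "unit_id", "region", "trial_id", "emotion",
                 "memory", "abs_z"],
    )


def build_ztable(
    units: list[UnitSpikeData],
    trials: list[TrialRecord],
    baseline: tuple[float, float] = BASELINE_WINDOW,
    stimulus: tuple[float, float] = STIMULUS_WINDOW,
) -> tuple[pd.DataFrame, list[str]]:
    """abs(z) rows for all units; returns (table, excluded unit ids)."""
    frames, excluded = [], []
    for u in units:
        try:
            frames.append(compute_abs_z(u, trials, baseline, stimulus))
        except ZeroDivisionError:
            excluded.append(u.unit_id)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["patient_id", "unit_id", "region",
                                   "trial_id", "emotion", "memory", "abs_z"])
    )
    return table, excluded


def build_population_tensor(
    units: list[UnitSpikeData],
    trials: list[TrialRecord],
    phase: str,
    window: tuple[float, float] = (-0.5, 2.5),
    sigma: float = 0.05,
    bin_width: float = 0.01,
) -> PopulationTensor:
    """Assemble the (unit x emotion x memory x time) tensor of smoothed rates.

    Units missing all trials in any condition cell are dropped (logged in
    ``dropped_units``) rather than propagating NaNs.
    """
    emotions = ("emotional", "neutral")
    mem_levels = (
        ENCODING_MEMORY_LEVELS if phase == "encoding" else RECOGNITION_MEMORY_LEVELS
    )
    by_id = {t.trial_id: t for t in trials if t.phase == phase}

    unit_ids, regions, patients, avgs, all_rates, all_counts, dropped = (
        [], [], [], [], [], [], []
    )
    time = None
    for u in units:
        if u.phase != phase:
            continue
        psth = compute_psth(u, window=window, sigma=sigma, bin_width=bin_width)
        if time is None:
            time = psth.bin_centers
        cond_idx: dict[tuple[str, str], list[int]] = {}
        for i, tid in enumerate(u.trial_ids):
            t = by_id.get(tid)
            if t is None:
                continue
            lvl = memory_level(t)
            if lvl is None or lvl not in mem_levels:
                continue
            cond_idx.setdefault((t.emotion, lvl), []).append(i)
        if any(
            (e, m) not in cond_idx for e in emotions for m in mem_levels
        ):
            dropped.append(u.unit_id)
            continue
        rates_em = [
            [psth.rates[cond_idx[(e, m)]] for m in mem_levels] for e in emotions
        ]
        avg = np.array(
            [[r.mean(axis=0) for r in row] for row in rates_em]
        )
        counts = np.array(
            [[len(cond_idx[(e, m)]) for m in mem_levels] for e in emotions]
        )
        unit_ids.append(u.unit_id)
        regions.append(u.region)
        patients.append(u.patient_id)
        avgs.append(avg)
        all_rates.append(rates_em)
        all_counts.append(counts)

    if not unit_ids:
        raise ValueError("no unit has trials in every condition cell")
    return PopulationTensor(
        unit_ids=unit_ids, regions=regions, patient_ids=patients,
        emotions=emotions, memory_levels=mem_levels, time=time,
        avg=np.stack(avgs), trial_rates=all_rates,
        counts=np.stack(all_counts), dropped_units=dropped,
    )
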