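"""Canonical data model, trial labeling, and unit quality control.

The experiment is an emotional recognition-memory task recorded with MTL
microwires: during *encoding*, patients view emotional (aversive) and
neutral scenes and make an indoor/outdoor judgment; ~24 h later, during
*recognition*, old scenes are intermixed with an equal number of new ones
and patients answer Remember (R), Know (K) or New (N).  Spiking activity of
putative single units in hippocampus (HIP), amygdala (AMY) and entorhinal
cortex (EC) is aligned to stimulus onset (t = 0 s; offset at 0.5 s).

Conventions enforced throughout the package:

* time is in seconds, stimulus onset at 0;
* all analysis windows are half-open ``[lo, hi)`` **except** the artifact
  windows around stimulus onset/offset, which are closed ``[t - w, t + w]``;
* encoding outcomes are derived from the later recognition response to the
  same stimulus (subsequent-memory labeling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PHASES = ("encoding", "recognition")
EMOTIONS = ("emotional", "neutral")
REGIONS = ("HIP", "AMY", "EC")

#: recognition responses; indoor/outdoor are encoding judgments
RESPONSES = ("R", "K", "N", "indoor", "outdoor", "none")

ENCODING_OUTCOMES = ("eR", "nR", "eF", "nF", "eK", "nK")
RECOGNITION_OUTCOMES = (
    "eRHit", "nRHit", "eKHit", "nKHit", "eMiss", "nMiss",
    "eCR", "nCR", "eFA", "nFA",
)


class LabelingError(ValueError):
    """Raised when trial metadata cannot be consistently labeled."""


class UndefinedWidthError(ValueError):
    """Raised when a waveform has no peak-trough pair (e.g. monotone)."""


@dataclass
class TrialRecord:
    """One task trial with its derived outcome label.

    ``outcome`` is filled in by :func:`label_trials`; encoding outcomes
    encode the *subsequent* memory fate of the item (eR = emotional,
    subsequently remembered; nF = neutral, subsequently forgotten, i.e. an
    old item that later received a New response).  K-based outcomes are
    retained but flagged ``excluded_primary`` because Know and false-alarm
    trials are too few for the primary analyses.
    """

    trial_id: int
    phase: str
    emotion: str
    old_new: str            # "old" | "new" | "n/a"
    response: str
    stimulus_id: str
    outcome: str | None = None
    reaction_time: float | None = None
    excluded_primary: bool = False
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise LabelingError(f"unknown phase {self.phase!r}")
        if self.emotion not in EMOTIONS:
            raise LabelingError(f"unknown emotion {self.emotion!r}")
        if self.response not in RESPONSES:
            raise LabelingError(
                f"trial {self.trial_id}: unknown response code {self.response!r}"
            )
        if self.phase == "recognition" and self.old_new not in ("old", "new"):
            raise LabelingError(
                f"recognition trial {self.trial_id} must be old or new"
            )
        if self.phase == "encoding" and self.old_new != "n/a":
            raise LabelingError(
                f"encoding trial {self.trial_id} must have old_new = 'n/a'"
            )
        if self.reaction_time is not None and self.reaction_time < 0:
            raise LabelingError(f"trial {self.trial_id}: negative reaction time")


@dataclass
class UnitSpikeData:
    """One putative single unit ("neuron"): trial-aligned spike trains.

    ``spikes[i]`` holds the spike times (s, relative to stimulus onset,
    sorted ascending) on the trial whose id is ``trial_ids[i]``.
    """

    unit_id: str
    patient_id: str
    region: str
    phase: str
    trial_ids: list[int]
    spikes: list[np.ndarray]
    waveform: np.ndarray | None = None
    waveform_fs: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if len(self.trial_ids) != len(self.spikes):
            raise ValueError("trial_ids and spikes must align 1:1")
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for s in self.spikes:
            if s.size > 1 and np.any(np.diff(s) < 0):
                raise ValueError(f"unit {self.unit_id}: unsorted spike train")

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    def total_spikes(self) -> int:
        return int(sum(s.size for s in self.spikes))


@dataclass
class QualityReport:
    unit_id: str
    pct_isi_under_3ms: float
    mean_rate: float
    n_trials_with_spike: int
    spike_width: float | None
    included: bool
    exclusion_reasons: list[str] = field(default_factory=list)


def _encoding_outcome(emotion: str, recognition_response: str) -> tuple[str, bool]:
    prefix = "e" if emotion == "emotional" else "n"
    if recognition_response == "R":
        return prefix + "R", False
    if recognition_response == "N":
        return prefix + "F", False
    if recognition_response == "K":
        return prefix + "K", True
    raise LabelingError(
        f"recognition response {recognition_response!r} cannot label encoding"
    )


def _recognition_outcome(emotion: str, old_new: str, response: str) -> tuple[str, bool]:
    prefix = "e" if emotion == "emotional" else "n"
    if old_new == "old":
        if response == "R":
            return prefix + "RHit", False
        if response == "K":
            return prefix + "KHit", True
        if response == "N":
            return prefix + "Miss", False
    else:
        if response == "N":
            return prefix + "CR", False
        if response in ("R", "K"):
            return prefix + "FA", True
    raise LabelingError(f"cannot label {old_new} item with response {response!r}")


def label_trials(
    encoding_trials: list[TrialRecord],
    recognition_trials: list[TrialRecord],
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Derive outcome labels for both phases from the recognition responses.

    Every encoding item must reappear exactly once as an old item at
    recognition; its R/K/N response there determines the encoding trial's
    subsequent-memory outcome (R -> eR/nR, N -> eF/nF, K -> eK/nK, the K
    outcomes flagged ``excluded_primary``).  Recognition outcomes are
    RHit/KHit/Miss for old items and CR/FA for new ones, per emotion.

    Returns new lists; the inputs are not mutated.
    """
    old_by_stim: dict[str, TrialRecord] = {}
    for t in recognition_trials:
        if t.old_new == "old":
            if t.stimulus_id in old_by_stim:
                raise LabelingError(
                    f"stimulus {t.stimulus_id!r} appears twice as old at recognition"
                )
            old_by_stim[t.stimulus_id] = t

    labeled_enc = []
    for t in encoding_trials:
        rec = old_by_stim.get(t.stimulus_id)
        if rec is None:
            raise LabelingError(
                f"encoding trial {t.trial_id}: stimulus {t.stimulus_id!r} "
                "has no old recognition trial"
            )
        if rec.emotion != t.emotion:
            raise LabelingError(
                f"stimulus {t.stimulus_id!r}: emotion differs between phases"
            )
        outcome, excl = _encoding_outcome(t.emotion, rec.response)
        labeled_enc.append(replace(t, outcome=outcome, excluded_primary=excl))

    labeled_rec = []
    for t in recognition_trials:
        if t.response not in ("R", "K", "N"):
            raise LabelingError(
                f"recognition trial {t.trial_id}: response {t.response!r} invalid"
            )
        outcome, excl = _recognition_outcome(t.emotion, t.old_new, t.response)
        labeled_rec.append(replace(t, outcome=outcome, excluded_primary=excl))
    return labeled_enc, labeled_rec


def remove_artifact_spikes(
    unit: UnitSpikeData,
    onset: float = 0.0,
    offset: float = 0.5,
    half_width: float = 0.003,
) -> tuple[UnitSpikeData, int]:
    """Delete spikes within +-``half_width`` s of stimulus onset and offset.

    Mechanical/electrical artifacts of the display coincide with stimulus
    appearance and disappearance; spikes inside the *closed* intervals
    ``[onset - w, onset + w]`` and ``[offset - w, offset + w]`` are removed.
    Idempotent.  Returns the cleaned unit and the number of spikes removed.
    """
    cleaned, removed = [], 0
    for s in unit.spikes:
        keep = ~(
            ((s >= onset - half_width) & (s <= onset + half_width))
            | ((s >= offset - half_width) & (s <= offset + half_width))
        )
        removed += int(s.size - keep.sum())
        cleaned.append(s[keep])
    return replace(unit, spikes=cleaned), removed


def _within_trial_isis(unit: UnitSpikeData) -> np.ndarray:
    # cross-trial ISIs span multi-second inter-trial gaps and carry no
    # information about sorting quality, so only within-trial diffs count
    isis = [np.diff(s) for s in unit.spikes if s.size > 1]
    return np.concatenate(isis) if isis else np.empty(0)


def quality_filter(
    units: list[UnitSpikeData],
    phase: str,
    window: tuple[float, float] = (-1.5, 2.5),
    min_rate_hz: float = 0.25,
    max_pct_short_isi: float = 3.0,
    isi_threshold_s: float = 0.003,
    min_trials_with_spike: int | None = None,
) -> tuple[list[UnitSpikeData], list[QualityReport]]:
    """Apply the unit inclusion rules and report every unit's metrics.

    A unit is retained iff (a) fewer than ``max_pct_short_isi`` percent of
    its within-trial ISIs fall below 3 ms, (b) its mean firing rate over the
    peri-stimulus window exceeds ``min_rate_hz``, and (c) it fires at least
    one spike on 50 (encoding) or 100 (recognition) trials.  The mean rate
    denominator is ``n_trials * (window[1] - window[0])`` seconds.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if min_trials_with_spike is None:
        min_trials_with_spike = 50 if phase == "encoding" else 100
    duration = window[1] - window[0]
    if duration <= 0:
        raise ValueError("window must have positive length")

    retained, reports = [], []
    for u in units:
        reasons = []
        total = u.total_spikes()
        isis = _within_trial_isis(u)
        pct_short = (
            100.0 * float(np.mean(isis < isi_threshold_s)) if isis.size else 0.0
        )
        mean_rate = total / (u.n_trials * duration) if u.n_trials else 0.0
        n_with_spike = sum(1 for s in u.spikes if s.size > 0)

        if total == 0:
            reasons.append("no spikes")
        if pct_short >= max_pct_short_isi:
            reasons.append(
                f"{pct_short:.2f}% ISIs < 3 ms (limit {max_pct_short_isi}%)"
            )
        if mean_rate <= min_rate_hz:
            reasons.append(f"mean rate {mean_rate:.3f} Hz <= {min_rate_hz} Hz")
        if n_with_spike < min_trials_with_spike:
            reasons.append(
                f"spikes on {n_with_spike} trials < {min_trials_with_spike}"
            )

        width = None
        if u.waveform is not None and u.waveform_fs:
            try:
                width = spike_width(u.waveform, u.waveform_fs)
            except UndefinedWidthError:
                width = None

        included = not reasons
        reports.append(
            QualityReport(
                unit_id=u.unit_id,
                pct_isi_under_3ms=pct_short,
                mean_rate=mean_rate,
                n_trials_with_spike=n_with_spike,
                spike_width=width,
                included=included,
                exclusion_reasons=reasons,
            )
        )
        if included:
            retained.append(u)
    return retained, reports


def spike_width(
    waveform: np.ndarray,
    sampling_rate_hz: float,
    first_extremum: str = "trough",
) -> float:
    """Peak-to-trough width of a mean waveform, in milliseconds.

    Finds the global extremum of the configured sign (default: the trough,
    the convention for negative-going extracellular spikes) and measures the
    time to the subsequent opposite extremum.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3:
        raise UndefinedWidthError("waveform too short")
    if first_extremum not in ("trough", "peak"):
        raise ValueError("first_extremum must be 'trough' or 'peak'")
    if first_extremum == "peak":
        w = -w
    i0 = int(np.argmin(w))
    tail = w[i0 + 1:]
    if tail.size == 0 or np.max(tail) <= w[i0]:
        raise UndefinedWidthError("no opposite extremum after the first one")
    if np.ptp(w) == 0:
        raise UndefinedWidthError("flat waveform")
    i1 = i0 + 1 + int(np.argmax(tail))
    return (i1 - i0) / sampling_rate_hz * 1000.0
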