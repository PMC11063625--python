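"""Synthetic task designs, behavior, and inhomogeneous-Poisson spike trains.

The generator emulates the structure of the emotional memory study: 5
patients, ~50 units each spread over HIP/AMY/EC, 120 encoding trials (40
emotional / 80 neutral scenes, presentation 0.5 s, interstimulus interval
3.5 s), 240 recognition trials (120 old + 120 new), with a pseudo-random
order in which no two emotional images are adjacent.

Each simulated unit is an inhomogeneous Poisson process

    lambda(t | trial) = baseline + bump(t) * (g_event
                        + g_emotion * 1[emotional]
                        + g_memory * 1[remembered]
                        + g_interaction * 1[emotional] * 1[remembered])

clipped at zero, where ``bump`` is a Gaussian of unit peak amplitude
(default latency 0.3 s, width 0.2 s) standing in for the stimulus-evoked
response.  Refractoriness is enforced by deleting spikes closer than the
dead time (3 ms, matching the sorting-quality criterion), so the fraction
of ISIs < 3 ms is zero by construction.  "Remembered" means a subsequently-remembered old
item at encoding and an RHit at recognition.

Ground truth (per-unit effect class and gains) is returned alongside the
dataset so recovery can be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import EMOTIONS, REGIONS, TrialRecord, UnitSpikeData, label_trials
from .io import Dataset

EFFECT_CLASSES = ("none", "event_only", "emotion", "memory", "interaction")


class DesignError(ValueError):
    pass


@dataclass
class TaskConfig:
    """Trial counts and timing of one session pair."""

    n_emotional: int = 40
    n_neutral: int = 80
    n_new_emotional: int = 40
    n_new_neutral: int = 80
    presentation_s: float = 0.5
    isi_s: float = 3.5
    window: tuple[float, float] = (-1.5, 2.5)


@dataclass
class BehaviorRates:
    """Response probabilities: (P(R), P(K), P(N)) per item status and emotion.

    For old items R is a remember hit, K a know hit and N a miss; for new
    items R/K are false alarms and N a correct rejection.  Defaults give the
    moderate performance typical of intracranial patient cohorts (hit rates
    under 50%, few K responses and false alarms).
    """

    old_emotional: tuple[float, float, float] = (0.45, 0.10, 0.45)
    old_neutral: tuple[float, float, float] = (0.40, 0.10, 0.50)
    new_emotional: tuple[float, float, float] = (0.05, 0.05, 0.90)
    new_neutral: tuple[float, float, float] = (0.05, 0.05, 0.90)

    def validate(self) -> None:
        for name, row in asdict(self).items():
            row = np.asarray(row, dtype=float)
            if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"behavior rates {name}={tuple(row)} must be a probability "
                    "simplex (non-negative, summing to 1)"
                )


@dataclass
class UnitProfile:
    """Intensity-function parameters of one simulated unit."""

    baseline_rate: float = 2.0        # Hz
    event_gain: float = 0.0           # Hz at bump peak, condition-independent
    emotion_gain: float = 0.0         # signed, Hz at bump peak
    memory_gain: float = 0.0
    interaction_gain: float = 0.0
    response_latency: float = 0.3     # s
    response_width: float = 0.2       # s (Gaussian sigma)
    refractory: float = 0.003         # s dead time; matches the 3 ms ISI
                                      # quality criterion, so simulated units
                                      # can never violate it

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.event_gain < 0:
            raise ValueError("event_gain must be >= 0")


@dataclass
class CohortConfig:
    """Cohort structure and planted-effect prevalences."""

    n_patients: int = 5
    units_per_region: int = 17        # x3 regions -> ~51 units per patient
    frac_emotion: float = 0.10
    frac_memory: float = 0.07
    frac_interaction: float = 0.05
    frac_event_only: float = 0.30
    effect_gain_scale: float = 1.5    # |condition gain| as multiple of baseline
    event_gain_range: tuple[float, float] = (0.5, 1.5)  # x baseline
    prob_positive_effect: float = 0.7
    # log-normal baselines: median 2 Hz with enough spread that a small
    # fraction of units straddles the 0.25 Hz inclusion boundary
    baseline_median_hz: float = 2.0
    baseline_sigma_log: float = 1.0
    phases: tuple[str, ...] = ("encoding", "recognition")
    task: TaskConfig = field(default_factory=TaskConfig)
    rates: BehaviorRates = field(default_factory=BehaviorRates)

    def validate(self) -> None:
        fracs = (
            self.frac_emotion + self.frac_memory
            + self.frac_interaction + self.frac_event_only
        )
        if fracs > 1.0 + 1e-12:
            raise ValueError("effect-class fractions exceed 1")
        self.rates.validate()


@dataclass
class SimulationGroundTruth:
    seed: int
    unit_classes: dict[str, str]            # unit_id -> effect class
    unit_gains: dict[str, dict[str, float]]
    trial_counts: dict[str, dict[str, int]]  # phase -> outcome -> count


def _interleave_no_adjacent(
    emotional_items: list, neutral_items: list, rng: np.random.Generator
) -> list:
    """Pseudo-random order with no two emotional items adjacent.

    Neutral items are shuffled and the emotional items dropped into distinct
    gaps between/around them, which guarantees the adjacency constraint.
    Requires n_emotional <= n_neutral so the order remains genuinely random.
    """
    n_e, n_n = len(emotional_items), len(neutral_items)
    if n_e > n_n:
        raise DesignError(
            f"cannot interleave {n_e} emotional among {n_n} neutral items "
            "without adjacent emotional pairs"
        )
    e = list(emotional_items)
    n = list(neutral_items)
    rng.shuffle(e)
    rng.shuffle(n)
    gaps = rng.choice(n_n + 1, size=n_e, replace=False)
    order: list = []
    for i, item in enumerate(n):
        if i in gaps:
            order.append(e.pop())
        order.append(item)
    if n_n in gaps:
        order.append(e.pop())
    return order


def build_task_design(
    seed: int | np.random.Generator, config: TaskConfig | None = None
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Generate unlabeled encoding and recognition trial sequences.

    Every encoding item reappears exactly once as an old item at
    recognition, intermixed with an equal number of new items; emotional
    items are never adjacent in either session.
    """
    config = config or TaskConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    enc_stims = [("emotional", f"old_e{i:03d}") for i in range(config.n_emotional)]
    enc_stims += [("neutral", f"old_n{i:03d}") for i in range(config.n_neutral)]
    order = _interleave_no_adjacent(
        [s for s in enc_stims if s[0] == "emotional"],
        [s for s in enc_stims if s[0] == "neutral"],
        rng,
    )
    encoding = [
        TrialRecord(
            trial_id=i, phase="encoding", emotion=emo, old_new="n/a",
            response="none", stimulus_id=stim,
        )
        for i, (emo, stim) in enumerate(order)
    ]

    rec_stims = [(emo, stim, "old") for emo, stim in enc_stims]
    rec_stims += [
        ("emotional", f"new_e{i:03d}", "new") for i in range(config.n_new_emotional)
    ]
    rec_stims += [
        ("neutral", f"new_n{i:03d}", "new") for i in range(config.n_new_neutral)
    ]
    rec_order = _interleave_no_adjacent(
        [s for s in rec_stims if s[0] == "emotional"],
        [s for s in rec_stims if s[0] == "neutral"],
        rng,
    )
    recognition = [
        TrialRecord(
            trial_id=i, phase="recognition", emotion=emo, old_new=status,
            response="N", stimulus_id=stim,
        )
        for i, (emo, stim, status) in enumerate(rec_order)
    ]
    return encoding, recognition


def count_adjacent_emotional(trials: list[TrialRecord]) -> int:
    emo = [t.emotion == "emotional" for t in trials]
    return sum(1 for a, b in zip(emo, emo[1:]) if a and b)


def assign_behavior(
    design: tuple[list[TrialRecord], list[TrialRecord]],
    rates: BehaviorRates,
    seed: int | np.random.Generator,
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Draw R/K/N responses per item and derive outcome labels.

    Encoding responses are the indoor/outdoor judgment (uninformative,
    drawn 50/50); recognition responses follow the configured rates, and
    encoding subsequent-memory labels are then derived via
    :func:`~emomem.core.label_trials`.  Reaction times are log-normal
    (medians ~0.9 s encoding, ~1.5 s recognition).
    """
    rates.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    encoding, recognition = design

    table = {
        ("old", "emotional"): rates.old_emotional,
        ("old", "neutral"): rates.old_neutral,
        ("new", "emotional"): rates.new_emotional,
        ("new", "neutral"): rates.new_neutral,
    }
    enc = [
        TrialRecord(
            trial_id=t.trial_id, phase=t.phase, emotion=t.emotion,
            old_new=t.old_new, stimulus_id=t.stimulus_id,
            response=rng.choice(["indoor", "outdoor"]),
            reaction_time=float(rng.lognormal(np.log(0.9), 0.3)),
        )
        for t in encoding
    ]
    rec = [
        TrialRecord(
            trial_id=t.trial_id, phase=t.phase, emotion=t.emotion,
            old_new=t.old_new, stimulus_id=t.stimulus_id,
            response=str(rng.choice(["R", "K", "N"], p=table[(t.old_new, t.emotion)])),
            reaction_time=float(rng.lognormal(np.log(1.5), 0.35)),
        )
        for t in recognition
    ]
    return label_trials(enc, rec)


def _remembered(trial: TrialRecord) -> bool:
    return trial.outcome in ("eR", "nR", "eRHit", "nRHit")


def intensity(
    profile: UnitProfile, t: np.ndarray, emotional: bool, remembered: bool
) -> np.ndarray:
    """Evaluate lambda(t) in Hz for one trial condition (clipped at 0)."""
    gain = (
        profile.event_gain
        + profile.emotion_gain * emotional
        + profile.memory_gain * remembered
        + profile.interaction_gain * emotional * remembered
    )
    bump = np.exp(
        -0.5 * ((t - profile.response_latency) / profile.response_width) ** 2
    )
    return np.clip(profile.baseline_rate + gain * bump, 0.0, None)


def simulate_unit(
    profile: UnitProfile,
    trials: list[TrialRecord],
    seed: int | np.random.Generator,
    window: tuple[float, float] = (-1.5, 2.5),
    unit_id: str = "sim",
    patient_id: str = "p00",
    region: str = "HIP",
) -> UnitSpikeData:
    """Sample per-trial spike trains by thinning a homogeneous Poisson process."""
    if window[1] <= window[0]:
        raise ValueError("window must have positive length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = window[1] - window[0]
    spikes = []
    for t in trials:
        emotional = t.emotion == "emotional"
        remembered = _remembered(t)
        gain = (
            profile.event_gain
            + profile.emotion_gain * emotional
            + profile.memory_gain * remembered
            + profile.interaction_gain * emotional * remembered
        )
        lam_max = profile.baseline_rate + max(gain, 0.0)
        n = rng.poisson(lam_max * duration)
        times = np.sort(rng.uniform(window[0], window[1], size=n))
        lam = intensity(profile, times, emotional, remembered)
        keep = rng.uniform(0, lam_max, size=n) < lam
        times = times[keep]
        if times.size > 1 and profile.refractory > 0:
            # dead-time thinning: drop any spike within `refractory` of the
            # previously kept one
            kept = [times[0]]
            for x in times[1:]:
                if x - kept[-1] >= profile.refractory:
                    kept.append(x)
            times = np.asarray(kept)
        spikes.append(times)
    return UnitSpikeData(
        unit_id=unit_id, patient_id=patient_id, region=region,
        phase=trials[0].phase if trials else "encoding",
        trial_ids=[t.trial_id for t in trials], spikes=spikes,
    )


def _draw_profile(
    cls: str, config: CohortConfig, rng: np.random.Generator
) -> UnitProfile:
    baseline = float(
        rng.lognormal(np.log(config.baseline_median_hz), config.baseline_sigma_log)
    )
    sign = 1.0 if rng.uniform() < config.prob_positive_effect else -1.0
    event = float(rng.uniform(*config.event_gain_range)) * baseline
    gain = config.effect_gain_scale * baseline * sign
    kw = dict(baseline_rate=baseline)
    if cls == "event_only":
        kw["event_gain"] = event
    elif cls == "emotion":
        kw.update(event_gain=event, emotion_gain=gain)
    elif cls == "memory":
        kw.update(event_gain=event, memory_gain=gain)
    elif cls == "interaction":
        kw.update(event_gain=event, interaction_gain=gain)
    return UnitProfile(**kw)


def simulate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[Dataset, SimulationGroundTruth]:
    """Simulate a full multi-patient cohort with planted effects.

    Each patient receives their own task design and behavioral draw; units
    are assigned an effect class (none / event-only / emotion / memory /
    interaction) at the configured prevalences, independently per phase
    (sessions 24 h apart record different neurons).  Deterministic for a
    fixed seed.
    """
    config = config or CohortConfig()
    config.validate()
    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(config.n_patients)

    classes = np.array(EFFECT_CLASSES)
    probs = np.array([
        1.0 - (config.frac_event_only + config.frac_emotion
               + config.frac_memory + config.frac_interaction),
        config.frac_event_only, config.frac_emotion,
        config.frac_memory, config.frac_interaction,
    ])

    trials: dict[str, list[TrialRecord]] = {"encoding": [], "recognition": []}
    units: list[UnitSpikeData] = []
    unit_classes: dict[str, str] = {}
    unit_gains: dict[str, dict[str, float]] = {}

    for p, pseed in enumerate(patient_seeds):
        pid = f"p{p:02d}"
        rng = np.random.default_rng(pseed)
        enc, rec = assign_behavior(
            build_task_design(rng, config.task), config.rates, rng
        )
        # one shared design per patient; trial ids offset per patient so the
        # pooled tables keep unique (phase, trial_id) keys
        offset = p * 10_000
        enc = [
            TrialRecord(**{**asdict(t), "trial_id": t.trial_id + offset,
                           "patient_id": pid})
            for t in enc
        ]
        rec = [
            TrialRecord(**{**asdict(t), "trial_id": t.trial_id + offset,
                           "patient_id": pid})
            for t in rec
        ]
        trials["encoding"].extend(enc)
        trials["recognition"].extend(rec)

        phase_trials = {"encoding": enc, "recognition": rec}
        for phase in config.phases:
            for r, region in enumerate(REGIONS):
                for k in range(config.units_per_region):
                    uid = f"{pid}_{phase[:3]}_{region}_{k:02d}"
                    cls = str(rng.choice(classes, p=probs))
                    profile = _draw_profile(cls, config, rng)
                    unit = simulate_unit(
                        profile, phase_trials[phase], rng,
                        window=config.task.window, unit_id=uid,
                        patient_id=pid, region=region,
                    )
                    units.append(unit)
                    unit_classes[uid] = cls
                    unit_gains[uid] = {
                        "baseline_rate": profile.baseline_rate,
                        "event_gain": profile.event_gain,
                        "emotion_gain": profile.emotion_gain,
                        "memory_gain": profile.memory_gain,
                        "interaction_gain": profile.interaction_gain,
                    }

    counts: dict[str, dict[str, int]] = {}
    for phase, ts in trials.items():
        c: dict[str, int] = {}
        for t in ts:
            c[t.outcome] = c.get(t.outcome, 0) + 1
        counts[phase] = c

    truth = SimulationGroundTruth(
        seed=seed, unit_classes=unit_classes, unit_gains=unit_gains,
        trial_counts=counts,
    )
    return Dataset(trials=trials, units=units), truth
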