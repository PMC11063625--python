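"""CSV/JSON interchange for spike trains, trials, and results.

A dataset directory holds three delimited text files:

* ``spikes.csv`` — one row per spike: patient_id, unit_id, region, phase,
  trial_id, spike_time_s;
* ``trials.csv`` — one row per trial with the :class:`~emomem.core.TrialRecord`
  fields;
* ``units.csv`` — one row per unit (manifest, so units that never fired are
  preserved on round trip).

Results objects are serialized as JSON with numpy types coerced to plain
Python scalars/lists.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PHASES, TrialRecord, UnitSpikeData

SPIKE_COLUMNS = ["patient_id", "unit_id", "region", "phase", "trial_id", "spike_time_s"]
TRIAL_COLUMNS = [
    "trial_id", "phase", "emotion", "old_new", "response", "stimulus_id",
    "outcome", "reaction_time", "excluded_primary", "patient_id",
]
UNIT_COLUMNS = ["unit_id", "patient_id", "region", "phase"]


class SchemaError(ValueError):
    pass


@dataclasses.dataclass
class Dataset:
    """In-memory dataset: trials per phase plus all units."""

    trials: dict[str, list[TrialRecord]]
    units: list[UnitSpikeData]

    def units_for(self, phase: str) -> list[UnitSpikeData]:
        return [u for u in self.units if u.phase == phase]

    def total_spikes(self) -> int:
        return sum(u.total_spikes() for u in self.units)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {missing}")


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(t) for t in trials]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    _require_columns(df, TRIAL_COLUMNS, "trial table")
    dup = df.duplicated(subset=["phase", "trial_id"])
    if dup.any():
        key = df.loc[dup, ["phase", "trial_id"]].iloc[0].tolist()
        raise SchemaError(f"duplicate trial key {tuple(key)}")
    out = []
    for row in df.itertuples(index=False):
        rt = None if pd.isna(row.reaction_time) else float(row.reaction_time)
        outcome = None if pd.isna(row.outcome) else str(row.outcome)
        pid = None if pd.isna(row.patient_id) else str(row.patient_id)
        out.append(
            TrialRecord(
                trial_id=int(row.trial_id),
                phase=str(row.phase),
                emotion=str(row.emotion),
                old_new=str(row.old_new),
                response=str(row.response),
                stimulus_id=str(row.stimulus_id),
                outcome=outcome,
                reaction_time=rt,
                excluded_primary=bool(row.excluded_primary),
                patient_id=pid,
            )
        )
    return out


def spikes_to_frame(units: list[UnitSpikeData]) -> pd.DataFrame:
    recs = []
    for u in units:
        for tid, s in zip(u.trial_ids, u.spikes):
            for t in s:
                recs.append((u.patient_id, u.unit_id, u.region, u.phase, tid, t))
    return pd.DataFrame(recs, columns=SPIKE_COLUMNS)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    all_trials = [t for phase in PHASES for t in dataset.trials.get(phase, [])]
    trials_to_frame(all_trials).to_csv(path / "trials.csv", index=False)
    spikes_to_frame(dataset.units).to_csv(
        path / "spikes.csv", index=False, float_format="%.6f"
    )
    units_df = pd.DataFrame(
        [(u.unit_id, u.patient_id, u.region, u.phase) for u in dataset.units],
        columns=UNIT_COLUMNS,
    )
    units_df.to_csv(path / "units.csv", index=False)


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory; schema-validated, spike trains re-sorted."""
    path = Path(path)
    # keep_default_na: the old_new level "n/a" is a real category, not NaN
    trials_df = pd.read_csv(
        path / "trials.csv", keep_default_na=False, na_values=[""]
    )
    spikes_df = pd.read_csv(path / "spikes.csv")
    units_df = pd.read_csv(path / "units.csv")
    _require_columns(spikes_df, SPIKE_COLUMNS, "spike table")
    _require_columns(units_df, UNIT_COLUMNS, "unit table")
    trials = frame_to_trials(trials_df)
    by_phase: dict[str, list[TrialRecord]] = {p: [] for p in PHASES}
    for t in trials:
        by_phase[t.phase].append(t)

    dup = units_df.duplicated(subset=["unit_id", "phase"])
    if dup.any():
        raise SchemaError(
            f"duplicate unit key {tuple(units_df.loc[dup].iloc[0][['unit_id', 'phase']])}"
        )

    grouped = {
        k: g for k, g in spikes_df.groupby(["unit_id", "phase"], sort=False)
    }
    units = []
    for row in units_df.itertuples(index=False):
        phase_trials = by_phase[row.phase]
        tids = [t.trial_id for t in phase_trials]
        g = grouped.get((row.unit_id, row.phase))
        spikes = {tid: [] for tid in tids}
        if g is not None:
            for tid, t in zip(g["trial_id"], g["spike_time_s"]):
                if int(tid) not in spikes:
                    raise SchemaError(
                        f"unit {row.unit_id}: spike on unknown trial {tid}"
                    )
                spikes[int(tid)].append(float(t))
        units.append(
            UnitSpikeData(
                unit_id=str(row.unit_id),
                patient_id=str(row.patient_id),
                region=str(row.region),
                phase=str(row.phase),
                trial_ids=tids,
                spikes=[np.sort(np.array(spikes[tid])) for tid in tids],
            )
        )
    return Dataset(trials=by_phase, units=units)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_results(path: str | Path, objects: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(objects, fh, cls=_NumpyEncoder, indent=2, sort_keys=True)


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def per_unit_structure_to_spike_table(per_unit: dict) -> pd.DataFrame:
    """Adapter for a deposited-style per-unit spike-train structure.

    Maps ``{unit_id: {"patient_id", "region", "phase", "trials": {trial_id:
    [spike times...]}}}`` (the layout of per-unit archival deposits, one
    struct per unit with trial-indexed spike-time vectors) onto the flat
    spike table.  Total spike count is preserved exactly.  Whether archived
    units were stored pre- or post-inclusion filtering is deposit-specific,
    so no quality filtering is applied here.
    """
    recs = []
    for unit_id, info in per_unit.items():
        for trial_id, times in info["trials"].items():
            for t in np.asarray(times, dtype=float):
                recs.append(
                    (info["patient_id"], unit_id, info["region"], info["phase"],
                     int(trial_id), float(t))
                )
    return pd.DataFrame(recs, columns=SPIKE_COLUMNS)
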