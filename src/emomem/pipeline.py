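"""Orchestration: behavioral summaries, run configuration, and the full
simulate -> QC -> responsiveness -> census -> mixed model -> dPCA pipeline.

Every stage reads its parameters from a single :class:`RunConfig`; a hash
of the config is embedded in all outputs so a report can always be traced
to the exact settings and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import census as census_mod
from . import dpca as dpca_mod
from . import mixed_model as mm
from . import responsiveness as resp_mod
from .core import PHASES, TrialRecord, quality_filter, remove_artifact_spikes
from .io import Dataset, write_results
from .psth import build_population_tensor, build_ztable
from .synth import CohortConfig, simulate_cohort

log = logging.getLogger("emomem")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run."""

    seed: int = 0
    output_dir: str = "emomem_out"
    phases: tuple[str, ...] = PHASES
    baseline_window: tuple[float, float] = (-1.5, -0.2)
    stimulus_window: tuple[float, float] = (0.2, 1.5)
    peri_window: tuple[float, float] = (-1.5, 2.5)
    psth_window: tuple[float, float] = (-0.5, 2.5)
    psth_sigma: float = 0.05
    psth_bin: float = 0.01
    alpha: float = 0.05
    n_perm: int = 1000
    census_B: int = 10_000
    bonferroni_pairwise_p: float = 0.0086
    dpca_components: int = 20
    dpca_lambda: float | str = 0.0
    n_iter: int = 100
    n_shuffles: int = 100
    stratify: tuple[str, ...] = ("region",)
    min_pr: float = 0.05      # behavioral inclusion: PR >= min_pr
    min_dprime: float = 0.1   # and d' >= min_dprime
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        for name in ("baseline_window", "stimulus_window", "peri_window",
                     "psth_window"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"{name} must satisfy lo < hi")
        if not set(self.phases) <= set(PHASES):
            raise ValueError(f"unknown phase in {self.phases}")
        self.cohort.validate()

    def hash(self) -> str:
        # output_dir is where results land, not an analysis parameter
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            raw["cohort"] = CohortConfig(**raw["cohort"])
        for key in ("baseline_window", "stimulus_window", "peri_window",
                    "psth_window", "phases", "stratify"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class BehavioralSummary:
    per_patient: pd.DataFrame   # patient x emotion rates, PR, d'
    anova: dict                 # repeated-measures memory x emotion ANOVA
    included_patients: list[str]


def _dprime(hit: float, fa: float, n_old: int, n_new: int) -> float:
    # extreme-rate correction: 0 -> 1/(2N), 1 -> 1 - 1/(2N)
    hit = min(max(hit, 1.0 / (2 * n_old)), 1 - 1.0 / (2 * n_old))
    fa = min(max(fa, 1.0 / (2 * n_new)), 1 - 1.0 / (2 * n_new))
    return float(sps.norm.ppf(hit) - sps.norm.ppf(fa))


def behavioral_summary(
    recognition_trials: list[TrialRecord],
    min_pr: float = 0.05,
    min_dprime: float = 0.1,
) -> BehavioralSummary:
    """Recognition performance per patient and emotion.

    Hit rate counts Remember responses to old items; the false-alarm rate
    counts old responses (R or K) to new items.  PR = hit - FA and d' uses
    the inverse-normal transform with the 1/(2N) extreme-rate correction.
    The cohort-level test is a 2x2 repeated-measures ANOVA on remembered%
    vs FA% crossed with emotion.  Patients below the PR/d' inclusion
    thresholds are flagged (not dropped).
    """
    rows = []
    patients = sorted({t.patient_id or "all" for t in recognition_trials})
    for pid in patients:
        ts = [
            t for t in recognition_trials if (t.patient_id or "all") == pid
        ]
        for emo in ("emotional", "neutral"):
            old = [t for t in ts if t.emotion == emo and t.old_new == "old"]
            new = [t for t in ts if t.emotion == emo and t.old_new == "new"]
            if not new:
                raise ValueError(f"patient {pid}: no new {emo} trials")
            n_old, n_new = len(old), len(new)
            r = sum(t.response == "R" for t in old) / n_old
            k = sum(t.response == "K" for t in old) / n_old
            miss = sum(t.response == "N" for t in old) / n_old
            fa = sum(t.response in ("R", "K") for t in new) / n_new
            rows.append(
                (pid, emo, n_old, n_new, r, k, miss, fa, r - fa,
                 _dprime(r, fa, n_old, n_new))
            )
    per_patient = pd.DataFrame(
        rows,
        columns=["patient_id", "emotion", "n_old", "n_new", "hit_rate_R",
                 "know_rate", "miss_rate", "fa_rate", "PR", "dprime"],
    )

    # repeated-measures ANOVA: memory (remembered% vs FA%) x emotion
    long = pd.concat(
        [
            per_patient.assign(memory="remembered", value=per_patient.hit_rate_R),
            per_patient.assign(memory="fa", value=per_patient.fa_rate),
        ],
        ignore_index=True,
    )[["patient_id", "emotion", "memory", "value"]]
    anova: dict = {}
    if per_patient["patient_id"].nunique() >= 2:
        from statsmodels.stats.anova import AnovaRM

        res = AnovaRM(
            long, depvar="value", subject="patient_id",
            within=["memory", "emotion"],
        ).fit()
        tbl = res.anova_table
        anova = {
            term: {
                "F": float(tbl.loc[term, "F Value"]),
                "df1": float(tbl.loc[term, "Num DF"]),
                "df2": float(tbl.loc[term, "Den DF"]),
                "p": float(tbl.loc[term, "Pr > F"]),
            }
            for term in tbl.index
        }

    overall = per_patient.groupby("patient_id")[["PR", "dprime"]].mean()
    included = overall[
        (overall["PR"] >= min_pr) & (overall["dprime"] >= min_dprime)
    ].index.tolist()
    return BehavioralSummary(
        per_patient=per_patient, anova=anova, included_patients=included
    )


def _phase_analysis(
    dataset: Dataset, phase: str, config: RunConfig
) -> dict:
    trials = dataset.trials[phase]
    units = dataset.units_for(phase)
    units = [remove_artifact_spikes(u)[0] for u in units]
    retained, reports = quality_filter(
        units, phase, window=config.peri_window
    )
    log.info("%s: %d/%d units pass QC", phase, len(retained), len(units))

    resp = resp_mod.run_responsiveness(
        retained, trials, phase, n_perm=config.n_perm, seed=config.seed
    )
    resp_summary = resp_mod.responsiveness_summary(resp, alpha=config.alpha)

    unit_counts, unanalyzable = census_mod.build_unit_counts(
        retained, trials, phase, stimulus=config.stimulus_window
    )
    census = census_mod.census_all(
        unit_counts, B=config.census_B, alpha=config.alpha, seed=config.seed
    )
    strata = {
        by: census_mod.stratified_census(
            unit_counts, by=by, B=config.census_B, alpha=config.alpha,
            seed=config.seed,
        )
        for by in config.stratify
    }
    pairwise = None
    if phase == "recognition":
        cats = census_mod.build_unit_categories(
            retained, trials, stimulus=config.stimulus_window
        )
        pairwise = census_mod.pairwise_census(
            cats, B=config.census_B, alpha=config.alpha, seed=config.seed
        )

    ztable, z_excluded = build_ztable(
        retained, trials, baseline=config.baseline_window,
        stimulus=config.stimulus_window,
    )
    mixed = None
    try:
        mixed = mm.fit_mixed_model(ztable, phase)
        mm.pairwise_contrasts(mixed)
    except ValueError as exc:
        log.warning("%s: mixed model skipped (%s)", phase, exc)

    tensor = build_population_tensor(
        retained, trials, phase, window=config.psth_window,
        sigma=config.psth_sigma, bin_width=config.psth_bin,
    )
    n_comp = min(config.dpca_components, tensor.n_units)
    model = dpca_mod.fit_dpca(
        tensor, single_trials=tensor, n_components=n_comp,
        lam=config.dpca_lambda, seed=config.seed,
    )
    var_report = dpca_mod.explained_variance(model)
    signal_frac = dpca_mod.estimate_signal_variance(tensor)
    significance = {}
    for phi in dpca_mod.CONDITION_MARGINALIZATIONS:
        try:
            significance[phi] = dpca_mod.decode_significance(
                model, tensor, phi, n_iter=config.n_iter,
                n_shuffles=config.n_shuffles, seed=config.seed,
            )
        except ValueError as exc:
            log.warning("%s: decoding %s skipped (%s)", phase, phi, exc)
    pca = dpca_mod.pca_baseline(tensor, n_components=5)

    return {
        "phase": phase,
        "qc": reports,
        "responsiveness": resp,
        "responsiveness_summary": resp_summary,
        "census": census,
        "census_strata": strata,
        "pairwise": pairwise,
        "unanalyzable_units": unanalyzable,
        "ztable": ztable,
        "ztable_excluded": z_excluded,
        "mixed_model": mixed,
        "tensor": tensor,
        "dpca": model,
        "dpca_variance": var_report,
        "signal_variance_fraction": signal_frac,
        "decoding": significance,
        "pca": pca,
    }


def _census_json(c: census_mod.CensusResult) -> dict:
    return {
        "effect": c.effect, "observed_count": c.observed_count,
        "p": c.p, "B": c.B, "n_units": c.n_units,
        "underpowered": c.underpowered,
        "null_count_mean": float(np.mean(c.null_counts)),
    }


def _summarize(result: dict, config: RunConfig) -> dict:
    """JSON-safe summary of one phase's analysis."""
    out = {
        "phase": result["phase"],
        "n_units_qc_pass": int(sum(r.included for r in result["qc"])),
        "n_units_total": len(result["qc"]),
        "responsiveness_summary":
            result["responsiveness_summary"].to_dict(orient="records"),
        "census": {k: _census_json(v) for k, v in result["census"].items()},
        "census_strata": {
            by: {s: {k: _census_json(v) for k, v in res.items()}
                 for s, res in strat.items()}
            for by, strat in result["census_strata"].items()
        },
        "signal_variance_fraction": result["signal_variance_fraction"],
        "dpca_variance": result["dpca_variance"],
        "decoding": {
            phi: {
                "fraction_significant_bins":
                    float(sig.significant.mean()),
                "peak_accuracy": float(sig.accuracy.max()),
                "chance": sig.chance,
            }
            for phi, sig in result["decoding"].items() if sig is not None
        },
    }
    if result["pairwise"] is not None:
        out["pairwise"] = {
            "-".join(k): _census_json(v) for k, v in result["pairwise"].items()
        }
        out["pairwise_threshold_p"] = config.bonferroni_pairwise_p
    if result["mixed_model"] is not None:
        mixed = result["mixed_model"]
        out["mixed_model"] = {
            "terms": mixed.terms.reset_index().to_dict(orient="records"),
            "variance_components": mixed.variance_components,
            "converged": mixed.converged,
            "contrasts": (
                mixed.contrasts.to_dict(orient="records")
                if mixed.contrasts is not None else None
            ),
        }
    return out


def _figures(result: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phase = result["phase"]
    model = result["dpca"]
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, phi in zip(
        axes.ravel(), dpca_mod.MARGINALIZATIONS
    ):
        comps = model.components_of(phi)
        if comps.size:
            c = comps[0]
            for e in range(model.scores.shape[1]):
                for m in range(model.scores.shape[2]):
                    ax.plot(model.time, model.scores[c, e, m],
                            label=f"e{e} m{m}")
            ax.set_title(
                f"{phi} dPC ({model.explained_var_pct[c]:.1f}% var)"
            )
        sig = result["decoding"].get(phi)
        if sig is not None:
            y = ax.get_ylim()[0]
            ax.plot(sig.time[sig.significant],
                    np.full(sig.significant.sum(), y), "k.", ms=2)
        ax.axvline(0, color="gray", lw=0.5)
        ax.axvline(0.5, color="gray", lw=0.5)
    axes[0, 0].legend(fontsize=6)
    fig.suptitle(f"dPCA components - {phase}")
    fig.savefig(outdir / f"dpca_{phase}.png", dpi=120)
    plt.close(fig)


def run_full_analysis(
    config: RunConfig, dataset: Dataset | None = None, figures: bool = True
) -> dict:
    """Execute the whole pipeline and write a reproducible report bundle.

    With no ``dataset``, a synthetic cohort is simulated from
    ``config.cohort``.  Writes ``report.json`` (plus per-phase figures)
    into ``config.output_dir``; the returned dict holds the full in-memory
    results keyed by phase.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if dataset is None:
        dataset, truth = simulate_cohort(config.cohort, seed=config.seed)

    report: dict = {"config_hash": config.hash(), "seed": config.seed}
    results: dict = {"config": config, "ground_truth": truth}

    behavior = behavioral_summary(
        dataset.trials["recognition"], min_pr=config.min_pr,
        min_dprime=config.min_dprime,
    )
    results["behavior"] = behavior
    report["behavior"] = {
        "per_patient": behavior.per_patient.to_dict(orient="records"),
        "anova": behavior.anova,
        "included_patients": behavior.included_patients,
    }

    for phase in config.phases:
        try:
            res = _phase_analysis(dataset, phase, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed in phase {phase!r}: {exc}") from exc
        results[phase] = res
        report[phase] = _summarize(res, config)
        if figures:
            _figures(res, outdir)

    write_results(outdir / "report.json", report)
    return results
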