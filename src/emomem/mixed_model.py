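"""Population summary of abs(z) with a nested linear mixed-effects model.

The model is  abs(z) ~ 1 + Emotion * Memory + (1 | Patient / Neuron):
fixed effects for emotion, memory and their interaction, with random
intercepts for patients and for neurons nested within patients (neurons are
pseudo-replicated across trials and patients contribute unequal numbers of
neurons).  Fixed terms are tested with omnibus Wald chi-square tests on the
sum-coded coefficient blocks; follow-up pairwise contrasts are estimated
marginal mean differences between memory levels within each emotion, with
Benjamini-Hochberg FDR correction across the contrast family.

Estimation is delegated to statsmodels' MixedLM (REML); the contribution of
this module is the abs(z) construction upstream, the model contract, and
the Wald/contrast machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


@dataclass
class MixedModelResult:
    phase: str
    terms: pd.DataFrame              # index: term; columns chi2, df, p
    variance_components: dict[str, float]
    converged: bool
    n_obs: int
    n_patients: int
    n_neurons: int
    contrasts: pd.DataFrame | None = None
    _fit: object = field(default=None, repr=False)


def _term_indices(exog_names: list[str]) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {"Emotion": [], "Memory": [], "Emotion:Memory": []}
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            continue
        if ":" in name:
            idx["Emotion:Memory"].append(i)
        elif "emotion" in name:
            idx["Emotion"].append(i)
        elif "memory" in name:
            idx["Memory"].append(i)
    return idx


def fit_mixed_model(ztable: pd.DataFrame, phase: str) -> MixedModelResult:
    """Fit the nested mixed model on trial-level abs(z) rows.

    ``ztable`` needs columns patient_id, unit_id, emotion, memory, abs_z.
    Encoding uses 2-level memory (R/F), recognition 3-level (RHit/Miss/CR).
    Raises on fewer than 2 patients or fewer than 2 neurons in any patient;
    a non-converged or singular fit is reported in ``converged``, not
    masked.
    """
    df = ztable.copy()
    required = {"patient_id", "unit_id", "emotion", "memory", "abs_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ztable missing columns {sorted(missing)}")
    n_pat = df["patient_id"].nunique()
    if n_pat < 2:
        raise ValueError("mixed model requires >= 2 patients")
    per_pat = df.groupby("patient_id")["unit_id"].nunique()
    if (per_pat < 2).any():
        raise ValueError("every patient needs >= 2 neurons")

    levels = (
        ["R", "F"] if phase == "encoding" else ["RHit", "Miss", "CR"]
    )
    df["memory"] = pd.Categorical(df["memory"], categories=levels)
    df["emotion"] = pd.Categorical(
        df["emotion"], categories=["emotional", "neutral"]
    )

    model = smf.mixedlm(
        "abs_z ~ C(emotion, Sum) * C(memory, Sum)",
        data=df,
        groups="patient_id",
        re_formula="1",
        vc_formula={"neuron": "0 + C(unit_id)"},
    )
    fit = model.fit(reml=True)

    k_fe = len(fit.fe_params)
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    rows = []
    for term, idx in _term_indices(list(fit.fe_params.index)).items():
        b = beta[idx]
        v = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(v, b))
        dfree = len(idx)
        rows.append((term, chi2, dfree, float(stats.chi2.sf(chi2, dfree))))
    terms = pd.DataFrame(
        rows, columns=["term", "chi2", "df", "p"]
    ).set_index("term")

    vc = {
        "patient": float(np.asarray(fit.cov_re)[0, 0]),
        "neuron_within_patient": float(fit.vcomp[0]) if len(fit.vcomp) else 0.0,
        "residual": float(fit.scale),
    }
    return MixedModelResult(
        phase=phase, terms=terms, variance_components=vc,
        converged=bool(fit.converged), n_obs=int(len(df)),
        n_patients=int(n_pat), n_neurons=int(df["unit_id"].nunique()),
        _fit=fit,
    )


def _cell_design_row(fit, emotion: str, memory: str) -> np.ndarray:
    design_info = fit.model.data.design_info
    from patsy import dmatrix

    row = dmatrix(
        design_info,
        pd.DataFrame({"emotion": [emotion], "memory": [memory]}),
        return_type="dataframe",
    )
    return np.asarray(row)[0]


def pairwise_contrasts(
    result: MixedModelResult, method: str = "fdr_bh"
) -> pd.DataFrame:
    """Memory-level contrasts of estimated marginal means within each emotion.

    Encoding: R - F per emotion.  Recognition: RHit - Miss, RHit - CR,
    Miss - CR per emotion.  p-values are two-sided normal (Z ratio) and
    adjusted within the whole family by Benjamini-Hochberg FDR.
    """
    fit = result._fit
    if fit is None:
        raise ValueError("result carries no fitted model")
    levels = (
        ["R", "F"] if result.phase == "encoding" else ["RHit", "Miss", "CR"]
    )
    pairs = [
        (a, b) for i, a in enumerate(levels) for b in levels[i + 1:]
    ]
    k_fe = len(fit.fe_params)
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    rows = []
    for emotion in ("emotional", "neutral"):
        for a, b in pairs:
            c = _cell_design_row(fit, emotion, a) - _cell_design_row(fit, emotion, b)
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            z = est / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
            rows.append((emotion, f"{a} - {b}", est, se, z, p))
    out = pd.DataFrame(
        rows, columns=["emotion", "contrast", "estimate", "se", "z_ratio", "p"]
    )
    out["p_adjusted"] = multipletests(out["p"], method=method)[1]
    result.contrasts = out
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
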