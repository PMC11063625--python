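"""Demixed principal component analysis of the population tensor.

Given trial-averaged firing rates X[unit, emotion, memory, time], dPCA
splits the per-unit-centered tensor into four additive marginalizations --
condition-independent (time), emotion x time, memory x time and the
emotion x memory interaction -- by sequential condition averaging, then
finds, per marginalization phi, decoder/encoder axis pairs (D, F)
minimizing the ridge-penalized reduced-rank regression loss

    || X_phi - F D X ||^2 + mu ||F D||^2 ,

whose closed-form solution takes the leading singular vectors of
A X with A = X_phi X^T (X X^T + mu I)^{-1}.  Unlike PCA, the decoder and
encoder of a component need not coincide, which lets a component capture
variance attributable to a single task factor (demixing) while remaining
close to the principal subspace (compression).

Components are pooled across marginalizations and ranked by explained
variance.  Decoding significance of a condition component is assessed by
stratified Monte Carlo leave-one-pseudo-trial-out cross-validation: at each
time bin held-out pseudo-trials are projected on the decoder axis and
assigned to the nearest training class mean; real accuracy is compared
with the 97.5% quantile of accuracies obtained after shuffling trial-type
labels (preserving per-condition trial counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psth import PopulationTensor

MARGINALIZATIONS = ("time", "emotion", "memory", "interaction")
CONDITION_MARGINALIZATIONS = ("emotion", "memory", "interaction")


@dataclass
class MarginalizationSet:
    """Additive decomposition of the centered trial-average tensor."""

    unit_mean: np.ndarray           # (N,)
    terms: dict[str, np.ndarray]    # name -> (N, E, M, T), broadcast to full

    def reconstruction(self) -> np.ndarray:
        return (
            sum(self.terms.values())
            + self.unit_mean[:, None, None, None]
        )


@dataclass
class DPCAModel:
    encoders: np.ndarray            # (N, C), orthonormal within marginalization
    decoders: np.ndarray            # (C, N)
    marginalization: list[str]      # phi per component
    explained_var_pct: np.ndarray   # (C,) % of total centered variance
    marg_var_pct: np.ndarray        # (C, 4) variance split over marginalizations
    scores: np.ndarray              # (C, E, M, T) component time courses
    regularization: float           # mu actually used
    total_var: float
    time: np.ndarray | None = None
    unit_mean: np.ndarray | None = None
    shape: tuple = ()

    @property
    def n_components(self) -> int:
        return self.decoders.shape[0]

    def components_of(self, phi: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.marginalization) == phi)


@dataclass
class DecodingSignificance:
    marginalization: str
    component: int
    time: np.ndarray
    accuracy: np.ndarray            # (T,)
    shuffle_q95: np.ndarray
    shuffle_q975: np.ndarray
    shuffle_max: np.ndarray
    significant: np.ndarray         # bool (T,): accuracy > q975
    n_iterations: int
    n_shuffles: int
    seed: int
    chance: float


def _as_tensor(tensor) -> np.ndarray:
    if isinstance(tensor, PopulationTensor):
        return tensor.avg
    return np.asarray(tensor, dtype=float)


def marginalize(tensor) -> MarginalizationSet:
    """Sequential-averaging split of X into time/emotion/memory/interaction.

    The decomposition is exact: unit mean + sum of terms reproduces the
    input tensor to machine precision.
    """
    X = _as_tensor(tensor)
    if X.ndim != 4:
        raise ValueError("expected tensor of shape (units, E, M, T)")
    N, E, M, T = X.shape
    if E < 2 or M < 2:
        raise ValueError("condition axes must have >= 2 levels")
    unit_mean = X.mean(axis=(1, 2, 3))
    Xc = X - unit_mean[:, None, None, None]
    t_term = Xc.mean(axis=(1, 2), keepdims=True)         # (N,1,1,T)
    e_term = Xc.mean(axis=2, keepdims=True) - t_term     # (N,E,1,T)
    m_term = Xc.mean(axis=1, keepdims=True) - t_term     # (N,1,M,T)
    x_term = Xc - t_term - e_term - m_term
    full = np.broadcast_to
    terms = {
        "time": np.ascontiguousarray(full(t_term, X.shape)),
        "emotion": np.ascontiguousarray(full(e_term, X.shape)),
        "memory": np.ascontiguousarray(full(m_term, X.shape)),
        "interaction": x_term,
    }
    return MarginalizationSet(unit_mean=unit_mean, terms=terms)


def _flat(X: np.ndarray) -> np.ndarray:
    return X.reshape(X.shape[0], -1)


def _fit_axes(
    Xf: np.ndarray, marg_flat: dict[str, np.ndarray], mu: float, q: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-marginalization reduced-rank ridge solutions, concatenated."""
    N = Xf.shape[0]
    G = Xf @ Xf.T
    reg = np.linalg.inv(G + mu * np.eye(N)) if mu > 0 else np.linalg.pinv(G)
    encoders, decoders, margs = [], [], []
    for phi, Xphi in marg_flat.items():
        A = Xphi @ Xf.T @ reg
        M_pred = A @ Xf
        U, s, _ = np.linalg.svd(M_pred, full_matrices=False)
        k = min(q, np.count_nonzero(s > s[0] * 1e-12) if s.size else 0)
        if k == 0:
            continue
        F = U[:, :k]
        D = F.T @ A
        encoders.append(F)
        decoders.append(D)
        margs.extend([phi] * k)
    if not encoders:
        # degenerate all-zero input: emit a single null component
        return np.zeros((N, 1)), np.zeros((1, N)), ["time"]
    return np.hstack(encoders), np.vstack(decoders), margs


def _component_variances(
    F: np.ndarray, D: np.ndarray, Xf: np.ndarray,
    marg_flat: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Explained total variance per component, and its split over
    marginalizations (variance of the decoder projection of each term)."""
    total = float(np.sum(Xf**2))
    C = D.shape[0]
    ev = np.empty(C)
    marg_split = np.empty((C, len(MARGINALIZATIONS)))
    for c in range(C):
        d = D[c]
        f = F[:, c]
        s = d @ Xf
        ev[c] = 2 * float(f @ (Xf @ s)) - float(s @ s)
        for j, phi in enumerate(MARGINALIZATIONS):
            marg_split[c, j] = float(np.sum((d @ marg_flat[phi]) ** 2))
    ev_pct = 100.0 * ev / total if total > 0 else np.zeros(C)
    row_sums = marg_split.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return ev_pct, 100.0 * marg_split / row_sums


def fit_dpca(
    tensor,
    single_trials=None,
    n_components: int = 20,
    lam: float | str = 0.0,
    seed: int = 0,
    n_folds: int = 10,
) -> DPCAModel:
    """Fit demixed PCA on the trial-averaged tensor.

    ``lam`` is the ridge strength as a fraction of total variance
    (mu = lam * ||X||^2); pass ``"cv"`` to select it by held-out-trial
    reconstruction error (requires ``single_trials``, a
    :class:`PopulationTensor` or an (N, E, M, max_trials, T) NaN-padded
    array).  ``n_components`` caps the per-marginalization rank and the
    pooled model size.
    """
    pop = tensor if isinstance(tensor, PopulationTensor) else None
    X = _as_tensor(tensor)
    N = X.shape[0]
    if n_components > N:
        raise ValueError("n_components cannot exceed the number of units")
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains non-finite values")

    ms = marginalize(X)
    Xc = X - ms.unit_mean[:, None, None, None]
    Xf = _flat(Xc)
    marg_flat = {k: _flat(v) for k, v in ms.terms.items()}
    total = float(np.sum(Xf**2))

    if lam == "cv":
        trials = single_trials if single_trials is not None else pop
        if trials is None:
            raise ValueError("lambda='cv' requires single trials")
        lam_value = _select_lambda(
            X, trials, n_components, seed=seed, n_folds=n_folds
        )
    else:
        lam_value = float(lam)
    mu = lam_value * total

    F, D, margs = _fit_axes(Xf, marg_flat, mu, n_components)
    ev_pct, marg_split = _component_variances(F, D, Xf, marg_flat)
    # rank by explained variance, but never drop a marginalization entirely:
    # its leading component stays so condition components remain decodable
    ranked = list(np.argsort(ev_pct)[::-1])
    protected = set()
    for phi in MARGINALIZATIONS:
        members = [i for i, m in enumerate(margs) if m == phi]
        if members:
            protected.add(max(members, key=lambda i: ev_pct[i]))
    order = []
    for i in ranked:
        slots_left = n_components - len(order)
        still_needed = len(protected - set(order) - {i})
        if i in protected or slots_left > still_needed:
            order.append(i)
        if len(order) == n_components:
            break
    order = np.asarray(order)
    F, D = F[:, order], D[order]
    margs = [margs[i] for i in order]
    ev_pct, marg_split = ev_pct[order], marg_split[order]
    scores = (D @ Xf).reshape(D.shape[0], *X.shape[1:])

    return DPCAModel(
        encoders=F, decoders=D, marginalization=margs,
        explained_var_pct=ev_pct, marg_var_pct=marg_split, scores=scores,
        regularization=mu, total_var=total,
        time=pop.time if pop is not None else None,
        unit_mean=ms.unit_mean, shape=X.shape,
    )


def _padded(single_trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(single_trials, PopulationTensor):
        return single_trials.padded_trials(), single_trials.counts
    P = np.asarray(single_trials, dtype=float)
    counts = np.sum(~np.isnan(P[..., 0]), axis=3)
    return P, counts


DEFAULT_LAMBDA_GRID = (0.0, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)


def _select_lambda(
    X: np.ndarray,
    single_trials,
    n_components: int,
    seed: int = 0,
    n_folds: int = 10,
    grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> float:
    """Ridge strength by held-out-trial reconstruction error.

    Each fold holds out one random trial per (unit, condition) cell as the
    test average; dPCA axes fit on the remaining-trial averages must
    reconstruct it.  The lambda minimizing mean squared error is returned.
    """
    P, counts = _padded(single_trials)
    if np.any(counts < 2):
        raise ValueError("lambda CV needs >= 2 trials per condition cell")
    rng = np.random.default_rng(seed)
    N, E, M, _, T = P.shape
    sums = np.nansum(P, axis=3)
    errors = np.zeros(len(grid))
    for _ in range(n_folds):
        pick = (rng.random((N, E, M)) * counts).astype(int)
        test = np.take_along_axis(
            P, pick[..., None, None], axis=3
        )[:, :, :, 0, :]
        train = (sums - test) / (counts - 1)[..., None]
        mtrain = marginalize(train)
        Xf_train = _flat(train - mtrain.unit_mean[:, None, None, None])
        marg_train = {k: _flat(v) for k, v in mtrain.terms.items()}
        test_c = _flat(test - mtrain.unit_mean[:, None, None, None])
        tot_train = float(np.sum(Xf_train**2))
        for gi, lam in enumerate(grid):
            F, D, _ = _fit_axes(
                Xf_train, marg_train, lam * tot_train, n_components
            )
            recon = F @ (D @ Xf_train)
            errors[gi] += float(np.sum((test_c - recon) ** 2))
    return grid[int(np.argmin(errors))]


def explained_variance(model: DPCAModel, first_k: int = 15) -> dict:
    """Variance accounting: per-component %, marginalization totals,
    cumulative curve, and pie shares normalized to the first ``first_k``."""
    ev = model.explained_var_pct
    k = min(first_k, ev.size)
    cum = np.cumsum(ev)
    marg_totals = {
        phi: float(ev[model.components_of(phi)].sum())
        for phi in MARGINALIZATIONS
    }
    top = slice(0, k)
    top_total = float(ev[top].sum())
    pie = {}
    for phi in MARGINALIZATIONS:
        members = [
            i for i in range(k) if model.marginalization[i] == phi
        ]
        pie[phi] = (
            100.0 * float(ev[members].sum()) / top_total if top_total > 0 else 0.0
        )
    return {
        "component_pct": ev.tolist(),
        "component_marginalization": list(model.marginalization),
        "cumulative_pct": cum.tolist(),
        "marginalization_totals_pct": marg_totals,
        "pie_normalized_pct": pie,
        "first_k": k,
    }


def estimate_signal_variance(tensor, single_trials=None) -> float:
    """Fraction of the trial-average variance attributable to signal.

    The trial average of n trials inherits 1/n of the single-trial noise
    variance; estimating that noise from the across-trial variability
    within condition cells gives the expected noise content of the tensor,
    and the remainder is potentially explainable ("signal") variance.
    """
    if isinstance(tensor, PopulationTensor) and single_trials is None:
        single_trials = tensor
    X = _as_tensor(tensor)
    P, counts = _padded(single_trials)
    if np.any(counts < 2):
        raise ValueError("signal variance needs >= 2 trials per cell")
    ms = marginalize(X)
    Xc = X - ms.unit_mean[:, None, None, None]
    total = float(np.sum(Xc**2))
    if total == 0:
        return 1.0
    with np.errstate(invalid="ignore"):
        cell_var = np.nanvar(P, axis=3, ddof=1)   # (N, E, M, T)
    noise = float(np.nansum(cell_var / counts[..., None]))
    return float(np.clip((total - noise) / total, 0.0, 1.0))


def _class_reduce(
    arr: np.ndarray, E: int, M: int, phi: str
) -> np.ndarray:
    """Collapse a (..., E*M, T) array onto the decoded classes of phi."""
    full = arr.reshape(*arr.shape[:-2], E, M, arr.shape[-1])
    if phi == "emotion":
        return full.mean(axis=-2)
    if phi == "memory":
        return full.mean(axis=-3)
    return arr  # interaction: all cells are classes


def decode_significance(
    model: DPCAModel,
    single_trials,
    marginalization: str,
    component: int | None = None,
    n_iter: int = 1000,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> DecodingSignificance:
    """Cross-validated decoding significance of one condition component.

    Per iteration one held-out pseudo-trial per condition (a random trial
    per unit per cell) is projected on the component's decoder axis and
    classified at each time bin to the nearest training-class mean; real
    accuracy is the mean over iterations.  The null repeats the whole
    procedure -- including refitting the decoder axis -- after shuffling
    trial-type labels within units (preserving per-condition counts), and
    significance marks bins where real accuracy exceeds the 97.5% quantile
    of shuffled accuracies.  Ties in classification go to the first class
    in condition order.
    """
    if marginalization not in CONDITION_MARGINALIZATIONS:
        raise ValueError(f"cannot decode marginalization {marginalization!r}")
    comps = model.components_of(marginalization)
    if comps.size == 0:
        raise ValueError(f"model has no {marginalization} component")
    c = int(comps[0]) if component is None else int(component)
    d = model.decoders[c]

    P, counts = _padded(single_trials)
    N, E, M, J, T = P.shape
    if np.any(counts < 2):
        raise ValueError("decoding needs >= 2 trials per condition cell")
    n_cells = E * M
    cellcounts = counts.reshape(N, n_cells)
    tot = cellcounts.sum(axis=1)
    Jmax = int(tot.max())

    # flat per-unit trial store: rates (N, Jmax, T); cell membership of each
    # row is given by an index matrix R (N, cells, maxcell)
    flat_r = np.zeros((N, Jmax, T))
    maxcell = int(cellcounts.max())
    R_real = np.zeros((N, n_cells, maxcell), dtype=np.intp)
    Pc = P.reshape(N, n_cells, J, T)
    for u in range(N):
        start = 0
        for cell in range(n_cells):
            nc = int(cellcounts[u, cell])
            flat_r[u, start:start + nc] = Pc[u, cell, :nc]
            R_real[u, cell, :nc] = np.arange(start, start + nc)
            start += nc

    root = np.random.SeedSequence(seed)
    s_real, s_shuffle = root.spawn(2)
    accuracy = _decode_accuracy(
        d[:, None, None] * flat_r, R_real, cellcounts, E, M, marginalization,
        n_iter, np.random.default_rng(s_real),
    )

    mu_frac = model.regularization / model.total_var if model.total_var else 0.0
    rng_s = np.random.default_rng(s_shuffle)
    shuffled = np.empty((n_shuffles, T))
    urange = np.arange(N)[:, None]
    for s in range(n_shuffles):
        R_s = np.zeros_like(R_real)
        for u in range(N):
            perm = rng_s.permutation(tot[u])
            start = 0
            for cell in range(n_cells):
                nc = int(cellcounts[u, cell])
                R_s[u, cell, :nc] = perm[start:start + nc]
                start += nc
        # shuffled trial-average tensor and a refit decoder axis
        mask = np.arange(maxcell)[None, None, :] < cellcounts[:, :, None]
        gathered = flat_r[urange, R_s.reshape(N, -1)].reshape(
            N, n_cells, maxcell, T
        )
        sums_s = np.where(mask[..., None], gathered, 0.0).sum(axis=2)
        avg_s = (sums_s / cellcounts[..., None]).reshape(N, E, M, T)
        d_s = _refit_axis(avg_s, marginalization, mu_frac)
        shuffled[s] = _decode_accuracy(
            d_s[:, None, None] * flat_r, R_s, cellcounts, E, M,
            marginalization, n_iter, rng_s,
        )

    q95 = np.quantile(shuffled, 0.95, axis=0)
    q975 = np.quantile(shuffled, 0.975, axis=0)
    qmax = shuffled.max(axis=0)
    n_classes = {"emotion": E, "memory": M, "interaction": E * M}[marginalization]
    return DecodingSignificance(
        marginalization=marginalization, component=c,
        time=model.time if model.time is not None else np.arange(T),
        accuracy=accuracy, shuffle_q95=q95, shuffle_q975=q975,
        shuffle_max=qmax, significant=accuracy > q975,
        n_iterations=n_iter, n_shuffles=n_shuffles, seed=seed,
        chance=1.0 / n_classes,
    )


def _refit_axis(avg: np.ndarray, phi: str, mu_frac: float) -> np.ndarray:
    """Leading decoder axis of one marginalization on a (re)averaged tensor."""
    ms = marginalize(avg)
    Xf = _flat(avg - ms.unit_mean[:, None, None, None])
    Xphi = _flat(ms.terms[phi])
    total = float(np.sum(Xf**2))
    F, D, _ = _fit_axes(Xf, {phi: Xphi}, mu_frac * total, 1)
    return D[0]


def _decode_accuracy(
    q_flat: np.ndarray,
    R: np.ndarray,
    cellcounts: np.ndarray,
    E: int,
    M: int,
    phi: str,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean leave-one-pseudo-trial-out accuracy time series.

    ``q_flat`` holds decoder projections of every trial (N, Jmax, T); ``R``
    maps (unit, cell, within-cell index) -> row of ``q_flat``.
    """
    N, _, T = q_flat.shape
    n_cells = cellcounts.shape[1]
    urange = np.arange(N)[:, None]
    maxcell = R.shape[2]
    mask = np.arange(maxcell)[None, None, :] < cellcounts[:, :, None]
    gathered = q_flat[urange, R.reshape(N, -1)].reshape(N, n_cells, maxcell, T)
    sums = np.where(mask[..., None], gathered, 0.0).sum(axis=2)  # (N,cells,T)

    correct = np.zeros(T)
    for _ in range(n_iter):
        pick = (rng.random((N, n_cells)) * cellcounts).astype(int)
        rows = np.take_along_axis(R, pick[:, :, None], axis=2)[:, :, 0]
        test_u = q_flat[urange, rows]                  # (N, cells, T)
        train_u = (sums - test_u) / (cellcounts - 1)[:, :, None]
        test = test_u.sum(axis=0)                      # (cells, T)
        train = train_u.sum(axis=0)
        test_cls = _class_reduce(test, E, M, phi)      # (K, T)
        train_cls = _class_reduce(train, E, M, phi)
        dist = np.abs(test_cls[:, None, :] - train_cls[None, :, :])
        assigned = np.argmin(dist, axis=1)
        truth = np.arange(test_cls.shape[0])[:, None]
        correct += (assigned == truth).mean(axis=0)
    return correct / n_iter


@dataclass
class PCAResult:
    loadings: np.ndarray          # (N, k) orthonormal
    explained_var_pct: np.ndarray
    scores: np.ndarray            # (k, E, M, T)


def pca_baseline(tensor, n_components: int = 5) -> PCAResult:
    """Plain PCA (SVD) of the centered unit x (condition.time) matrix."""
    X = _as_tensor(tensor)
    ms = marginalize(X)
    Xf = _flat(X - ms.unit_mean[:, None, None, None])
    U, s, Vt = np.linalg.svd(Xf, full_matrices=False)
    k = min(n_components, s.size)
    total = float(np.sum(s**2))
    ev = 100.0 * s[:k] ** 2 / total if total > 0 else np.zeros(k)
    scores = (U[:, :k].T @ Xf).reshape(k, *X.shape[1:])
    return PCAResult(loadings=U[:, :k], explained_var_pct=ev, scores=scores)


def leave_one_region_out(
    tensor: PopulationTensor,
    region: str,
    n_components: int = 20,
    lam: float | str = 0.0,
    decode: bool = True,
    n_iter: int = 100,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Re-run the dPCA pipeline excluding all units of one region.

    Returns the reduced model plus the change in marginalization variance
    shares and (optionally) per-marginalization decoding significance.
    """
    regions = np.asarray(tensor.regions)
    if tensor.n_units and region not in set(regions) and region not in (
        "HIP", "AMY", "EC"
    ):
        raise ValueError(f"unknown region {region!r}")
    keep = regions != region
    if np.count_nonzero(~keep) == 0:
        sub = tensor
    else:
        sub = tensor.subset(keep)
    if len(set(sub.regions)) < 1:
        raise ValueError("no units left after exclusion")
    model = fit_dpca(
        sub, single_trials=sub, n_components=min(n_components, sub.n_units),
        lam=lam, seed=seed,
    )
    full_model = fit_dpca(
        tensor, single_trials=tensor,
        n_components=min(n_components, tensor.n_units), lam=lam, seed=seed,
    )
    report = {
        "excluded_region": region,
        "n_units": sub.n_units,
        "model": model,
        "marg_totals_pct": explained_variance(model)["marginalization_totals_pct"],
        "marg_totals_full_pct": explained_variance(full_model)[
            "marginalization_totals_pct"
        ],
    }
    if decode:
        sig = {}
        for phi in CONDITION_MARGINALIZATIONS:
            try:
                sig[phi] = decode_significance(
                    model, sub, phi, n_iter=n_iter, n_shuffles=n_shuffles,
                    seed=seed,
                )
            except ValueError:
                sig[phi] = None
        report["significance"] = sig
    return report
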