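"""Data analysis protocols: family-aware resampling, nested model selection.

Two protocols are provided.

``run_l1l2_dap`` is the stringent nested protocol: the cohort is split into
development and validation sets 15 times at the family level (relatives
never straddle a split), hyperparameters are chosen on each development set
by internal k-fold cross-validation scored jointly on mean squared error
and on the Canberra stability of the fold-wise ranked marker lists, the
selected model is refit on the whole development set, and accuracy is the
squared Pearson correlation between predicted and observed trait on the
untouched validation set.

``run_bootstrap_dap`` is the simpler baseline protocol: grid search on
50% interfamily resamplings maximizing mean squared correlation, then
evaluation of the selected parameters on further interfamily train/test
resamplings.  Because the same samples inform both selection and
evaluation, its accuracy estimates are flagged as potentially optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix, PhenotypeVector
from .l1l2 import (
    L1L2Hyperparams,
    L1L2Model,
    SolverSettings,
    fit_l1l2,
    fit_naive_elastic_net,
    predict,
    rank_features,
    rls_debias,
    select_support,
    _standardize,
)
from .stability import RankedList, stability_indicator

__all__ = [
    "SplitPlan",
    "GridPoint",
    "DapResult",
    "RegressorPlugin",
    "SVRPlugin",
    "RidgePlugin",
    "make_interfamily_splits",
    "squared_correlation",
    "tau_max",
    "make_grid",
    "run_internal_cv",
    "select_model",
    "run_l1l2_dap",
    "run_bootstrap_dap",
]


@dataclass
class SplitPlan:
    """Family-respecting development/validation resamplings with internal folds."""

    n_resamplings: int
    dev_families: list[list[str]]
    val_families: list[list[str]]
    fold_of_family: list[dict[str, int]]  # per resampling: family -> internal fold
    k_folds: int
    seed: int

    def indices(self, family_ids: Sequence[str], r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(dev sample indices, val sample indices, fold id per dev sample)."""
        fams = np.asarray(family_ids)
        dev_set = set(self.dev_families[r])
        val_set = set(self.val_families[r])
        dev = np.flatnonzero([f in dev_set for f in fams])
        val = np.flatnonzero([f in val_set for f in fams])
        folds = np.array([self.fold_of_family[r][fams[i]] for i in dev])
        return dev, val, folds


@dataclass(frozen=True)
class GridPoint:
    hyperparams: L1L2Hyperparams
    cv_mse: float
    cv_stability: float
    mean_support_size: float = 0.0


@dataclass
class DapResult:
    selected: list                    # per-resampling selected hyperparams/params
    r2: list[float]                   # per-resampling validation squared correlation
    ranked_lists: list[RankedList]
    weight_vectors: list[np.ndarray]  # per-resampling debiased weights (standardized scale)
    accuracy_stability: pd.DataFrame | None = None
    selection_bias_prone: bool = False

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def r2_range(self) -> tuple[float, float]:
        return (float(np.min(self.r2)), float(np.max(self.r2)))

    def summary(self) -> dict:
        return {
            "n_resamplings": len(self.r2),
            "mean_r2": self.mean_r2,
            "min_r2": self.r2_range[0],
            "max_r2": self.r2_range[1],
            "selection_bias_prone": self.selection_bias_prone,
        }


class RegressorPlugin(Protocol):
    """Contract for pluggable baseline regressors (fit / predict / rank)."""

    def fit(self, X: np.ndarray, y: np.ndarray, params: dict): ...

    def predict(self, model, X: np.ndarray) -> np.ndarray: ...

    def ranking_weights(self, X: np.ndarray, y: np.ndarray, params: dict) -> np.ndarray | None: ...


class SVRPlugin:
    """Support vector regression baseline (scikit-learn backend).

    Predictions use a Gaussian (RBF) kernel; feature-ranking weights come
    from a linear-kernel SVR fit with the same C/epsilon, since the RBF
    model has no per-feature weights.
    """

    def fit(self, X, y, params):
        from sklearn.svm import SVR

        m = SVR(kernel="rbf", C=params.get("C", 1.0), epsilon=params.get("epsilon", 0.1),
                gamma=params.get("gamma", "scale"))
        m.fit(X, y)
        return m

    def predict(self, model, X):
        return model.predict(X)

    def ranking_weights(self, X, y, params):
        from sklearn.svm import SVR

        m = SVR(kernel="linear", C=params.get("C", 1.0), epsilon=params.get("epsilon", 0.1))
        m.fit(X, y)
        return np.asarray(m.coef_).ravel()


class RidgePlugin:
    """Linear ridge baseline; its coefficients double as ranking weights."""

    def fit(self, X, y, params):
        from sklearn.linear_model import Ridge

        m = Ridge(alpha=params.get("alpha", 1.0))
        m.fit(X, y)
        return m

    def predict(self, model, X):
        return model.predict(X)

    def ranking_weights(self, X, y, params):
        return np.asarray(self.fit(X, y, params).coef_).ravel()


# ---------------------------------------------------------------------------
# Splits and scores


def make_interfamily_splits(
    family_ids: Sequence[str],
    n_resamplings: int = 15,
    dev_fraction: float = 0.7,
    k_folds: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Resample whole families into development/validation, plus internal folds.

    Families are shuffled per resampling and assigned to development until
    the development sample count reaches ``dev_fraction`` of the cohort;
    the rest validate.  Internal folds also split at family level (greedy
    balancing of sample counts), so no fold shares relatives with another.
    """
    if not (0.0 < dev_fraction < 1.0):
        raise ValueError("dev_fraction must lie in (0, 1)")
    fams = np.asarray(family_ids)
    unique, counts = np.unique(fams, return_counts=True)
    if unique.size < 2:
        raise ValueError("interfamily splits need at least two families")
    n = fams.size
    if counts.max() >= dev_fraction * n:
        big = unique[int(np.argmax(counts))]
        raise ValueError(f"family {big!r} alone exceeds the development fraction; splits impossible")
    sizes = dict(zip(unique.tolist(), counts.tolist()))
    rng = np.random.default_rng(seed)

    dev_families, val_families, fold_maps = [], [], []
    for _ in range(n_resamplings):
        order = list(rng.permutation(unique))
        dev, total = [], 0
        for f in order:
            if total >= dev_fraction * n:
                break
            dev.append(f)
            total += sizes[f]
        val = [f for f in order if f not in set(dev)]
        if not val:  # keep validation nonempty
            val = [dev.pop()]
        fold_load = [0] * k_folds
        fold_map: dict[str, int] = {}
        for f in dev:  # greedy: next family to the lightest fold
            k = int(np.argmin(fold_load))
            fold_map[f] = k
            fold_load[k] += sizes[f]
        dev_families.append([str(f) for f in dev])
        val_families.append([str(f) for f in val])
        fold_maps.append({str(k): v for k, v in fold_map.items()})
    return SplitPlan(n_resamplings, dev_families, val_families, fold_maps, k_folds, seed)


def squared_correlation(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation; zero-variance predictions score 0."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    st, sp = y_true.std(), y_pred.std()
    if st == 0 or sp == 0:
        return 0.0
    r = float(np.mean((y_true - y_true.mean()) * (y_pred - y_pred.mean())) / (st * sp))
    return min(r * r, 1.0)


def tau_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest tau for which the elastic-net solution is identically zero.

    Computed on standardized columns and centered response, matching what
    the solver sees: tau_max = 2 max_j |x_j^T y| / n.
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    return float(2.0 * np.max(np.abs(Xs.T @ yc)) / Xs.shape[0])


def make_grid(mus: Sequence[float], taus: Sequence[float], lams: Sequence[float]) -> list[L1L2Hyperparams]:
    return [L1L2Hyperparams(m, t, l) for m in mus for t in taus for l in lams]


# ---------------------------------------------------------------------------
# Internal CV and model selection


def _rank_from_weights(weights: np.ndarray, names: Sequence[str]) -> RankedList:
    nz = np.flatnonzero(weights)
    items = sorted(((float(-abs(weights[j])), names[j]) for j in nz))
    return RankedList(items=[nm for _, nm in items], universe=list(names))


def run_internal_cv(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    fold_ids: np.ndarray,
    grid: Sequence[L1L2Hyperparams],
    settings: SolverSettings = SolverSettings(),
) -> list[GridPoint]:
    """Score every hyperparameter triple by k-fold CV on the development set.

    For each grid point: fit on k-1 folds, squared-error on the held-out
    fold, and collect the fold-wise ranked marker lists; the grid point
    carries the mean MSE and the Canberra stability of those k lists.

    Selection fits (mu, tau) are shared across lam values, and the solver
    is warm-started along the tau path within each (fold, mu), so the grid
    costs far fewer iterations than independent fits would.
    """
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = np.unique(fold_ids)
    if folds.size < 2:
        raise ValueError("internal CV needs at least two folds")

    sel_pairs = sorted({(h.mu, h.tau) for h in grid})
    lams_of = {}
    for h in grid:
        lams_of.setdefault((h.mu, h.tau), []).append(h.lam)

    # per grid point: list over folds of (mse, ranked list, support size)
    per_point: dict[L1L2Hyperparams, list] = {h: [] for h in grid}
    for k in folds:
        tr = fold_ids != k
        te = ~tr
        if te.sum() < 2 or tr.sum() < 2:
            raise ValueError(f"fold {k} leaves fewer than two samples on one side")
        Xtr, x_mean, x_scale = _standardize(X[tr])
        y_mean = y[tr].mean()
        ytr = y[tr] - y_mean
        Xte = (X[te] - x_mean) / x_scale
        yte = y[te]

        warm: dict[float, np.ndarray] = {}  # last naive solution per mu
        for mu in sorted({m for m, _ in sel_pairs}):
            taus = sorted([t for m, t in sel_pairs if m == mu], reverse=True)
            for t in taus:
                w0 = warm.get(mu)
                w_naive, _, _ = fit_naive_elastic_net(
                    Xtr, ytr, L1L2Hyperparams(mu, t, 0.0), settings, w0=w0
                )
                warm[mu] = w_naive
                support = select_support(w_naive)
                for lam in lams_of[(mu, t)]:
                    weights = np.zeros(X.shape[1])
                    if support.size:
                        weights[support] = rls_debias(Xtr[:, support], ytr, lam)
                    pred = Xte @ weights + y_mean
                    mse = float(np.mean((yte - pred) ** 2))
                    rl = _rank_from_weights(weights, feature_names)
                    per_point[L1L2Hyperparams(mu, t, lam)].append((mse, rl, support.size))

    points: list[GridPoint] = []
    for h in grid:
        rows = per_point[h]
        mses = [m for m, _, _ in rows]
        lists = [rl for _, rl, _ in rows]
        stab = stability_indicator(lists).mean_distance
        points.append(
            GridPoint(
                hyperparams=h,
                cv_mse=float(np.mean(mses)),
                cv_stability=stab,
                mean_support_size=float(np.mean([s for _, _, s in rows])),
            )
        )
    return points


def select_model(
    grid_points: Sequence[GridPoint], mse_tolerance_fraction: float = 0.05
) -> L1L2Hyperparams:
    """Pick the most stable model among those within tolerance of the best MSE.

    Candidates are grid points with cv_mse <= (1 + tol) * min cv_mse; the
    one with minimal stability wins.  Ties prefer sparser models (larger
    tau), then lexicographic (mu, tau, lam) — a total order, so the choice
    is invariant to input order.
    """
    if not grid_points:
        raise ValueError("no grid points")
    best = min(gp.cv_mse for gp in grid_points)
    cands = [gp for gp in grid_points if gp.cv_mse <= (1.0 + mse_tolerance_fraction) * best]
    key = lambda gp: (gp.cv_stability, -gp.hyperparams.tau,
                      gp.hyperparams.mu, gp.hyperparams.tau, gp.hyperparams.lam)
    return min(cands, key=key).hyperparams


# ---------------------------------------------------------------------------
# Full protocols


def _check_inputs(g: GenotypeMatrix, ph: PhenotypeVector) -> None:
    if g.missing_mask.any():
        raise ValueError("genotypes contain missing calls; impute before the DAP")
    if ph.values.size != g.n_samples:
        raise ValueError("phenotype length differs from sample count")


def run_l1l2_dap(
    g: GenotypeMatrix,
    ph: PhenotypeVector,
    plan: SplitPlan,
    grid: Sequence[L1L2Hyperparams],
    settings: SolverSettings = SolverSettings(),
    mse_tolerance_fraction: float = 0.05,
) -> DapResult:
    """Nested accuracy-stability protocol for the L1L2 estimator."""
    _check_inputs(g, ph)
    X, y = g.values, ph.values
    names = g.snp_names

    selected, r2s, lists, wvecs, table_rows = [], [], [], [], []
    for r in range(plan.n_resamplings):
        dev, val, fold_ids = plan.indices(g.family_ids, r)
        assert np.intersect1d(dev, val).size == 0, "development/validation overlap"
        points = run_internal_cv(X[dev], y[dev], names, fold_ids, grid, settings)
        h = select_model(points, mse_tolerance_fraction)
        model = fit_l1l2(X[dev], y[dev], h, settings, feature_names=names)
        pred = predict(model, X[val])
        r2s.append(squared_correlation(y[val], pred))
        lists.append(rank_features(model))
        wvecs.append(model.weights.copy())
        selected.append(h)
        for gp in points:
            table_rows.append(
                {
                    "resampling": r,
                    "mu": gp.hyperparams.mu,
                    "tau": gp.hyperparams.tau,
                    "lam": gp.hyperparams.lam,
                    "cv_mse": gp.cv_mse,
                    "cv_stability": gp.cv_stability,
                    "mean_support_size": gp.mean_support_size,
                    "selected": gp.hyperparams == h,
                }
            )
    return DapResult(
        selected=selected,
        r2=r2s,
        ranked_lists=lists,
        weight_vectors=wvecs,
        accuracy_stability=pd.DataFrame(table_rows),
        selection_bias_prone=False,
    )


def _interfamily_half_split(family_ids, fraction, rng):
    fams = np.asarray(family_ids)
    unique, counts = np.unique(fams, return_counts=True)
    sizes = dict(zip(unique.tolist(), counts.tolist()))
    order = list(rng.permutation(unique))
    train, total = set(), 0
    n = fams.size
    for f in order:
        if total >= fraction * n:
            break
        train.add(f)
        total += sizes[f]
    if len(train) == len(unique):
        train.discard(order[-1])
    tr = np.flatnonzero([f in train for f in fams])
    te = np.flatnonzero([f not in train for f in fams])
    return tr, te


def run_bootstrap_dap(
    g: GenotypeMatrix,
    ph: PhenotypeVector,
    plugin: RegressorPlugin,
    param_grid: Sequence[dict],
    n_grid_bootstraps: int = 10,
    n_eval_bootstraps: int = 15,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> DapResult:
    """Baseline protocol: grid search on interfamily half-splits, then evaluation.

    The selected parameter set maximizes the mean squared correlation over
    the grid-search resamplings and is then scored on fresh interfamily
    train/test resamplings.  The result is flagged selection-bias-prone:
    selection and evaluation draw from the same cohort.
    """
    _check_inputs(g, ph)
    if not param_grid:
        raise ValueError("empty parameter grid")
    X, y = g.values, ph.values
    rng = np.random.default_rng(seed)

    mean_r2 = []
    for params in param_grid:
        scores = []
        grid_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        for _ in range(n_grid_bootstraps):
            tr, te = _interfamily_half_split(g.family_ids, train_fraction, grid_rng)
            Xtr, x_mean, x_scale = _standardize(X[tr])
            Xte = (X[te] - x_mean) / x_scale
            model = plugin.fit(Xtr, y[tr], params)
            scores.append(squared_correlation(y[te], plugin.predict(model, Xte)))
        mean_r2.append(float(np.mean(scores)))
    best_ix = int(np.argmax(mean_r2))
    best_params = param_grid[best_ix]

    r2s, lists, wvecs = [], [], []
    eval_rng = np.random.default_rng(seed + 1)
    for _ in range(n_eval_bootstraps):
        tr, te = _interfamily_half_split(g.family_ids, train_fraction, eval_rng)
        assert np.intersect1d(tr, te).size == 0, "train/test overlap"
        Xtr, x_mean, x_scale = _standardize(X[tr])
        Xte = (X[te] - x_mean) / x_scale
        model = plugin.fit(Xtr, y[tr], best_params)
        r2s.append(squared_correlation(y[te], plugin.predict(model, Xte)))
        w = plugin.ranking_weights(Xtr, y[tr], best_params)
        if w is not None:
            wvecs.append(np.asarray(w, dtype=float))
            items = sorted(((float(-abs(v)), nm) for v, nm in zip(w, g.snp_names)))
            lists.append(RankedList(items=[nm for _, nm in items], universe=g.snp_names))
    return DapResult(
        selected=[best_params] * n_eval_bootstraps,
        r2=r2s,
        ranked_lists=lists,
        weight_vectors=wvecs,
        accuracy_stability=None,
        selection_bias_prone=True,
    )
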