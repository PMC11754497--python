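"""Organoid drug-response models over hub-gene expression.

Three candidate models map hub-gene expression to IC50:

* ridge regression (genes standardized internally, penalty chosen by
  k-fold cross-validation, coefficients reported on the original scale);
* a regression random forest whose feature relevance is out-of-bag
  permutation importance (mean increase in OOB squared error when a
  feature's values are permuted);
* an ensemble: genes with positive forest permutation importance are
  refitted by ridge regression, yielding a sparse linear signature.

The final model is picked by repeated k-fold cross-validated error on
the organoid cohort, discrimination (AUC) of the score against the
tissue cohort's survival-event indicator, and a significant log-rank
separation after maxstat dichotomization.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "DrugResponseModel",
    "RandomForestModel",
    "CvReport",
    "fit_ridge",
    "fit_rf",
    "fit_ensemble",
    "repeated_cv",
    "auc_from_scores",
    "select_final_model",
]


@dataclass
class DrugResponseModel:
    """A trained drug-response model.

    For linear kinds (``ridge``, ``ensemble``) the exported score is the
    intercept-free linear combination of ``coefficients`` over
    ``selected_genes``; the intercept used during fitting is kept in
    ``intercept`` for prediction but deliberately omitted from the score
    (a constant shift cannot change groups or rank-based tests).
    """

    kind: str                          # "ridge" | "rf" | "ensemble"
    selected_genes: list[str]
    coefficients: np.ndarray | None = None
    intercept: float = 0.0
    lambda_: float | None = None
    forest: "RandomForestModel | None" = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ridge", "rf", "ensemble"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind != "rf":
            if self.coefficients is None:
                raise ValueError("linear model kinds need coefficients")
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if len(self.coefficients) != len(self.selected_genes):
                raise ValueError("one coefficient per selected gene required")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fitted-value prediction (includes the intercept for linear kinds)."""
        X = np.asarray(X, dtype=float)
        if self.kind == "rf":
            assert self.forest is not None
            return self.forest.predict(X)
        return X @ self.coefficients + self.intercept

    def to_json(self, path: str | Path) -> None:
        if self.kind == "rf":
            raise ValueError("forest models have no portable JSON form; export the ensemble instead")
        payload = {
            "kind": self.kind,
            "selected_genes": self.selected_genes,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "lambda": self.lambda_,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DrugResponseModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            kind=payload["kind"],
            selected_genes=list(payload["selected_genes"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload.get("intercept", 0.0)),
            lambda_=payload.get("lambda"),
            metadata=payload.get("metadata", {}),
        )


class RandomForestModel:
    """Bagged regression trees with explicit bootstrap bookkeeping.

    Bootstrap indices are drawn by this class (not the tree learner) so
    out-of-bag sets are known exactly, which makes the Breiman-style OOB
    permutation importance below fully deterministic given the seed.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None, seed: int = 0,
                 min_samples_leaf: int = 5):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_indices: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        mtry = self.mtry if self.mtry is not None else max(1, math.ceil(p / 3))
        rng = np.random.default_rng(self.seed)
        self.trees, self.oob_indices = [], []
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            self.oob_indices.append(oob)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.zeros(X.shape[0])
        for tree in self.trees:
            preds += tree.predict(X)
        return preds / len(self.trees)

    def oob_permutation_importance(
        self, X: np.ndarray, y: np.ndarray, n_permutations: int = 10, seed: int = 0
    ) -> np.ndarray:
        """Mean increase in out-of-bag MSE when one feature is permuted,
        averaged over trees and ``n_permutations`` draws per feature."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        p = X.shape[1]
        rng = np.random.default_rng(seed)
        increase = np.zeros(p)
        weight = np.zeros(p)
        for tree, oob in zip(self.trees, self.oob_indices):
            if len(oob) == 0:
                continue
            X_oob = X[oob]
            y_oob = y[oob]
            base = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
            n_oob = len(oob)
            # one predict call per tree: stack every (feature, permutation) copy
            stacked = np.tile(X_oob, (p * n_permutations, 1))
            perm_idx = np.argsort(rng.random((p * n_permutations, n_oob)), axis=1)
            permuted = X_oob[perm_idx, np.repeat(np.arange(p), n_permutations)[:, None]]
            rows = np.arange(p * n_permutations * n_oob)
            cols = np.repeat(np.repeat(np.arange(p), n_permutations), n_oob)
            stacked[rows, cols] = permuted.ravel()
            preds = tree.predict(stacked).reshape(p, n_permutations, n_oob)
            err = np.mean((preds - y_oob[None, None, :]) ** 2, axis=(1, 2))
            increase += err - base
            weight += 1.0
        weight[weight == 0] = 1.0
        return increase / weight


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant feature(s); cannot standardize")
    return (X - mu) / sd, mu, sd


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, size: int = 100) -> np.ndarray:
    """Log-spaced penalty grid from a data-driven maximum down to 1e-4 of it."""
    lam_max = float(np.abs(Xs.T @ yc).max())
    lam_max = max(lam_max, 1e-8)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), size)


def _ridge_solve_grid(Xs: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Ridge solutions (XsᵀXs + λI)⁻¹Xsᵀyc for every λ at once via one SVD;
    returns an array of shape (len(lams), p)."""
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    uty = u.T @ yc
    # beta(λ) = V diag(s / (s² + λ)) Uᵀ yc
    shrink = s[None, :] / (s[None, :] ** 2 + np.asarray(lams)[:, None])
    return (shrink * uty[None, :]) @ vt


def _ridge_solve(Xs: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    return _ridge_solve_grid(Xs, yc, np.array([lam]))[0]


def fit_ridge(
    X: np.ndarray,
    y: np.ndarray,
    genes: Sequence[str],
    lambda_grid: Sequence[float] | None = None,
    folds: int = 3,
    seed: int = 0,
    alpha_grid: Sequence[float] | None = None,
) -> DrugResponseModel:
    """Ridge regression with the penalty chosen by minimum mean k-fold CV
    MSE over a log-spaced grid.  Genes are standardized internally; the
    returned coefficients are on the original expression scale.  An
    optional elastic-net mixing grid (``alpha_grid``) extends the search;
    the default is pure ridge (mixing 0)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(genes) != p:
        raise ValueError("one gene name per column required")
    if y.std() == 0:
        raise ValueError("constant response; nothing to fit")
    if not (2 <= folds <= n):
        raise ValueError("need n >= folds >= 2")
    Xs, mu, sd = _standardize(X)
    yc = y - y.mean()
    if lambda_grid is None:
        lambda_grid = _lambda_grid(Xs, yc)
    alphas = [0.0] if alpha_grid is None else list(alpha_grid)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))
    lams = np.asarray(list(lambda_grid), dtype=float)

    def cv_mse_pure_ridge() -> np.ndarray:
        # all lambdas at once: one SVD per fold
        errs = np.zeros(len(lams))
        for train, test in splits:
            betas = _ridge_solve_grid(Xs[train], yc[train], lams)  # (L, p)
            resid = betas @ Xs[test].T - yc[test][None, :]
            errs += np.mean(resid**2, axis=1)
        return errs / len(splits)

    def cv_mse(alpha: float, lam: float) -> float:
        errs = []
        for train, test in splits:
            bt = _fit_linear(Xs[train], yc[train], alpha, lam)
            errs.append(float(np.mean((Xs[test] @ bt - yc[test]) ** 2)))
        return float(np.mean(errs))

    scored: list[tuple[float, float, float]] = []  # (mse, alpha, lam)
    for alpha in alphas:
        if alpha == 0.0:
            mses = cv_mse_pure_ridge()
            scored += [(float(m), 0.0, float(l)) for m, l in zip(mses, lams)]
        else:
            scored += [(cv_mse(alpha, float(l)), alpha, float(l)) for l in lams]
    _, alpha_opt, lam_opt = min(scored, key=lambda t: t[0])
    beta_std = _fit_linear(Xs, yc, alpha_opt, lam_opt)
    coef = beta_std / sd
    intercept = float(y.mean() - float(mu @ coef))
    return DrugResponseModel(
        kind="ridge",
        selected_genes=list(genes),
        coefficients=coef,
        intercept=intercept,
        lambda_=float(lam_opt),
        metadata={"seed": seed, "folds": folds, "alpha": float(alpha_opt)},
    )


def _fit_linear(Xs: np.ndarray, yc: np.ndarray, alpha: float, lam: float) -> np.ndarray:
    if alpha == 0.0:
        return _ridge_solve(Xs, yc, lam)
    n = Xs.shape[0]
    model = ElasticNet(alpha=lam / n, l1_ratio=alpha, fit_intercept=False, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, yc)
    return model.coef_


def fit_rf(
    X: np.ndarray,
    y: np.ndarray,
    genes: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
    n_permutations: int = 10,
) -> tuple[DrugResponseModel, pd.Series]:
    """Regression forest plus per-gene OOB permutation importances."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    forest = RandomForestModel(n_trees=n_trees, seed=seed).fit(X, y)
    importances = forest.oob_permutation_importance(
        X, y, n_permutations=n_permutations, seed=seed + 1
    )
    model = DrugResponseModel(
        kind="rf",
        selected_genes=list(genes),
        forest=forest,
        metadata={"seed": seed, "n_trees": n_trees},
    )
    return model, pd.Series(importances, index=list(genes), name="importance")


def fit_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    genes: Sequence[str],
    seed: int = 0,
    n_trees: int = 500,
    n_permutations: int = 10,
    folds: int = 3,
) -> DrugResponseModel:
    """Forest-then-ridge ensemble: genes with positive OOB permutation
    importance are refitted by ridge; the ridge coefficients define the
    exported signature."""
    _rf_model, importances = fit_rf(
        X, y, genes, n_trees=n_trees, seed=seed, n_permutations=n_permutations
    )
    keep = importances[importances > 0].index.tolist()
    if not keep:
        raise ValueError(
            "no gene has positive permutation importance; "
            "fall back to the plain forest model"
        )
    cols = [list(genes).index(g) for g in keep]
    ridge = fit_ridge(X[:, cols], y, keep, folds=folds, seed=seed)
    return DrugResponseModel(
        kind="ensemble",
        selected_genes=keep,
        coefficients=ridge.coefficients,
        intercept=ridge.intercept,
        lambda_=ridge.lambda_,
        metadata={
            "seed": seed,
            "n_trees": n_trees,
            "folds": folds,
            "importances": {g: float(importances[g]) for g in keep},
        },
    )


def _fit_spec(kind: str, X: np.ndarray, y: np.ndarray, genes: Sequence[str],
              seed: int, n_trees: int, folds: int):
    if kind == "ridge":
        return fit_ridge(X, y, genes, folds=folds, seed=seed)
    if kind == "rf":
        return fit_rf(X, y, genes, n_trees=n_trees, seed=seed)[0]
    if kind == "ensemble":
        return fit_ensemble(X, y, genes, seed=seed, n_trees=n_trees, folds=folds)
    raise ValueError(f"unknown model kind {kind!r}")


def repeated_cv(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    genes: Sequence[str],
    folds: int = 3,
    reps: int = 100,
    seed: int = 0,
    n_trees: int = 500,
) -> dict:
    """Repeated k-fold CV of one model kind: per repetition, folds are
    redrawn with seed ``seed + rep``; fold MSEs are pooled and summarized
    by mean and sd."""
    if folds < 2 or reps < 1:
        raise ValueError("need folds >= 2 and reps >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fold_mses: list[float] = []
    for rep in range(reps):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train, test in kf.split(X):
            model = _fit_spec(kind, X[train], y[train], genes, seed=seed + rep,
                              n_trees=n_trees, folds=min(folds, len(train)))
            # the ensemble may keep a gene subset; predict on those columns
            cols = [list(genes).index(g) for g in model.selected_genes]
            preds = model.predict(X[test][:, cols])
            fold_mses.append(float(np.mean((preds - y[test]) ** 2)))
    arr = np.asarray(fold_mses)
    return {
        "kind": kind,
        "cv_mse_mean": float(arr.mean()),
        "cv_mse_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "folds": folds,
        "reps": reps,
        "fold_mses": fold_mses,
    }


def auc_from_scores(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """Mann-Whitney AUC: probability that a positive (label 1) sample
    scores higher than a negative one; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = float(ranks[labels == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CvReport:
    """Selection evidence for the candidate models."""

    entries: list[dict]  # each: kind, cv_mse_mean, cv_mse_sd, auc, logrank_p

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries).set_index("kind")


def select_final_model(report: CvReport, alpha: float = 0.05) -> str:
    """Pick the final model kind: restrict to candidates with log-rank
    p < alpha; among them prefer the one best on both CV error (lowest)
    and AUC (highest); when no candidate dominates both, rank by CV
    error with AUC as tie-break (a warning notes the conflict).  When no
    candidate passes the log-rank filter, the lowest-CV-error model is
    returned with a warning."""
    if not report.entries:
        raise ValueError("empty CV report")
    df = report.frame()
    passing = df[df["logrank_p"] < alpha]
    if passing.empty:
        warnings.warn("no candidate reaches log-rank significance; choosing by CV error alone")
        passing = df
    best_mse = passing["cv_mse_mean"].idxmin()
    best_auc = passing["auc"].idxmax()
    if best_mse != best_auc:
        warnings.warn(
            f"no candidate dominates both criteria (CV error favors {best_mse!r}, "
            f"AUC favors {best_auc!r}); selecting by CV error"
        )
    order = passing.sort_values(["cv_mse_mean", "auc"], ascending=[True, False])
    return str(order.index[0])
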