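"""Feature-importance and simplified-model procedures.

Three independent routes from a full interaction model to a small,
interpretable one:

1. λ-path scan — walk the regularization path of the cross-validated fit
   and keep the sparsest model retaining a stated fraction of the full
   model's test accuracy;
2. bootstrap-Lasso stability selection — refit the Lasso along a fixed
   geometric λ-grid on bootstrap resamples; a term's selection probability
   is its normalized frequency of nonzero coefficients over all
   (resample, λ) fits, with a coefficient z-score at the prediction λ;
3. exhaustive best-subset search — ordinary least squares over all feature
   subsets up to size four, ranked by test accuracy with BIC tracking model
   complexity.

A fourth procedure quantifies the significance of a single feature by
refitting on bootstrap samples with every term involving it removed and
comparing paired accuracy distributions with a two-sided rank-sum test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ranksums
from sklearn.linear_model import lasso_path

from ._rng import substream, subseed
from .lasso import (
    Design,
    ExpansionSpec,
    LassoFit,
    build_design,
    fit_lasso_cv,
    lambda_max,
    predict,
    split_train_test,
)

__all__ = [
    "lambda_sequence_geometric",
    "SimplifiedModel",
    "simplified_from_path",
    "SelectionProfile",
    "bootstrap_lasso",
    "ExclusionResult",
    "exclusion_significance",
    "ExhaustiveSearchResult",
    "exhaustive_search",
    "subset_model_counts",
]


def lambda_sequence_geometric(lam_empty: float, lam_full: float, n: int = 100) -> np.ndarray:
    """Decreasing geometric sequence with exact endpoints and constant
    consecutive ratio (lam_empty > lam_full > 0)."""
    if not (lam_empty > lam_full > 0):
        raise ValueError("need lam_empty > lam_full > 0")
    if n < 2:
        raise ValueError("need n >= 2")
    seq = np.geomspace(lam_empty, lam_full, n)
    seq[0], seq[-1] = lam_empty, lam_full
    return seq


@dataclass
class SimplifiedModel:
    terms: list[str]
    lam: float | None
    rho: float
    fraction: float
    empty: bool = False


def simplified_from_path(
    fit: LassoFit,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    min_fraction: float = 0.75,
) -> SimplifiedModel:
    """Sparsest λ-path model retaining ``min_fraction`` of full-model accuracy.

    Test accuracy is evaluated at every λ with the fold-averaged
    coefficients; among qualifying λ the model with fewest nonzero terms
    wins, ties broken toward the larger λ. The all-zero model has undefined
    accuracy and never qualifies.
    """
    rho_full = predict(fit, X_test, y_test).rho
    best = None
    for idx in range(len(fit.lambdas)):
        nnz = int(np.count_nonzero(fit.coefs[:, idx]))
        if nnz == 0:
            continue
        res = predict(fit, X_test, y_test, lambda_idx=idx)
        if not np.isfinite(res.rho) or res.rho < min_fraction * rho_full:
            continue
        # path is decreasing: earlier idx = larger lambda wins ties
        if best is None or nnz < best[0]:
            best = (nnz, idx, res.rho)
    if best is None:
        return SimplifiedModel(terms=[], lam=None, rho=float("nan"),
                               fraction=float("nan"), empty=True)
    nnz, idx, rho = best
    terms = [t for t, c in zip(fit.term_names, fit.coefs[:, idx]) if c != 0]
    return SimplifiedModel(
        terms=terms, lam=float(fit.lambdas[idx]), rho=rho,
        fraction=rho / rho_full if rho_full else float("nan"),
    )


@dataclass
class SelectionProfile:
    """Per-term bootstrap-Lasso stability summary.

    ``table`` columns: p_sel (selection probability = nonzero count /
    (B*G)), z (mean/SD of the coefficient at the prediction λ across
    bootstraps; NaN with fewer than two nonzero draws there), mean_coef,
    sign (majority sign of nonzero draws), nonzero_count.
    """

    table: pd.DataFrame
    B: int
    G: int
    prediction_lambda: float

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("p_sel", ascending=False)


def bootstrap_lasso(
    design: Design,
    y: pd.Series,
    B: int = 100,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    prediction_lambda: float | None = None,
    lambda_min_ratio: float = 1e-3,
    n_lambdas: int = 100,
    k_folds: int = 10,
    max_iter: int = 3000,
    tol: float = 1e-5,
) -> SelectionProfile:
    """Stability selection by Lasso refits on bootstrap resamples.

    Each of ``B`` resamples (with replacement, size n) is fitted along the
    fixed decreasing ``lambda_grid`` (default: geometric from λ_max of the
    full data — the empty model — down to 10⁻³·λ_max, an almost-full model).
    ``prediction_lambda`` anchors the z-scores; when None it is chosen by a
    ``k_folds`` cross-validated fit on the full data.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    V = design.values.to_numpy()
    yv = y.loc[design.values.index].to_numpy(dtype=float)
    if not (np.isfinite(V).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite values")
    mean = V.mean(axis=0)
    sd = np.where(V.std(axis=0) < 1e-12, 1.0, V.std(axis=0))
    D = (V - mean) / sd
    n, p = D.shape

    if lambda_grid is None:
        lam_hi = lambda_max(D, yv)
        lambda_grid = lambda_sequence_geometric(lam_hi, lambda_min_ratio * lam_hi, n_lambdas)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    G = len(lambda_grid)

    if prediction_lambda is None:
        fit = fit_lasso_cv(
            design, y, k_folds=k_folds, seed=subseed(seed, "bootstrap-cv"),
            lambdas=lambda_grid, max_iter=max_iter, tol=tol,
        )
        prediction_lambda = fit.lambda_star
    pred_idx = int(np.argmin(np.abs(lambda_grid - prediction_lambda)))

    rng = substream(seed, "bootstrap")
    nonzero = np.zeros(p, dtype=int)
    pos = np.zeros(p, dtype=int)
    neg = np.zeros(p, dtype=int)
    coef_at_pred = np.empty((B, p))
    for b in range(B):
        idx = rng.integers(n, size=n)
        Db, yb = D[idx], yv[idx]
        _, coefs, _ = lasso_path(
            Db, yb - yb.mean(), alphas=lambda_grid, max_iter=max_iter, tol=tol
        )
        nz = coefs != 0
        nonzero += nz.sum(axis=1)
        pos += (coefs > 0).sum(axis=1)
        neg += (coefs < 0).sum(axis=1)
        coef_at_pred[b] = coefs[:, pred_idx]

    p_sel = nonzero / (B * G)
    nz_draws = (coef_at_pred != 0).sum(axis=0)
    mean_coef = coef_at_pred.mean(axis=0)
    sd_coef = coef_at_pred.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where((nz_draws >= 2) & (sd_coef > 0), mean_coef / sd_coef, np.nan)
    sign = np.where(pos >= neg, 1, -1)
    sign = np.where(nonzero == 0, 0, sign)
    table = pd.DataFrame(
        {
            "p_sel": p_sel,
            "z": z,
            "mean_coef": mean_coef,
            "sign": sign,
            "nonzero_count": nonzero,
        },
        index=design.term_names,
    )
    return SelectionProfile(table=table, B=B, G=G, prediction_lambda=float(prediction_lambda))


@dataclass
class ExclusionResult:
    p_value: float
    acc_full: np.ndarray
    acc_reduced: np.ndarray
    excluded: str
    low_power: bool = False


def exclusion_significance(
    X: pd.DataFrame,
    y: pd.Series,
    excluded_feature: str,
    spec: ExpansionSpec | None = None,
    B: int = 100,
    seed: int = 0,
    train_fraction: float = 0.662,
    k_folds: int = 10,
    n_lambdas: int = 50,
    max_iter: int = 3000,
    tol: float = 1e-5,
) -> ExclusionResult:
    """Does removing every term involving one feature cost accuracy?

    For each of ``B`` bootstrap samples of the regions: split train/test,
    fit the full cross-validated model and the model lacking all terms that
    involve ``excluded_feature``, record both test accuracies, and compare
    the two samples with a two-sided Wilcoxon rank-sum test. The default
    train fraction mirrors a 5000/2552-style split.
    """
    spec = spec or ExpansionSpec(order=2)
    full_design = build_design(X, spec)
    if not any(excluded_feature in t for t in full_design.terms):
        raise ValueError(f"feature {excluded_feature!r} appears in no model term")
    keep = [t for t in full_design.terms if excluded_feature not in t]

    ids = list(X.index)
    n = len(ids)
    rng = substream(seed, "exclusion")
    acc_full = np.empty(B)
    acc_red = np.empty(B)
    for b in range(B):
        boot = rng.integers(n, size=n)
        Xb = X.iloc[boot].reset_index(drop=True)
        Xb.index = [f"b{i}" for i in range(n)]
        yb = pd.Series(y.iloc[boot].to_numpy(), index=Xb.index)
        n_tr = int(round(train_fraction * n))
        tr, te = split_train_test(list(Xb.index), n_tr, subseed(seed, "exclusion-split", str(b)))
        for which, terms in (("full", None), ("reduced", keep)):
            d = build_design(Xb, spec)
            if terms is not None:
                cols = [":".join(t) for t in terms]
                d = Design(values=d.values[cols], terms=terms, spec=spec,
                           main_mean=d.main_mean, main_sd=d.main_sd)
            f = fit_lasso_cv(
                d, yb, k_folds=k_folds, seed=subseed(seed, "exclusion-fit", which, str(b)),
                n_lambdas=n_lambdas, train_ids=tr, test_ids=te,
                max_iter=max_iter, tol=tol,
            )
            res = predict(f, Xb.loc[te], yb.loc[te])
            # a degenerate (constant) prediction carries no accuracy
            rho = 0.0 if not np.isfinite(res.rho) else res.rho
            if which == "full":
                acc_full[b] = rho
            else:
                acc_red[b] = rho
    stat, p = ranksums(acc_full, acc_red)
    return ExclusionResult(
        p_value=float(p), acc_full=acc_full, acc_reduced=acc_red,
        excluded=excluded_feature, low_power=B < 10,
    )


def subset_model_counts(m: int, k_max: int = 4) -> dict[int, int]:
    """Number of distinct k-feature subsets from an m-feature pool, k=1..k_max."""
    return {k: math.comb(m, k) for k in range(1, k_max + 1)}


@dataclass
class ExhaustiveSearchResult:
    models: pd.DataFrame            # subset, k, rho, bic per fitted model
    best_per_k: pd.DataFrame
    appearance_freq: pd.Series      # over qualifying models
    rho_full: float
    n_qualifying: int


def exhaustive_search(
    X: pd.DataFrame,
    y: pd.Series,
    train_ids: Sequence,
    test_ids: Sequence,
    k_max: int = 4,
    rho_full: float | None = None,
    fraction: float = 0.6,
    max_models: int = 200_000,
    force: bool = False,
) -> ExhaustiveSearchResult:
    """Best-subset search: OLS on every feature subset of size <= k_max.

    Each subset is fitted by ordinary least squares on the training rows
    (OLS has no tuning parameter, so no inner CV); test accuracy is the
    Pearson correlation on the held-out rows and BIC on the training fit is
    ``n·ln(RSS/n) + (k+1)·ln(n)`` (Gaussian likelihood, intercept counted,
    error variance profiled out). Appearance frequencies are computed over
    models whose test accuracy reaches ``fraction`` of ``rho_full`` (the
    full-model accuracy; defaults to the best observed subset accuracy).
    """
    m = X.shape[1]
    counts = subset_model_counts(m, k_max)
    total = sum(counts.values())
    if total > max_models and not force:
        raise ValueError(
            f"{total} models projected for m={m}, k<=4; pass force=True to run anyway"
        )
    Xtr = X.loc[list(train_ids)].to_numpy()
    ytr = y.loc[list(train_ids)].to_numpy(dtype=float)
    Xte = X.loc[list(test_ids)].to_numpy()
    yte = y.loc[list(test_ids)].to_numpy(dtype=float)
    n = len(ytr)
    feats = list(X.columns)
    rows = []
    for k in range(1, k_max + 1):
        for combo in combinations(range(m), k):
            A = np.column_stack([np.ones(n), Xtr[:, combo]])
            beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
            rss = float(((ytr - A @ beta) ** 2).sum())
            bic = n * math.log(max(rss / n, 1e-300)) + (k + 1) * math.log(n)
            pred = beta[0] + Xte[:, combo] @ beta[1:]
            rho = float(pearsonr(yte, pred)[0]) if np.std(pred) > 1e-12 else float("nan")
            rows.append((tuple(feats[j] for j in combo), k, rho, bic))
    models = pd.DataFrame(rows, columns=["subset", "k", "rho", "bic"])
    if rho_full is None:
        rho_full = float(models["rho"].max())
    best_idx = models.groupby("k")["rho"].idxmax()
    best_per_k = models.loc[best_idx].reset_index(drop=True)
    qual = models[models["rho"] >= fraction * rho_full]
    freq = pd.Series(0.0, index=feats)
    if len(qual):
        for subset in qual["subset"]:
            for f in subset:
                freq[f] += 1
        freq /= len(qual)
    return ExhaustiveSearchResult(
        models=models, best_per_k=best_per_k, appearance_freq=freq,
        rho_full=rho_full, n_qualifying=int(len(qual)),
    )
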