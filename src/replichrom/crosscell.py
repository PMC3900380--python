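"""Cross-cell-type replication timing prediction.

Given two cell types profiled for a common set of histone modifications
(CHMs), this module: restricts both feature matrices to the shared
features, fits one interaction-expanded model per cell type and evaluates
matched vs unmatched accuracy, models differential timing Δt from
differential marks ΔX, and evaluates how well one cell type's model
predicts the timing of differentially replicating promoters (DRPs) in the
other.

Timing values are on a log-ratio (M-value) scale, so the timing difference
between cell types is itself the log fold change; DRPs are promoters with
|Δt| at or above a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._rng import subseed
from .lasso import (
    ExpansionSpec,
    LassoFit,
    PredictionResult,
    build_design,
    fit_lasso_cv,
    predict,
    split_train_test,
)
from .selection import SelectionProfile, bootstrap_lasso

__all__ = [
    "load_chm_list",
    "CellPairDataset",
    "subset_common_features",
    "CellTypeModels",
    "fit_celltype_models",
    "DifferentialSet",
    "define_drps",
    "fit_differential_model",
    "cross_predict_drps",
]

_VAR_TOL = 1e-12


def load_chm_list() -> list[str]:
    """The packaged list of histone modifications profiled in both cell types."""
    text = resources.files("replichrom.data").joinpath("chm_list.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class CellPairDataset:
    X_a: pd.DataFrame
    X_b: pd.DataFrame
    t_a: pd.Series
    t_b: pd.Series

    def __post_init__(self) -> None:
        if list(self.X_a.columns) != list(self.X_b.columns):
            raise ValueError("cell types must share identical feature columns")
        if not self.X_a.index.equals(self.X_b.index):
            raise ValueError("cell types must share the region index")


def subset_common_features(
    X_a: pd.DataFrame,
    X_b: pd.DataFrame,
    t_a: pd.Series,
    t_b: pd.Series,
    chm_list: list[str] | None = None,
) -> CellPairDataset:
    """Restrict both cell types to shared features and co-scored regions."""
    chm_list = chm_list if chm_list is not None else load_chm_list()
    if not chm_list:
        raise ValueError("empty common-feature list")
    common = [f for f in chm_list if f in X_a.columns and f in X_b.columns]
    if not common:
        raise ValueError("no features shared by both cell types")
    regions = X_a.index.intersection(X_b.index).intersection(t_a.index).intersection(t_b.index)
    return CellPairDataset(
        X_a=X_a.loc[regions, common],
        X_b=X_b.loc[regions, common],
        t_a=t_a.loc[regions],
        t_b=t_b.loc[regions],
    )


@dataclass
class CellTypeModels:
    fit_a: LassoFit
    fit_b: LassoFit
    rho_matched: dict[str, float]
    rho_unmatched: dict[str, float]


def fit_celltype_models(
    pair: CellPairDataset,
    order: int = 2,
    train_fraction: float = 0.662,
    k_folds: int = 10,
    n_lambdas: int = 100,
    seed: int = 0,
) -> CellTypeModels:
    """One interaction-expanded model per cell type, plus cross-application.

    Both models use the same train/test region split so the matched and
    unmatched evaluations are directly comparable on identical test regions.
    """
    spec = ExpansionSpec(order=order)
    ids = list(pair.X_a.index)
    n_tr = int(round(train_fraction * len(ids)))
    tr, te = split_train_test(ids, n_tr, subseed(seed, "celltype-split"))
    fits = {}
    for name, X, t in (("a", pair.X_a, pair.t_a), ("b", pair.X_b, pair.t_b)):
        design = build_design(X, spec)
        fits[name] = fit_lasso_cv(
            design, t, k_folds=k_folds, seed=subseed(seed, "celltype-fit", name),
            n_lambdas=n_lambdas, train_ids=tr, test_ids=te,
        )
    rho_matched = {
        "a": predict(fits["a"], pair.X_a.loc[te], pair.t_a.loc[te]).rho,
        "b": predict(fits["b"], pair.X_b.loc[te], pair.t_b.loc[te]).rho,
    }
    rho_unmatched = {
        "a_on_b": predict(fits["a"], pair.X_b.loc[te], pair.t_b.loc[te]).rho,
        "b_on_a": predict(fits["b"], pair.X_a.loc[te], pair.t_a.loc[te]).rho,
    }
    return CellTypeModels(fit_a=fits["a"], fit_b=fits["b"],
                          rho_matched=rho_matched, rho_unmatched=rho_unmatched)


@dataclass
class DifferentialSet:
    """Differential marks and timing between two cell types (A − B)."""

    dX: pd.DataFrame
    dt: pd.Series
    delta: float
    drp_ids: list
    quadrant: pd.Series  # per-region label from the signs of (t_a, t_b)


_QUADRANTS = {
    (True, True): "early/early",
    (True, False): "early/late",
    (False, True): "late/early",
    (False, False): "late/late",
}


def define_drps(pair: CellPairDataset, delta: float) -> DifferentialSet:
    """Differentially replicating promoters: |t_A − t_B| >= delta.

    Timing is a log-scale M-value, so the difference is the log fold
    change. Quadrant labels follow the signs of the two timing values
    (positive = early). Swapping A and B negates ΔX and Δt and mirrors the
    quadrant labels.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    dX = pair.X_a - pair.X_b
    dt = (pair.t_a - pair.t_b).rename("dt")
    drp = dt.index[dt.abs() >= delta]
    quad = pd.Series(
        [
            _QUADRANTS[(a >= 0, b >= 0)]
            for a, b in zip(pair.t_a.to_numpy(), pair.t_b.to_numpy())
        ],
        index=dt.index,
        name="quadrant",
    )
    return DifferentialSet(dX=dX, dt=dt, delta=delta, drp_ids=list(drp), quadrant=quad)


@dataclass
class DifferentialModelResult:
    fit: LassoFit | None
    rho: float
    selection: SelectionProfile | None
    degenerate: bool = False


def fit_differential_model(
    dX: pd.DataFrame,
    dt: pd.Series,
    order: int = 2,
    train_fraction: float = 0.662,
    k_folds: int = 10,
    n_lambdas: int = 100,
    seed: int = 0,
    bootstrap_B: int | None = None,
    bootstrap_G: int = 100,
) -> DifferentialModelResult:
    """Predict differential timing from differential marks.

    Standard protocol (interaction expansion, shared λ-path, 10-fold CV,
    held-out accuracy) on ΔX vs Δt. Optionally attaches a bootstrap-Lasso
    selection profile over the differential terms. Zero-variance ΔX yields
    a degenerate zero model.
    """
    if float(dX.to_numpy().var()) < _VAR_TOL or float(dt.var()) < _VAR_TOL:
        return DifferentialModelResult(fit=None, rho=0.0, selection=None, degenerate=True)
    spec = ExpansionSpec(order=order)
    design = build_design(dX, spec)
    ids = list(dX.index)
    n_tr = int(round(train_fraction * len(ids)))
    tr, te = split_train_test(ids, n_tr, subseed(seed, "diff-split"))
    fit = fit_lasso_cv(
        design, dt, k_folds=k_folds, seed=subseed(seed, "diff-fit"),
        n_lambdas=n_lambdas, train_ids=tr, test_ids=te,
    )
    rho = predict(fit, dX.loc[te], dt.loc[te]).rho
    selection = None
    if bootstrap_B:
        selection = bootstrap_lasso(
            design, dt, B=bootstrap_B, seed=subseed(seed, "diff-bootstrap"),
            n_lambdas=bootstrap_G, prediction_lambda=fit.lambda_star,
        )
    return DifferentialModelResult(fit=fit, rho=rho, selection=selection)


def cross_predict_drps(
    fit_a: LassoFit,
    pair: CellPairDataset,
    drps: DifferentialSet,
) -> PredictionResult:
    """Apply cell A's model to cell B's marks at the DRPs, scored vs t_B."""
    ids = drps.drp_ids
    if not ids:
        return PredictionResult(
            predicted=pd.Series(dtype=float), measured=None,
            rho=float("nan"), residuals=None, degenerate=True,
        )
    return predict(fit_a, pair.X_b.loc[ids], pair.t_b.loc[ids])
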