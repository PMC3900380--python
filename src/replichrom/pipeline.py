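"""End-to-end orchestration of the synthetic pipeline from a single config.

``run_pipeline`` sequences the stages — simulate → fit → select → genome →
crosscell — from one seed, writing per-stage outputs and a JSON manifest
(inputs, seeds, accuracies). Every random draw flows from the single config
seed through named substreams, so re-running any stage in isolation
reproduces its output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._rng import subseed
from . import synthetic
from .lasso import ExpansionSpec, build_design, fit_lasso_cv, predict, split_train_test
from .selection import bootstrap_lasso, simplified_from_path
from .genome import classify_gene_density, modwt_smooth, predict_genome, segment_ttrs, stratified_accuracy
from .crosscell import CellPairDataset, define_drps, fit_differential_model, cross_predict_drps, fit_celltype_models

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline protocol parameters (defaults follow the study protocol)."""

    out_dir: str = "replichrom-run"
    seed: int = 0
    n_regions: int = 2000
    target_r2: float = 0.5
    interaction_order: int = 2
    train_fraction: float = 0.662   # a 5000/2552-style split
    k_folds: int = 10
    n_lambdas: int = 100
    bootstrap_B: int = 100
    min_fraction: float = 0.75
    delta_cutoffs: tuple[float, ...] = (0.8, 0.9, 1.0)
    bin_width: int = 10_000
    ttr_halfwidth: int = 15_000
    genome_bins: int = 600
    verbose: bool = False


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data; returns (and writes) the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        if config.verbose:
            print(f"[{stage}] " + json.dumps(info, default=float))

    # -- simulate ---------------------------------------------------------
    cfg = synthetic.SynthConfig(
        n_regions=config.n_regions, seed=subseed(config.seed, "simulate"),
        pair=synthetic.PairConfig(),
        genome=synthetic.GenomeConfig(n_bins=config.genome_bins),
    )
    cfg = synthetic.SynthConfig(
        **{**cfg.__dict__, "noise_sd": synthetic.noise_sd_for_r2(cfg, config.target_r2)}
    )
    ds = synthetic.generate_promoter_dataset(cfg)
    synthetic.write_dataset(ds, config.out_dir, prefix="promoters")
    record("simulate", n_regions=config.n_regions, oracle_r2=ds.truth.oracle_r2)

    # -- fit --------------------------------------------------------------
    spec = ExpansionSpec(order=config.interaction_order)
    design = build_design(ds.features, spec)
    n_tr = int(round(config.train_fraction * config.n_regions))
    tr, te = split_train_test(list(ds.features.index), n_tr, subseed(config.seed, "fit-split"))
    fit = fit_lasso_cv(
        design, ds.timing, k_folds=config.k_folds,
        seed=subseed(config.seed, "fit"), n_lambdas=config.n_lambdas,
        train_ids=tr, test_ids=te,
    )
    res = predict(fit, ds.features.loc[te], ds.timing.loc[te])
    with open(os.path.join(config.out_dir, "model.json"), "w") as fh:
        json.dump(fit.to_dict(), fh)
    record("fit", test_rho=res.rho, lambda_star=fit.lambda_star,
           support_size=len(fit.support))

    # -- select -----------------------------------------------------------
    simp = simplified_from_path(fit, ds.features.loc[te], ds.timing.loc[te],
                                min_fraction=config.min_fraction)
    prof = bootstrap_lasso(
        design, ds.timing, B=min(config.bootstrap_B, 30),
        seed=subseed(config.seed, "bootstrap"), n_lambdas=min(config.n_lambdas, 50),
        prediction_lambda=fit.lambda_star,
    )
    top = list(prof.ranked().head(5).index)
    record("select", simplified_terms=simp.terms, simplified_rho=simp.rho,
           top_selection=top)

    # -- genome -----------------------------------------------------------
    gds = synthetic.generate_genome_profile(cfg)
    gfit_design = build_design(gds.features, ExpansionSpec(order=1))
    g_tr, g_te = split_train_test(list(gds.features.index),
                                  int(0.7 * len(gds.features)),
                                  subseed(config.seed, "genome-split"))
    gfit = fit_lasso_cv(gfit_design, gds.timing, k_folds=min(config.k_folds, 5),
                        seed=subseed(config.seed, "genome-fit"),
                        n_lambdas=min(config.n_lambdas, 50), train_ids=g_tr)
    prof_df = predict_genome(gfit, gds.features, gds.timing)
    smooth = modwt_smooth(prof_df["predicted"].to_numpy())
    seg = segment_ttrs(gds.timing.to_numpy(), bin_width=config.bin_width,
                       ttr_halfwidth=config.ttr_halfwidth,
                       seed=subseed(config.seed, "genome-seg"))
    gd = classify_gene_density(gds.labels["gene_count"].to_numpy(),
                               seed=subseed(config.seed, "genome-hmm"))
    strat = stratified_accuracy(
        gds.timing.to_numpy(), prof_df["predicted"].to_numpy(),
        {"domain": seg.is_domain, "ttr": seg.is_ttr,
         "gene_dense": gd.labels == 1, "gene_poor": gd.labels == 0},
    )
    rho_smooth = float(np.corrcoef(smooth, gds.timing.to_numpy())[0, 1])
    record("genome", rho=prof_df.attrs.get("rho"), rho_smoothed=rho_smooth,
           n_boundaries=len(seg.boundaries), stratified=strat.to_dict())

    # -- crosscell --------------------------------------------------------
    ds_a, ds_b = synthetic.generate_cell_pair(cfg)
    pair = CellPairDataset(X_a=ds_a.features, X_b=ds_b.features,
                           t_a=ds_a.timing, t_b=ds_b.timing)
    models = fit_celltype_models(pair, order=config.interaction_order,
                                 train_fraction=config.train_fraction,
                                 k_folds=config.k_folds,
                                 n_lambdas=min(config.n_lambdas, 50),
                                 seed=subseed(config.seed, "crosscell"))
    diff = fit_differential_model(pair.X_a - pair.X_b, pair.t_a - pair.t_b,
                                  order=config.interaction_order,
                                  n_lambdas=min(config.n_lambdas, 50),
                                  seed=subseed(config.seed, "diff"))
    drp_rhos = {}
    for delta in config.delta_cutoffs:
        drps = define_drps(pair, delta)
        drp_rhos[str(delta)] = cross_predict_drps(models.fit_a, pair, drps).rho
    record("crosscell", rho_matched=models.rho_matched,
           rho_unmatched=models.rho_unmatched, rho_differential=diff.rho,
           drp_rho=drp_rhos)

    manifest["complete"] = True
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
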