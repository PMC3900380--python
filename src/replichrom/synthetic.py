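"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the modeling stages assume:

* a promoters x features signal matrix whose columns fall into
  block-correlated groups (shared Gaussian latent factor per block, mimicking
  correlated histone-modification families);
* a timing response from a sparse linear model over standardized features,
  with optional pairwise multiplicative interaction effects, plus Gaussian
  noise;
* Poisson read counts for a ChIP sample/input pair whose expected
  enrichment equals a prescribed target M;
* a genome-wide timing profile with geometrically-distributed early/late
  domains, linear transition ramps at the boundaries, noisy feature
  encodings, and a two-state Markov gene-density process;
* a paired second cell type sharing the regression structure except for a
  known divergent subset, for the cross-cell-type stage.

All outputs are reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "generate_promoter_dataset",
    "generate_count_tracks",
    "generate_genome_profile",
    "generate_cell_pair",
    "noise_sd_for_r2",
]


@dataclass(frozen=True)
class GenomeConfig:
    n_bins: int = 1000
    domain_mean_len_bins: int = 40
    ttr_halfwidth_bins: int = 2
    n_encoding_features: int = 6
    n_nuisance_features: int = 4
    feature_noise_sd: float = 0.5
    level_sd: float = 1.2
    gene_density_stay_prob: float = 0.97
    gene_rate_poor: float = 0.3
    gene_rate_dense: float = 4.0


@dataclass(frozen=True)
class PairConfig:
    n_divergent: int = 2
    divergence_scale: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for all synthetic generators.

    ``true_terms`` lists (term, effect) pairs where a term is a feature name
    or a tuple of feature names (a multiplicative interaction).
    ``block_corr`` is the within-block correlation of features induced by a
    shared latent factor; blocks are consecutive runs of ``block_size``
    features within each class (HMs, then CBPs).
    """

    n_regions: int = 5000
    n_hms: int = 12
    n_cbps: int = 8
    true_terms: tuple = (
        ("HM01", 1.0),
        ("HM02", 0.8),
        ("CBP01", 0.6),
        (("HM01", "HM03"), 0.5),
        (("HM02", "HM04"), 0.5),
    )
    noise_sd: float = 1.0
    block_corr: float = 0.3
    block_size: int = 4
    seed: int = 0
    genome: GenomeConfig | None = None
    pair: PairConfig | None = None

    @property
    def feature_names(self) -> list[str]:
        return [f"HM{i + 1:02d}" for i in range(self.n_hms)] + [
            f"CBP{i + 1:02d}" for i in range(self.n_cbps)
        ]

    def __post_init__(self) -> None:
        if self.n_regions < 10:
            raise ValueError("n_regions must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")
        feats = set(self.feature_names)
        for term, effect in self.true_terms:
            if not np.isfinite(effect):
                raise ValueError(f"non-finite effect for term {term}")
            for f in _term_features(term):
                if f not in feats:
                    raise ValueError(f"unknown feature in true_terms: {f}")
        if self.pair is not None and self.pair.n_divergent > len(self.true_terms):
            raise ValueError("n_divergent exceeds the number of true terms")


def _term_features(term) -> tuple[str, ...]:
    return (term,) if isinstance(term, str) else tuple(term)


@dataclass
class SynthTruth:
    true_terms: list
    noise_sd: float
    oracle_r2: float
    divergent_terms: list = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["true_terms"] = [[list(_term_features(t)), e] for t, e in self.true_terms]
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SynthDataset:
    features: pd.DataFrame
    timing: pd.Series
    truth: SynthTruth
    counts: pd.DataFrame | None = None
    labels: pd.DataFrame | None = None
    regions: pd.DataFrame | None = None


def _standardize(M: np.ndarray) -> np.ndarray:
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)


def _draw_features(cfg: SynthConfig, rng: np.random.Generator, n: int | None = None) -> pd.DataFrame:
    """Block-correlated standard-normal features: within a block,
    x = sqrt(rho)*z_block + sqrt(1-rho)*eps, so corr(x_i, x_j) = rho."""
    n = cfg.n_regions if n is None else n
    names = cfg.feature_names
    cols = np.empty((n, len(names)))
    j = 0
    for class_size in (cfg.n_hms, cfg.n_cbps):
        done = 0
        while done < class_size:
            b = min(cfg.block_size, class_size - done)
            z = rng.standard_normal(n)
            eps = rng.standard_normal((n, b))
            cols[:, j : j + b] = (
                np.sqrt(cfg.block_corr) * z[:, None] + np.sqrt(1 - cfg.block_corr) * eps
            )
            j += b
            done += b
    X = pd.DataFrame(cols, columns=names)
    X.index = [f"r{i:06d}" for i in range(n)]
    return X


def _signal(cfg: SynthConfig, X: pd.DataFrame, terms=None) -> np.ndarray:
    """Noise-free response: sum of effects over standardized feature columns,
    interaction terms as elementwise products of standardized mains."""
    Z = _standardize(X.to_numpy())
    name_to_col = {f: i for i, f in enumerate(X.columns)}
    s = np.zeros(len(X))
    for term, effect in (cfg.true_terms if terms is None else terms):
        col = np.ones(len(X))
        for f in _term_features(term):
            col = col * Z[:, name_to_col[f]]
        s += effect * col
    return s


def noise_sd_for_r2(cfg: SynthConfig, target_r2: float, n_probe: int = 50_000) -> float:
    """Noise level giving an expected oracle R² of ``target_r2``.

    The signal variance is estimated by simulating a large feature draw from
    the same configuration; then sd = sqrt(var_signal*(1-R²)/R²).
    """
    if not 0 < target_r2 <= 1:
        raise ValueError("target_r2 must be in (0, 1]")
    rng = substream(cfg.seed, "noise-calibration")
    Xp = _draw_features(cfg, rng, n=n_probe)
    var_signal = float(np.var(_signal(cfg, Xp)))
    return float(np.sqrt(var_signal * (1 - target_r2) / target_r2))


def generate_promoter_dataset(cfg: SynthConfig) -> SynthDataset:
    """Promoter-level feature matrix and timing response with known truth.

    ``oracle_r2`` is the empirical 1 − var(ε)/var(y) of the realized draw —
    the ceiling any model can reach on this dataset.
    """
    rng = substream(cfg.seed, "promoters")
    X = _draw_features(cfg, rng)
    signal = _signal(cfg, X)
    eps = cfg.noise_sd * rng.standard_normal(cfg.n_regions)
    y = pd.Series(signal + eps, index=X.index, name="timing")
    var_y = float(np.var(y))
    oracle_r2 = 1.0 - float(np.var(eps)) / var_y if var_y > 0 else 1.0
    truth = SynthTruth(
        true_terms=list(cfg.true_terms), noise_sd=cfg.noise_sd,
        oracle_r2=float(np.clip(oracle_r2, 0.0, 1.0)),
    )
    return SynthDataset(features=X, timing=y, truth=truth)


def generate_count_tracks(
    cfg: SynthConfig,
    target_m: np.ndarray | pd.Series | None = None,
    input_rate: float = 100.0,
    lib_sample: int = 10_000_000,
    lib_input: int = 10_000_000,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Poisson sample/input read counts whose expected enrichment is target M.

    Input counts are Poisson(``input_rate``); sample counts are Poisson with
    rate ``2**M * input_rate * (lib_sample / lib_input)``, so the
    library-normalized log2 enrichment recovers M in expectation (bias → 0
    as rates grow). Columns follow the scoring module's count-table schema.
    """
    rng = substream(cfg.seed, "counts")
    if target_m is None:
        target_m = np.zeros(cfg.n_regions)
    target_m = np.asarray(target_m, dtype=float)
    n = len(target_m)
    ids = [f"r{i:06d}" for i in range(n)]
    c = lib_sample / lib_input
    rows = []
    for d in range(1, n_replicates + 1):
        n_input = rng.poisson(input_rate, size=n)
        n_sample = rng.poisson(np.exp2(target_m) * input_rate * c, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "region_id": ids,
                    "replicate": d,
                    "n_sample": n_sample,
                    "n_input": n_input,
                    "lib_sample": lib_sample,
                    "lib_input": lib_input,
                    "target_m": target_m,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _domain_profile(g: GenomeConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant latent timing over geometric domain lengths with
    linear ramps of half-width ttr_halfwidth_bins at the boundaries."""
    import warnings as _warnings

    if g.n_bins < 3 * g.domain_mean_len_bins:
        _warnings.warn("n_bins allows very few domains; estimates will be coarse")
    lengths, levels = [], []
    total = 0
    sign = rng.choice([-1.0, 1.0])
    while total < g.n_bins:
        ln = int(rng.geometric(1.0 / g.domain_mean_len_bins))
        ln = max(ln, 2 * g.ttr_halfwidth_bins + 1)
        lengths.append(ln)
        levels.append(sign * g.level_sd + 0.2 * rng.standard_normal())
        sign = -sign
        total += ln
    lengths[-1] -= total - g.n_bins
    if lengths[-1] <= 0:
        lengths.pop()
        levels.pop()
        lengths[-1] += g.n_bins - sum(lengths)
    step = np.repeat(levels, lengths)
    domain_id = np.repeat(np.arange(len(lengths)), lengths)
    boundaries = np.cumsum(lengths)[:-1]  # index of first bin of each new domain
    latent = step.astype(float).copy()
    h = g.ttr_halfwidth_bins
    for b in boundaries:
        lo, hi = b - h, b + h
        if lo < 0 or hi > g.n_bins:
            continue
        left, right = step[b - 1], step[b]
        ramp = np.linspace(left, right, hi - lo + 1)
        latent[lo:hi] = ramp[:-1]
    return latent, domain_id, boundaries


def generate_genome_profile(cfg: SynthConfig) -> SynthDataset:
    """Bin-level genome: latent timing profile, noisy feature encodings,
    per-bin truth labels (domain id, boundaries, gene-density state)."""
    if cfg.genome is None:
        raise ValueError("config.genome must be set")
    g = cfg.genome
    rng = substream(cfg.seed, "genome")
    latent, domain_id, boundaries = _domain_profile(g, rng)
    n = g.n_bins

    k = g.n_encoding_features
    slopes = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1, 1], size=k)
    enc = latent[:, None] * slopes[None, :] + g.feature_noise_sd * rng.standard_normal((n, k))
    nui = rng.standard_normal((n, g.n_nuisance_features))
    names = [f"ENC{i+1:02d}" for i in range(k)] + [
        f"NUI{i+1:02d}" for i in range(g.n_nuisance_features)
    ]
    X = pd.DataFrame(np.hstack([enc, nui]), columns=names)
    X.index = [f"bin{i:06d}" for i in range(n)]

    # two-state Markov gene-density process with Poisson gene counts
    stay = g.gene_density_stay_prob
    state = np.empty(n, dtype=int)
    state[0] = rng.integers(2)
    flips = rng.random(n) > stay
    for i in range(1, n):
        state[i] = state[i - 1] ^ flips[i]
    gene_counts = np.where(
        state == 1,
        rng.poisson(g.gene_rate_dense, size=n),
        rng.poisson(g.gene_rate_poor, size=n),
    )

    timing = pd.Series(latent, index=X.index, name="timing")
    labels = pd.DataFrame(
        {
            "domain_id": domain_id,
            "is_boundary": np.isin(np.arange(n), boundaries),
            "gene_density_state": state,
            "gene_count": gene_counts,
        },
        index=X.index,
    )
    truth = SynthTruth(true_terms=[], noise_sd=g.feature_noise_sd, oracle_r2=1.0)
    return SynthDataset(features=X, timing=timing, truth=truth, labels=labels)


def generate_cell_pair(cfg: SynthConfig) -> tuple[SynthDataset, SynthDataset]:
    """Two cell types sharing the regression structure except a known subset.

    Cell B reuses cell A's feature matrix and coefficients; divergence enters
    through the *levels* of the features underlying the first ``n_divergent``
    true terms, which in cell B are shifted by ``divergence_scale`` times a
    fresh standard-normal draw per region. With divergence 0 the feature
    difference ΔX is pure zero for the effect-bearing columns and Δt is pure
    noise; with divergence > 0, E[Δt | ΔX] is linear in the divergent terms.
    """
    if cfg.pair is None:
        raise ValueError("config.pair must be set")
    pc = cfg.pair
    rng = substream(cfg.seed, "cell-pair")
    ds_a = generate_promoter_dataset(cfg)
    X_a = ds_a.features
    divergent = list(cfg.true_terms[: pc.n_divergent])
    div_feats = sorted({f for term, _ in divergent for f in _term_features(term)})

    X_b = X_a.copy()
    for f in div_feats:
        X_b[f] = X_a[f] + pc.divergence_scale * rng.standard_normal(len(X_a))
    # small cell-type-specific wobble on all features keeps ΔX nonconstant
    # even at divergence 0 (chromatin is never measured identically twice)
    wobble = 0.05
    X_b = X_b + wobble * rng.standard_normal(X_b.shape)

    signal_b = _signal(cfg, X_b)
    eps_b = cfg.noise_sd * rng.standard_normal(cfg.n_regions)
    y_b = pd.Series(signal_b + eps_b, index=X_b.index, name="timing")
    var_yb = float(np.var(y_b))
    truth_b = SynthTruth(
        true_terms=list(cfg.true_terms),
        noise_sd=cfg.noise_sd,
        oracle_r2=float(np.clip(1 - np.var(eps_b) / var_yb, 0, 1)) if var_yb else 1.0,
        divergent_terms=[_term_features(t) for t, _ in divergent],
    )
    ds_a.truth.divergent_terms = truth_b.divergent_terms
    ds_b = SynthDataset(features=X_b, timing=y_b, truth=truth_b)
    return ds_a, ds_b


# ---------------------------------------------------------------------------
# Serialization helpers (regions BED, matrix TSV, timing bedGraph, truth JSON)
# ---------------------------------------------------------------------------

def write_dataset(ds: SynthDataset, outdir, prefix: str = "synth") -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    ds.features.rename_axis("region_id").to_csv(
        os.path.join(outdir, f"{prefix}.features.tsv"), sep="\t"
    )
    ds.timing.rename_axis("region_id").to_csv(
        os.path.join(outdir, f"{prefix}.timing.tsv"), sep="\t"
    )
    with open(os.path.join(outdir, f"{prefix}.truth.json"), "w") as fh:
        fh.write(ds.truth.to_json())
    if ds.counts is not None:
        ds.counts.to_csv(os.path.join(outdir, f"{prefix}.counts.tsv"), sep="\t", index=False)
    if ds.labels is not None:
        ds.labels.rename_axis("region_id").to_csv(
            os.path.join(outdir, f"{prefix}.labels.tsv"), sep="\t"
        )
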