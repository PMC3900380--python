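"""Genome-wide application of a promoter-trained model.

The promoter model is applied to the binned genome (the design is rebuilt
with the fit's stored expansion spec and standardization parameters), the
predicted profile is denoised with an undecimated wavelet transform, the
measured profile is segmented into replication domains and timing transition
regions (TTRs), bins are stratified by gene density with a two-state Poisson
HMM, and prediction accuracy is reported per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.stats import pearsonr

from ._rng import substream
from .lasso import LassoFit, predict

__all__ = [
    "predict_genome",
    "modwt_smooth",
    "segment_ttrs",
    "SegmentationResult",
    "classify_gene_density",
    "GeneDensityResult",
    "stratified_accuracy",
]


def predict_genome(
    fit: LassoFit,
    bin_features: pd.DataFrame,
    measured: pd.Series | None = None,
    chrom: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-bin predictions from a promoter-trained fit.

    Returns a DataFrame with a ``predicted`` column and, when measurements
    are given, attaches overall and per-chromosome Pearson accuracies in
    ``result.attrs['rho']`` / ``attrs['rho_by_chrom']``.
    """
    res = predict(fit, bin_features, measured)
    out = pd.DataFrame({"predicted": res.predicted})
    if measured is not None:
        out["measured"] = measured.loc[out.index]
        out.attrs["rho"] = res.rho
        if chrom is not None:
            by = {}
            for c, grp in out.groupby(chrom.loc[out.index]):
                if len(grp) >= 3 and grp["predicted"].std() > 0:
                    by[c] = float(pearsonr(grp["measured"], grp["predicted"])[0])
            out.attrs["rho_by_chrom"] = by
    return out


def modwt_smooth(
    values: np.ndarray,
    wavelet: str = "sym4",
    level: int = 2,
    boundary: str = "reflection",
) -> np.ndarray:
    """Wavelet smooth of a profile: the level-``level`` approximation of an
    undecimated (maximum-overlap) transform.

    The default ``sym4`` wavelet is the 8-tap least-asymmetric Daubechies
    filter (the classical "la8"). The signal is extended by reflection,
    decomposed with a stationary wavelet multiresolution analysis, and the
    smooth (scaling-coefficient) component is returned at the original
    length. Constants are reproduced exactly; the transform commutes with
    affine maps of the input.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in profile")
    n = len(x)
    w = pywt.Wavelet(wavelet)
    if n < w.dec_len:
        raise ValueError("profile shorter than the wavelet filter support")
    if boundary != "reflection":
        raise ValueError("only reflection boundaries are supported")
    # reflect-pad so the padded length is a multiple of 2**level and edge
    # effects fall outside the retained window
    block = 2**level
    pad = max(w.dec_len * block, block)
    total = n + 2 * pad
    extra = (-total) % block
    x_pad = np.pad(x, (pad, pad + extra), mode="reflect")
    comps = pywt.mra(x_pad, w, level=level, transform="swt")
    smooth = comps[0]
    return smooth[pad : pad + n]


@dataclass
class SegmentationResult:
    """Changepoint segmentation of a binned timing profile.

    ``boundaries`` are bin indices of the first bin of each new segment;
    ``is_ttr`` marks bins within the fixed-width transition window around a
    boundary (overlapping windows merged); domains are the complement.
    """

    boundaries: list[int]
    is_ttr: np.ndarray
    segment_of: np.ndarray
    segment_means: list[float]
    ttr_flank_bins: int

    @property
    def is_domain(self) -> np.ndarray:
        return ~self.is_ttr


def _max_t_split(x: np.ndarray, min_seg: int) -> tuple[int, float]:
    """Best split of x into [0,t) | [t,n) by the two-sample t statistic."""
    n = len(x)
    csum = np.cumsum(x)
    c2sum = np.cumsum(x * x)
    ts = np.arange(min_seg, n - min_seg + 1)
    if len(ts) == 0:
        return -1, 0.0
    n1 = ts
    n2 = n - ts
    s1 = csum[ts - 1]
    s2 = csum[-1] - s1
    m1, m2 = s1 / n1, s2 / n2
    ss1 = c2sum[ts - 1] - n1 * m1**2
    ss2 = (c2sum[-1] - c2sum[ts - 1]) - n2 * m2**2
    dof = n - 2
    pooled = np.sqrt(np.maximum(ss1 + ss2, 1e-300) / dof * (1 / n1 + 1 / n2))
    tstat = np.abs(m1 - m2) / pooled
    j = int(np.argmax(tstat))
    return int(ts[j]), float(tstat[j])


def _perm_pvalue(x: np.ndarray, t_obs: float, min_seg: int, n_perm: int,
                 rng: np.random.Generator) -> float:
    hits = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        _, t = _max_t_split(xp, min_seg)
        if t >= t_obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def segment_ttrs(
    values: np.ndarray,
    bin_width: int = 10_000,
    ttr_halfwidth: int = 15_000,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_seg: int = 3,
    seed: int = 0,
) -> SegmentationResult:
    """Recursive binary segmentation of a timing profile into constant-level
    domains, with timing transition regions around each boundary.

    At each segment the maximal two-sample t statistic over candidate splits
    is tested against ``n_perm`` within-segment permutations; a split is
    accepted at significance ``alpha`` and both halves are recursed
    (CBS-style behavior at desk scale). A TTR is the window of
    ``ttr_halfwidth`` on either side of a boundary; on ``bin_width`` bins
    that is the boundary bin plus ``ttr_halfwidth // bin_width`` flanking
    bins per side. The procedure is invariant to adding a constant to the
    profile.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 bins to segment")
    rng = substream(seed, "cbs")
    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if len(seg) < 2 * min_seg or np.ptp(seg) == 0:
            return
        t_rel, t_obs = _max_t_split(seg, min_seg)
        if t_rel < 0:
            return
        p = _perm_pvalue(seg, t_obs, min_seg, n_perm, rng)
        if p > alpha:
            return
        split = lo + t_rel
        boundaries.append(split)
        recurse(lo, split)
        recurse(split, hi)

    recurse(0, n)
    boundaries.sort()

    flank = int(ttr_halfwidth // bin_width)
    is_ttr = np.zeros(n, dtype=bool)
    for b in boundaries:
        is_ttr[max(0, b - flank) : min(n, b + flank + 1)] = True

    edges = [0] + boundaries + [n]
    segment_of = np.empty(n, dtype=int)
    means = []
    for s, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        segment_of[a:b] = s
        means.append(float(x[a:b].mean()))
    return SegmentationResult(
        boundaries=boundaries, is_ttr=is_ttr, segment_of=segment_of,
        segment_means=means, ttr_flank_bins=flank,
    )


@dataclass
class GeneDensityResult:
    labels: np.ndarray          # 1 = gene-dense, 0 = gene-poor
    rates: tuple[float, float]  # (poor, dense) Poisson means
    degenerate: bool = False


def classify_gene_density(
    gene_counts: np.ndarray,
    seed: int = 0,
    n_restarts: int = 3,
    n_iter: int = 100,
) -> GeneDensityResult:
    """Two-state Poisson HMM over per-bin gene counts.

    Fitted by Baum-Welch with seeded restarts (best likelihood kept),
    decoded by Viterbi. The state with the larger emission mean is labeled
    gene-dense regardless of initialization, so labels are stable.
    """
    counts = np.asarray(gene_counts)
    if counts.ndim != 1 or len(counts) < 50:
        raise ValueError("need a 1-D array of at least 50 bins")
    if (counts < 0).any():
        raise ValueError("gene counts must be non-negative")
    if counts.min() == counts.max():
        warnings.warn("all-equal gene counts: degenerate single-state labeling")
        return GeneDensityResult(
            labels=np.zeros(len(counts), dtype=int),
            rates=(float(counts[0]), float(counts[0])),
            degenerate=True,
        )
    from hmmlearn.hmm import PoissonHMM

    obs = counts.reshape(-1, 1)
    best = None
    for r in range(n_restarts):
        model = PoissonHMM(
            n_components=2, n_iter=n_iter,
            random_state=int(substream(seed, "hmm", str(r)).integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(obs)
            score = model.score(obs)
        if best is None or score > best[0]:
            best = (score, model)
    model = best[1]
    states = model.predict(obs)
    lam = model.lambdas_.ravel()
    dense_state = int(np.argmax(lam))
    labels = (states == dense_state).astype(int)
    rates = (float(lam.min()), float(lam.max()))
    return GeneDensityResult(labels=labels, rates=rates)


def stratified_accuracy(
    measured: np.ndarray,
    predicted: np.ndarray,
    strata: dict[str, np.ndarray],
) -> pd.Series:
    """Pearson accuracy within each stratum (boolean mask per class).

    Classes with fewer than 3 bins, or degenerate variance, report NaN.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    out = {}
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 3 or np.std(measured[mask]) == 0 or np.std(predicted[mask]) == 0:
            out[name] = float("nan")
        else:
            out[name] = float(pearsonr(measured[mask], predicted[mask])[0])
    return pd.Series(out, name="rho")
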