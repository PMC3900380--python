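"""Quantification of chromatin features and replication timing within regions.

Two signal sources are supported, mirroring how ChIP experiments are
delivered in practice:

* sequencing counts — per-region aligned-read counts for a ChIP sample and
  its matched input, turned into a library-size-normalized log2 enrichment
  ``M`` with an integer pseudocount;
* tiling-array tracks — already-normalized smoothed M-values, averaged over
  the probes falling entirely within each region.

Replication timing is scored the same way as an array feature (mean smoothed
M-value of probes entirely within the region; higher = earlier replication).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_score",
    "array_signal_score",
    "score_regions",
    "cluster_features",
    "FeatureClustering",
]

COUNT_COLUMNS = ["region_id", "replicate", "n_sample", "n_input", "lib_sample", "lib_input"]


def enrichment_score(counts: pd.DataFrame, pseudocount: int = 1) -> pd.Series:
    """Library-normalized log2 ChIP enrichment per region.

    For replicate ``d`` with sample/input read counts ``n_S``/``n_I`` (reads
    aligning entirely within the region) and library sizes ``L_S``/``L_I``::

        M_d = log2( (n_S + p) / (c * (n_I + p)) ),   c = L_S / L_I

    and the feature enrichment is the arithmetic mean of ``M_d`` over the
    available replicates. The integer pseudocount ``p >= 1`` guards the
    logarithm when a region has zero reads; the library-size ratio ``c``
    scales the input count to the sample sequencing depth. The score is
    antisymmetric under swapping (sample, L_S) with (input, L_I).

    ``counts`` columns: region_id, replicate, n_sample, n_input, lib_sample,
    lib_input. All replicates must cover the same region set.
    """
    if pseudocount < 1 or int(pseudocount) != pseudocount:
        raise ValueError("pseudocount must be an integer >= 1")
    df = counts
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (df[["n_sample", "n_input"]] < 0).any().any():
        raise ValueError("negative read counts")
    if (df["lib_input"] <= 0).any() or (df["lib_sample"] <= 0).any():
        raise ValueError("library sizes must be positive")
    universes = df.groupby("replicate")["region_id"].apply(frozenset)
    if universes.nunique() > 1:
        raise ValueError("replicates do not share a common region universe")
    c = df["lib_sample"] / df["lib_input"]
    m_d = np.log2((df["n_sample"] + pseudocount) / (c * (df["n_input"] + pseudocount)))
    return m_d.groupby(df["region_id"]).mean().rename("M")


def array_signal_score(track: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Mean track value over probes/intervals lying entirely within each region.

    Probes straddling a region edge are excluded ("entirely within" rule);
    regions with no covered probe get NaN (missing, handled at assembly).
    The mean is unweighted — splitting a probe into pieces changes it.
    """
    out = pd.Series(np.nan, index=regions["id"].to_numpy(), dtype=float, name="signal")
    for chrom, reg in regions.groupby("chrom"):
        sub = track[track["chrom"] == chrom]
        if sub.empty:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["value"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        # track is sorted, non-overlapping: probes within [s, e) form a
        # contiguous run lo..hi with starts >= s and ends <= e
        lo = np.searchsorted(starts, reg["start"].to_numpy(), side="left")
        hi = np.searchsorted(ends, reg["end"].to_numpy(), side="right")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            means = np.where(n > 0, (csum[np.maximum(hi, lo)] - csum[lo]) / np.where(n > 0, n, 1), np.nan)
        out.loc[reg["id"].to_numpy()] = means
    return out


def score_regions(
    regions: pd.DataFrame,
    feature_sources: Mapping[str, object],
    timing_track: pd.DataFrame,
    pseudocount: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the regions x features matrix ``X`` and timing vector ``y``.

    ``feature_sources`` maps a feature name to either an array track
    (DataFrame with chrom/start/end/value — scored by containment mean) or a
    count table (DataFrame with the count columns — scored by the enrichment
    formula). Regions with any missing value are dropped and logged.
    """
    names = list(feature_sources)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    cols = {}
    for name, src in feature_sources.items():
        if isinstance(src, pd.DataFrame) and "n_sample" in src.columns:
            scored = enrichment_score(src, pseudocount=pseudocount)
            cols[name] = scored.reindex(regions["id"])
        else:
            cols[name] = array_signal_score(src, regions)
    X = pd.DataFrame(cols, index=regions["id"].to_numpy())
    y = array_signal_score(timing_track, regions).rename("timing")
    mask = X.notna().all(axis=1) & y.notna()
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("dropping %d/%d regions with missing values", n_drop, len(mask))
    return X[mask], y[mask]


@dataclass
class FeatureClustering:
    """Correlation-based hierarchical clustering of feature profiles (QC)."""

    dissimilarity: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]


def cluster_features(
    X: pd.DataFrame,
    linkage: str = "average",
    measure: str = "half",
) -> FeatureClustering:
    """Hierarchically cluster feature columns by correlation dissimilarity.

    ``measure='half'`` uses d = (1 - rho)/2, bounded in [0, 1] (d=0 for
    identical, 1 for perfectly anticorrelated columns); ``measure='one'``
    uses d = 1 - rho. Columns are ordered by name first so leaf order is
    deterministic under ties.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two features to cluster")
    sd = X.std(axis=0, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature(s): {list(zero.index)}")
    X = X[sorted(X.columns)]
    rho = np.corrcoef(X.to_numpy(), rowvar=False)
    if measure == "half":
        d = (1.0 - rho) / 2.0
    elif measure == "one":
        d = 1.0 - rho
    else:
        raise ValueError(f"unknown measure: {measure}")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = sch.linkage(squareform(d, checks=False), method=linkage)
    order = [X.columns[i] for i in sch.leaves_list(Z)]
    dmat = pd.DataFrame(d, index=X.columns, columns=X.columns)
    return FeatureClustering(dissimilarity=dmat, linkage=Z, leaf_order=order)
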