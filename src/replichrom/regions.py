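"""Genomic region universes: unique promoters and genome-wide bins.

Coordinates are 0-based, half-open throughout (BED/bedGraph native; GTF is
converted on read). The default chromosome universe is the four large
Drosophila melanogaster autosome arms — chromosomes 4 and X carry special
chromatin (heterochromatic chr4; dosage-compensated, early-replicating X in
male cell lines) and are excluded from modeling by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "DEFAULT_CHROMS",
    "DM3_ARM_LENGTHS",
    "read_tss_bed",
    "read_tss_gtf",
    "select_unique_promoters",
    "make_bins",
    "read_chrom_sizes",
    "read_track",
    "write_bedgraph",
    "write_regions_bed",
]

#: Chromosome arms used for modeling (chr4 and chrX excluded).
DEFAULT_CHROMS: tuple[str, ...] = ("2L", "2R", "3L", "3R")

#: D. melanogaster dm3 (BDGP release 5) chromosome-arm lengths in bp.
#: With 10 kb ceil-binning these four arms yield 2302+2115+2455+2791 = 9663
#: bins, which pins the partial-final-bin convention.
DM3_ARM_LENGTHS: dict[str, int] = {
    "2L": 23011544,
    "2R": 21146708,
    "3L": 24543557,
    "3R": 27905053,
}

REGION_COLUMNS = ["chrom", "start", "end", "id"]


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def read_tss_bed(path) -> pd.DataFrame:
    """Read TSS records from a BED6 file.

    The TSS is the 5' end of the interval: ``start`` on the + strand and
    ``end - 1`` on the − strand. Returns columns (chrom, tss, strand).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if df[["start", "end"]].isna().any().any():
        raise ValueError(f"malformed BED record in {path}")
    minus = df["strand"] == "-"
    tss = np.where(minus, df["end"].to_numpy() - 1, df["start"].to_numpy())
    return pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "tss": tss.astype(int), "strand": df["strand"]}
    )


def read_tss_gtf(path, feature: str = "transcript") -> pd.DataFrame:
    """Extract per-transcript TSS positions from a GTF/GFF file.

    GTF coordinates are 1-based inclusive; the returned ``tss`` is 0-based.
    """
    names = [
        "chrom", "source", "feature", "start", "end",
        "score", "strand", "frame", "attribute",
    ]
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=names, dtype={"chrom": str}
    )
    if df.empty:
        warnings.warn(f"no records in {path}")
        return pd.DataFrame({"chrom": [], "tss": [], "strand": []})
    bad = df["start"].isna() | df["end"].isna()
    if bad.any():
        raise ValueError(f"malformed GTF record at line {int(np.argmax(bad.to_numpy())) + 1}")
    df = df[df["feature"] == feature]
    minus = df["strand"] == "-"
    tss = np.where(minus, df["end"].to_numpy() - 1, df["start"].to_numpy() - 1)
    return pd.DataFrame(
        {"chrom": df["chrom"].astype(str), "tss": tss.astype(int), "strand": df["strand"]}
    ).reset_index(drop=True)


def select_unique_promoters(
    tss: pd.DataFrame,
    window: int = 1000,
    chroms: Sequence[str] = DEFAULT_CHROMS,
) -> pd.DataFrame:
    """Build the unique-promoter universe: fixed-width windows on isolated TSSs.

    A TSS is retained iff no other distinct TSS lies within ``window/2`` bp of
    it on the same chromosome, regardless of strand (identical positions shared
    by several transcripts are collapsed before the distance test). Retained
    TSSs become ``window``-wide regions centered on the TSS.

    Parameters
    ----------
    tss : DataFrame with columns (chrom, tss[, strand]).
    window : promoter window width in bp (default 1 kb).
    chroms : chromosome universe; TSSs elsewhere are dropped.

    Returns
    -------
    DataFrame with columns (chrom, start, end, id, tss, strand), sorted by
    (chrom, start). Output is invariant to input ordering.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be a positive even integer")
    if len(tss) == 0:
        warnings.warn("empty annotation: returning empty promoter set")
        return pd.DataFrame(columns=REGION_COLUMNS + ["tss", "strand"])
    df = tss.copy()
    if "strand" not in df:
        df["strand"] = "."
    df = df[df["chrom"].isin(chroms)]
    # collapse transcripts sharing an identical TSS before the distance test
    df = df.drop_duplicates(subset=["chrom", "tss"]).sort_values(["chrom", "tss"])
    half = window // 2
    keep_parts = []
    for _, grp in df.groupby("chrom", sort=True):
        pos = grp["tss"].to_numpy()
        left = np.empty(len(pos))
        right = np.empty(len(pos))
        left[0], right[-1] = np.inf, np.inf
        left[1:] = pos[1:] - pos[:-1]
        right[:-1] = pos[1:] - pos[:-1]
        keep = (np.minimum(left, right) >= half) & (pos >= half)
        keep_parts.append(grp[keep])
    out = pd.concat(keep_parts) if keep_parts else df.iloc[:0]
    out = out.reset_index(drop=True)
    result = pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["tss"] - half,
            "end": out["tss"] + half,
            "tss": out["tss"],
            "strand": out["strand"],
        }
    )
    result["id"] = [
        f"{c}:{t}" for c, t in zip(result["chrom"], result["tss"])
    ]
    return result[["chrom", "start", "end", "id", "tss", "strand"]]


def make_bins(chrom_sizes: Mapping[str, int], width: int = 10_000) -> pd.DataFrame:
    """Tile chromosomes with fixed-width bins; the final partial bin is kept.

    Bin count per chromosome is ``ceil(length / width)``.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"non-positive size for chromosome {chrom}")
        starts = np.arange(0, size, width)
        ends = np.minimum(starts + width, size)
        for s, e in zip(starts, ends):
            rows.append((str(chrom), int(s), int(e), f"{chrom}:{s}-{e}"))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def _read_wig(path) -> pd.DataFrame:
    rows = []
    chrom, start, step, span, mode = None, 0, 1, 1, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    start = int(fields["start"]) - 1  # wig is 1-based
                    step = int(fields.get("step", span))
                else:
                    mode = "variable"
                continue
            if mode == "fixed":
                rows.append((chrom, start, start + span, float(line)))
                start += step
            elif mode == "variable":
                p, v = line.split()
                s = int(p) - 1
                rows.append((chrom, s, s + span, float(v)))
            else:
                raise ValueError(f"wig data before a step declaration in {path}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_track(path, fmt: str | None = None, chroms: Iterable[str] | None = None) -> pd.DataFrame:
    """Read an interval-value track (bedGraph, wig, or 4-column TSV).

    Records are sorted by (chrom, start); overlapping intervals within a
    chromosome raise (the per-region signal would be ambiguous). Records on
    chromosomes outside ``chroms`` (if given) are dropped with a warning.
    """
    if fmt is None:
        name = str(path).lower()
        if name.endswith((".wig",)):
            fmt = "wig"
        else:
            fmt = "bedgraph"
    if fmt == "wig":
        df = _read_wig(path)
    elif fmt in ("bedgraph", "tsv"):
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
        df = df.astype({"start": int, "end": int, "value": float})
    else:
        raise ValueError(f"unknown track format: {fmt}")
    if chroms is not None:
        known = set(chroms)
        unknown = ~df["chrom"].isin(known)
        if unknown.any():
            warnings.warn(
                f"dropping {int(unknown.sum())} records on chromosomes outside the universe"
            )
            df = df[~unknown]
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite values in track")
    for chrom, grp in df.groupby("chrom"):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping intervals on {chrom}: ambiguous signal")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def write_regions_bed(regions: pd.DataFrame, path, name_col: str = "id") -> None:
    out = regions[["chrom", "start", "end"]].copy()
    out["name"] = regions[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)
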