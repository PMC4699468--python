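"""Abundance quantification and seasonal co-occurrence analysis.

The abundance statistic is the *fraction of reads per nucleotide in bin*:
reads mapping to a bin in a sample, divided by the sample's total read count,
divided by the bin size.  It is comparable across samples of different
sequencing depth and across bins of different size.  Reads per bin are
recovered from a per-contig mean-coverage table as coverage x contig length /
read length, summed over the bin's contigs.

Seasonal profiles are row-wise Z-scores of the abundance table; co-occurrence
structure is average-linkage hierarchical clustering of 1 - Spearman
correlation between profiles (optionally with appended external rows such as
microscopy-counted phytoplankton groups).  The filter-fraction analysis
relates the (mid/small)-fraction matched-read ratio to genome size by Spearman
rank correlation on log scales.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import Bin

__all__ = [
    "AbundanceTable",
    "FractionRatio",
    "reads_per_bin",
    "abundance_fraction",
    "build_abundance_table",
    "zscore_profiles",
    "cooccurrence_cluster",
    "spearman",
    "fraction_ratio_analysis",
]


@dataclass(frozen=True)
class AbundanceTable:
    """Bin x sample fraction-of-reads-per-nucleotide values with provenance."""

    values: pd.DataFrame
    bin_sizes: dict[str, int]
    total_reads: dict[str, float]


@dataclass(frozen=True)
class FractionRatio:
    cluster_id: str
    counts_small: float
    counts_mid: float
    counts_large: float | None
    ratio_mid_small: float | None


def reads_per_bin(
    coverage: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    bin_: Bin | Sequence[str],
    sample: str,
    read_len: int = 100,
) -> float:
    """Number of reads attributable to a bin in one sample.

    Mean per-nucleotide coverage times contig length, summed over the bin's
    contigs, divided by the read length.
    """
    contig_ids = bin_.contig_ids if isinstance(bin_, Bin) else tuple(bin_)
    missing = [c for c in contig_ids if c not in coverage.index]
    if missing:
        raise KeyError(f"coverage table missing contigs: {missing[:5]}")
    cov = coverage.loc[list(contig_ids), sample].to_numpy(dtype=float)
    lengths = np.array([contig_lengths[c] for c in contig_ids], dtype=float)
    return float((cov * lengths).sum() / read_len)


def abundance_fraction(reads_in_bin: float, total_reads: float, bin_size: int) -> float:
    """(reads_in_bin / total_reads) / bin_size — fraction of reads per nucleotide in bin."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    return (reads_in_bin / total_reads) / bin_size


def build_abundance_table(
    coverage: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    bins: Sequence[Bin],
    total_reads: Mapping[str, float],
    read_len: int = 100,
) -> AbundanceTable:
    samples = list(coverage.columns)
    data = {}
    sizes = {}
    for b in bins:
        sizes[b.id] = b.size
        data[b.id] = [
            abundance_fraction(reads_per_bin(coverage, contig_lengths, b, s, read_len), total_reads[s], b.size)
            for s in samples
        ]
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return AbundanceTable(values=values, bin_sizes=sizes, total_reads=dict(total_reads))


def zscore_profiles(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores (population SD); constant rows map to all zeros."""
    df = table.values if isinstance(table, AbundanceTable) else table
    if df.shape[1] < 2:
        raise ValueError("need at least two samples to standardize")
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    out = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


@dataclass(frozen=True)
class CooccurrenceResult:
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    distance: pd.DataFrame
    newick: str


def _to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.get_left()), rec(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return rec(tree) + ";"


def cooccurrence_cluster(
    profiles: pd.DataFrame,
    external_profiles: pd.DataFrame | None = None,
) -> CooccurrenceResult:
    """Average-linkage clustering of rows at distance 1 - Spearman correlation.

    External rows (e.g. microscopy groups) are appended before clustering.
    Zero-variance rows get the maximal distance of 2.0 to every other row and
    raise a warning.
    """
    df = profiles
    if external_profiles is not None:
        df = pd.concat([profiles, external_profiles], axis=0)
    if df.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    df = df.loc[sorted(df.index)]  # deterministic tie-breaking by row id
    arr = df.to_numpy(dtype=float)
    flat = arr.std(axis=1) == 0
    if flat.any():
        warnings.warn(f"zero-variance rows assigned maximal distance: {list(df.index[flat])}")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant rows are handled explicitly below (NaN -> max distance)
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(arr, axis=1).statistic
    if arr.shape[0] == 2:  # scipy returns a scalar for two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    dist = np.clip(dist, 0.0, 2.0)
    ddf = pd.DataFrame(dist, index=df.index, columns=df.index)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = tuple(df.index[i] for i in hierarchy.leaves_list(z))
    return CooccurrenceResult(linkage=z, leaf_order=order, distance=ddf, newick=_to_newick(z, list(df.index)))


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    n = x_rank.size
    perms = np.array(list(itertools.permutations(range(n))))
    xs = x_rank[perms]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    rhos = (xc @ yc) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def spearman(x: Sequence[float], y: Sequence[float], exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with mid-ranks for ties; exact permutation p for n <= 8,
    t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 points")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if x.size <= exact_max_n:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        return rho, _exact_spearman_p(xr, yr, rho)
    return rho, float(res.pvalue)


def fraction_ratio_analysis(
    counts: pd.DataFrame,
    genome_sizes: Mapping[str, float],
) -> tuple[pd.DataFrame, float, float]:
    """Filter-fraction ratio vs genome size.

    ``counts`` rows are clusters with columns ``counts_small`` (0.1-0.8 um)
    and ``counts_mid`` (0.8-3.0 um), both matched reads per 10,000 queried;
    the ratio mid/small is defined only where counts_small > 0.  Returns the
    per-cluster ratio table plus Spearman rho and two-sided p between
    log(ratio) and log(genome size).
    """
    required = {"counts_small", "counts_mid"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    table = counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ratio_mid_small"] = np.where(
            table["counts_small"] > 0, table["counts_mid"] / table["counts_small"], np.nan
        )
    table["genome_size"] = [genome_sizes[c] for c in table.index]
    defined = table.dropna(subset=["ratio_mid_small"])
    defined = defined[defined["ratio_mid_small"] > 0]
    if defined.shape[0] < 3:
        raise ValueError("fewer than 3 clusters with defined ratios")
    rho, p = spearman(np.log(defined["ratio_mid_small"]), np.log(defined["genome_size"]))
    return table, rho, p
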