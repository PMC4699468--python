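"""Genome streamlining features and between-group enrichment tests.

Streamlined oligotroph genomes are small, coding-dense and depleted in
regulatory gene classes.  The feature set used for ordination is the one
established for distinguishing oligotrophs from copiotrophs: percentage of
non-coding DNA (computed only on contigs longer than 5000 nt, to avoid the
bias of short contig ends), GC content, and the proportions of genes in the
COG categories transcription (K), signal transduction (T), defense
mechanisms (V), secondary metabolites biosynthesis (Q) and lipid transport
and metabolism (I) — all log-transformed.

Group comparisons use Welch's unequal-variance t-test with Benjamini-Hochberg
false-discovery-rate correction over the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Bin, gc_fraction

__all__ = [
    "GenomeFeatures",
    "STREAMLINING_COGS",
    "gc_content",
    "noncoding_fraction",
    "cog_category_proportions",
    "welch_test",
    "bh_adjust",
    "enrichment_report",
    "streamlining_table",
]

STREAMLINING_COGS = ("K", "T", "V", "Q", "I")
LOG_PSEUDOCOUNT = 0.01  # percentage points, to admit zero percentages


@dataclass(frozen=True)
class GenomeFeatures:
    """Streamlining-relevant features of one bin/genome.

    ``noncoding`` is None (flagged undefined) when no contig exceeds the
    minimum length used for the non-coding estimate.
    """

    bin_id: str
    size: int
    gc: float  # percent
    noncoding: float | None  # percent
    cog_category_pct: dict[str, float]

    def log_features(self, categories: Sequence[str] = STREAMLINING_COGS) -> dict[str, float] | None:
        if self.noncoding is None:
            return None
        feats = {"noncoding": self.noncoding, "gc": self.gc}
        for c in categories:
            feats[f"cog_{c}"] = self.cog_category_pct.get(c, 0.0)
        return {k: float(np.log(v + LOG_PSEUDOCOUNT)) for k, v in feats.items()}


def gc_content(bin_: Bin | str) -> float:
    """GC percent over unambiguous bases of the whole bin."""
    seq = bin_ if isinstance(bin_, str) else "".join(c.sequence for c in bin_.contigs)
    return 100.0 * gc_fraction(seq)


def _merged_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def noncoding_fraction(
    bin_: Bin, genes: pd.DataFrame, min_contig: int = 5000
) -> float | None:
    """Percent of bases covered by no gene, over contigs longer than ``min_contig``.

    Overlapping genes are merged before counting.  Returns None (undefined)
    when no contig qualifies.
    """
    required = {"contig_id", "start", "end"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    total = 0
    coding = 0
    by_contig = {cid: g for cid, g in genes.groupby("contig_id")}
    for contig in bin_.contigs:
        if contig.length <= min_contig:
            continue
        total += contig.length
        g = by_contig.get(contig.id)
        if g is None:
            continue
        ivals = []
        for s, e in zip(g["start"], g["end"]):
            s, e = int(s), int(e)
            if not (0 <= s < e <= contig.length):
                raise ValueError(f"gene interval [{s},{e}) outside contig {contig.id!r}")
            ivals.append((s, e))
        coding += sum(e - s for s, e in _merged_intervals(ivals))
    if total == 0:
        return None
    return 100.0 * (total - coding) / total


def cog_category_proportions(gene_annotations: pd.DataFrame) -> dict[str, float]:
    """Percent of annotated genes per COG category.

    ``gene_annotations`` columns: gene_id, cog_category, where cog_category
    may hold several letters (e.g. "KT"); such genes contribute fractionally
    to each listed category, so percentages always sum to 100.
    """
    required = {"gene_id", "cog_category"}
    if not required <= set(gene_annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    ann = gene_annotations.dropna(subset=["cog_category"])
    ann = ann[ann["cog_category"].astype(str).str.len() > 0]
    if ann.shape[0] == 0:
        raise ValueError("no annotated genes")
    weights: dict[str, float] = {}
    n_genes = ann["gene_id"].nunique()
    for _, grp in ann.groupby("gene_id"):
        cats: list[str] = []
        for val in grp["cog_category"]:
            cats.extend(list(str(val)))
        w = 1.0 / len(cats)
        for c in cats:
            weights[c] = weights.get(c, 0.0) + w
    return {c: 100.0 * w / n_genes for c, w in sorted(weights.items())}


def welch_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance with different means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def enrichment_report(
    feature_table: pd.DataFrame, groups: Mapping[str, str], group_a: str, group_b: str
) -> pd.DataFrame:
    """Welch's t with BH correction for every feature column between two groups.

    ``groups`` maps row id -> group label.  Returns a DataFrame with columns
    feature, t, p, q sorted by q.
    """
    labels = pd.Series(groups)
    ids_a = [i for i in feature_table.index if labels.get(i) == group_a]
    ids_b = [i for i in feature_table.index if labels.get(i) == group_b]
    rows = []
    for feature in feature_table.columns:
        a = feature_table.loc[ids_a, feature].dropna()
        b = feature_table.loc[ids_b, feature].dropna()
        t, p = welch_test(a, b)
        rows.append({"feature": feature, "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out.sort_values("q", kind="stable").reset_index(drop=True)


def streamlining_table(
    features: Sequence[GenomeFeatures], categories: Sequence[str] = STREAMLINING_COGS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordination-ready log-feature matrix plus size-vs-noncoding scatter data.

    Rows with undefined non-coding fractions are dropped with a warning.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 genomes for an ordination table")
    rows = {}
    scatter = []
    for f in features:
        lf = f.log_features(categories)
        if lf is None:
            warnings.warn(f"dropping {f.bin_id}: non-coding fraction undefined")
            continue
        rows[f.bin_id] = lf
        scatter.append({"bin_id": f.bin_id, "size": f.size, "noncoding": f.noncoding})
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    return matrix, pd.DataFrame(scatter)
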