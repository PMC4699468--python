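"""Single-copy-gene (SCG) quality control of genome bins.

A bin assembled from a metagenome should contain each single-copy marker gene
exactly once.  Counting how many of a reference panel's markers are present
(completeness) and how many occur in extra copies (contamination/misassembly)
gives a quality gate that needs no reference genome.

Two panels are used the way the study used them: a small general prokaryotic
panel of 36 markers drives the accept/reject gate (at least 30 of 36 present,
at most two in multiple copies), and larger taxon-specific panels (order of
119-332 markers, selected to be present in >= 97 % of sequenced
representatives of the taxon with a mean gene count below 1.03) drive the
quantitative completeness / error estimates.

This module also owns the binning-facing contig splitting: contigs of at
least 20 kb are split into 10-kb fragments before clustering, and fragments
that land in the same bin and were adjacent in the source contig are joined
back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import Bin

__all__ = [
    "SCGPanel",
    "BinQuality",
    "SplitContig",
    "split_contigs",
    "rejoin_contigs",
    "detect_scgs",
    "gate_bin",
    "select_panel",
    "estimate_quality",
    "GENERAL_PANEL_SIZE",
]

GENERAL_PANEL_SIZE = 36


@dataclass(frozen=True)
class SCGPanel:
    """A marker panel with its selection scope (general, phylum or class)."""

    panel_id: str
    taxon_scope: str
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("panel marker ids must be unique")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def general_panel(marker_ids: Sequence[str] | None = None) -> SCGPanel:
    """The 36-marker general prokaryotic panel (synthetic marker ids by default)."""
    ids = tuple(marker_ids) if marker_ids is not None else tuple(f"scg_{i:02d}" for i in range(GENERAL_PANEL_SIZE))
    if len(ids) != GENERAL_PANEL_SIZE:
        raise ValueError(f"general panel must have {GENERAL_PANEL_SIZE} markers")
    return SCGPanel("general", "general", ids)


@dataclass(frozen=True)
class BinQuality:
    """SCG-based quality summary of one bin.

    ``passed`` is only meaningful for the general-panel gate and is None for
    taxon-specific quality estimates.
    """

    bin_id: str
    n_present: int
    n_multi: int
    completeness: float
    est_error: float
    passed: bool | None


@dataclass(frozen=True)
class SplitContig:
    """A binning fragment of a long contig; ``part_index`` orders adjacency."""

    id: str
    sequence: str
    source_contig: str
    part_index: int
    n_parts: int


def split_contigs(contigs: Sequence, threshold: int = 20_000, piece: int = 10_000) -> list[SplitContig]:
    """Split contigs of length >= ``threshold`` into consecutive ``piece``-bp
    fragments; a remainder shorter than ``piece`` is appended to the last
    fragment.  Shorter contigs pass through as a single part."""
    if threshold < piece:
        raise ValueError("threshold must be at least the piece size")
    out: list[SplitContig] = []
    for i, c in enumerate(contigs):
        cid, seq = (c.id, c.sequence) if hasattr(c, "sequence") else (c[0], c[1])
        n = len(seq)
        if n < threshold:
            out.append(SplitContig(cid, seq, cid, 0, 1))
            continue
        n_parts = n // piece
        bounds = [j * piece for j in range(n_parts)] + [n]  # remainder merges into last
        parts = [seq[bounds[j] : bounds[j + 1]] for j in range(n_parts)]
        for j, part in enumerate(parts):
            out.append(SplitContig(f"{cid}.p{j:03d}", part, cid, j, n_parts))
    return out


def rejoin_contigs(assignment: Mapping[str, str], parts: Sequence[SplitContig]) -> dict[str, list[tuple[str, str]]]:
    """Join split fragments that were assigned to the same bin and were
    adjacent in their source contig.

    Returns bin id -> list of (contig_id, sequence); a run of adjacent parts
    is named after its source contig (suffixed with the run's first part index
    when the contig was torn apart by the binning).
    """
    by_part = {p.id: p for p in parts}
    per_bin: dict[str, dict[str, list[SplitContig]]] = {}
    for pid, bin_id in assignment.items():
        part = by_part[pid]
        per_bin.setdefault(bin_id, {}).setdefault(part.source_contig, []).append(part)
    out: dict[str, list[tuple[str, str]]] = {}
    for bin_id, by_source in sorted(per_bin.items()):
        joined: list[tuple[str, str]] = []
        for source, group in sorted(by_source.items()):
            group.sort(key=lambda p: p.part_index)
            run: list[SplitContig] = []
            runs: list[list[SplitContig]] = []
            for part in group:
                if run and part.part_index == run[-1].part_index + 1:
                    run.append(part)
                else:
                    if run:
                        runs.append(run)
                    run = [part]
            if run:
                runs.append(run)
            for r in runs:
                whole = r[0].part_index == 0 and len(r) == r[0].n_parts
                name = source if whole else f"{source}.j{r[0].part_index:03d}"
                joined.append((name, "".join(p.sequence for p in r)))
        out[bin_id] = joined
    return out


def detect_scgs(bin_: Bin, annotations: pd.DataFrame, min_ref_coverage: float = 0.5) -> dict[str, int]:
    """Count marker copies in a bin from a gene->marker hit table.

    ``annotations`` columns: contig_id, gene_id, marker_id, ref_coverage
    (fraction of the marker reference covered by the hit; an optional bin_id
    column restricts rows first).  A hit counts only if it covers more than
    half of the reference length (strict inequality).
    """
    required = {"contig_id", "gene_id", "marker_id", "ref_coverage"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    table = annotations
    if "bin_id" in table.columns:
        table = table[table["bin_id"] == bin_.id]
    contig_ids = set(bin_.contig_ids)
    unknown = set(table["contig_id"]) - contig_ids
    if unknown:
        raise ValueError(f"annotation references contigs not in bin {bin_.id!r}: {sorted(unknown)[:5]}")
    hits = table[table["ref_coverage"] > min_ref_coverage]
    counts = hits.groupby("marker_id")["gene_id"].nunique()
    return {str(m): int(c) for m, c in counts.items()}


def _quality(bin_id: str, scg_counts: Mapping[str, int], panel: SCGPanel) -> tuple[int, int, float, float]:
    counts = {m: int(scg_counts.get(m, 0)) for m in panel.marker_ids}
    n_present = sum(1 for c in counts.values() if c >= 1)
    n_multi = sum(1 for c in counts.values() if c > 1)
    completeness = 100.0 * n_present / panel.n_markers
    total = sum(counts.values())
    excess = sum(max(c - 1, 0) for c in counts.values())
    est_error = 100.0 * excess / total if total else 0.0
    return n_present, n_multi, completeness, est_error


def gate_bin(
    scg_counts: Mapping[str, int],
    panel: SCGPanel,
    min_present: int = 30,
    max_multi: int = 2,
    bin_id: str = "bin",
) -> BinQuality:
    """Accept/reject gate: pass iff at least ``min_present`` of the panel's
    markers are present and at most ``max_multi`` are in multiple copies."""
    if min_present > panel.n_markers:
        raise ValueError("min_present exceeds panel size")
    n_present, n_multi, completeness, est_error = _quality(bin_id, scg_counts, panel)
    return BinQuality(
        bin_id=bin_id,
        n_present=n_present,
        n_multi=n_multi,
        completeness=completeness,
        est_error=est_error,
        passed=(n_present >= min_present and n_multi <= max_multi),
    )


def estimate_quality(scg_counts: Mapping[str, int], panel: SCGPanel, bin_id: str = "bin") -> BinQuality:
    """Completeness and error estimate against a (taxon-specific) panel.

    completeness = 100 * (distinct panel markers present) / panel size;
    est_error = 100 * (excess copies) / (total observed copies), i.e. the
    fraction of observed marker copies that are surplus — a base-rate proxy
    for misassembled or wrongly binned sequence.
    """
    if panel.n_markers == 0:
        raise ValueError("empty panel")
    n_present, n_multi, completeness, est_error = _quality(bin_id, scg_counts, panel)
    return BinQuality(bin_id, n_present, n_multi, completeness, est_error, passed=None)


def select_panel(
    presence: pd.DataFrame,
    taxon_scope: str,
    min_presence: float = 0.97,
    max_mean_count: float = 1.03,
) -> SCGPanel:
    """Select markers for a taxon from a genome x marker copy-count table.

    A marker is included iff it is present (count >= 1) in at least
    ``min_presence`` of the taxon's genomes and its mean count over all the
    taxon's genomes (absent = 0) is strictly below ``max_mean_count``.
    """
    if presence.shape[0] == 0:
        raise ValueError(f"no genomes for taxon {taxon_scope!r}")
    frac_present = (presence >= 1).mean(axis=0)
    mean_count = presence.mean(axis=0)
    chosen = [
        str(m)
        for m in presence.columns
        if frac_present[m] >= min_presence - 1e-12 and mean_count[m] < max_mean_count - 1e-12
    ]
    return SCGPanel(panel_id=f"panel_{taxon_scope}", taxon_scope=taxon_scope, marker_ids=tuple(chosen))


def marker_hits_from_truth(bin_: Bin, genomes: Mapping[str, "object"]) -> pd.DataFrame:
    """Synthetic-mode hit table: marker hits derived from embedded-marker truth.

    Each contig inherits the portion of any marker interval it overlaps in its
    source genome; ``ref_coverage`` is that overlap divided by the marker
    length, so fragmentation naturally produces partial hits subject to the
    >50 % rule downstream.
    """
    rows = []
    for contig in bin_.contigs:
        genome = genomes.get(contig.source_genome)
        if genome is None or contig.source_start is None:
            continue
        c_start = contig.source_start
        c_end = c_start + contig.length
        for marker, m_start, m_end, copy_index in genome.marker_map:
            ov = min(c_end, m_end) - max(c_start, m_start)
            if ov > 0:
                rows.append(
                    {
                        "bin_id": bin_.id,
                        "contig_id": contig.id,
                        "gene_id": f"{contig.id}:{marker}:{copy_index}",
                        "marker_id": marker,
                        "ref_coverage": ov / (m_end - m_start),
                    }
                )
    return pd.DataFrame(rows, columns=["bin_id", "contig_id", "gene_id", "marker_id", "ref_coverage"])
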