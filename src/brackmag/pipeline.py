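"""End-to-end orchestration: configuration, I/O binding and stage sequencing.

``run_pipeline`` takes either a synthetic community fixture or user-supplied
tables and runs the downstream stages in order: SCG quality gating, ANI
dereplication into genome clusters, abundance quantification with Z-score
seasonal profiles and co-occurrence clustering, fragment-recruitment identity
profiles, streamlining feature computation, and weighted-LCA taxonomy.  Every
numeric parameter carries the stated default (cut-up 2000/100, OLC 40 bp /
90 %, gate 30-of-36 with <=2 multi-copy, panel 97 % / 1.03, subsample
10,000 x 350 bp, filters >200 bp / e<1e-5, LCA support 30 %, ...) and is
validated before any stage runs.

All internal coordinates are 0-based half-open; GFF input (1-based inclusive)
is converted at this boundary.  Reruns with the same config, inputs and seed
are bit-identical; a manifest with input checksums, the echoed config and
per-stage record counts is written into the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import binqc, dereplicate, genomestats, quantify, recruit, taxonomy
from .core import Bin, Contig
from .synthetic_community import CommunityConfig, CommunityFixture, make_community_fixture, simulate_reads

__all__ = ["RunConfig", "run_pipeline", "read_inputs", "write_fasta", "read_fasta"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters with their stated defaults."""

    # merge stage (ensemble assembly)
    window: int = 2000
    step: int = 100
    small_cutoff: int = 1100
    min_overlap: int = 40
    merge_min_identity: float = 0.90
    # binning-facing contig splitting
    split_threshold: int = 20_000
    split_piece: int = 10_000
    # quality gate
    gate_min_present: int = 30
    gate_max_multi: int = 2
    panel_min_presence: float = 0.97
    panel_max_mean_count: float = 1.03
    # dereplication
    ani_cutoff: float = 0.96
    linkage: str = "average"
    # abundance
    read_len: int = 100
    log_zscores: bool = False
    # recruitment
    subsample_n: int = 10_000
    subsample_len: int = 350
    recruit_min_len: int = 200
    recruit_max_evalue: float = 1e-5
    recruit_divergences: tuple[float, ...] = (0.01, 0.15)
    recruit_reads_per_pool: int = 400
    # streamlining
    min_contig_noncoding: int = 5000
    # taxonomy
    lca_min_support: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if not self.window > self.step > 0:
            raise ValueError("require window > step > 0")
        if self.min_overlap <= 0 or not 0 < self.merge_min_identity <= 1:
            raise ValueError("invalid merge overlap parameters")
        if self.split_threshold < self.split_piece:
            raise ValueError("split threshold below piece size")
        if not 0 <= self.gate_min_present <= binqc.GENERAL_PANEL_SIZE:
            raise ValueError("gate_min_present outside the general panel size")
        if self.gate_max_multi < 0:
            raise ValueError("gate_max_multi must be non-negative")
        if not 0 < self.ani_cutoff < 1:
            raise ValueError("ani_cutoff must be in (0,1)")
        if self.linkage not in ("single", "average", "complete", "full"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.subsample_n <= 0 or self.subsample_len <= 0:
            raise ValueError("invalid subsampling parameters")
        if not 0 <= self.lca_min_support <= 1:
            raise ValueError("lca_min_support must be in [0,1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# standard-format I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA reader with duplicate-id rejection."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Parse gene records from a GFF3 file into the internal 0-based half-open
    convention (GFF is 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in ("gene", "CDS"):
                continue
            gene_id = seqid + f":{start}-{end}"
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
            rows.append(
                {
                    "contig_id": seqid,
                    "gene_id": gene_id,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand if strand in "+-" else "+",
                }
            )
    return pd.DataFrame(rows, columns=["contig_id", "gene_id", "start", "end", "strand"])


def write_gff_genes(path: str | Path, genes: pd.DataFrame) -> None:
    """Write internal 0-based half-open gene intervals as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            fh.write(
                f"{row.contig_id}\tbrackmag\tgene\t{int(row.start) + 1}\t{int(row.end)}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_inputs(paths: Mapping[str, str | Path]) -> dict:
    """Load and validate user-supplied inputs.

    Recognized keys: contigs (FASTA), coverage (TSV contig x sample),
    bins (TSV contig_id,bin_id), genes (GFF3), classifications (TSV
    contig_id,lineage,probability), marker_hits (TSV per binqc schema).
    """
    data: dict = {}
    if "contigs" in paths:
        data["contigs"] = read_fasta(paths["contigs"])
    if "coverage" in paths:
        cov = pd.read_csv(paths["coverage"], sep="\t", index_col=0)
        data["coverage"] = cov
    if "bins" in paths:
        tbl = pd.read_csv(paths["bins"], sep="\t")
        need = {"contig_id", "bin_id"}
        if not need <= set(tbl.columns):
            raise ValueError(f"{paths['bins']}: bin table needs columns {sorted(need)}")
        data["bin_assignment"] = dict(zip(tbl["contig_id"], tbl["bin_id"]))
    if "genes" in paths:
        data["genes"] = read_gff_genes(paths["genes"])
    if "classifications" in paths:
        cls = pd.read_csv(paths["classifications"], sep="\t")
        need = {"contig_id", "lineage", "probability"}
        if not need <= set(cls.columns):
            raise ValueError(f"{paths['classifications']}: needs columns {sorted(need)}")
        data["classifications"] = cls
    if "marker_hits" in paths:
        data["marker_hits"] = pd.read_csv(paths["marker_hits"], sep="\t")
    if "contigs" in data and "coverage" in data and "bin_assignment" in data:
        missing = [c for c in data["bin_assignment"] if c not in data["coverage"].index]
        if missing:
            raise ValueError(f"coverage table missing binned contigs: {missing[:5]}")
    return data


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _fixture_bins(fixture: CommunityFixture) -> list[Bin]:
    return [Bin(genome_id, tuple(contigs)) for genome_id, contigs in sorted(fixture.bins().items())]


def run_pipeline(
    out_dir: str | Path,
    config: RunConfig | None = None,
    fixture: CommunityFixture | None = None,
    fixture_config: CommunityConfig | None = None,
    inputs: Mapping[str, str | Path] | None = None,
) -> dict:
    """Run all stages on a fixture (default) or user inputs; returns the manifest.

    Outputs are written only inside ``out_dir``: bin_quality.tsv,
    clusters.tsv, abundance.tsv, zscores.tsv, cooccurrence.nwk,
    recruitment_profiles.tsv, features.tsv, taxonomy.tsv, manifest.json.
    """
    cfg = config or RunConfig()
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if fixture is None and inputs is None:
        fixture = make_community_fixture(fixture_config, seed=cfg.seed)

    if fixture is not None:
        bins = _fixture_bins(fixture)
        genomes = {g.id: g for g in fixture.genomes}
        hit_tables = [binqc.marker_hits_from_truth(b, genomes) for b in bins]
        marker_hits = pd.concat(hit_tables, ignore_index=True)
        coverage = fixture.coverage
        contig_lengths = {c.id: c.length for c in fixture.contigs}
        total_reads = fixture.total_reads
        genes = fixture.genes
        classifications = fixture.classifications
        contig_seqs = {c.id: c.sequence for c in fixture.contigs}
    else:
        data = read_inputs(inputs)
        contig_seqs = data.get("contigs", {})
        assignment = data.get("bin_assignment", {})
        grouped: dict[str, list[Contig]] = {}
        for contig_id, bin_id in assignment.items():
            if contig_id not in contig_seqs:
                raise ValueError(f"bin table references unknown contig {contig_id!r}")
            grouped.setdefault(str(bin_id), []).append(Contig(contig_id, contig_seqs[contig_id]))
        bins = [Bin(bid, tuple(cs)) for bid, cs in sorted(grouped.items())]
        marker_hits = data.get("marker_hits", pd.DataFrame(
            columns=["bin_id", "contig_id", "gene_id", "marker_id", "ref_coverage"]))
        coverage = data.get("coverage")
        contig_lengths = {cid: len(s) for cid, s in contig_seqs.items()}
        total_reads = {s: float(coverage[s].sum()) for s in coverage.columns} if coverage is not None else {}
        genes = data.get("genes", pd.DataFrame(columns=["contig_id", "gene_id", "start", "end", "strand"]))
        classifications = data.get("classifications", pd.DataFrame(columns=["contig_id", "lineage", "probability"]))

    # --- stage: SCG quality gate -------------------------------------------
    panel = binqc.general_panel()
    qualities = []
    for b in bins:
        scg = binqc.detect_scgs(b, marker_hits)
        qualities.append(binqc.gate_bin(scg, panel, cfg.gate_min_present, cfg.gate_max_multi, bin_id=b.id))
    quality_df = pd.DataFrame([dataclasses.asdict(q) for q in qualities])
    quality_df.to_csv(out / "bin_quality.tsv", sep="\t", index=False)
    approved = [b for b, q in zip(bins, qualities) if q.passed]
    counts["bins_total"] = len(bins)
    counts["bins_approved"] = len(approved)
    if not approved:
        raise RuntimeError("no bins passed the SCG gate; nothing to analyse")

    # --- stage: dereplication ----------------------------------------------
    clusters = dereplicate.cluster_bins(approved, ani_cutoff=cfg.ani_cutoff, linkage=cfg.linkage)
    cluster_rows = [
        {"bin_id": m, "cluster_id": c.cluster_id, "representative": c.representative}
        for c in clusters
        for m in c.member_bins
    ]
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    counts["clusters"] = len(clusters)

    # --- stage: abundance ---------------------------------------------------
    table = quantify.build_abundance_table(coverage, contig_lengths, approved, total_reads, cfg.read_len)
    cluster_of = {m: c.cluster_id for c in clusters for m in c.member_bins}
    cluster_values = table.values.groupby(table.values.index.map(cluster_of)).mean()
    cluster_values.to_csv(out / "abundance.tsv", sep="\t")
    z_input = np.log10(cluster_values + 1e-12) if cfg.log_zscores else cluster_values
    zscores = quantify.zscore_profiles(z_input)
    zscores.to_csv(out / "zscores.tsv", sep="\t")
    if zscores.shape[0] >= 2:
        cooc = quantify.cooccurrence_cluster(zscores)
        (out / "cooccurrence.nwk").write_text(cooc.newick + "\n")
    counts["abundance_rows"] = int(cluster_values.shape[0])

    # --- stage: fragment recruitment ----------------------------------------
    approved_contigs = {cid: s for b in approved for cid, s in b.sequences().items()}
    gene_rows = genes[genes["contig_id"].isin(approved_contigs)].copy()
    profile_rows = []
    if gene_rows.shape[0] > 0:
        contig_to_bin = {cid: b.id for b in approved for cid in b.contig_ids}
        gene_rows["bin_id"] = gene_rows["contig_id"].map(contig_to_bin)
        db = recruit.build_orf_db(approved_contigs, gene_rows)
        members = {c.cluster_id: list(c.member_bins) for c in clusters}
        bin_sizes = {b.id: b.size for b in approved}
        source = max(approved, key=lambda b: b.size)
        ref_genome = None
        if fixture is not None:
            ref_genome = next((g for g in fixture.genomes if g.id == source.id), None)
        for div in cfg.recruit_divergences:
            if ref_genome is None:
                break
            pool = simulate_reads(
                ref_genome,
                cfg.recruit_reads_per_pool,
                read_len=cfg.subsample_len,
                divergence=div,
                seed=cfg.seed + int(div * 1000),
                read_prefix=f"d{int(div * 100):02d}_r",
            )
            sample_id = f"divergence_{div:g}"
            sub = recruit.subsample_reads(pool, n=min(cfg.subsample_n, len(pool)),
                                          length=cfg.subsample_len, seed=cfg.seed)
            hits = recruit.recruit_reads(sub, db, cfg.recruit_min_len, cfg.recruit_max_evalue)
            for prof in recruit.cluster_recruitment(hits, members, bin_sizes, len(sub), sample_id=sample_id):
                for cut, val in zip(prof.cutoffs, prof.normalized_counts):
                    profile_rows.append(
                        {"cluster_id": prof.cluster_id, "sample_id": sample_id, "cutoff": cut, "value": val}
                    )
    pd.DataFrame(profile_rows, columns=["cluster_id", "sample_id", "cutoff", "value"]).to_csv(
        out / "recruitment_profiles.tsv", sep="\t", index=False
    )
    counts["recruitment_rows"] = len(profile_rows)

    # --- stage: streamlining features ---------------------------------------
    feats = []
    for b in approved:
        gene_sub = genes[genes["contig_id"].isin(b.contig_ids)]
        cogs = (
            genomestats.cog_category_proportions(gene_sub)
            if "cog_category" in gene_sub.columns and gene_sub.shape[0] > 0
            else {}
        )
        feats.append(
            genomestats.GenomeFeatures(
                bin_id=b.id,
                size=b.size,
                gc=genomestats.gc_content(b),
                noncoding=genomestats.noncoding_fraction(b, gene_sub, cfg.min_contig_noncoding),
                cog_category_pct=cogs,
            )
        )
    feat_rows = [
        {"bin_id": f.bin_id, "size": f.size, "gc": f.gc,
         "noncoding": f.noncoding if f.noncoding is not None else float("nan"),
         "coding": 100.0 - f.noncoding if f.noncoding is not None else float("nan")}
        for f in feats
    ]
    pd.DataFrame(feat_rows).to_csv(out / "features.tsv", sep="\t", index=False)
    counts["feature_rows"] = len(feat_rows)

    # --- stage: taxonomy -----------------------------------------------------
    tax_rows = []
    if classifications.shape[0] > 0:
        cls_by_contig = classifications.set_index("contig_id", drop=False)
        for b in approved:
            sub = classifications[classifications["contig_id"].isin(b.contig_ids)]
            if sub.shape[0] == 0:
                continue
            assignment = taxonomy.weighted_lca(
                [(r.contig_id, r.lineage, float(r.probability)) for r in sub.itertuples(index=False)],
                {c.id: c.length for c in b.contigs},
                min_support=cfg.lca_min_support,
                bin_id=b.id,
            )
            tax_rows.append({"bin_id": b.id, "lineage": assignment.lineage})
    pd.DataFrame(tax_rows, columns=["bin_id", "lineage"]).to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    counts["taxonomy_rows"] = len(tax_rows)

    # --- manifest ------------------------------------------------------------
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "mode": "fixture" if fixture is not None else "inputs",
        "record_counts": counts,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
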