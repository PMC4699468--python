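"""SCG detection, the quality gate, panel selection and completeness estimates."""

import numpy as np
import pandas as pd
import pytest

from brackmag.binqc import (
    SCGPanel,
    detect_scgs,
    estimate_quality,
    gate_bin,
    general_panel,
    marker_hits_from_truth,
    rejoin_contigs,
    select_panel,
    split_contigs,
)
from brackmag.core import Bin, Contig
from brackmag.synthetic_community import embed_markers, fragment_genome, make_genome
from conftest import random_seq


class TestSplitContigs:
    def test_remainder_merges_into_last(self, rng):
        seq = random_seq(rng, 25_000)
        parts = split_contigs([("c1", seq)])
        assert [len(p.sequence) for p in parts] == [10_000, 15_000]
        assert "".join(p.sequence for p in parts) == seq

    def test_below_threshold_unchanged(self, rng):
        seq = random_seq(rng, 19_999)
        (p,) = split_contigs([("c1", seq)])
        assert p.sequence == seq and p.n_parts == 1

    def test_exact_multiples(self, rng):
        seq = random_seq(rng, 30_000)
        parts = split_contigs([("c1", seq)])
        assert [len(p.sequence) for p in parts] == [10_000, 10_000, 10_000]

    def test_roundtrip_identity(self, rng):
        contigs = [("a", random_seq(rng, 47_000)), ("b", random_seq(rng, 9_000)), ("c", random_seq(rng, 20_000))]
        parts = split_contigs(contigs)
        assignment = {p.id: "bin1" for p in parts}
        rejoined = rejoin_contigs(assignment, parts)
        assert sorted(rejoined["bin1"]) == sorted(contigs)

    def test_partial_rejoin_of_torn_contig(self, rng):
        seq = random_seq(rng, 40_000)
        parts = split_contigs([("c1", seq)])  # 4 pieces
        # middle two pieces go to another bin
        assignment = {parts[0].id: "x", parts[1].id: "y", parts[2].id: "y", parts[3].id: "x"}
        rejoined = rejoin_contigs(assignment, parts)
        y_seqs = [s for _, s in rejoined["y"]]
        assert y_seqs == [seq[10_000:30_000]]
        assert sorted(s for _, s in rejoined["x"]) == sorted([seq[:10_000], seq[30_000:]])

    def test_invalid_piece(self):
        with pytest.raises(ValueError):
            split_contigs([("c", "ACGT")], threshold=5_000, piece=10_000)


def _hit_table(rows):
    return pd.DataFrame(rows, columns=["contig_id", "gene_id", "marker_id", "ref_coverage"])


class TestDetectSCGs:
    def setup_method(self):
        self.bin = Bin("b1", (Contig("c1", "ACGT" * 100), Contig("c2", "ACGT" * 100)))

    def test_coverage_boundary(self):
        tbl = _hit_table(
            [("c1", "g1", "m1", 0.51), ("c1", "g2", "m2", 0.50), ("c2", "g3", "m3", 0.499)]
        )
        counts = detect_scgs(self.bin, tbl)
        assert counts == {"m1": 1}

    def test_two_qualifying_genes_count_two(self):
        tbl = _hit_table([("c1", "g1", "m1", 0.9), ("c2", "g2", "m1", 0.8)])
        assert detect_scgs(self.bin, tbl) == {"m1": 2}

    def test_unknown_contig_error(self):
        tbl = _hit_table([("nope", "g1", "m1", 0.9)])
        with pytest.raises(ValueError, match="nope"):
            detect_scgs(self.bin, tbl)


class TestGateBin:
    panel = general_panel()

    def _counts(self, n_present, n_multi):
        counts = {}
        for i in range(n_present):
            counts[self.panel.marker_ids[i]] = 2 if i < n_multi else 1
        return counts

    @pytest.mark.parametrize(
        "present,multi,expected",
        [(31, 2, True), (29, 0, False), (36, 3, False), (30, 2, True), (36, 0, True), (0, 0, False)],
    )
    def test_examples(self, present, multi, expected):
        q = gate_bin(self._counts(present, multi), self.panel)
        assert q.passed is expected
        assert q.n_present == present and q.n_multi == multi
        assert q.completeness == pytest.approx(100.0 * present / 36)

    def test_exhaustive_accept_region(self):
        for present in range(0, 37):
            for multi in range(0, min(present, 5) + 1):
                q = gate_bin(self._counts(present, multi), self.panel)
                assert q.passed is (present >= 30 and multi <= 2)

    def test_gate_monotonicity(self, rng):
        """Adding a single-copy panel marker never flips pass -> fail."""
        for _ in range(50):
            present = int(rng.integers(0, 36))
            multi = int(rng.integers(0, min(present, 5) + 1))
            counts = self._counts(present, multi)
            before = gate_bin(counts, self.panel).passed
            counts[self.panel.marker_ids[present]] = 1
            after = gate_bin(counts, self.panel).passed
            assert not (before and not after)

    def test_min_present_exceeds_panel(self):
        with pytest.raises(ValueError):
            gate_bin({}, self.panel, min_present=40)


class TestSelectPanel:
    def _presence(self, frac_present, mean_count, n=100):
        """One marker column engineered to hit the given presence/mean."""
        n_present = round(frac_present * n)
        col = np.zeros(n)
        col[:n_present] = 1.0
        col[0] += mean_count * n - n_present  # adjust a single genome's count
        return pd.DataFrame({"m": col})

    def test_included(self):
        panel = select_panel(self._presence(0.98, 1.00), "general")
        assert panel.marker_ids == ("m",)

    def test_presence_below_floor_excluded(self):
        assert select_panel(self._presence(0.96, 1.00), "general").marker_ids == ()

    def test_mean_count_boundary_strict(self):
        assert select_panel(self._presence(1.0, 1.03), "general").marker_ids == ()
        assert select_panel(self._presence(1.0, 1.02), "general").marker_ids == ("m",)

    def test_panel_monotonicity(self, rng):
        counts = pd.DataFrame(rng.poisson(1.0, size=(50, 20)), columns=[f"m{i}" for i in range(20)])
        base = set(select_panel(counts, "t").marker_ids)
        stricter_presence = set(select_panel(counts, "t", min_presence=0.99).marker_ids)
        stricter_count = set(select_panel(counts, "t", max_mean_count=1.01).marker_ids)
        assert stricter_presence <= base and stricter_count <= base

    def test_empty_taxon(self):
        with pytest.raises(ValueError):
            select_panel(pd.DataFrame(columns=["m"]), "t")


class TestEstimateQuality:
    panel = SCGPanel("p119", "phylum", tuple(f"pm{i:03d}" for i in range(119)))

    def test_completeness_simple(self):
        counts = {f"pm{i:03d}": 1 for i in range(100)}
        q = estimate_quality(counts, self.panel)
        assert q.completeness == pytest.approx(100 * 100 / 119)
        assert q.est_error == 0.0

    def test_one_duplicate(self):
        counts = {f"pm{i:03d}": 1 for i in range(119)}
        counts["pm000"] = 2
        q = estimate_quality(counts, self.panel)
        assert q.completeness == 100.0
        assert q.est_error == pytest.approx(100.0 / 120, abs=1e-9)

    def test_empty_counts(self):
        q = estimate_quality({}, self.panel)
        assert q.completeness == 0.0 and q.est_error == 0.0

    def test_parameter_recovery(self, rng):
        """Known completeness is recovered exactly; injected duplication is
        recovered within one percentage point."""
        for completeness in (0.5, 0.827, 1.0):
            n_present = round(completeness * 119)
            counts = {f"pm{i:03d}": 1 for i in range(n_present)}
            q = estimate_quality(counts, self.panel)
            assert q.completeness == pytest.approx(100.0 * n_present / 119)
        # 5 % of copies are surplus duplicates
        n_dup = 5
        counts = {f"pm{i:03d}": 1 for i in range(100)}
        for i in range(n_dup):
            counts[f"pm{i:03d}"] = 2
        q = estimate_quality(counts, self.panel)
        assert abs(q.est_error - 5.0) <= 1.0


class TestTruthDrivenHits:
    def test_fragmented_marker_respects_half_rule(self):
        genome = make_genome(60_000, 0.5, seed=21)
        genome = embed_markers(genome, [f"scg_{i:02d}" for i in range(36)], marker_length=300, seed=21)
        contigs = fragment_genome(genome, 6, min_len=2000, seed=21)
        b = Bin(genome.id, tuple(contigs))
        hits = marker_hits_from_truth(b, {genome.id: genome})
        counts = detect_scgs(b, hits)
        # fragmentation only loses markers, never invents them
        assert set(counts) <= {m for m, *_ in genome.marker_map}
        assert all(c >= 1 for c in counts.values())
        gate = gate_bin(counts, general_panel())
        assert gate.n_present <= 36
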