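"""Synthetic-community generator: determinism, calibration and truth recovery."""

import numpy as np
import pytest

from brackmag.core import encode
from brackmag.synthetic_community import (
    CommunityConfig,
    PeakModel,
    embed_markers,
    fragment_genome,
    make_community_fixture,
    make_genome,
    simulate_coverage,
    simulate_reads,
)


class TestMakeGenome:
    def test_length_and_gc_band(self):
        g = make_genome(10_000, 0.5, seed=1)
        assert g.length == 10_000
        codes = encode(g.sequence)
        gc = ((codes == 1) | (codes == 2)).mean()
        assert 0.45 <= gc <= 0.55
        assert set(g.sequence) <= set("ACGT")

    def test_extreme_gc(self):
        g = make_genome(1000, 0.999, seed=1)
        assert sum(b in "GC" for b in g.sequence) >= 990

    def test_seeded_determinism(self):
        assert make_genome(5000, 0.4, seed=3).sequence == make_genome(5000, 0.4, seed=3).sequence
        assert make_genome(5000, 0.4, seed=3).sequence != make_genome(5000, 0.4, seed=4).sequence

    def test_gc_calibration_large(self):
        # +-0.02 of target for genomes of at least 100 kb
        g = make_genome(100_000, 0.37, seed=9)
        codes = encode(g.sequence)
        assert abs(((codes == 1) | (codes == 2)).mean() - 0.37) < 0.02

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (999, 0.5), (1000, 0.0), (1000, 1.0)])
    def test_invalid_parameters(self, length, gc):
        with pytest.raises(ValueError):
            make_genome(length, gc, seed=1)


class TestEmbedMarkers:
    def test_panel_placement_and_recovery(self):
        g = make_genome(100_000, 0.5, seed=2)
        markers = [f"scg_{i:02d}" for i in range(36)]
        g2 = embed_markers(g, markers, marker_length=500, seed=2)
        assert len(g2.marker_map) == 36
        # exact substring search finds each token exactly once
        for marker, start, end, _ in g2.marker_map:
            token = g2.sequence[start:end]
            assert g2.sequence.count(token) == 1
        # intervals non-overlapping
        ivals = sorted((s, e) for _, s, e, _ in g2.marker_map)
        assert all(ivals[i][1] <= ivals[i + 1][0] for i in range(len(ivals) - 1))

    def test_multi_copy(self):
        g = make_genome(50_000, 0.5, seed=3)
        g2 = embed_markers(g, ["scg_7"], copies={"scg_7": 2}, marker_length=400, seed=3)
        entries = [m for m in g2.marker_map if m[0] == "scg_7"]
        assert len(entries) == 2
        token0 = g2.sequence[entries[0][1] : entries[0][2]]
        token1 = g2.sequence[entries[1][1] : entries[1][2]]
        # copies are independent tokens, each recoverable exactly once
        assert g2.sequence.count(token0) == 1 and g2.sequence.count(token1) == 1

    def test_errors(self):
        g = make_genome(2000, 0.5, seed=1)
        with pytest.raises(ValueError, match="duplicate"):
            embed_markers(g, ["m1", "m1"], marker_length=100, seed=1)
        with pytest.raises(ValueError, match="fit"):
            embed_markers(g, [f"m{i}" for i in range(20)], marker_length=100, seed=1)


class TestFragmentGenome:
    def test_contract(self):
        g = make_genome(100_000, 0.5, seed=4)
        contigs = fragment_genome(g, 50, min_len=1000, seed=4)
        assert len(contigs) == 50
        assert sum(c.length for c in contigs) >= 90_000
        assert all(c.length >= 1000 for c in contigs)

    def test_single_contig(self):
        g = make_genome(10_000, 0.5, seed=5)
        (c,) = fragment_genome(g, 1, min_len=1000, seed=5)
        assert c.length >= 9000

    def test_provenance_coordinates(self):
        g = make_genome(30_000, 0.5, seed=6)
        for c in fragment_genome(g, 10, min_len=1000, seed=6):
            assert g.sequence[c.source_start : c.source_start + c.length] == c.sequence

    def test_infeasible(self):
        g = make_genome(5000, 0.5, seed=1)
        with pytest.raises(ValueError):
            fragment_genome(g, 10, min_len=1000, seed=1)


class TestSimulateCoverage:
    def _contigs(self, seed=1):
        g = make_genome(10_000, 0.5, seed=seed)
        return g, fragment_genome(g, 4, min_len=1000, seed=seed)

    def test_noise_free_peak(self):
        g, contigs = self._contigs()
        cov = simulate_coverage(contigs, {g.id: PeakModel(5, 2.0, 10.0)}, n_samples=10, noise_sd=0.0)
        assert np.allclose(cov["s05"], 10.0)
        assert (cov.mean(axis=0).idxmax()) == "s05"

    def test_zero_height(self):
        g, contigs = self._contigs()
        cov = simulate_coverage(contigs, {g.id: PeakModel(3, 2.0, 0.0)}, n_samples=8, noise_sd=0.0)
        assert (cov.to_numpy() == 0).all()

    def test_nonnegative_under_noise(self):
        g, contigs = self._contigs()
        cov = simulate_coverage(contigs, {g.id: PeakModel(3, 2.0, 1.0)}, n_samples=8, noise_sd=5.0, seed=1)
        assert (cov.to_numpy() >= 0).all()

    def test_errors(self):
        g, contigs = self._contigs()
        with pytest.raises(ValueError):
            simulate_coverage(contigs, {g.id: PeakModel(0, 1.0, 1.0)}, n_samples=1)
        with pytest.raises(ValueError):
            simulate_coverage(contigs, {g.id: PeakModel(0, 1.0, 1.0)}, n_samples=5, noise_sd=-1)


class TestSimulateReads:
    def test_exact_substrings_at_zero_divergence(self):
        g = make_genome(5000, 0.5, seed=7)
        for r in simulate_reads(g, 20, read_len=100, divergence=0.0, seed=7):
            assert r.sequence in g.sequence
            assert g.sequence[r.source_start : r.source_start + 100] == r.sequence

    def test_divergence_calibration(self):
        g = make_genome(20_000, 0.5, seed=8)
        reads = simulate_reads(g, 1000, read_len=350, divergence=0.15, seed=8)
        mean_identity = 1.0 - np.mean([r.n_substitutions for r in reads]) / 350
        # generous band around the binomial 3-sigma over n*L Bernoulli trials
        assert abs(mean_identity - 0.85) <= 0.011
        # verify n_substitutions against the actual sequences
        r = reads[0]
        src = g.sequence[r.source_start : r.source_start + 350]
        assert sum(a != b for a, b in zip(src, r.sequence)) == r.n_substitutions

    def test_seeded_determinism(self):
        g = make_genome(5000, 0.5, seed=9)
        a = simulate_reads(g, 50, 100, 0.1, seed=3)
        b = simulate_reads(g, 50, 100, 0.1, seed=3)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_errors(self):
        g = make_genome(1000, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(g, 10, read_len=2000, divergence=0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(g, 10, read_len=100, divergence=0.6, seed=1)


class TestCommunityFixture:
    def test_contract(self, small_fixture, small_config):
        fx = small_fixture
        assert len(fx.genomes) >= 5
        assert fx.coverage.shape[1] == 37
        # every contig maps to exactly one genome
        assert set(fx.true_bins) == {c.id for c in fx.contigs}
        assert set(fx.true_bins.values()) <= {g.id for g in fx.genomes}
        # coverage has one row per contig
        assert set(fx.coverage.index) == {c.id for c in fx.contigs}

    def test_config_roundtrip_determinism(self, small_config, small_fixture):
        cfg2 = CommunityConfig.from_dict(small_config.to_dict())
        fx2 = make_community_fixture(cfg2, seed=7)
        assert [g.sequence for g in fx2.genomes] == [g.sequence for g in small_fixture.genomes]
        assert fx2.coverage.equals(small_fixture.coverage)
        assert [r.sequence for r in fx2.reads_by_sample["s00"]] == [
            r.sequence for r in small_fixture.reads_by_sample["s00"]
        ]
        assert fx2.genes.equals(small_fixture.genes)

    def test_default_world_is_stated(self):
        cfg = CommunityConfig()
        assert cfg.n_samples == 37
        assert cfg.n_markers == 36
        assert cfg.genome_length_range == (1_000_000, 3_000_000)
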