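"""Abundance statistic, Z-score profiles, co-occurrence and fraction ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from brackmag.core import Bin, Contig
from brackmag.quantify import (
    abundance_fraction,
    build_abundance_table,
    cooccurrence_cluster,
    fraction_ratio_analysis,
    reads_per_bin,
    spearman,
    zscore_profiles,
)


def _bin(bin_id, lengths):
    return Bin(bin_id, tuple(Contig(f"{bin_id}_c{i}", "A" * n) for i, n in enumerate(lengths)))


class TestReadsPerBin:
    def test_single_contig(self):
        b = _bin("b", [1000])
        cov = pd.DataFrame({"s1": [10.0]}, index=["b_c0"])
        assert reads_per_bin(cov, {"b_c0": 1000}, b, "s1", read_len=100) == 100.0

    def test_zero_coverage(self):
        b = _bin("b", [1000])
        cov = pd.DataFrame({"s1": [0.0]}, index=["b_c0"])
        assert reads_per_bin(cov, {"b_c0": 1000}, b, "s1") == 0.0

    def test_two_contigs(self):
        b = _bin("b", [2000, 1000])
        cov = pd.DataFrame({"s1": [5.0, 20.0]}, index=["b_c0", "b_c1"])
        assert reads_per_bin(cov, {"b_c0": 2000, "b_c1": 1000}, b, "s1", 100) == 300.0

    def test_missing_row(self):
        b = _bin("b", [1000, 500])
        cov = pd.DataFrame({"s1": [1.0]}, index=["b_c0"])
        with pytest.raises(KeyError):
            reads_per_bin(cov, {"b_c0": 1000, "b_c1": 500}, b, "s1")


class TestAbundanceFraction:
    def test_arithmetic(self):
        assert abundance_fraction(100, 10_000, 1000) == pytest.approx(1e-5)

    def test_depth_invariance(self):
        assert abundance_fraction(200, 20_000, 1000) == abundance_fraction(100, 10_000, 1000)

    def test_size_scaling(self):
        assert abundance_fraction(100, 10_000, 2000) == abundance_fraction(100, 10_000, 1000) / 2

    def test_zero_denominators(self):
        with pytest.raises(ValueError):
            abundance_fraction(1, 0, 100)
        with pytest.raises(ValueError):
            abundance_fraction(1, 100, 0)


class TestAbundanceTable:
    def _setup(self):
        bins = [_bin("b1", [1000, 2000]), _bin("b2", [4000])]
        cov = pd.DataFrame(
            {"s1": [10.0, 5.0, 2.0], "s2": [0.0, 1.0, 8.0]},
            index=["b1_c0", "b1_c1", "b2_c0"],
        )
        lengths = {"b1_c0": 1000, "b1_c1": 2000, "b2_c0": 4000}
        total = {"s1": 1000.0, "s2": 2000.0}
        return bins, cov, lengths, total

    def test_partition_bound(self):
        bins, cov, lengths, total = self._setup()
        table = build_abundance_table(cov, lengths, bins, total)
        for s in ("s1", "s2"):
            mass = sum(table.values.loc[b.id, s] * table.bin_sizes[b.id] for b in bins)
            assert mass <= 1.0 + 1e-12

    def test_depth_invariance_per_sample(self):
        bins, cov, lengths, total = self._setup()
        base = build_abundance_table(cov, lengths, bins, total)
        cov2 = cov.copy()
        cov2["s1"] *= 3.0
        total2 = dict(total, s1=total["s1"] * 3.0)
        scaled = build_abundance_table(cov2, lengths, bins, total2)
        assert np.allclose(base.values["s1"], scaled.values["s1"])


class TestZscores:
    def test_standardization(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
        z = zscore_profiles(df)
        assert z.loc["r"].mean() == pytest.approx(0.0)
        assert z.loc["r"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_row(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0]], index=["r"], columns=list("abc"))
        assert (zscore_profiles(df).loc["r"] == 0).all()

    def test_argmax_preserved(self, rng):
        df = pd.DataFrame(rng.random((4, 10)), index=list("wxyz"))
        z = zscore_profiles(df)
        for r in df.index:
            assert z.loc[r].idxmax() == df.loc[r].idxmax()

    def test_idempotent_on_standardized(self, rng):
        df = pd.DataFrame(rng.random((3, 8)))
        z = zscore_profiles(df)
        assert np.allclose(zscore_profiles(z).values, z.values)

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            zscore_profiles(pd.DataFrame([[1.0]]))


class TestCooccurrence:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]], index=list("abc"), dtype=float)
        res = cooccurrence_cluster(df)
        assert res.distance.loc["a", "b"] == pytest.approx(0.0)

    def test_negated_row_distance_two(self):
        df = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=list("ab"), dtype=float)
        res = cooccurrence_cluster(df)
        assert res.distance.loc["a", "b"] == pytest.approx(2.0)

    def test_bloom_groups_split_top_level(self, rng):
        """Spring-bloom vs autumn-bloom genome groups form the two top branches."""
        x = np.arange(20, dtype=float)
        spring = [np.exp(-0.5 * ((x - 4) / 2) ** 2) + rng.normal(0, 0.01, 20) for _ in range(3)]
        autumn = [np.exp(-0.5 * ((x - 15) / 2) ** 2) + rng.normal(0, 0.01, 20) for _ in range(3)]
        df = pd.DataFrame(
            spring + autumn, index=[f"sp{i}" for i in range(3)] + [f"au{i}" for i in range(3)]
        )
        res = cooccurrence_cluster(df)
        labels = hierarchy.fcluster(res.linkage, t=2, criterion="maxclust")
        groups = {}
        for name, lab in zip(sorted(df.index), labels):
            groups.setdefault(lab, set()).add(name)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"sp0", "sp1", "sp2"}),
            frozenset({"au0", "au1", "au2"}),
        }

    def test_zero_variance_row_warns(self):
        df = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=list("ab"), dtype=float)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cooccurrence_cluster(df)
        assert res.distance.loc["a", "b"] == 2.0

    def test_newick_has_all_leaves(self, rng):
        df = pd.DataFrame(rng.random((4, 6)), index=list("wxyz"))
        res = cooccurrence_cluster(df)
        assert all(leaf in res.newick for leaf in "wxyz")


class TestFractionRatio:
    def _counts(self, ratios, smalls=None):
        smalls = smalls or [100.0] * len(ratios)
        return pd.DataFrame(
            {
                "counts_small": smalls,
                "counts_mid": [r * s for r, s in zip(ratios, smalls)],
            },
            index=[f"cl{i}" for i in range(len(ratios))],
        )

    def test_monotone_ratio_gives_rho_one(self):
        sizes = {f"cl{i}": 1e6 * (i + 1) for i in range(6)}
        counts = self._counts([0.5 + 0.2 * i for i in range(6)])
        _, rho, p = fraction_ratio_analysis(counts, sizes)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_permuted_sizes_rho_small(self, rng):
        n = 30
        sizes = {f"cl{i}": float(rng.uniform(1e6, 3e6)) for i in range(n)}
        counts = self._counts(list(rng.uniform(0.5, 2.0, n)))
        _, rho, p = fraction_ratio_analysis(counts, sizes)
        assert abs(rho) < 0.4

    def test_sqrt_law_recovered(self, rng):
        n = 12
        size_vals = np.linspace(1e6, 3e6, n)
        ratios = (size_vals / 1e6) ** 0.5 + rng.normal(0, 0.02, n)
        sizes = {f"cl{i}": float(s) for i, s in enumerate(size_vals)}
        _, rho, _ = fraction_ratio_analysis(self._counts(list(ratios)), sizes)
        assert abs(rho - 1.0) <= 0.1

    def test_undefined_ratios_dropped(self):
        counts = self._counts([1.0, 2.0, 3.0, 4.0], smalls=[100.0, 0.0, 100.0, 100.0])
        sizes = {f"cl{i}": 1e6 * (i + 1) for i in range(4)}
        table, rho, _ = fraction_ratio_analysis(counts, sizes)
        assert np.isnan(table.loc["cl1", "ratio_mid_small"])

    def test_too_few_defined(self):
        counts = self._counts([1.0, 2.0], smalls=[100.0, 100.0])
        with pytest.raises(ValueError):
            fraction_ratio_analysis(counts, {"cl0": 1e6, "cl1": 2e6})


class TestSpearman:
    def test_exact_small_n_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rho, p = spearman(x, y)
        # rho = 1 - sum(d^2)/20 = 0.8 here; |rho| >= 0.8 means sum(d^2) <= 4
        # (1 + 4 + 3 = 8 permutations) or >= 36 (8 by symmetry): p = 16/120
        assert rho == pytest.approx(0.8)
        assert p == pytest.approx(16 / 120)

    def test_large_n_uses_t_approx(self, rng):
        x = rng.random(30)
        y = x + rng.normal(0, 0.2, 30)
        rho, p = spearman(x, y)
        assert rho > 0.6 and p < 1e-3
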