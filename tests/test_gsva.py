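"""Enrichment engine: kernel-CDF gene statistics and the KS-like walk,
checked against hand computations and an independently coded brute-force
walk."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from lupusmod.gsva import gene_level_cdf_stats, module_enrichment_scores
from lupusmod.modules import GeneModule, ModuleCollection

from conftest import toy_modules


def brute_walk_score(z_col: pd.Series, module_genes, tau=1.0, mode="diff"):
    """Independent O(N) reference walk: explicit loop, no vectorization."""
    n = len(z_col)
    # descending z, ties by gene id
    ranked = sorted(z_col.index, key=lambda g: (-z_col[g], g))
    in_set = [g in set(module_genes) for g in ranked]
    m = sum(in_set)
    rsym = [abs(n / 2 - (i + 1)) ** tau for i in range(n)]
    denom = sum(r for r, inside in zip(rsym, in_set) if inside)
    walk, num, miss = [], 0.0, 0
    for i in range(n):
        if in_set[i]:
            num += rsym[i]
        else:
            miss += 1
        walk.append(num / denom - miss / (n - m))
    if mode == "diff":
        return max(max(walk), 0.0) + min(min(walk), 0.0)
    return walk[int(np.argmax(np.abs(walk)))]


class TestGeneStats:
    def test_symmetric_values_give_half_n(self):
        # gene symmetric about 5: mirrored pairs sum to 1, self term is 0.5
        expr = pd.DataFrame([[3.0, 4.0, 5.0, 6.0, 7.0]], index=["g"],
                            columns=list("abcde"))
        z = gene_level_cdf_stats(expr)
        assert z.loc["g", "c"] == pytest.approx(5 / 2)

    def test_monotone_in_expression(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (20, 15)),
                            index=[f"g{i}" for i in range(20)])
        z = gene_level_cdf_stats(expr)
        for g in expr.index:
            order_x = np.argsort(expr.loc[g].to_numpy())
            assert (np.diff(z.loc[g].to_numpy()[order_x]) >= 0).all()

    def test_three_sample_hand_oracle(self):
        vals = np.array([1.0, 2.0, 3.0])
        expr = pd.DataFrame([vals], index=["g"], columns=list("abc"))
        h = vals.std(ddof=1) / 4
        expected = [sum(ndtr((v - vals) / h)) for v in vals]
        z = gene_level_cdf_stats(expr)
        np.testing.assert_allclose(z.loc["g"].to_numpy(), expected, rtol=1e-12)

    def test_zero_variance_gene_warns_and_keeps_universe(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                            index=["flat", "ok"], columns=list("abc"))
        with pytest.warns(UserWarning, match="flat"):
            z = gene_level_cdf_stats(expr)
        assert z.shape == expr.shape
        assert np.isfinite(z.to_numpy()).all()

    def test_requires_two_samples(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            gene_level_cdf_stats(pd.DataFrame([[1.0]], index=["g"]))


class TestWalk:
    def _stats(self, rng, n_genes=40, n_samples=6):
        expr = pd.DataFrame(
            rng.normal(8, 1, (n_genes, n_samples)),
            index=[f"g{i:02d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        return gene_level_cdf_stats(expr)

    def test_matches_brute_force_oracle(self, rng):
        z = self._stats(rng)
        mods = toy_modules([f"g{i:02d}" for i in range(0, 12, 2)],
                           [f"g{i:02d}" for i in range(25, 40, 3)])
        scores = module_enrichment_scores(z, mods)
        for mod in mods:
            for s in z.columns:
                assert scores.loc[mod.name, s] == pytest.approx(
                    brute_walk_score(z[s], mod.genes), abs=1e-12)

    def test_extreme_mode_matches_brute_force(self, rng):
        z = self._stats(rng)
        mods = toy_modules([f"g{i:02d}" for i in range(5, 20)])
        scores = module_enrichment_scores(z, mods, mode="extreme")
        for s in z.columns:
            assert scores.loc["M0", s] == pytest.approx(
                brute_walk_score(z[s], mods["M0"].genes, mode="extreme"),
                abs=1e-12)

    def test_top_ranked_module_scores_positive(self):
        # module genes occupy the top m ranks in one engineered sample
        genes = [f"g{i:02d}" for i in range(30)]
        z = pd.DataFrame({"s": np.arange(30, 0, -1, dtype=float)}, index=genes)
        module = genes[:8]
        score = module_enrichment_scores(z, toy_modules(module)).loc["M0", "s"]
        assert score > 0
        assert score == pytest.approx(brute_walk_score(z["s"], module), abs=1e-12)

    def test_rank_reversal_antisymmetry(self):
        genes = [f"g{i:02d}" for i in range(30)]
        top = pd.DataFrame({"s": np.arange(30, 0, -1, dtype=float)}, index=genes)
        bottom = pd.DataFrame({"s": np.arange(1, 31, dtype=float)}, index=genes)
        module = genes[:8]
        s_top = module_enrichment_scores(top, toy_modules(module)).loc["M0", "s"]
        s_bot = module_enrichment_scores(bottom, toy_modules(module)).loc["M0", "s"]
        assert s_bot == pytest.approx(-s_top, abs=1e-12)

    def test_random_modules_center_near_zero_and_stay_bounded(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (2000, 30)),
                            index=[f"g{i:04d}" for i in range(2000)])
        z = gene_level_cdf_stats(expr)
        picks = [list(rng.choice(expr.index, 30, replace=False))
                 for _ in range(5)]
        scores = module_enrichment_scores(z, toy_modules(*picks))
        assert (scores.to_numpy() >= -1).all() and (scores.to_numpy() <= 1).all()
        assert abs(scores.to_numpy().mean()) < 0.1

    def test_shift_of_one_gene_leaves_scores_unchanged(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (50, 8)),
                            index=[f"g{i:02d}" for i in range(50)])
        mods = toy_modules([f"g{i:02d}" for i in range(10, 22)])
        base = module_enrichment_scores(gene_level_cdf_stats(expr), mods)
        shifted = expr.copy()
        shifted.loc["g05"] += 100.0  # constant shift: gene-level z is shift-free
        after = module_enrichment_scores(gene_level_cdf_stats(shifted), mods)
        pd.testing.assert_frame_equal(base, after)

    def test_permutation_invariance_of_gene_order(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (40, 6)),
                            index=[f"g{i:02d}" for i in range(40)])
        mods = toy_modules([f"g{i:02d}" for i in range(7, 19)])
        a = module_enrichment_scores(gene_level_cdf_stats(expr), mods)
        perm = expr.sample(frac=1, random_state=1)
        b = module_enrichment_scores(gene_level_cdf_stats(perm), mods)
        pd.testing.assert_frame_equal(a, b)

    def test_raising_module_genes_does_not_lower_score(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (60, 10)),
                            index=[f"g{i:02d}" for i in range(60)])
        module = [f"g{i:02d}" for i in range(20, 35)]
        mods = toy_modules(module)
        before = module_enrichment_scores(gene_level_cdf_stats(expr), mods)
        boosted = expr.copy()
        boosted.loc[module, boosted.columns[0]] += 2.0
        after = module_enrichment_scores(gene_level_cdf_stats(boosted), mods)
        assert after.iloc[0, 0] >= before.iloc[0, 0] - 1e-12

    def test_module_spanning_universe_rejected(self, rng):
        z = self._stats(rng, n_genes=10)
        with pytest.raises(ValueError, match="entire gene universe"):
            module_enrichment_scores(z, toy_modules(list(z.index)))

    def test_unmeasured_module_omitted_with_warning(self, rng):
        z = self._stats(rng, n_genes=10)
        mods = toy_modules(["absent1", "absent2"], list(z.index[:3]))
        with pytest.warns(UserWarning, match="no measured genes"):
            scores = module_enrichment_scores(z, mods)
        assert list(scores.index) == ["M1"]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(10, 50), st.integers(3, 8))
    def test_bounds_and_oracle_on_fuzzed_matrices(self, seed, n_genes, n_samp):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(0, rng.uniform(0.1, 3), (n_genes, n_samp)),
            index=[f"g{i:02d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samp)],
        )
        z = gene_level_cdf_stats(expr)
        m = int(rng.integers(1, n_genes))
        module = list(rng.choice(expr.index, m, replace=False))
        scores = module_enrichment_scores(z, toy_modules(module))
        vals = scores.to_numpy()
        assert (vals >= -1 - 1e-12).all() and (vals <= 1 + 1e-12).all()
        s0 = z.columns[0]
        assert scores.loc["M0", s0] == pytest.approx(
            brute_walk_score(z[s0], module), abs=1e-10)
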