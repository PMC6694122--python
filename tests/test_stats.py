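"""Genotype-expression integration statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scsomatic.stats import (
    bh_adjust,
    cluster_mutant_enrichment,
    cluster_summaries,
    correlation_screen,
    density_regression,
    expression_normalized_mcf,
    geneset_overlap,
    infer_lineage,
    infer_lineages,
    qc_normalize,
    wilcoxon_signature,
)


class TestQcNormalize:
    def make_counts(self):
        rng = np.random.default_rng(0)
        genes = [f"GENE{i}" for i in range(40)] + ["RPS1", "RPL2", "MT-CO1"]
        counts = pd.DataFrame(
            rng.poisson(5, size=(len(genes), 8)),
            index=genes,
            columns=[f"cell{i}" for i in range(8)],
        )
        return counts

    def test_low_complexity_cell_removed(self):
        counts = self.make_counts()
        counts["cell0"] = 0
        counts.loc["GENE0":"GENE8", "cell0"] = 1  # 9 expressed genes
        norm = qc_normalize(counts)
        assert "cell0" not in norm.columns

    def test_ribosomal_and_mito_fractions(self):
        counts = self.make_counts()
        counts["cell1"] = 1
        counts.loc[["RPS1", "RPL2"], "cell1"] = 30  # >50% ribosomal
        counts["cell2"] = 2
        counts.loc["MT-CO1", "cell2"] = 11  # >10% mitochondrial
        norm = qc_normalize(counts)
        assert {"cell1", "cell2"}.isdisjoint(norm.columns)

    def test_rare_gene_removed(self):
        counts = self.make_counts()
        counts.loc["GENE5"] = 0
        counts.loc["GENE5", ["cell3", "cell4"]] = 7  # 2 cells < 3
        norm = qc_normalize(counts)
        assert "GENE5" not in norm.index

    def test_normalization_arithmetic(self):
        counts = self.make_counts()
        depth = counts["cell5"].sum()
        scaled = counts.loc["GENE1", "cell5"] / depth * 10_000
        norm = qc_normalize(counts)
        assert norm.loc["GENE1", "cell5"] == pytest.approx(math.log1p(scaled))

    def test_matches_scanpy_normalization(self):
        scanpy = pytest.importorskip("scanpy")
        import anndata

        counts = self.make_counts()
        norm = qc_normalize(counts)
        ad = anndata.AnnData(counts[norm.columns].loc[norm.index].T.to_numpy()
                             .astype(float))
        scanpy.pp.normalize_total(ad, target_sum=1e4)
        scanpy.pp.log1p(ad)
        assert np.allclose(norm.to_numpy(), ad.X.T)


class TestLineage:
    def refs(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(60)]
        return pd.DataFrame(rng.gamma(2.0, 1.0, size=(3, 60)),
                            index=["HSC", "Tcell", "Ery"], columns=genes)

    def test_identical_profile_recovers_lineage(self):
        refs = self.refs()
        label, rho = infer_lineage(refs.loc["Tcell"], refs)
        assert label == "Tcell" and rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        refs = self.refs()
        warped = np.log1p(refs.loc["Ery"]) ** 2  # rank-preserving warp
        label, rho = infer_lineage(warped, refs)
        assert label == "Ery" and rho == pytest.approx(1.0)

    def test_constant_profile_rejected(self):
        refs = self.refs()
        with pytest.raises(ValueError):
            infer_lineage(pd.Series(1.0, index=refs.columns), refs)

    def test_too_few_shared_genes_rejected(self):
        refs = self.refs()
        with pytest.raises(ValueError):
            infer_lineage(refs.loc["HSC"].iloc[:5], refs)

    def test_noisy_cells_mostly_assigned_to_their_lineage(self):
        refs = self.refs()
        rng = np.random.default_rng(2)
        cells, truth = {}, []
        for i in range(120):
            lin = refs.index[i % 3]
            noise = rng.normal(0, 0.1, size=refs.shape[1])
            cells[f"c{i}"] = refs.loc[lin] * np.exp(noise)
            truth.append(lin)
        res = infer_lineages(pd.DataFrame(cells), refs)
        accuracy = (res.lineage.to_numpy() == np.array(truth)).mean()
        assert accuracy >= 0.95


class TestEnrichment:
    def test_concentrated_mutants_are_highly_significant(self):
        cluster_of = {f"c{i}": ("hot" if i < 20 else "cold") for i in range(100)}
        mutants = {f"c{i}" for i in range(15)}  # all 15 mutants in the 20-cell cluster
        res = cluster_mutant_enrichment(mutants, cluster_of).set_index("cluster")
        # enumeration oracle: P(X >= 15), X ~ Hypergeom(N=100, K=15, n=20)
        oracle = sum(
            math.comb(15, k) * math.comb(85, 20 - k) for k in range(15, 16)
        ) / math.comb(100, 20)
        assert res.loc["hot", "p"] == pytest.approx(oracle, rel=1e-9)
        assert res.loc["hot", "p"] < 1e-9
        assert res.loc["hot", "significant"]

    def test_null_cluster_not_flagged(self):
        # mutant fraction identical inside and outside the cluster
        cluster_of = {f"c{i}": ("a" if i < 50 else "b") for i in range(100)}
        mutants = {f"c{i}" for i in list(range(5)) + list(range(50, 55))}
        res = cluster_mutant_enrichment(mutants, cluster_of).set_index("cluster")
        assert (res.p > 0.4).all()
        assert not res.significant.any()

    def test_no_mutants_gives_p_one(self):
        cluster_of = {f"c{i}": i % 3 for i in range(30)}
        res = cluster_mutant_enrichment(set(), cluster_of)
        assert (res.p == 1.0).all()

    def test_depletion_direction(self):
        cluster_of = {f"c{i}": ("normal" if i < 20 else "tumor") for i in range(100)}
        mutants = {f"c{i}" for i in range(20, 90)}  # none in "normal"
        res = cluster_mutant_enrichment(mutants, cluster_of,
                                        direction="depleted").set_index("cluster")
        assert res.loc["normal", "p"] < 1e-6
        assert res.loc["tumor", "p"] == pytest.approx(1.0)


class TestExpressionNormalizedMcf:
    def test_ratio_and_proportionality(self):
        m = pd.Series({1: 0.2, 2: 0.2, 3: 0.1})
        g = pd.Series({1: 2.0, 2: 4.0, 3: 0.0})
        out = expression_normalized_mcf(m, g)
        assert out[1] == pytest.approx(0.1)
        assert out[2] == pytest.approx(out[1] / 2)  # doubled expression halves it
        assert np.isnan(out[3])  # undefined where the gene is silent


class TestDensityRegression:
    def test_exact_linear_relation_recovered(self):
        m = np.linspace(0.05, 0.6, 8)
        g = np.array([1.0, 1.8, 1.2, 2.0, 1.1, 1.6, 1.9, 1.3])  # not collinear with m
        E = pd.DataFrame({
            "hit": 0.7 + 1.5 * m + 0.3 * g,
            "flat": np.full(8, 2.0),
        })
        res = density_regression(E, m, g).set_index("gene")
        assert res.loc["hit", "y"] == pytest.approx(1.5, abs=1e-9)
        assert res.loc["hit", "z"] == pytest.approx(0.3, abs=1e-9)
        assert res.loc["hit", "p"] < 1e-12
        assert res.loc["hit", "selected"]
        assert res.loc["flat", "y"] == pytest.approx(0.0, abs=1e-9)
        assert not res.loc["flat", "selected"]

    def test_negative_association_not_selected(self):
        m = np.linspace(0.05, 0.6, 8)
        E = pd.DataFrame({"down": 2.0 - 1.0 * m})
        res = density_regression(E, m).set_index("gene")
        assert res.loc["down", "q"] <= 0.05 and not res.loc["down", "selected"]

    def test_planted_signature_recovered(self):
        # cluster means carry the planted slope with cell-level noise
        # averaged out over the cells in each cluster
        from scsomatic.simulate import ExpressionSimConfig, simulate_expression

        cfg = ExpressionSimConfig(seed=7)
        counts, cluster_of, m, planted = simulate_expression(cfg)
        norm = qc_normalize(counts)
        summ = cluster_summaries(norm, cluster_of, mutant_cells=set())
        res = density_regression(summ[list(norm.index)], m.to_numpy())
        selected = set(res.gene[res.selected])
        planted = set(planted) & set(norm.index)
        recall = len(selected & planted) / len(planted)
        fdr = len(selected - planted) / max(1, len(selected))
        assert recall >= 0.9
        assert fdr <= 0.10  # BH at q <= 0.05 with selection slack

    def test_null_effect_selects_almost_nothing(self):
        from scsomatic.simulate import ExpressionSimConfig, simulate_expression

        cfg = ExpressionSimConfig(seed=8, effect_size=0.0, n_genes=400)
        counts, cluster_of, m, _ = simulate_expression(cfg)
        norm = qc_normalize(counts)
        summ = cluster_summaries(norm, cluster_of, mutant_cells=set())
        res = density_regression(summ[list(norm.index)], m.to_numpy())
        # with no true effects BH controls expected false selections near 0
        assert res.selected.sum() <= max(3, 0.02 * len(res))

    def test_constant_m_rejected_and_collinearity_flagged(self):
        E = pd.DataFrame({"gene": np.arange(6, dtype=float)})
        with pytest.raises(ValueError):
            density_regression(E, np.full(6, 0.3))
        m = np.linspace(0, 1, 6)
        res = density_regression(E, m, g=2 * m)  # g collinear with m
        assert res.rank_deficient.all()


class TestWilcoxonSignature:
    def make_data(self, rich_fraction=0.5):
        rng = np.random.default_rng(3)
        cluster_of = {f"c{i}": i % 4 for i in range(80)}
        frac = {0: rich_fraction, 1: 0.02, 2: 0.10, 3: 0.01}  # cluster 2 at boundary
        expr = pd.DataFrame(
            rng.normal(1, 0.2, size=(5, 80)),
            index=[f"g{i}" for i in range(5)],
            columns=list(cluster_of),
        )
        return expr, cluster_of, frac

    def test_exclusive_gene_has_smallest_p(self):
        expr, cluster_of, frac = self.make_data()
        rich_cells = [c for c in expr.columns if cluster_of[c] == 0]
        expr.loc["g0"] = 0.0
        expr.loc["g0", rich_cells] = 5.0  # expressed only in the rich group
        res = wilcoxon_signature(expr, cluster_of, frac).set_index("gene")
        assert res.p.idxmin() == "g0"
        assert res.loc["g0", "significant"]

    def test_boundary_cluster_is_not_rich(self):
        expr, cluster_of, frac = self.make_data()
        expr.loc["g1"] = 0.0
        cells_2 = [c for c in expr.columns if cluster_of[c] == 2]
        expr.loc["g1", cells_2] = 9.0
        res = wilcoxon_signature(expr, cluster_of, frac).set_index("gene")
        # cluster 2 sits exactly at 10% -> non-rich group; its marker gene
        # separates the groups in the poor>rich direction
        assert res.loc["g1", "significant"]

    def test_empty_group_is_an_error(self):
        expr, cluster_of, _ = self.make_data()
        with pytest.raises(ValueError):
            wilcoxon_signature(expr, cluster_of, {k: 0.9 for k in range(4)})

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(4)
        cluster_of = {f"c{i}": i % 6 for i in range(120)}
        frac = {k: (0.5 if k < 3 else 0.01) for k in range(6)}
        expr = pd.DataFrame(rng.normal(size=(400, 120)),
                            index=[f"g{i}" for i in range(400)],
                            columns=list(cluster_of))
        res = wilcoxon_signature(expr, cluster_of, frac)
        below = (res.p < 0.05).mean()
        assert 0.01 <= below <= 0.10


class TestCorrelationScreen:
    def make_bulk(self, n_samples=40, n_genes=200, seed=5):
        rng = np.random.default_rng(seed)
        bulk = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                            index=[f"g{i}" for i in range(n_genes)])
        return bulk

    def test_perfect_correlates_included_either_sign(self):
        bulk = self.make_bulk()
        bulk.loc["twin"] = bulk.loc["g0"]
        bulk.loc["anti"] = -bulk.loc["g0"]
        res = correlation_screen(bulk, "g0").set_index("gene")
        assert res.loc["twin", "r"] == pytest.approx(1.0)
        assert res.loc["anti", "r"] == pytest.approx(-1.0)
        assert res.loc["twin", "in_set"] and res.loc["anti", "in_set"]
        assert not res.loc["g0", "in_set"]  # the anchor itself is excluded

    def test_independent_genes_rarely_pass(self):
        res = correlation_screen(self.make_bulk(seed=6), "g0")
        assert res.in_set.sum() == 0

    def test_agrees_with_scipy_pearsonr(self):
        from scipy import stats as sps

        bulk = self.make_bulk()
        res = correlation_screen(bulk, "g0").set_index("gene")
        r, p = sps.pearsonr(bulk.loc["g0"], bulk.loc["g7"])
        assert res.loc["g7", "r"] == pytest.approx(r)
        assert res.loc["g7", "p"] == pytest.approx(p)

    def test_constant_anchor_rejected(self):
        bulk = self.make_bulk()
        bulk.loc["g0"] = 3.0
        with pytest.raises(ValueError):
            correlation_screen(bulk, "g0")


class TestGenesetOverlap:
    def test_enumeration_oracle_small_universe(self):
        universe = [f"g{i}" for i in range(10)]
        A = {"g0", "g1", "g2"}
        B = {"g1", "g2", "g9"}  # overlap 2
        # oracle: enumerate every possible draw of |B| genes from the universe
        draws = list(itertools.combinations(universe, len(B)))
        tail = sum(1 for d in draws if len(A & set(d)) >= 2) / len(draws)
        k, p = geneset_overlap(A, B, universe)
        assert k == 2
        assert p == pytest.approx(tail)  # = 22/120
        assert p == pytest.approx(22 / 120)

    def test_identical_sets_minimal_p(self):
        universe = [f"g{i}" for i in range(30)]
        A = set(universe[:5])
        k, p = geneset_overlap(A, A, universe)
        assert k == 5
        assert p == pytest.approx(1 / math.comb(30, 5))

    def test_disjoint_small_sets_near_one(self):
        universe = [f"g{i}" for i in range(1000)]
        _, p = geneset_overlap(set(universe[:3]), set(universe[500:503]), universe)
        assert p > 0.99

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            geneset_overlap({"x"}, {"a"}, {"a", "b"})


class TestBH:
    @staticmethod
    def reference_bh(p):
        """Step-up BH from first principles: cumulative minimum of n*p/i."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(n)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            assert np.allclose(bh_adjust(p), self.reference_bh(p))

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(100)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClusterSummaries:
    def test_means_fraction_and_covariate(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]],
            index=["GATA2", "other"], columns=["a", "b", "c", "d"])
        cluster_of = {"a": 0, "b": 0, "c": 1, "d": 1}
        summ = cluster_summaries(expr, cluster_of, mutant_cells={"a", "c"},
                                 covariate_gene="GATA2")
        assert summ.loc[0, "GATA2"] == pytest.approx(1.5)
        assert summ.loc[0, "m"] == pytest.approx(0.5)
        assert summ.loc[1, "g"] == pytest.approx(3.5)
        assert summ.loc[1, "n_cells"] == 2
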