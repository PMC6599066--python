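import numpy as np
import pytest

import coreg
from coreg.component_space import compute_gene_correlation, decompose
from coreg.prediction import (
    GeneSetCollection,
    build_prediction_matrix,
    component_t_z,
    contaminate_sets,
    filter_terms,
    prioritization_z,
    term_auc,
    term_profile,
)
from oracles import naive_auc, naive_corr_z, naive_prediction_z, naive_t_z


class TestComponentTZ:
    def test_identical_distributions_give_zero(self):
        x = np.array([0.1, -0.2, 0.3, 0.0])
        assert component_t_z(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention(self):
        rng = np.random.default_rng(1)
        bg = rng.standard_normal(30)
        assert component_t_z(bg[:5] + 1.0, bg) > 0

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(12)
        in_set = [1.0, 1.2, 0.9]
        bg = rng.standard_normal(20)
        assert component_t_z(in_set, bg) == pytest.approx(
            naive_t_z(in_set, bg), abs=1e-10
        )


class TestTermProfile:
    def test_excluding_nonmember_changes_nothing(self, tiny_space):
        genes = tiny_space.gene_ids[:4]
        p1 = term_profile(tiny_space, genes)
        p2 = term_profile(tiny_space, genes, exclude_gene="g19")
        assert np.array_equal(p1.z, p2.z)

    def test_profile_length_is_n_retained(self, tiny_space):
        p = term_profile(tiny_space, tiny_space.gene_ids[:5])
        assert p.z.shape == (tiny_space.n_retained,)

    def test_shrunken_set_rejected(self, tiny_space):
        with pytest.raises(ValueError, match=">=2"):
            term_profile(tiny_space, ["g00", "g01"], exclude_gene="g00")

    def test_planted_set_peaks_on_its_component(self, small_study,
                                                small_space):
        # a set drawn from one factor's block has its largest |Z| on the
        # component aligned with that factor
        study = small_study
        term = next(t for t, f in study.term_factor.items()
                    if len(study.collection.sets[t]) >= 10)
        factor = study.term_factor[term]
        profile = term_profile(small_space, study.collection.sets[term])
        # find the component matching the factor by loading correlation
        load = study.compendium.loadings[:, factor]
        comp = np.abs(small_space.eigenvectors.T @ load).argmax()
        assert np.abs(profile.z).argmax() == comp


class TestPrioritizationZ:
    def test_orthogonal_profile_gives_zero(self, tiny_space):
        profile = term_profile(tiny_space, tiny_space.gene_ids[:4])
        yc = profile.z - profile.z.mean()
        x = np.random.default_rng(0).standard_normal(yc.size)
        xc = x - x.mean()
        coeffs = xc - (xc @ yc) / (yc @ yc) * yc  # exactly decorrelated
        z, _ = prioritization_z(coeffs, profile)
        assert z == pytest.approx(0.0, abs=1e-8)

    def test_constant_vector_warns_and_returns_zero(self, tiny_space):
        profile = term_profile(tiny_space, tiny_space.gene_ids[:4])
        with pytest.warns(UserWarning):
            z, _ = prioritization_z(np.ones_like(profile.z), profile)
        assert z == 0.0

    def test_self_correlation_capped(self, tiny_space):
        profile = term_profile(tiny_space, tiny_space.gene_ids[:4])
        z, capped = prioritization_z(profile.z.copy(), profile)
        assert z == coreg.Z_MAX and capped

    def test_matches_chained_oracle(self):
        rng = np.random.default_rng(21)
        profile = coreg.TermComponentProfile("t", rng.standard_normal(8))
        coeffs = rng.standard_normal(8)
        z, _ = prioritization_z(coeffs, profile)
        assert z == pytest.approx(naive_corr_z(coeffs, profile.z), abs=1e-8)


class TestTermAuc:
    def test_perfect_separation(self):
        auc, p = term_auc([3.0, 2.5], [1.0, 0.5, 0.0])
        assert auc == 1.0
        assert p < 0.2

    def test_identical_groups_give_half(self):
        auc, _ = term_auc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert auc == pytest.approx(0.5)

    def test_matches_pair_enumeration(self):
        ann, bg = [3.0, 1.0], [2.0, 0.0, -1.0]
        auc, _ = term_auc(ann, bg)
        assert auc == pytest.approx(naive_auc(ann, bg))
        assert auc == pytest.approx(5.0 / 6.0)

    def test_complementarity(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(10), rng.standard_normal(15)
        auc_ab, _ = term_auc(a, b)
        auc_ba, _ = term_auc(b, a)
        assert auc_ab + auc_ba == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            term_auc([], [1.0])


class TestFilterTerms:
    def _matrix_with_stats(self, rows):
        import pandas as pd
        ts = pd.DataFrame(rows).set_index("term_id")
        n_genes = 5
        return coreg.PredictionMatrix(
            "db", [f"g{i}" for i in range(n_genes)], list(ts.index),
            np.zeros((n_genes, len(ts))), np.zeros((n_genes, len(ts)), bool),
            ts,
        )

    def test_small_sets_never_significant(self):
        m = self._matrix_with_stats([
            {"term_id": "a", "n_annotated": 9, "auc": 0.99, "u_p": 1e-10},
            {"term_id": "b", "n_annotated": 10, "auc": 0.9, "u_p": 1e-4},
        ])
        sig = filter_terms(m, min_genes=10, alpha=0.05)
        assert sig == ["b"]

    def test_bonferroni_uses_eligible_count(self):
        rows = [{"term_id": f"t{i}", "n_annotated": 10, "auc": 0.7,
                 "u_p": 0.2} for i in range(99)]
        rows.append({"term_id": "hit", "n_annotated": 10, "auc": 0.9,
                     "u_p": 4e-4})
        m = self._matrix_with_stats(rows)
        sig = filter_terms(m, min_genes=10, alpha=0.05)
        assert sig == ["hit"]  # 4e-4 <= 0.05/100
        assert m.term_stats.loc["hit", "bonferroni_p"] == pytest.approx(0.04)


class TestContaminateSets:
    def test_ten_percent_growth(self):
        coll = GeneSetCollection(
            "db", {"t": tuple(f"g{i}" for i in range(20))}
        )
        universe = [f"g{i}" for i in range(100)]
        out = contaminate_sets(coll, 0.10, universe, seed=1)
        assert len(out.sets["t"]) == 22
        assert set(coll.sets["t"]) <= set(out.sets["t"])

    def test_zero_fraction_is_identity(self):
        coll = GeneSetCollection("db", {"t": ("a", "b", "c")})
        out = contaminate_sets(coll, 0.0, ["a", "b", "c", "d"], seed=1)
        assert out.sets == coll.sets

    def test_deterministic_given_seed(self):
        coll = GeneSetCollection("db", {"t": tuple(f"g{i}" for i in
                                                   range(10))})
        universe = [f"g{i}" for i in range(50)]
        a = contaminate_sets(coll, 0.5, universe, seed=3)
        b = contaminate_sets(coll, 0.5, universe, seed=3)
        assert a.sets == b.sets

    def test_insufficient_pool_rejected(self):
        coll = GeneSetCollection("db", {"t": ("a", "b")})
        with pytest.raises(ValueError, match="cannot add"):
            contaminate_sets(coll, 3.0, ["a", "b", "c"], seed=1)


class TestBuildPredictionMatrix:
    def test_matches_naive_reimplementation(self, tiny_space):
        # full oracle equivalence on a 20-gene, 6-component instance
        sets = {
            "T1": ("g00", "g01", "g02", "g03"),
            "T2": ("g05", "g06", "g07", "g08", "g09", "g10"),
            "T3": ("g11", "g12", "g13"),
        }
        matrix = build_prediction_matrix(
            tiny_space, GeneSetCollection("db", sets)
        )
        expected = naive_prediction_z(tiny_space, sets)
        assert np.allclose(matrix.z, expected, atol=1e-8, equal_nan=True)

    def test_two_gene_term_cells_missing(self, tiny_space):
        matrix = build_prediction_matrix(
            tiny_space, GeneSetCollection("db", {"t": ("g00", "g01")})
        )
        col = matrix.z[:, 0]
        assert np.isnan(col[0]) and np.isnan(col[1])
        assert np.isfinite(col[2:]).all()
        assert not matrix.loo[0, 0]

    def test_loo_flag_marks_annotated_cells(self, small_study, small_matrix):
        gi = {g: i for i, g in enumerate(small_matrix.gene_ids)}
        ti = {t: j for j, t in enumerate(small_matrix.term_ids)}
        for term, genes in small_study.collection.sets.items():
            if len(genes) < 3:
                continue
            for g in genes:
                assert small_matrix.loo[gi[g], ti[term]]

    def test_planted_terms_have_high_auc(self, small_matrix):
        ts = small_matrix.term_stats
        leaf = ts[(ts["n_annotated"] >= 10)]
        assert (leaf["auc"] >= 0.9).all()
        assert leaf["significant"].all()

    def test_antisymmetry_under_global_sign_flip(self, tiny_space):
        sets = {"T1": ("g00", "g01", "g02", "g03")}
        m1 = build_prediction_matrix(tiny_space,
                                     GeneSetCollection("db", sets))
        flipped = coreg.ComponentSpace(
            list(tiny_space.gene_ids), -tiny_space.eigenvectors,
            tiny_space.eigenvalues.copy(),
        )
        flipped.n_retained = tiny_space.n_retained
        m2 = build_prediction_matrix(flipped,
                                     GeneSetCollection("db", sets))
        assert np.allclose(m1.z, m2.z, atol=1e-10, equal_nan=True)

    def test_genes_outside_space_dropped_with_size_gate(self, tiny_space):
        sets = {"t": ("g00", "g01", "g02", "nope1", "nope2")}
        matrix = build_prediction_matrix(
            tiny_space, GeneSetCollection("db", sets)
        )
        assert matrix.term_stats.loc["t", "n_annotated"] == 3


class TestNullCalibration:
    def test_null_sets_unbiased(self):
        # annotated-gene scores under random sets on unstructured data:
        # no bias towards known annotations thanks to leave-one-out
        rng = np.random.default_rng(40)
        x = rng.standard_normal((150, 800))
        gene_ids = [f"n{i:03d}" for i in range(150)]
        expr = coreg.ExpressionMatrix(
            gene_ids, [f"s{j}" for j in range(800)], x
        )
        space = decompose(compute_gene_correlation(expr), gene_ids,
                          max_components=8)
        space.n_retained = 8
        sets = {
            f"N{i:03d}": tuple(
                np.array(gene_ids)[rng.choice(150, 8, replace=False)]
            )
            for i in range(70)
        }
        matrix = build_prediction_matrix(space,
                                         GeneSetCollection("null", sets))
        ann = matrix.z[matrix.loo]
        ann = ann[np.isfinite(ann)]
        assert ann.size >= 500
        assert abs(ann.mean()) < 3 * ann.std() / np.sqrt(ann.size)


class TestMonotoneSignal:
    def test_held_out_gene_score_increases_with_snr(self):
        # expectation over replicates: stronger co-regulation -> higher
        # prioritization Z for a held-out block gene
        means = []
        for snr in (0.5, 2.0, 8.0):
            zs = []
            for rep in range(50):
                comp = coreg.simulate_compendium(
                    n_genes=60, n_samples=150, n_factors=2, snr=snr,
                    seed=1000 + rep, block_size=[12, 8],
                )
                expr = comp.expression
                space = decompose(compute_gene_correlation(expr),
                                  list(expr.gene_ids), max_components=4)
                space.n_retained = 4
                block = comp.blocks[0]
                held, members = block[0], block[1:7]
                profile = term_profile(space, members)
                i = expr.gene_ids.index(held)
                z, _ = prioritization_z(space.eigenvectors[i], profile)
                zs.append(z)
            means.append(np.mean(zs))
        assert means[0] < means[1] < means[2]
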