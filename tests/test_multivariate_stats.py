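"""Distance matrices, PERMANOVA, beta-dispersion and NMDS.

scikit-bio's PERMANOVA implementation serves as the independent
cross-check for the pseudo-F statistic; the classical one-way ANOVA from
stats_core is the oracle for the 1-D equivalence and for the dispersion
ANOVA.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from evodiv.multivariate_stats import (
    DistanceMatrix,
    betadisper,
    euclidean_distances,
    nmds,
    permanova,
    variant_feature_matrix,
)
from evodiv.pool_diversity import VariantRecord, VariantTable
from evodiv.stats_core import lm_f_test


def vt(pid, variants, treatment=None):
    """variants: dict mapping pos -> proportion."""
    return VariantTable(
        pid,
        [VariantRecord(f"v{pos}", "chr1", pos, "A", "G", "SNP", p) for pos, p in variants.items()],
        treatment,
    )


class TestFeatureMatrix:
    def test_disjoint_variants_identity_like(self):
        mat = variant_feature_matrix([vt("a", {1: 1.0}), vt("b", {2: 1.0})])
        np.testing.assert_allclose(mat.to_numpy(), [[1, 0], [0, 1]])

    def test_identical_tables_zero_distance(self):
        mat = variant_feature_matrix([vt("a", {1: 0.5}), vt("b", {1: 0.5})])
        dist = euclidean_distances(mat)
        assert dist.d[0, 1] == 0.0

    def test_shared_variant_axis_distance(self):
        mat = variant_feature_matrix([vt("a", {1: 0.5}), vt("b", {1: 0.9})])
        assert euclidean_distances(mat).d[0, 1] == pytest.approx(0.4)

    def test_duplicate_population_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            variant_feature_matrix([vt("a", {1: 0.5}), vt("a", {2: 0.5})])


class TestEuclideanDistances:
    def test_hand_345(self):
        d = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.d[0, 1] == pytest.approx(5.0)

    def test_triangle_inequality(self, rng):
        x = rng.normal(size=(6, 4))
        d = euclidean_distances(x).d
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric


class TestPermanova:
    def test_hand_partition(self):
        d = euclidean_distances(np.array([[0.0], [2.0], [10.0], [12.0]]))
        res = permanova(d, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.pseudo_F == pytest.approx(50.0)
        assert res.R2 == pytest.approx(100 / 104)

    def test_matches_classical_anova_on_1d(self, rng):
        x = rng.normal(size=12)
        groups = ["a"] * 6 + ["b"] * 6
        d = euclidean_distances(x[:, None])
        res = permanova(d, groups, n_perm=9, seed=0)
        oracle = lm_f_test(x, groups)
        assert res.pseudo_F == pytest.approx(oracle.statistic, abs=1e-10)

    def test_cross_check_against_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        x = rng.normal(size=(10, 4))
        groups = ["a"] * 5 + ["b"] * 5
        d = euclidean_distances(x)
        ours = permanova(d, groups, n_perm=9, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.d, d.labels), groups, permutations=99
        )
        assert ours.pseudo_F == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_p_resolution_and_range(self, rng):
        x = rng.normal(size=(8, 2))
        res = permanova(euclidean_distances(x), ["a"] * 4 + ["b"] * 4, n_perm=99, seed=3)
        assert 1 / 100 <= res.p <= 1.0

    def test_null_p_roughly_uniform(self, rng):
        # exchangeable data: p-values spread over (0, 1]
        ps = []
        for i in range(100):
            x = rng.normal(size=(10, 2))
            res = permanova(
                euclidean_distances(x), ["a"] * 5 + ["b"] * 5, n_perm=99, seed=i
            )
            ps.append(res.p)
        assert 0.35 < np.mean(ps) < 0.65
        assert (np.array(ps) < 0.1).mean() < 0.25

    def test_label_permutation_invariance(self, rng):
        x = rng.normal(size=(8, 3))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        d = euclidean_distances(x)
        perm = rng.permutation(8)
        d_perm = DistanceMatrix([d.labels[i] for i in perm], d.d[np.ix_(perm, perm)])
        r1 = permanova(d, groups, n_perm=199, seed=5)
        r2 = permanova(d_perm, groups[perm], n_perm=199, seed=5)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)

    def test_single_group_rejected(self):
        d = euclidean_distances(np.eye(3))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a"], n_perm=9)


class TestBetadisper:
    def test_hand_dispersion_anova(self):
        d = euclidean_distances(np.array([[0.0], [4.0], [10.0], [11.0]]))
        res = betadisper(d, ["a", "a", "b", "b"])
        np.testing.assert_allclose(
            sorted(res.distance_to_centroid), [0.5, 0.5, 2.0, 2.0]
        )
        oracle = lm_f_test([2.0, 2.0, 0.5, 0.5], ["a", "a", "b", "b"])
        # identical within-group spreads make both F's blow up identically
        assert (res.anova.statistic > 1e10) == (oracle.statistic > 1e10)

    def test_equal_spread_groups_give_small_f(self, rng):
        # two point clouds, same shape, different location
        base = rng.normal(size=(6, 2))
        x = np.vstack([base, base + 50.0])
        res = betadisper(euclidean_distances(x), ["a"] * 6 + ["b"] * 6)
        assert res.anova.statistic == pytest.approx(0.0, abs=1e-10)

    def test_distances_non_negative(self, rng):
        x = rng.normal(size=(9, 3))
        res = betadisper(euclidean_distances(x), ["a"] * 4 + ["b"] * 5)
        assert np.all(res.distance_to_centroid >= 0)

    def test_single_group_rejected(self):
        d = euclidean_distances(np.eye(3))
        with pytest.raises(ValueError):
            betadisper(d, ["a", "a", "a"])


class TestNMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        d = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        )
        res = nmds(d, k=2, seed=0)
        assert res.stress < 0.02

    def test_rank_fidelity_at_low_stress(self, rng):
        x = rng.normal(size=(10, 2))
        d = euclidean_distances(x)
        res = nmds(d, k=2, seed=1)
        if res.stress < 0.05:
            from scipy.spatial.distance import pdist

            rho, _ = spearmanr(pdist(x), pdist(res.coordinates))
            assert rho > 0.95

    def test_seeded_determinism_up_to_alignment(self, rng):
        x = rng.normal(size=(8, 3))
        d = euclidean_distances(x)
        a = nmds(d, k=2, seed=7)
        b = nmds(d, k=2, seed=7)
        np.testing.assert_allclose(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_degenerate_input_rejected(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError):
            nmds(d, k=2)
        with pytest.raises(ValueError):
            nmds(euclidean_distances(np.eye(3)), k=3)  # k >= n


class TestTreatmentStructureDetection:
    def test_exclusive_variant_drives_significance(self):
        # one variant at p >= 0.5 in every population of one treatment only
        from evodiv.synthetic_data import SharedVariant, VariantScenario, generate_variant_tables

        hits = 0
        for seed in range(20):
            scenario = VariantScenario(
                n_populations=12,
                mean_variants_per_population=1.0,
                shared_variant_spec=(
                    SharedVariant("diag", "homogeneous", 1.0, 0.9, "SNP"),
                ),
                seed=seed,
            )
            tables = generate_variant_tables(scenario)
            mat = variant_feature_matrix(tables)
            groups = [t.treatment for t in tables]
            res = permanova(euclidean_distances(mat), groups, n_perm=999, seed=seed)
            hits += res.p <= 0.05
        assert hits >= 19  # >= 95% of seeds
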