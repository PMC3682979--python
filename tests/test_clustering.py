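"""Filters, Z-normalization, fuzzy c-means, assignment and family enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from devotf import clustering
from devotf.containers import ExpressionTimeCourse, PresenceTable, TFCatalog


class TestFilterForClustering:
    def test_range_below_one_dropped_as_constant(self, toy_expression):
        # "constantish" spans [5.0, 5.9]: 0.9 < 1 -> dropped
        out = clustering.filter_for_clustering(toy_expression)
        assert "constantish" not in out.genes

    def test_range_exactly_one_retained(self, toy_expression):
        # "range_one" spans [5.0, 6.0]: the rule is strictly "less than 1"
        out = clustering.filter_for_clustering(toy_expression)
        assert "range_one" in out.genes

    def test_never_present_gene_dropped_despite_dynamic_range(self, toy_expression):
        pres = PresenceTable(
            "toy",
            pd.DataFrame(
                True, index=toy_expression.values.index,
                columns=toy_expression.values.columns,
            ),
        )
        pres.values.loc["dynamic"] = False
        out = clustering.filter_for_clustering(toy_expression, pres)
        assert "dynamic" not in out.genes
        assert out.meta["n_dropped_never_expressed"] == 1

    def test_all_filtered_is_an_error(self):
        df = pd.DataFrame({"a": [1.0], "b": [1.1]}, index=["g"])
        with pytest.raises(ValueError, match="all genes filtered"):
            clustering.filter_for_clustering(ExpressionTimeCourse("s", df))


class TestZNormalize:
    def test_unit_moments(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z = clustering.z_normalize(ExpressionTimeCourse("s", df)).values.to_numpy()[0]
        assert z.mean() == pytest.approx(0.0)
        assert z.std() == pytest.approx(1.0)

    def test_hand_computed_population_sd(self):
        df = pd.DataFrame([[0.0, 0.0, 4.0, 4.0]], index=["g"], columns=list("abcd"))
        z = clustering.z_normalize(ExpressionTimeCourse("s", df)).values.to_numpy()[0]
        assert np.allclose(z, [-1, -1, 1, 1])

    @given(
        st.lists(st.floats(-10, 10), min_size=4, max_size=12).filter(
            lambda xs: max(xs) - min(xs) > 0.1
        ),
        st.floats(0.1, 5),
        st.floats(-20, 20),
    )
    def test_affine_invariance(self, xs, a, b):
        row = np.array(xs)
        df1 = pd.DataFrame([row], index=["g"])
        df2 = pd.DataFrame([a * row + b], index=["g"])
        z1 = clustering.z_normalize(ExpressionTimeCourse("s", df1)).values.to_numpy()
        z2 = clustering.z_normalize(ExpressionTimeCourse("s", df2)).values.to_numpy()
        assert np.allclose(z1, z2, atol=1e-7)

    def test_zero_variance_row_names_gene(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["flatgene"])
        with pytest.raises(ValueError, match="flatgene"):
            clustering.z_normalize(ExpressionTimeCourse("s", df))


def _two_clouds(rng, n=40, sep=5.0, sd=0.1, T=4):
    a = rng.normal(-sep / 2, sd, size=(n, T))
    b = rng.normal(sep / 2, sd, size=(n, T))
    return np.vstack([a, b])


class TestFuzzyCMeans:
    def test_separated_clouds_get_crisp_memberships(self, rng):
        x = _two_clouds(rng)
        fc = clustering.fuzzy_cmeans(x, c=2, m=1.25, seed=0)
        u = fc.membership.to_numpy()
        assert (u.max(axis=1) > 0.99).all()
        # the two clouds land in different clusters
        assert u[:40].argmax(axis=1).std() == 0
        assert u[40:].argmax(axis=1).std() == 0
        assert u[0].argmax() != u[-1].argmax()

    def test_point_on_center_gets_full_membership(self):
        # two point-mass clouds: centers converge onto the points exactly
        x = np.array([[0.0, 0.0]] * 5 + [[4.0, 4.0]] * 5)
        fc = clustering.fuzzy_cmeans(x, c=2, m=1.25, seed=1)
        u = fc.membership.to_numpy()
        assert np.allclose(np.sort(u, axis=1)[:, -1], 1.0)

    def test_objective_non_increasing_over_random_data(self, rng):
        for _ in range(10):
            x = rng.normal(size=(50, 5))
            fc = clustering.fuzzy_cmeans(x, c=3, m=1.25, seed=int(rng.integers(1e6)))
            trace = np.array(fc.objective_trace)
            assert (np.diff(trace) <= 1e-8 * max(1.0, trace[0])).all()

    def test_membership_rows_sum_to_one_and_centers_in_data_box(self, rng):
        x = rng.normal(size=(60, 6))
        fc = clustering.fuzzy_cmeans(x, c=4, seed=2)
        assert np.allclose(fc.membership.sum(axis=1), 1.0, atol=1e-9)
        assert (fc.centers >= x.min(axis=0) - 1e-9).all()
        assert (fc.centers <= x.max(axis=0) + 1e-9).all()

    def test_small_fuzzifier_approaches_kmeans(self, rng):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        x = _two_clouds(rng, n=30, sep=6.0)
        fc = clustering.fuzzy_cmeans(x, c=2, m=1.01, seed=3)
        soft_labels = fc.membership.to_numpy().argmax(axis=1)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(x)
        assert adjusted_rand_score(soft_labels, km.labels_) == 1.0

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(40, 5))
        a = clustering.fuzzy_cmeans(x, c=3, seed=7)
        b = clustering.fuzzy_cmeans(x, c=3, seed=7)
        assert np.array_equal(a.centers, b.centers)
        assert a.membership.equals(b.membership)

    def test_non_finite_input_rejected(self):
        x = np.full((10, 3), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            clustering.fuzzy_cmeans(x, c=2)

    def test_needs_more_points_than_clusters(self, rng):
        with pytest.raises(ValueError, match="more points"):
            clustering.fuzzy_cmeans(rng.normal(size=(5, 3)), c=7)


class TestAssignMembers:
    def _fc(self, u):
        u = np.asarray(u, dtype=float)
        membership = pd.DataFrame(u, index=[f"g{i}" for i in range(len(u))])
        return clustering.FuzzyClustering(
            centers=np.zeros((u.shape[1], 2)), membership=membership, m=1.25,
            objective_trace=[0.0], seed=0, n_iter=1, converged=True,
        )

    def test_threshold_is_strict(self):
        fc = self._fc([[0.8, 0.2], [0.81, 0.19]])
        a = clustering.assign_members(fc, threshold=0.8)
        assert a.unassigned == ["g0"]
        assert a.labels == {"g1": 0}

    def test_assigned_to_argmax(self):
        fc = self._fc([[0.03, 0.95, 0.02]])
        a = clustering.assign_members(fc)
        assert a.labels["g0"] == 1

    def test_threshold_domain_checked(self):
        fc = self._fc([[0.5, 0.5]])
        with pytest.raises(ValueError, match="threshold"):
            clustering.assign_members(fc, threshold=0.4)


class TestClusterFamilyEnrichment:
    def _setup(self, rng, n=700, cluster_size=100, fam_size=60, planted=50):
        genes = [f"g{i}" for i in range(n)]
        labels = {}
        for i, g in enumerate(genes):
            labels[g] = 0 if i < cluster_size else 1 + (i % 6)
        fams = {}
        fam_members = set(genes[:planted])  # planted into cluster 0
        others = [g for g in genes[cluster_size:]]
        fam_members |= set(rng.choice(others, fam_size - planted, replace=False))
        for g in genes:
            fams[g] = frozenset({"Homeobox" if g in fam_members else "other"})
        assign = clustering.ClusterAssignment(labels, [], 0.8)
        return assign, TFCatalog("toy", fams)

    def test_planted_enrichment_flagged(self, rng):
        assign, cat = self._setup(rng)
        table = clustering.cluster_family_enrichment(assign, cat)
        row = table[(table.cluster == 0) & (table.family == "Homeobox")].iloc[0]
        assert row["over"]
        assert row["p_over"] < 0.0025

    def test_background_is_assigned_genes(self, rng):
        assign, cat = self._setup(rng)
        table = clustering.cluster_family_enrichment(assign, cat)
        assert (table["N"] == len(assign)).all()

    def test_absent_family_underrepresentation_boundary(self):
        labels = {f"g{i}": i % 2 for i in range(40)}
        fams = {
            f"g{i}": frozenset({"Ets"} if i % 2 == 0 and i < 20 else {"other"})
            for i in range(40)
        }
        assign = clustering.ClusterAssignment(labels, [], 0.8)
        table = clustering.cluster_family_enrichment(assign, TFCatalog("t", fams))
        row = table[(table.cluster == 1) & (table.family == "Ets")].iloc[0]
        assert row["k"] == 0
        assert 0 < row["p_under"] <= 1.0

    def test_no_assigned_genes_is_an_error(self):
        assign = clustering.ClusterAssignment({}, ["g0"], 0.8)
        with pytest.raises(ValueError, match="no assigned"):
            clustering.cluster_family_enrichment(assign, TFCatalog("t", {"g0": frozenset({"x"})}))
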