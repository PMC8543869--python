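import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itemclust import (
    ChecklistDataset,
    ItemMeta,
    SimulationConfig,
    bootstrap_comembership,
    cronbach_alpha,
    flag_outliers,
    integrate,
    simulate_dataset,
)
from itemclust.bootstrap import CoMembershipMatrix
from itemclust.cluster import Partition
from itemclust.congruence import match_score
from itemclust.efa import LoadingMatrix
from itemclust.reliability import (
    DEFAULT_CLUSTER_NAMES_K7,
    OutlierFlag,
    alpha_from_cov,
    reliability_report,
)
from oracles import kr20


def _binary_dataset(rng, n=20, k=4):
    return ChecklistDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        items=[ItemMeta(f"q{j}") for j in range(k)],
        responses=rng.integers(0, 2, (n, k)).astype(float),
    )


class TestAlpha:
    def test_compound_symmetry_closed_form_example(self):
        cov = np.full((3, 3), 0.5)
        np.fill_diagonal(cov, 1.0)
        assert alpha_from_cov(cov) == pytest.approx(0.75, abs=1e-12)

    @given(st.integers(2, 10), st.sampled_from([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]))
    @settings(max_examples=200, deadline=None)
    def test_compound_symmetry_closed_form(self, k, rho):
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        expected = k * rho / (1.0 + (k - 1) * rho)
        assert alpha_from_cov(cov) == pytest.approx(expected, abs=1e-10)

    def test_duplicated_items_alpha_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 30).astype(float)
        ds = ChecklistDataset(
            subject_ids=[f"s{i}" for i in range(30)],
            items=[ItemMeta("a"), ItemMeta("b"), ItemMeta("c")],
            responses=np.column_stack([x, x, x]),
        )
        alpha, _ = cronbach_alpha(ds)
        assert alpha == pytest.approx(1.0, abs=1e-12)

    def test_kr20_oracle_random_binary(self, rng):
        ds = _binary_dataset(rng)
        alpha, n_used = cronbach_alpha(ds)
        assert n_used == 20
        assert alpha == pytest.approx(kr20(ds.responses), abs=1e-12)

    def test_listwise_equals_pairwise_on_complete_data(self, rng):
        ds = _binary_dataset(rng, n=50)
        a_pair, _ = cronbach_alpha(ds, method="pairwise")
        a_list, n = cronbach_alpha(ds, method="listwise")
        assert n == 50
        assert a_pair == pytest.approx(a_list, abs=1e-12)

    def test_zero_variance_undefined(self):
        ds = ChecklistDataset(
            subject_ids=["a", "b", "c"],
            items=[ItemMeta("x"), ItemMeta("y")],
            responses=np.array([[1, 0], [1, 0], [1, 0]], dtype=float),
        )
        alpha, _ = cronbach_alpha(ds)
        assert np.isnan(alpha)

    def test_fewer_than_two_items_rejected(self, rng):
        ds = _binary_dataset(rng)
        with pytest.raises(ValueError):
            cronbach_alpha(ds, ["q0"])

    def test_reliability_report_matches_direct_calls(self, rng):
        ds = _binary_dataset(rng, n=40, k=6)
        part = Partition(labels=ds.item_ids, assignment=np.array([1, 1, 1, 2, 2, 3]), k=3)
        report = reliability_report(ds, part)
        for _, row in report.iterrows():
            items = row["items"].split(";") if row["items"] else []
            if row["n_items"] >= 2:
                assert row["alpha"] == pytest.approx(cronbach_alpha(ds, items)[0])
            else:
                assert np.isnan(row["alpha"])


def _comembership(labels, p):
    return CoMembershipMatrix(
        labels=labels, p=p, B=100, B_effective=100, n_dropped=0, k=2,
        method="ward_d2", seed=0,
    )


class TestFlagOutliers:
    def _setup_outlier(self):
        labels = ["x", "y", "z", "w", "v"]
        p = np.eye(5)
        p[0, 1] = p[1, 0] = 0.04  # x barely co-clusters with its own cluster
        p[0, 2] = p[2, 0] = 0.04
        p[0, 3] = p[3, 0] = 0.30
        p[0, 4] = p[4, 0] = 0.30
        p[1, 2] = p[2, 1] = 0.9
        p[3, 4] = p[4, 3] = 0.9
        part = Partition(labels=labels, assignment=np.array([1, 1, 1, 2, 2]), k=2)
        return _comembership(labels, p), part

    def test_outlier_flagged(self):
        cm, part = self._setup_outlier()
        flags = flag_outliers(cm, part)
        assert [f.item_id for f in flags] == ["x"]
        assert flags[0].best_other_cluster == 2

    def test_t_within_zero_never_flags(self):
        cm, part = self._setup_outlier()
        assert flag_outliers(cm, part, t_within=0.0) == []

    def test_clean_planted_structure_no_flags(self, planted):
        ds, truth = planted
        from itemclust import agglomerate, association_matrix, cut, to_dissimilarity

        dis = to_dissimilarity(association_matrix(ds))
        part = cut(agglomerate(dis, "ward_d2"), 7)
        cm = bootstrap_comembership(ds, "ward_d2", k=7, B=60, seed=4)
        assert flag_outliers(cm, part) == []

    def test_loading_evidence_attached(self):
        cm, part = self._setup_outlier()
        arr = np.array(
            [[0.1, 0.9], [0.9, 0.0], [0.8, 0.1], [0.0, 0.9], [0.1, 0.8]]
        )
        lm = LoadingMatrix(labels=part.labels, L=arr, extraction="pc", rotation="varimax", m=2)
        alignment = match_score(lm, part)
        flags = flag_outliers(cm, part, lm, alignment)
        assert flags[0].top_factor == 1
        assert flags[0].loading_cluster == 2


class TestIntegrate:
    def _ds(self, labels, rng):
        return ChecklistDataset(
            subject_ids=[f"s{i}" for i in range(40)],
            items=[ItemMeta(l) for l in labels],
            responses=rng.integers(0, 2, (40, len(labels))).astype(float),
        )

    def test_no_flags_is_identity(self, rng):
        labels = ["a", "b", "c", "d"]
        part = Partition(labels=labels, assignment=np.array([1, 1, 2, 2]), k=2)
        ds = self._ds(labels, rng)
        final = integrate(ds, part, [])
        assert [c["items"] for c in final.clusters] == [["a", "b"], ["c", "d"]]
        assert len(final.log) == 0
        for c in final.clusters:
            assert c["alpha"] == pytest.approx(cronbach_alpha(ds, c["items"])[0], nan_ok=True)

    def test_concordant_flag_moves_item(self, rng):
        labels = ["a", "b", "c", "d", "e"]
        part = Partition(labels=labels, assignment=np.array([1, 1, 1, 2, 2]), k=2)
        ds = self._ds(labels, rng)
        flag = OutlierFlag(item_id="a", cluster=1, within_mean=0.04,
                           best_other_cluster=2, best_other_mean=0.4, top_factor=1,
                           loading_cluster=2)
        final = integrate(ds, part, [flag])
        assert "a" in final.clusters[1]["items"]
        assert final.log.iloc[0]["action"] == "moved"

    def test_conflicting_flag_stays_and_logs(self, rng):
        labels = ["a", "b", "c", "d", "e", "f"]
        part = Partition(labels=labels, assignment=np.array([1, 1, 1, 2, 2, 3]), k=3)
        ds = self._ds(labels, rng)
        flag = OutlierFlag(item_id="a", cluster=1, within_mean=0.04,
                           best_other_cluster=2, best_other_mean=0.4, top_factor=0,
                           loading_cluster=3)
        final = integrate(ds, part, [flag])
        assert "a" in final.clusters[0]["items"]
        assert "expert review" in final.log.iloc[0]["action"]

    def test_partition_preserved_regardless_of_flags(self, rng):
        labels = [f"q{j}" for j in range(8)]
        part = Partition(labels=labels, assignment=np.array([1, 1, 2, 2, 3, 3, 4, 4]), k=4)
        ds = self._ds(labels, rng)
        flags = [
            OutlierFlag(item_id="q0", cluster=1, within_mean=0.01, best_other_cluster=3,
                        best_other_mean=0.5, loading_cluster=3),
            OutlierFlag(item_id="q2", cluster=2, within_mean=0.02, best_other_cluster=4,
                        best_other_mean=0.5, loading_cluster=1),
        ]
        final = integrate(ds, part, flags)
        all_items = sorted(x for c in final.clusters for x in c["items"])
        assert all_items == sorted(labels)

    def test_default_names_k7(self, rng):
        labels = [f"q{j}" for j in range(14)]
        part = Partition(labels=labels, assignment=np.repeat(np.arange(1, 8), 2), k=7)
        final = integrate(self._ds(labels, rng), part, [])
        assert tuple(c["name"] for c in final.clusters) == DEFAULT_CLUSTER_NAMES_K7

    def test_missing_name_rejected(self, rng):
        labels = ["a", "b", "c", "d"]
        part = Partition(labels=labels, assignment=np.array([1, 1, 2, 2]), k=2)
        with pytest.raises(ValueError, match="missing"):
            integrate(self._ds(labels, rng), part, [], names={1: "only one"})
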