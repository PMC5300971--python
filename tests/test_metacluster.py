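"""Tests of centroid rescaling, hierarchical merging and annotation."""

import numpy as np
import pandas as pd
import pytest

import nkstrat as nk
from nkstrat import synthetic as syn
from nkstrat.metacluster import (
    UNCLASSIFIED, Metacluster, to_expression_table, to_newick,
)

MARKERS = list(nk.DEFAULT_PANEL.nk_markers)


def make_cluster_table(values, rng=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "sample_id": ["s1"] * len(values),
            "cluster_id": range(len(values)),
            **{m: values[:, i] for i, m in enumerate(MARKERS)},
            "event_count": 10,
        }
    )


class TestRescale:
    def _table(self, rng):
        return make_cluster_table(rng.normal(2, 1, size=(40, 5)))

    def test_p5_maps_to_minus_3(self, rng):
        table = self._table(rng)
        rc = nk.rescale_centers(table)
        for m in MARKERS:
            p5 = np.percentile(table[m], 5.0)
            assert np.isclose(rc.apply_map(m, p5), -3.0)

    def test_p95_maps_to_plus_3(self, rng):
        table = self._table(rng)
        rc = nk.rescale_centers(table)
        for m in MARKERS:
            p95 = np.percentile(table[m], 95.0)
            assert np.isclose(rc.apply_map(m, p95), 3.0)

    def test_midpoint_maps_to_zero(self, rng):
        table = self._table(rng)
        rc = nk.rescale_centers(table)
        for m in MARKERS:
            p5, p95 = rc.anchors[m]
            assert np.isclose(rc.apply_map(m, (p5 + p95) / 2.0), 0.0)

    def test_values_outside_band_not_clipped(self, rng):
        table = self._table(rng)
        rc = nk.rescale_centers(table)
        assert (rc.matrix() > 3).any() or (rc.matrix() < -3).any()

    def test_constant_marker_rejected_by_name(self, rng):
        table = self._table(rng)
        table["NKG2C"] = 1.0
        with pytest.raises(ValueError, match="NKG2C"):
            nk.rescale_centers(table)

    def test_idempotent_on_anchors(self, rng):
        """Rescaling already-rescaled centers maps its own p5/p95 back to
        -3/+3."""
        rc1 = nk.rescale_centers(self._table(rng))
        rc2 = nk.rescale_centers(rc1.table)
        for m in MARKERS:
            p5, p95 = rc2.anchors[m]
            assert np.isclose(rc2.apply_map(m, p5), -3.0)
            assert np.isclose(rc2.apply_map(m, p95), 3.0)


class TestHcl:
    def test_two_rows_merge_at_their_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = nk.hcl(X)
        assert dend.linkage_matrix.shape == (1, 4)
        assert np.isclose(dend.heights[0], 5.0)

    def test_two_tight_pairs_merge_first(self):
        X = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        dend = nk.hcl(X)
        first_two = dend.linkage_matrix[:2, :2].astype(int)
        merged = {frozenset(pair) for pair in first_two}
        assert merged == {frozenset({0, 1}), frozenset({2, 3})}

    def test_average_linkage_final_height(self):
        """Final merge height equals the mean of the 4 between-pair
        distances (definition of average linkage)."""
        X = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        dend = nk.hcl(X)
        expected = np.mean([10.0, 10.1, 9.9, 10.0])
        assert np.isclose(dend.heights[-1], expected)

    def test_heights_non_decreasing(self, rng):
        dend = nk.hcl(rng.normal(size=(30, 5)))
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_non_finite_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="finite"):
            nk.hcl(X)

    def test_partition_invariant_to_row_order(self, rng):
        X = rng.normal(size=(25, 4))
        perm = rng.permutation(25)
        for k in (2, 5, 9):
            lab_a = nk.cut_dendrogram(nk.hcl(X), k)
            lab_b = nk.cut_dendrogram(nk.hcl(X[perm]), k)
            part_a = {frozenset(np.flatnonzero(lab_a == g)) for g in set(lab_a)}
            part_b = {
                frozenset(perm[np.flatnonzero(lab_b == g)]) for g in set(lab_b)
            }
            assert part_a == part_b

    def test_newick_export_parses(self, rng):
        import io
        import skbio

        X = rng.normal(size=(8, 3))
        dend = nk.hcl(X, labels=[f"leaf{i}" for i in range(8)])
        tree = skbio.TreeNode.read(io.StringIO(nk.to_newick(dend)))
        assert {t.name for t in tree.tips()} == {f"leaf{i}" for i in range(8)}


class TestCutTree:
    def test_singletons_and_one_group(self, rng):
        dend = nk.hcl(rng.normal(size=(12, 3)))
        assert len(set(nk.cut_dendrogram(dend, 12))) == 12
        assert len(set(nk.cut_dendrogram(dend, 1))) == 1

    def test_impossible_cut_rejected(self, rng):
        dend = nk.hcl(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            nk.cut_dendrogram(dend, 6)
        with pytest.raises(ValueError):
            nk.cut_dendrogram(dend, 0)

    def test_default_19_metaclusters_on_pooled_cohort(self, pipeline_result):
        labels = {m.id for m in pipeline_result.metaclusters}
        assert len(labels) == 19


class TestFilterRare:
    def _metas(self, sizes):
        return [
            Metacluster(
                id=i,
                members=[("s", j) for j in range(size)],
                signature=dict.fromkeys(MARKERS, 0.0),
            )
            for i, size in enumerate(sizes)
        ]

    def test_min_members_1_retains_all(self):
        out = nk.filter_rare(self._metas([1, 2, 5]), min_members=1)
        assert all(m.retained for m in out)

    def test_19_groups_6_rare_leaves_13(self):
        sizes = [10] * 13 + [1, 2, 1, 2, 1, 2]
        out = nk.filter_rare(self._metas(sizes), min_members=3)
        assert sum(m.retained for m in out) == 13

    def test_all_rare_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="nkstrat.metacluster"):
            out = nk.filter_rare(self._metas([1, 1]), min_members=5)
        assert not any(m.retained for m in out)
        assert caplog.records


class TestAnnotate:
    def _meta(self, sig):
        return Metacluster(
            id=0, members=[("s", 0)], signature=dict(zip(MARKERS, sig))
        )

    @pytest.mark.parametrize(
        "sig,expected",
        [
            ((2.5, -2.0, 2.0, -1.0, -1.0), syn.P_BRIGHT),
            ((0.5, 2.0, -1.5, -1.2, -1.1), syn.P_TN),
            ((2.5, -0.5, 2.0, -1.0, -1.0), syn.P_BRIGHT_LOW),
            ((0.7, 2.0, 2.0, -1.5, -1.5), syn.P_A),
            ((0.7, 2.0, 2.0, 2.0, -1.5), syn.P_AC),
            ((0.7, 2.0, -1.5, 2.0, 2.0), syn.P_C57),
            ((0.7, 2.0, -1.5, -1.5, 2.0), syn.P_57),
            ((-2.0, 2.0, 2.0, -1.5, -1.5), syn.P_NEG_A),
            ((-2.0, 2.0, -1.5, -1.5, 2.0), syn.P_NEG_57),
            ((0.7, -0.5, -1.5, -1.5, -1.5), syn.P_DIM_LOW),
        ],
    )
    def test_signature_rules(self, sig, expected):
        out = nk.annotate([self._meta(sig)])
        assert out[0].name == expected

    def test_no_match_is_unclassified(self):
        out = nk.annotate([self._meta((0.0,) * 5)], rules=[])
        assert out[0].name == UNCLASSIFIED

    def test_rare_metacluster_not_named(self):
        m = self._meta((2.5, -2.0, 2.0, -1.0, -1.0))
        m.retained = False
        out = nk.annotate([m])
        assert out[0].name == UNCLASSIFIED

    def test_end_to_end_annotation_recovery(self, pipeline_result):
        """>= 90% of named cluster centroids are assigned to the planted
        phenotype nearest to them (the generating phenotype, since the
        planted means are far apart relative to the event noise)."""
        name_of = {}
        for m in pipeline_result.metaclusters:
            for key in m.members:
                name_of[key] = m.name
        phen = {p.name: np.array([p.means[m] for m in MARKERS])
                for p in nk.build_default_phenotypes()}
        names = list(phen)
        centers = np.array([phen[n] for n in names])
        table = pipeline_result.cluster_table
        X = table[MARKERS].to_numpy(float)
        nearest = [
            names[int(np.argmin(((centers - x) ** 2).sum(axis=1)))] for x in X
        ]
        hits = total = 0
        for (sid, cid), true_name in zip(
            zip(table["sample_id"], table["cluster_id"]), nearest
        ):
            assigned = name_of[(sid, cid)]
            if assigned == UNCLASSIFIED:
                continue
            total += 1
            hits += assigned == true_name
        assert total > 0
        assert hits / total >= 0.90


def test_expression_table_shape(pipeline_result):
    table = to_expression_table(pipeline_result.rescaled)
    assert list(table.columns) == MARKERS
    assert len(table) == len(pipeline_result.cluster_table)
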