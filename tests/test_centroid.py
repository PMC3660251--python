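"""Centroid classifier: model construction, assignment with mixed calls,
serialization, and the cross-validated gene-pair scan."""

import numpy as np
import pandas as pd
import pytest

from colotype.centroid import (CentroidModel, NearestCentroidSubtyper,
                               build_centroid_model, calls_to_frame,
                               classify, cv_scan_pairs)
from colotype.degenes import moderated_t_all
from colotype.features import center_genes
from colotype.sim import SimConfig, marker_blocks, simulate_expression


def _fake_stats(gene_order, up, down):
    """Stats table ranking ``up`` then ``down`` as the strongest genes."""
    tab = pd.DataFrame(
        {"log_fc": 0.0, "t_mod": 0.0, "df_total": 10.0, "p": 1.0,
         "p_adj": 1.0}, index=gene_order)
    for rank, g in enumerate(up):
        tab.loc[g, ["log_fc", "t_mod", "p", "p_adj"]] = (2.0, 50 - rank,
                                                         1e-30, 1e-20)
    for rank, g in enumerate(down):
        tab.loc[g, ["log_fc", "t_mod", "p", "p_adj"]] = (-2.0, -(50 - rank),
                                                         1e-30, 1e-20)
    return tab


class TestBuildCentroidModel:
    def test_gene_count_without_and_with_sharing(self):
        """Five pairs over six subtypes give 60 model genes, or 57 when
        three genes are shared between two subtypes."""
        genes = [f"G{i:03d}" for i in range(80)]
        rng = np.random.default_rng(0)
        subtypes = [f"C{i}" for i in range(1, 7)]
        samples = [f"S{i}" for i in range(24)]
        labels = pd.Series(np.repeat(subtypes, 4), index=samples)
        expr = pd.DataFrame(rng.normal(0, 1, (80, 24)), index=genes,
                            columns=samples)
        stats = {}
        for i, s in enumerate(subtypes):
            up = genes[10 * i: 10 * i + 5]
            down = genes[10 * i + 5: 10 * i + 10]
            stats[s] = _fake_stats(genes, up, down)
        model = build_centroid_model(expr, labels, stats=stats, d_pairs=5)
        assert len(model.genes) == 60

        # let three of C2's top up genes be C1's top down genes
        shared = genes[5:8]
        stats["C2"] = _fake_stats(genes, shared + genes[10:12], genes[15:20])
        model = build_centroid_model(expr, labels, stats=stats, d_pairs=5)
        assert len(model.genes) == 57

    def test_single_subtype_rejected(self):
        expr = pd.DataFrame(np.ones((4, 4)))
        labels = pd.Series(["A"] * 4, index=expr.columns)
        with pytest.raises(ValueError, match="two subtypes"):
            build_centroid_model(expr, labels)

    def test_deficit_error_lists_subtype(self, small_cohort):
        expr, labels = small_cohort
        with pytest.raises(ValueError, match="C1"):
            build_centroid_model(expr, labels, d_pairs=5000)

    def test_noise_free_centroids_equal_planted_means(self):
        cfg = SimConfig(n_samples=30, n_genes=80, n_markers_per_subtype=10,
                        subtypes=("C1", "C2", "C3"),
                        prevalences=(0.34, 0.33, 0.33), noise_sd=0.0,
                        effect_size=2.0, seed=1)
        expr, labels = simulate_expression(cfg)
        model = build_centroid_model(expr, labels, d_pairs=3)
        centered = center_genes(expr.loc[list(model.genes)])
        for s in model.subtypes:
            planted = centered.loc[:, (labels == s).to_numpy()].mean(axis=1)
            assert np.allclose(model.centroids[s], planted)

    def test_serialization_round_trip_is_exact(self, separable_cohort):
        expr, labels = separable_cohort
        model = build_centroid_model(expr, labels, d_pairs=4)
        clone = CentroidModel.from_json(model.to_json())
        assert clone.genes == model.genes
        assert clone.subtypes == model.subtypes
        assert clone.mixed_delta == model.mixed_delta
        pd.testing.assert_frame_equal(clone.centroids, model.centroids)
        assert clone.markers == model.markers


@pytest.fixture(scope="module")
def fitted(separable_cohort):
    expr, labels = separable_cohort
    return expr, labels, build_centroid_model(expr, labels, d_pairs=5)


class TestClassify:
    def test_resubstitution_is_error_free(self, fitted):
        expr, labels, model = fitted
        calls = classify(model, expr)
        pred = {c.sample_id: c.label for c in calls}
        assert all(pred[s] == labels[s] for s in labels.index)

    def test_sample_equal_to_centroid(self, fitted):
        expr, _, model = fitted
        probe = model.centroids[[model.subtypes[0]]] * 1.0
        probe.columns = ["probe"]
        call = classify(model, probe)[0]
        assert call.label == model.subtypes[0]
        assert call.distances[model.subtypes[0]] == pytest.approx(0, abs=1e-9)
        assert call.mixed is None

    def test_symmetric_midway_sample_gets_mixed_call(self):
        # two mirror-image centroids and a probe symmetric to both
        genes = [f"G{i}" for i in range(6)]
        centroids = pd.DataFrame(
            {"A": [2.0, 1.0, -1.0, -2.0, 1.0, -1.0],
             "B": [-2.0, -1.0, 1.0, 2.0, 1.0, -1.0],
             "C": [0.5, -2.0, 2.0, 0.5, -1.0, 0.0]}, index=genes)
        model = CentroidModel(subtypes=("A", "B", "C"), genes=tuple(genes),
                              centroids=centroids, d_pairs=1)
        probe = pd.DataFrame({"mid": [0.0, 0.0, 0.0, 0.0, 2.0, -2.0]},
                             index=genes)
        call = classify(model, probe)[0]
        assert call.mixed == frozenset({"A", "B"})

    def test_shift_invariance_per_sample(self, fitted):
        expr, _, model = fitted
        shifted = expr.copy()
        shifted.iloc[:, 0] += 5.0
        # per-gene median centering changes, so compare single-sample calls
        one = expr.iloc[:, [0]]
        one_shift = one + 5.0
        c1 = classify(model, one)[0]
        c2 = classify(model, one_shift)[0]
        assert c1.label == c2.label
        assert c1.distances == pytest.approx(c2.distances)

    def test_deterministic_and_permutation_equivariant(self, fitted):
        expr, _, model = fitted
        calls = classify(model, expr)
        again = classify(model, expr)
        assert calls_to_frame(calls).equals(calls_to_frame(again))
        perm = expr.iloc[:, ::-1]
        permuted = classify(model, perm)
        lookup = {c.sample_id: c.label for c in permuted}
        assert all(lookup[c.sample_id] == c.label for c in calls)

    def test_missing_genes_dropped_until_half_then_error(self, fitted):
        expr, labels, model = fitted
        keep = list(model.genes)[: int(0.6 * len(model.genes))]
        other = [g for g in expr.index if g not in model.genes]
        sub = expr.loc[keep + other]
        calls = classify(model, sub)
        assert len(calls) == expr.shape[1]
        too_few = expr.loc[list(model.genes)[: len(model.genes) // 3] + other]
        with pytest.raises(ValueError, match="50%"):
            classify(model, too_few)

    def test_zero_variance_sample_unclassified(self, fitted):
        expr, _, model = fitted
        flat = expr.iloc[:, [0]].copy() * 0 + 3.0
        flat.columns = ["flat"]
        with pytest.warns(UserWarning, match="zero variance"):
            calls = classify(model, flat)
        assert calls[0].label is None

    def test_sklearn_estimator_round_trip(self, separable_cohort):
        expr, labels = separable_cohort
        est = NearestCentroidSubtyper(d_pairs=4).fit(expr.T, labels)
        pred = est.predict(expr.T)
        assert (pred == labels.to_numpy()).all()
        assert list(est.classes_) == sorted(labels.unique())


class TestCVScanPairs:
    def test_noise_free_data_is_error_free_for_all_d(self):
        cfg = SimConfig(n_samples=24, n_genes=60, n_markers_per_subtype=8,
                        subtypes=("C1", "C2", "C3"),
                        prevalences=(0.34, 0.33, 0.33), noise_sd=0.0,
                        effect_size=2.0, seed=2)
        expr, labels = simulate_expression(cfg)
        curve, d_sel = cv_scan_pairs(expr, labels, d_range=range(1, 4),
                                     folds=2, seed=0)
        assert len(curve) == 3
        assert (curve == 0).all()
        assert d_sel == 1  # smallest d attaining the minimum

    def test_small_subtype_suggests_fewer_folds(self, separable_cohort):
        expr, labels = separable_cohort
        with pytest.raises(ValueError, match="fewer folds"):
            cv_scan_pairs(expr, labels, d_range=[1], folds=50)

    def test_curve_indexed_by_requested_d(self, separable_cohort):
        expr, labels = separable_cohort
        curve, _ = cv_scan_pairs(expr, labels, d_range=[2, 4], folds=3,
                                 seed=1)
        assert list(curve.index) == [2, 4]
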