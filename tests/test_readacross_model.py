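import math

import numpy as np
import pandas as pd
import pytest

import readacross as ra
from readacross.labeling_split import ACTIVE, INACTIVE
from readacross.readacross_model import (
    KnnConfig,
    ModelBundle,
    compute_apd,
    knn_predict,
    train_readacross,
)


def brute_force_apd(points, z, retain="below_mean"):
    """Independent APD oracle: explicit double loop, no scipy."""
    pts = np.asarray(points, dtype=float)
    dists = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            dists.append(math.dist(pts[i], pts[j]))
    m = sum(dists) / len(dists)
    kept = [d for d in dists if (d <= m if retain == "below_mean" else d >= m)]
    d_bar = sum(kept) / len(kept)
    if len(kept) >= 2:
        sigma = math.sqrt(sum((d - d_bar) ** 2 for d in kept) / (len(kept) - 1))
    else:
        sigma = 0.0
    return d_bar, sigma, z * sigma + d_bar


def make_bundle(train_x, labels, k=5, z=0.5, **knn_kw):
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    if train_x.shape[0] == 1:
        train_x = train_x.T
    n_feat = train_x.shape[1]
    params = ra.StandardizationParams(
        column_names=tuple(f"f{i}" for i in range(n_feat)),
        mean=(0.0,) * n_feat,
        sd=(1.0,) * n_feat,
    )
    return ModelBundle(
        selected_features=params.column_names,
        standardization=params,
        train_matrix=train_x,
        train_ids=tuple(f"t{i}" for i in range(train_x.shape[0])),
        train_labels=tuple(labels),
        knn_config=KnnConfig(k=min(k, train_x.shape[0]), **knn_kw),
        apd=compute_apd(train_x, z=z) if train_x.shape[0] >= 2 else None,
    )


class TestComputeApd:
    def test_hand_enumerated_1d_example(self):
        # points {0,1,3}: distances {1,2,3}, mean 2, retained {1,2}
        apd = compute_apd(np.array([[0.0], [1.0], [3.0]]))
        sigma = np.std([1.0, 2.0], ddof=1)
        assert apd.d_bar == pytest.approx(1.5)
        assert apd.sigma == pytest.approx(sigma)
        assert apd.threshold == pytest.approx(1.5 + 0.5 * sigma)

    def test_equidistant_points_give_zero_sigma(self):
        c = 2.0
        tri = c * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
        apd = compute_apd(tri, z=7.3)
        assert apd.sigma == pytest.approx(0.0)
        assert apd.threshold == pytest.approx(c)

    def test_z_zero_gives_mean_of_retained(self, rng):
        pts = rng.normal(size=(6, 3))
        apd = compute_apd(pts, z=0.0)
        assert apd.threshold == apd.d_bar

    @pytest.mark.parametrize("retain", ["below_mean", "above_mean"])
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed, retain):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        pts = rng.normal(size=(n, int(rng.integers(1, 5))))
        apd = compute_apd(pts, z=0.5, retain=retain)
        d_bar, sigma, threshold = brute_force_apd(pts, 0.5, retain)
        assert apd.d_bar == pytest.approx(d_bar, abs=1e-12)
        assert apd.sigma == pytest.approx(sigma, abs=1e-12)
        assert apd.threshold == pytest.approx(threshold, abs=1e-12)

    def test_threshold_monotone_in_z(self, rng):
        pts = rng.normal(size=(10, 2))
        thresholds = [compute_apd(pts, z=z).threshold for z in (0.0, 0.5, 1.0, 2.0)]
        assert thresholds == sorted(thresholds)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            compute_apd(np.array([[1.0]]))
        with pytest.warns(UserWarning, match="zero"):
            apd = compute_apd(np.zeros((3, 2)))
        assert apd.threshold == 0.0


class TestKnnPredict:
    def test_hand_computed_inverse_distance_vote(self):
        bundle = make_bundle(
            [0.0, 1.0, 2.0, 3.0, 10.0], [ACTIVE, ACTIVE, INACTIVE, INACTIVE, INACTIVE]
        )
        pred = knn_predict(bundle, [0.9], query_id="q")
        w_active = 1 / 0.9 + 1 / 0.1
        w_inactive = 1 / 1.1 + 1 / 2.1 + 1 / 9.1
        assert pred.vote_weights[ACTIVE] == pytest.approx(w_active)
        assert pred.vote_weights[INACTIVE] == pytest.approx(w_inactive)
        assert pred.predicted_class == ACTIVE
        assert [nid for nid, _ in pred.neighbors] == ["t1", "t0", "t2", "t3", "t4"]

    def test_exact_match_inherits_class(self):
        bundle = make_bundle([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], [ACTIVE, ACTIVE, INACTIVE], k=3)
        pred = knn_predict(bundle, [1.0, 2.0])
        assert pred.predicted_class == ACTIVE
        assert pred.domain_distance == 0.0
        assert pred.reliable

    def test_neighbor_list_equals_exhaustive_sort(self, rng):
        n, d, k = 40, 4, 5
        train = rng.normal(size=(n, d))
        labels = [ACTIVE if u < 0.5 else INACTIVE for u in rng.uniform(size=n)]
        bundle = make_bundle(train, labels, k=k)
        for _ in range(200):
            q = rng.normal(size=d)
            pred = knn_predict(bundle, q)
            # independent reference: full sort of all training distances
            ref = sorted(
                (math.dist(train[i], q), i) for i in range(n)
            )[:k]
            assert [nid for nid, _ in pred.neighbors] == [f"t{i}" for _, i in ref]
            assert [dist for _, dist in pred.neighbors] == pytest.approx(
                [dist for dist, _ in ref]
            )
            assert pred.domain_distance == pytest.approx(ref[0][0])

    def test_agrees_with_sklearn_inverse_distance_knn(self, rng):
        sklearn = pytest.importorskip("sklearn.neighbors")
        n, d = 60, 3
        train = rng.normal(size=(n, d))
        labels = [ACTIVE if u < 0.55 else INACTIVE for u in rng.uniform(size=n)]
        bundle = make_bundle(train, labels, k=5)
        clf = sklearn.KNeighborsClassifier(n_neighbors=5, weights="distance")
        clf.fit(train, labels)
        queries = rng.normal(size=(100, d))
        ours = [knn_predict(bundle, q).predicted_class for q in queries]
        assert ours == list(clf.predict(queries))

    def test_uniform_weighting_and_tie_goes_inactive(self):
        bundle = make_bundle(
            [0.0, 2.0], [ACTIVE, INACTIVE], k=2, weighting="uniform"
        )
        pred = knn_predict(bundle, [1.0])
        assert pred.vote_weights == {ACTIVE: 1.0, INACTIVE: 1.0}
        assert pred.predicted_class == INACTIVE

    def test_scale_equivariance(self, rng):
        train = rng.normal(size=(12, 3))
        labels = [ACTIVE if i % 2 else INACTIVE for i in range(12)]
        q = rng.normal(size=3)
        s = 3.7
        base = knn_predict(make_bundle(train, labels), q)
        scaled = knn_predict(make_bundle(train * s, labels), q * s)
        assert scaled.predicted_class == base.predicted_class
        assert scaled.domain_distance == pytest.approx(s * base.domain_distance)
        assert scaled.apd_threshold == pytest.approx(s * base.apd_threshold)
        for (_, d0), (_, d1) in zip(base.neighbors, scaled.neighbors):
            assert d1 == pytest.approx(s * d0)

    def test_reliability_monotone_in_threshold(self, rng):
        train = rng.normal(size=(10, 2))
        labels = [ACTIVE] * 5 + [INACTIVE] * 5
        q = rng.normal(size=2) + 5.0
        low = knn_predict(make_bundle(train, labels, z=0.0), q)
        high = knn_predict(make_bundle(train, labels, z=50.0), q)
        assert (not low.reliable) or high.reliable

    def test_input_validation(self):
        bundle = make_bundle([0.0, 1.0], [ACTIVE, INACTIVE], k=2)
        with pytest.raises(ValueError, match="features"):
            knn_predict(bundle, [0.0, 1.0])
        with pytest.raises(ValueError, match="non-finite"):
            knn_predict(bundle, [np.nan])

    def test_extra_neighbor_reporting(self):
        bundle = make_bundle(
            [0.0, 1.0, 2.0, 3.0], [ACTIVE, ACTIVE, INACTIVE, INACTIVE],
            k=3, report_extra_neighbor=True,
        )
        pred = knn_predict(bundle, [0.1])
        assert len(pred.neighbors) == 4
        dists = [d for _, d in pred.neighbors]
        assert dists == sorted(dists)


class TestTrainReadacross:
    def test_default_synthetic_dataset_yields_95_training_rows(self, trained_bundle):
        assert trained_bundle.train_matrix.shape[0] == 95
        assert len(trained_bundle.provenance["test_ids"]) == 41
        assert math.isfinite(trained_bundle.apd.threshold)
        assert trained_bundle.apd.threshold > 0

    def test_training_rows_are_self_reliable(self, trained_bundle):
        for row in trained_bundle.train_matrix[:10]:
            pred = knn_predict(trained_bundle, row)
            assert pred.domain_distance == 0.0
            assert pred.reliable

    def test_single_compound_fails_at_split(self):
        comp = ra.CompoundRecord(compound_id="only", smiles="CC", ec50_uM=1.0)
        table = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["only"])
        with pytest.raises(ValueError):
            train_readacross([comp], table)

    def test_missing_ec50_is_named(self, default_dataset):
        compounds, descriptors, _ = default_dataset
        broken = [
            ra.CompoundRecord(compound_id=c.compound_id, smiles=c.smiles, ec50_uM=None)
            if i == 0
            else c
            for i, c in enumerate(compounds)
        ]
        with pytest.raises(ValueError, match=broken[0].compound_id):
            train_readacross(broken, descriptors)

    def test_full_scope_standardization_runs(self, default_dataset):
        compounds, descriptors, _ = default_dataset
        bundle = ra.train_readacross(
            compounds, descriptors, ra.PipelineConfig(standardization_scope="full")
        )
        assert bundle.train_matrix.shape[0] == 95
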