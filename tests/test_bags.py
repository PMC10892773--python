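import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pdseverity.bags import (
    BagModel,
    CodebookError,
    Document,
    Word,
    build_document,
    export_documents,
    fit_activity_codebooks,
    fit_topic_model,
    fuse_bag_vector,
    topic_vector,
    word_count_vector,
)
from pdseverity.features import WindowFeature


def make_feature(vector, subject="A", activity=1, index=0):
    vector = np.asarray(vector, dtype=float)
    names = tuple(f"f{i}" for i in range(len(vector)))
    return WindowFeature(subject, activity, index, vector, names)


def blob_features(seed=0, n_per=20, dim=5, separation=10.0, activity=1):
    """Two well-separated Gaussian blobs; returns (features, true labels).

    All features belong to one subject with sequential window indices so
    that document word order equals construction order."""
    rng = np.random.default_rng(seed)
    feats, truth = [], []
    for blob in (0, 1):
        center = np.full(dim, blob * separation)
        for i in range(n_per):
            v = center + rng.normal(scale=0.5, size=dim)
            feats.append(make_feature(v, subject="S0", activity=activity,
                                      index=blob * n_per + i))
            truth.append(blob)
    return feats, truth


class TestCodebooks:
    def test_recovers_blobs(self):
        feats, truth = blob_features()
        codebooks, std = fit_activity_codebooks(feats, k=2, seed=0, subjects=["S0"])
        doc = build_document(feats, codebooks, std)
        labels = [w.cluster_id for w in doc.words]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k1_rejected(self):
        feats, _ = blob_features()
        with pytest.raises(CodebookError, match="k must be >= 2"):
            fit_activity_codebooks(feats, k=1, seed=0,
                                   subjects=[f.subject_id for f in feats])

    def test_determinism(self):
        feats, _ = blob_features(seed=3)
        subjects = sorted({f.subject_id for f in feats})
        cb1, _ = fit_activity_codebooks(feats, k=3, seed=5, subjects=subjects)
        cb2, _ = fit_activity_codebooks(feats, k=3, seed=5, subjects=subjects)
        np.testing.assert_array_equal(cb1[1].centroids, cb2[1].centroids)

    def test_too_few_windows_names_activity(self):
        feats = [make_feature([float(i), 0.0], activity=7, index=i) for i in range(3)]
        with pytest.raises(CodebookError, match="activity 7"):
            fit_activity_codebooks(feats, k=4, seed=0, subjects=["A"])

    def test_fit_restricted_to_training_subjects(self):
        rng = np.random.default_rng(0)
        feats = [
            make_feature(rng.normal(size=3), subject=f"S{i % 4}", index=i)
            for i in range(24)
        ]
        train = ["S0", "S1"]
        codebooks, _ = fit_activity_codebooks(feats, k=2, seed=0, subjects=train)
        assert set(codebooks[1].fit_subject_ids) <= set(train)


class TestDocuments:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(8)
        feats = []
        for activity in (2, 5):
            for i in range(12):
                feats.append(make_feature(rng.normal(size=4),
                                          subject=f"S{i%3}", activity=activity,
                                          index=i // 3))
        subjects = ["S0", "S1", "S2"]
        codebooks, std = fit_activity_codebooks(feats, k=2, seed=1, subjects=subjects)
        return feats, codebooks, std

    def test_words_ordered_by_activity_then_index(self, fitted):
        feats, codebooks, std = fitted
        mine = [f for f in feats if f.subject_id == "S0"]
        doc = build_document(mine, codebooks, std)
        keys = [(w.activity_id, i) for i, w in enumerate(doc.words)]
        activities = [w.activity_id for w in doc.words]
        assert activities == sorted(activities)

    def test_missing_codebook_rejected(self, fitted):
        feats, codebooks, std = fitted
        del codebooks[5]
        mine = [f for f in feats if f.subject_id == "S0"]
        with pytest.raises(CodebookError, match="activity 5"):
            build_document(mine, codebooks, std)

    def test_subject_without_one_activity_allowed(self, fitted):
        feats, codebooks, std = fitted
        mine = [f for f in feats if f.subject_id == "S0" and f.activity_id == 2]
        doc = build_document(mine, codebooks, std)
        assert {w.activity_id for w in doc.words} == {2}

    def test_window_at_centroid_assigned_there(self, fitted):
        feats, codebooks, std = fitted
        centroid = codebooks[2].centroids[1]
        raw = std.mean + centroid * std.std  # invert standardization
        doc = build_document([make_feature(raw, activity=2)], codebooks, std)
        assert doc.words[0].cluster_id == 1

    def test_tie_breaks_to_lowest_cluster(self):
        names = tuple(f"f{i}" for i in range(2))
        from pdseverity.bags import ActivityCodebook, Standardizer

        cb = {1: ActivityCodebook(1, 2, np.array([[1.0, 0.0], [-1.0, 0.0]]), ("A",))}
        std = Standardizer(mean=np.zeros(2), std=np.ones(2))
        doc = build_document([make_feature([0.0, 5.0], activity=1)], cb, std)
        assert doc.words[0].cluster_id == 0

    def test_unseen_subject_transform_is_pure(self, fitted):
        feats, codebooks, std = fitted
        before = {a: cb.centroids.copy() for a, cb in codebooks.items()}
        marker = [make_feature(np.full(4, 99.0), subject="MARKER", activity=2)]
        build_document(marker, codebooks, std)
        for a, cb in codebooks.items():
            np.testing.assert_array_equal(before[a], cb.centroids)


class TestWordCounts:
    def test_empty_document(self):
        doc = Document("x", [])
        assert word_count_vector(doc, 8).sum() == 0

    def test_multiplicities(self):
        words = [Word(1, 3, 3), Word(1, 3, 3), Word(1, 7, 7)]
        counts = word_count_vector(Document("x", words), 16)
        assert counts[3] == 2 and counts[7] == 1 and counts.sum() == 3

    def test_order_invariance(self):
        words = [Word(1, i % 4, i % 4) for i in range(10)]
        a = word_count_vector(Document("x", words), 8)
        b = word_count_vector(Document("x", words[::-1]), 8)
        np.testing.assert_array_equal(a, b)

    def test_vocabulary_bijection(self):
        """Distinct (activity, cluster) pairs map to distinct global ids."""
        k, activities = 5, [2, 4, 9]
        ranks = {a: r for r, a in enumerate(sorted(activities))}
        ids = {ranks[a] * k + c for a in activities for c in range(k)}
        assert len(ids) == len(activities) * k
        assert ids == set(range(len(activities) * k))


def two_topic_corpus(seed, n_docs=30, doc_len=40, vocab=16):
    """Documents drawn from 2 disjoint-vocabulary topics."""
    rng = np.random.default_rng(seed)
    matrix = np.zeros((n_docs, vocab), dtype=int)
    truth = []
    for d in range(n_docs):
        topic = d % 2
        lo, hi = (0, vocab // 2) if topic == 0 else (vocab // 2, vocab)
        words = rng.integers(lo, hi, size=doc_len)
        for w in words:
            matrix[d, w] += 1
        truth.append(topic)
    return matrix, truth


class TestTopicModel:
    def test_topic_vector_on_simplex(self):
        matrix, _ = two_topic_corpus(0)
        model = fit_topic_model(matrix, t=2, seed=0)
        for row in matrix:
            theta = topic_vector(model, row)
            assert theta.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(theta >= 0)

    def test_recovers_disjoint_topics(self):
        """DERIVED oracle: the generating topic of each document; mean ARI
        over 10 seeds >= 0.9."""
        scores = []
        for seed in range(10):
            matrix, truth = two_topic_corpus(seed)
            model = fit_topic_model(matrix, t=2, seed=seed)
            assigned = [int(np.argmax(topic_vector(model, row))) for row in matrix]
            scores.append(adjusted_rand_score(truth, assigned))
        assert np.mean(scores) >= 0.9

    def test_all_zero_counts_uniform(self):
        matrix, _ = two_topic_corpus(1)
        model = fit_topic_model(matrix, t=4, seed=0)
        with pytest.warns(UserWarning, match="all-zero"):
            theta = topic_vector(model, np.zeros(16))
        np.testing.assert_allclose(theta, np.full(4, 0.25))

    def test_t1_rejected(self):
        matrix, _ = two_topic_corpus(0)
        with pytest.raises(ValueError, match=">= 2"):
            fit_topic_model(matrix, t=1, seed=0)

    def test_needs_t_documents(self):
        with pytest.raises(ValueError, match="documents"):
            fit_topic_model(np.ones((2, 4), dtype=int), t=3, seed=0)

    def test_determinism(self):
        matrix, _ = two_topic_corpus(2)
        m1 = fit_topic_model(matrix, t=3, seed=9)
        m2 = fit_topic_model(matrix, t=3, seed=9)
        np.testing.assert_array_equal(m1.components_, m2.components_)


class TestFusion:
    def test_paper_dimensions(self):
        # 4 activities x k=8 words + t=4 topics
        counts = np.zeros(32)
        topics = np.full(4, 0.25)
        assert len(fuse_bag_vector(counts, topics)) == 36

    def test_counts_only_ablation(self):
        assert len(fuse_bag_vector(np.zeros(32), None)) == 32

    def test_vertex_topics_preserved(self):
        fused = fuse_bag_vector(np.arange(4), np.array([1.0, 0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(fused[-4:], [1, 0, 0, 0])

    def test_relative_normalization(self):
        fused = fuse_bag_vector(np.array([1.0, 3.0]), None, counts_norm="relative")
        np.testing.assert_allclose(fused, [0.25, 0.75])


class TestBagModel:
    def test_end_to_end_determinism(self, small_features, small_config):
        features, labels, subjects = small_features
        vecs = []
        for _ in range(2):
            model = BagModel(k=4, t=2, seed=3, kmeans_restarts=2).fit(
                features, labels, subjects
            )
            vecs.append(np.stack([
                v.fused for v in model.transform(features, labels, subjects)
            ]))
        np.testing.assert_array_equal(vecs[0], vecs[1])

    def test_counts_sum_to_document_length(self, small_documents):
        model, docs = small_documents
        for doc in docs:
            vec = model.vector_from_document(doc)
            assert vec.counts.sum() == len(doc)
            assert vec.topics.sum() == pytest.approx(1.0, abs=1e-9)

    def test_transform_does_not_mutate_model(self, small_features):
        features, labels, subjects = small_features
        model = BagModel(k=4, t=2, seed=0, kmeans_restarts=2).fit(
            features, labels, subjects[:-1]
        )
        snapshot = {
            "centroids": {a: cb.centroids.copy() for a, cb in model.codebooks.items()},
            "mean": model.standardizer.mean.copy(),
            "components": model.topic_model.components_.copy(),
        }
        model.transform(features, labels, subjects)  # includes unseen subject
        for a, cb in model.codebooks.items():
            np.testing.assert_array_equal(cb.centroids, snapshot["centroids"][a])
        np.testing.assert_array_equal(model.standardizer.mean, snapshot["mean"])
        np.testing.assert_array_equal(
            model.topic_model.components_, snapshot["components"]
        )

    def test_save_load_round_trip(self, small_features, tmp_path, small_config):
        features, labels, subjects = small_features
        model = BagModel(k=4, t=2, seed=1, kmeans_restarts=2).fit(
            features, labels, subjects
        )
        model.save(tmp_path / "bundle")
        loaded = BagModel.load(tmp_path / "bundle")
        a = model.transform(features, labels, subjects)
        b = loaded.transform(features, labels, subjects)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.counts, vb.counts)
            np.testing.assert_allclose(va.topics, vb.topics, atol=1e-6)

    def test_document_export(self, small_documents, tmp_path):
        model, docs = small_documents
        path = export_documents(docs, tmp_path / "docs.txt")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(docs)
        first_ids = [int(x) for x in lines[0].split("\t")[1].split()]
        assert first_ids == docs[0].word_ids()
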