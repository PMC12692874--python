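"""Logit-matrix analysis: selection, PCA, clustering, markers, grouping,
enrichment, projection."""

import numpy as np
import pandas as pd
import pytest

import bindtext as bt
from bindtext.embedding import LogitMatrix, default_n_keep


def _matrix(values, targets=None):
    values = np.asarray(values, dtype=float)
    n, v = values.shape
    targets = targets if targets is not None else ["T"] * n
    meta = pd.DataFrame({"target": targets, "ligand_id": ["L"] * n,
                         "pose_id": [str(i) for i in range(n)]})
    return LogitMatrix(values=values, row_meta=meta, tokens=[f"tok{j}" for j in range(v)])


def _blobs(n_per=30, centers=((0, 8), (8, 0), (-8, -8)), dim=10, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, c in enumerate(centers):
        mu = np.zeros(dim)
        mu[:2] = c
        rows.append(rng.normal(size=(n_per, dim)) + mu)
        labels += [f"T{k + 1}"] * n_per
    return np.vstack(rows), np.array(labels)


class TestBuildLogitMatrix:
    def test_shape_and_row_definition(self, trained_model, synthetic_corpus,
                                      word_vocab, max_len, logit_matrix):
        assert logit_matrix.values.shape == (len(synthetic_corpus), len(word_vocab))
        s = bt.encode_sample(synthetic_corpus[7], word_vocab, max_len)
        assert np.allclose(logit_matrix.values[7], bt.sequence_logits(trained_model, s))

    def test_permutation_equivariance(self, trained_model, synthetic_corpus,
                                      word_vocab, max_len, logit_matrix):
        perm = [5, 0, 2]
        lm2 = bt.build_logit_matrix(trained_model,
                                    [synthetic_corpus[i] for i in perm],
                                    word_vocab, max_len)
        assert np.allclose(lm2.values, logit_matrix.values[perm])

    def test_unencodable_sentence_skipped(self, trained_model, synthetic_corpus,
                                          word_vocab, max_len):
        long = bt.BindingSentence(words=synthetic_corpus[0].words * 50, target="X")
        lm = bt.build_logit_matrix(trained_model, [synthetic_corpus[0], long],
                                   word_vocab, max_len)
        assert lm.n == 1

    def test_save_load_roundtrip(self, logit_matrix, tmp_path):
        logit_matrix.save(str(tmp_path / "m"))
        back = LogitMatrix.load(str(tmp_path / "m"))
        assert np.allclose(back.values, logit_matrix.values)
        assert list(back.row_meta["target"]) == list(logit_matrix.row_meta["target"])


class TestSelectHighVariance:
    def test_constant_column_never_selected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        X[:, 2] = 7.0
        sub = bt.select_high_variance_tokens(_matrix(X), 4)
        assert "tok2" not in sub.tokens

    def test_keep_all_is_identity(self):
        X = np.random.default_rng(1).normal(size=(10, 6))
        sub = bt.select_high_variance_tokens(_matrix(X), 6)
        assert np.allclose(sub.values, X)

    def test_nonpositive_n_keep_rejected(self):
        with pytest.raises(ValueError):
            bt.select_high_variance_tokens(_matrix(np.ones((3, 3))), 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_sd_ranking(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 10)) * rng.uniform(0.1, 5, size=10)
        m = _matrix(X)
        sub, keep = bt.select_high_variance_tokens(m, 4, return_index=True)
        sd = [float(np.std(X[:, j])) for j in range(10)]
        expected = sorted(sorted(range(10), key=lambda j: (-sd[j], j))[:4])
        assert list(keep) == expected

    def test_default_budget(self):
        assert default_n_keep(1000) == 750
        assert default_n_keep(100) == 97


class TestReducePca:
    def test_rank_one_data_captured_by_first_component(self):
        t = np.linspace(-3, 3, 50)
        X = np.stack([t, 2 * t], axis=1)
        scores, pca = bt.reduce_pca(_matrix(X), 2, return_model=True)
        assert pca.explained_variance_ratio_[0] > 0.999

    def test_reconstruction_error_monotone_in_components(self):
        X = np.random.default_rng(2).normal(size=(30, 8))
        Xc = X - X.mean(0)
        errs = []
        for k in (1, 3, 5, 8):
            scores, pca = bt.reduce_pca(_matrix(X), k, return_model=True)
            errs.append(float(((Xc - scores @ pca.components_) ** 2).sum()))
        assert errs == sorted(errs, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_scores_match_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 7))
        scores = bt.reduce_pca(_matrix(X), 4)
        Xc = X - X.mean(0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle = U[:, :4] * S[:4]
        for j in range(4):
            assert (np.allclose(scores[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(scores[:, j], -oracle[:, j], atol=1e-8))

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            bt.reduce_pca(_matrix(np.ones((4, 3))), 5)

    def test_sign_convention_deterministic(self):
        X = np.random.default_rng(3).normal(size=(12, 6))
        s1, p1 = bt.reduce_pca(_matrix(X), 3, return_model=True)
        s2, p2 = bt.reduce_pca(_matrix(X), 3, return_model=True)
        assert np.allclose(s1, s2)
        for j in range(3):
            load = p1.components_[j]
            assert load[np.argmax(np.abs(load))] > 0


class TestEmbedAndCluster:
    def test_separated_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        X, truth = _blobs(seed=4)
        cm = bt.embed_and_cluster(X, n_neighbors=10, seed=0)
        assert adjusted_rand_score(truth, cm.labels) >= 0.8

    def test_same_seed_identical(self):
        X, _ = _blobs(n_per=20, seed=5)
        a = bt.embed_and_cluster(X, n_neighbors=10, seed=1)
        b = bt.embed_and_cluster(X, n_neighbors=10, seed=1)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.coords2d, b.coords2d)

    def test_duplicated_blocks_co_cluster(self):
        rng = np.random.default_rng(6)
        block = rng.normal(size=(12, 6))
        X = np.vstack([block + [20, 0, 0, 0, 0, 0], block - 20,
                       rng.normal(size=(12, 6))])
        cm = bt.embed_and_cluster(X, n_neighbors=5, seed=0)
        for start in (0, 12):
            assert len(set(cm.labels[start:start + 12].tolist())) == 1

    def test_degenerate_identical_rows_single_cluster(self):
        X = np.ones((20, 4))
        with pytest.warns(UserWarning):
            cm = bt.embed_and_cluster(X, n_neighbors=5, seed=0)
        assert set(cm.labels.tolist()) == {0}

    def test_centroids_cover_labels(self):
        X, _ = _blobs(n_per=16, seed=7)
        cm = bt.embed_and_cluster(X, n_neighbors=8, seed=2)
        assert set(cm.centroids) == set(np.unique(cm.labels).tolist())


class TestClusterMarkers:
    def test_planted_marker_is_top_ranked(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 12))
        labels = np.array([0] * 20 + [1] * 20)
        X[labels == 0, 4] += 6.0      # token 4 is high only in cluster 0
        table = bt.cluster_markers(_matrix(X), labels)
        top_c0 = table[table["cluster"] == 0].iloc[0]
        assert top_c0["token_id"] == 4 and top_c0["direction"] == 1

    def test_q_values_valid_and_monotone_with_p(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 10))
        labels = np.array([0] * 15 + [1] * 15)
        table = bt.cluster_markers(_matrix(X), labels)
        assert table["q"].between(0, 1).all()
        for _, grp in table.groupby("cluster"):
            by_p = grp.sort_values("p")
            assert by_p["q"].is_monotonic_increasing

    def test_permuted_labels_rarely_significant(self):
        """Null calibration: with labels shuffled, clusters with any q < 0.05
        stay at the nominal false-positive level across 100 permutations."""
        rng = np.random.default_rng(10)
        X = rng.normal(size=(45, 12))
        X[:15, 3] += 5.0
        base = np.array([0] * 15 + [1] * 15 + [2] * 15)
        m = _matrix(X)
        flagged = total = 0
        for _ in range(100):
            perm = rng.permutation(base)
            table = bt.cluster_markers(m, perm)
            for _, grp in table.groupby("cluster"):
                total += 1
                flagged += (grp["q"] < 0.05).any()
        assert flagged / total <= 0.05

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            bt.cluster_markers(_matrix(np.ones((6, 3))), np.zeros(6, dtype=int))


class TestHierarchicalGrouping:
    def test_identical_means_merge_first(self):
        X = np.vstack([np.tile([1.0, 0.0], (4, 1)), np.tile([1.0, 0.0], (4, 1)),
                       np.tile([9.0, 9.0], (4, 1))])
        labels = np.repeat([0, 1, 2], 4)
        mapping, order = bt.group_clusters_hierarchically(_matrix(X), labels, 2)
        assert mapping[0] == mapping[1] != mapping[2]

    def test_identity_grouping_at_n_clusters(self):
        X = np.random.default_rng(11).normal(size=(12, 4))
        labels = np.repeat([0, 1, 2], 4)
        mapping, _ = bt.group_clusters_hierarchically(_matrix(X), labels, 3)
        assert len(set(mapping.values())) == 3

    def test_invalid_n_groups(self):
        X = np.ones((4, 2))
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError):
            bt.group_clusters_hierarchically(_matrix(X), labels, 0)
        with pytest.raises(ValueError):
            bt.group_clusters_hierarchically(_matrix(X), labels, 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_average_linkage(self, seed):
        """Naive agglomerative average linkage over 5 cluster means."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 6))
        labels = np.repeat(np.arange(5), 5)
        mapping, _ = bt.group_clusters_hierarchically(_matrix(X), labels, 3)

        means = [X[labels == c].mean(0) for c in range(5)]
        groups = [{c} for c in range(5)]
        while len(groups) > 3:
            best = None
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    d = np.mean([np.linalg.norm(means[a] - means[b])
                                 for a in groups[i] for b in groups[j]])
                    if best is None or d < best[0]:
                        best = (d, i, j)
            _, i, j = best
            groups[i] |= groups[j]
            del groups[j]
        expected = {c: g for g, members in enumerate(groups) for c in members}
        # compare partitions up to relabeling
        def canon(m):
            seen = {}
            return tuple(seen.setdefault(m[c], len(seen)) for c in range(5))
        assert canon(mapping) == canon(expected)


class TestEnrichment:
    def test_extreme_enrichment_ranks_first(self):
        background = {f"g{i}" for i in range(50)}
        annotation = {"covers": {"g0", "g1", "g2"},
                      "broad": {f"g{i}" for i in range(40)}}
        table = bt.enrich_terms(["g0", "g1", "g2"], annotation, background)
        assert table.iloc[0]["term"] == "covers"

    def test_term_in_more_than_ten_clusters_filtered(self):
        background = {f"g{i}" for i in range(20)}
        annotation = {"ubiquitous": {"g0", "g1"}, "specific": {"g0", "g1"}}
        table = bt.enrich_terms(["g0", "g1"], annotation, background,
                                n_clusters_with_term={"ubiquitous": 11, "specific": 3})
        assert list(table["term"]) == ["specific"]
        boundary = bt.enrich_terms(["g0", "g1"], annotation, background,
                                   n_clusters_with_term={"ubiquitous": 10, "specific": 3})
        assert set(boundary["term"]) == {"ubiquitous", "specific"}

    @pytest.mark.parametrize("k,K,n", [(2, 4, 5), (1, 3, 4), (3, 5, 6)])
    def test_hypergeometric_matches_exact_tail_enumeration(self, k, K, n):
        """Exact tail sum over a 10-gene universe via binomial coefficients."""
        from math import comb

        M = 10
        background = {f"g{i}" for i in range(M)}
        term = {f"g{i}" for i in range(K)}
        cluster = [f"g{i}" for i in range(k)] + [f"g{i}" for i in range(K, K + n - k)]
        assert len(set(cluster)) == n
        table = bt.enrich_terms(cluster, {"t": term}, background)
        expected = sum(comb(K, x) * comb(M - K, n - x) for x in range(k, min(K, n) + 1)) / comb(M, n)
        assert np.isclose(table.iloc[0]["p"], expected)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            bt.enrich_terms(["absent"], {"t": {"g0"}}, {"g0", "g1"})


@pytest.fixture(scope="module")
def reference():
    X, truth = _blobs(n_per=20, dim=8, seed=12)
    m = _matrix(X, targets=list(truth))
    cm, _ = bt.cluster_pipeline(m, n_keep=8, n_components=5, n_neighbors=10, seed=0)
    return m, cm, truth


class TestProjection:
    def test_duplicate_row_lands_on_its_twin(self, reference):
        m, cm, _ = reference
        coord, assigned, joint = bt.project_new_sample(m.values[5], m, cm)
        twin = joint.coords2d[5]
        spread = np.linalg.norm(joint.coords2d - joint.coords2d.mean(0), axis=1).mean()
        assert np.linalg.norm(coord - twin) < 0.25 * spread
        assert assigned == cm.labels[5]

    def test_length_mismatch_rejected(self, reference):
        m, cm, _ = reference
        with pytest.raises(ValueError):
            bt.project_new_sample(np.ones(3), m, cm)

    def test_new_draws_from_a_blob_assigned_to_its_cluster(self, reference):
        m, cm, truth = reference
        rng = np.random.default_rng(13)
        # majority cluster of blob T1 rows
        from collections import Counter
        t1_labels = Counter(cm.labels[np.array(truth) == "T1"].tolist())
        majority = t1_labels.most_common(1)[0][0]
        mu = m.values[np.array(truth) == "T1"].mean(0)
        hits = 0
        n_draws = 10
        for _ in range(n_draws):
            new = mu + rng.normal(size=m.values.shape[1])
            _, assigned, _ = bt.project_new_sample(new, m, cm)
            hits += assigned == majority
        assert hits >= 0.9 * n_draws

    def test_reference_neighbor_structure_stable(self, reference):
        from sklearn.neighbors import NearestNeighbors

        m, cm, _ = reference
        _, _, joint = bt.project_new_sample(m.values[0], m, cm)
        k = 15   # neighborhood at the blob scale (20 rows per blob)
        before = NearestNeighbors(n_neighbors=k + 1).fit(cm.coords2d) \
            .kneighbors(cm.coords2d, return_distance=False)[:, 1:]
        after_coords = joint.coords2d[:-1]
        after = NearestNeighbors(n_neighbors=k + 1).fit(after_coords) \
            .kneighbors(after_coords, return_distance=False)[:, 1:]
        overlap = np.mean([len(set(a) & set(b)) / k for a, b in zip(before, after)])
        assert overlap >= 0.8


class TestRadarWeights:
    def test_on_centroid_weight_one(self):
        w = bt.radar_weights([0.0, 0.0], {"a": [0.0, 0.0], "b": [3.0, 4.0]})
        assert w["a"] == 1.0 and w["b"] == 0.0

    def test_bounded_and_distance_ordered(self):
        centroids = {"a": [1, 0], "b": [5, 0], "c": [2, 2], "d": [-4, 1]}
        w = bt.radar_weights([0.0, 0.0], centroids)
        assert all(0.0 <= v <= 1.0 for v in w.values())
        d = {g: np.hypot(*c) for g, c in centroids.items()}
        order_by_d = sorted(d, key=d.get)
        order_by_w = sorted(w, key=w.get, reverse=True)
        assert order_by_d == order_by_w

    def test_equidistant_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            w = bt.radar_weights([0.0, 0.0], {"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert set(w.values()) == {1.0}
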