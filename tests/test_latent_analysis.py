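"""Latent diagnostics: embedding, similarity metrics, sparsity traces."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragnet.latent_analysis import (DimensionPopulationSummary, LatentMatrix,
                                     dimension_histogram,
                                     dimension_population, embed_corpus,
                                     fingerprint, map_2d, neighbor_query,
                                     similarity_scatter, tanimoto)
from fragnet.smiles_data import (MoleculeRecord, encode_sequence,
                                 enumerate_smiles)


def random_latents(n, d, seed, nonneg=True):
    rng = np.random.default_rng(seed)
    v = rng.random((n, d)) if nonneg else rng.normal(size=(n, d))
    return LatentMatrix(ids=[f"m{i}" for i in range(n)], vectors=v,
                        source_temperature=0.05)


class TestEmbedCorpus:
    def test_shape_and_determinism(self, clustered, small_corpus):
        model, vocab, _ = clustered
        lat1 = embed_corpus(small_corpus, model, vocab)
        lat2 = embed_corpus(small_corpus, model, vocab)
        assert lat1.vectors.shape == (24, model.cfg.d_model)
        np.testing.assert_array_equal(lat1.vectors, lat2.vectors)
        assert lat1.source_temperature == model.cfg.temperature

    def test_enumerated_variant_embeds_differently(self, clustered,
                                                   small_corpus):
        model, vocab, _ = clustered
        rec = small_corpus[0]
        rng = np.random.default_rng(0)
        variant = enumerate_smiles(rec.canonical_smiles, rng)
        while variant == rec.canonical_smiles:
            variant = enumerate_smiles(rec.canonical_smiles, rng)
        z1 = model.embed_sequence(
            encode_sequence(rec.canonical_smiles, vocab, model.cfg.max_len))
        z2 = model.embed_sequence(
            encode_sequence(variant, vocab, model.cfg.max_len))
        assert not np.allclose(z1, z2)

    def test_out_of_vocabulary_token_reported(self, clustered):
        model, vocab, _ = clustered
        bad = [MoleculeRecord(id="sulfur", canonical_smiles="CSC")]
        with pytest.raises(ValueError, match="sulfur"):
            embed_corpus(bad, model, vocab)

    def test_csv_round_trip(self, tmp_path):
        lat = random_latents(6, 4, seed=0)
        path = tmp_path / "latents.csv"
        lat.to_csv(path)
        back = LatentMatrix.from_csv(path)
        assert back.ids == lat.ids
        np.testing.assert_allclose(back.vectors, lat.vectors, rtol=1e-9)


class TestTanimoto:
    def test_identical_smiles_give_one(self):
        assert tanimoto("CCO", "CCO") == 1.0

    def test_matches_set_arithmetic_oracle(self, small_corpus):
        for a, b in [(small_corpus[0], small_corpus[5]),
                     (small_corpus[2], small_corpus[15])]:
            fa = set(fingerprint(a.canonical_smiles).GetOnBits())
            fb = set(fingerprint(b.canonical_smiles).GetOnBits())
            expected = len(fa & fb) / len(fa | fb)
            assert tanimoto(a.canonical_smiles,
                            b.canonical_smiles) == pytest.approx(expected)

    def test_explicit_bit_sets(self):
        # |{1,2,3} & {2,3,4}| / |{1,2,3} | {2,3,4}| = 2/4
        a, b = {1, 2, 3}, {2, 3, 4}
        assert len(a & b) / len(a | b) == 0.5


class TestNeighborQuery:
    def test_self_ranked_first(self, clustered, small_corpus):
        model, vocab, _ = clustered
        lat = embed_corpus(small_corpus, model, vocab)
        hits = neighbor_query(small_corpus[0], lat, small_corpus,
                              "cosine", 5)
        assert hits[0].neighbor_id == small_corpus[0].id
        assert hits[0].cosine == pytest.approx(1.0)
        assert hits[0].euclidean == pytest.approx(0.0)
        assert hits[0].tanimoto == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", ["cosine", "euclidean", "tanimoto"])
    def test_matches_full_scan_oracle(self, clustered, small_corpus, metric):
        model, vocab, _ = clustered
        lat = embed_corpus(small_corpus, model, vocab)
        query = small_corpus[3]
        hits = neighbor_query(query, lat, small_corpus, metric,
                              len(small_corpus))
        # oracle: recompute every value pairwise, sort the same way
        qvec = lat.row(query.id)
        rows = []
        for rec in small_corpus:
            vec = lat.row(rec.id)
            cos = float(qvec @ vec /
                        (np.linalg.norm(qvec) * np.linalg.norm(vec)))
            euc = float(np.linalg.norm(qvec - vec))
            tan = tanimoto(query.canonical_smiles, rec.canonical_smiles)
            rows.append((rec.id, cos, euc, tan))
        key = {"cosine": lambda r: (-r[1], r[0]),
               "euclidean": lambda r: (r[2], r[0]),
               "tanimoto": lambda r: (-r[3], r[0])}[metric]
        expected = [r[0] for r in sorted(rows, key=key)]
        assert [h.neighbor_id for h in hits] == expected

    def test_k_equals_n_is_permutation(self, clustered, small_corpus):
        model, vocab, _ = clustered
        lat = embed_corpus(small_corpus, model, vocab)
        hits = neighbor_query(small_corpus[1], lat, small_corpus,
                              "euclidean", len(small_corpus))
        assert sorted(h.neighbor_id for h in hits) == sorted(lat.ids)

    def test_k_too_large_raises(self, clustered, small_corpus):
        model, vocab, _ = clustered
        lat = embed_corpus(small_corpus, model, vocab)
        with pytest.raises(ValueError):
            neighbor_query(small_corpus[0], lat, small_corpus, "cosine",
                           len(small_corpus) + 1)


class TestSimilarityScatter:
    def test_self_comparison_lies_on_diagonal(self):
        lat = random_latents(8, 5, seed=1)
        rows = similarity_scatter("m0", lat, lat)
        for r in rows:
            assert r["cosine_a"] == pytest.approx(r["cosine_b"])

    def test_one_row_per_non_query_molecule(self):
        lat = random_latents(8, 5, seed=2)
        assert len(similarity_scatter("m3", lat)) == 7

    def test_mismatched_ids_rejected(self):
        la_, lb = random_latents(6, 4, 0), random_latents(7, 4, 0)
        with pytest.raises(ValueError):
            similarity_scatter("m0", la_, lb)

    def test_unit_sphere_law_of_cosines(self):
        """On normalized rows, d^2 = 2 - 2 cos for every pair."""
        lat = random_latents(10, 6, seed=3)
        v = lat.vectors / np.linalg.norm(lat.vectors, axis=1, keepdims=True)
        norm = LatentMatrix(ids=lat.ids, vectors=v, source_temperature=0.05)
        cos_rows = similarity_scatter("m0", norm, pair=("cosine", "euclidean"))
        for r in cos_rows:
            assert r["euclidean_b"] ** 2 == pytest.approx(
                2 - 2 * r["cosine_a"], abs=1e-6)


class TestDimensionPopulation:
    @pytest.mark.parametrize("matrix,expected", [
        (np.zeros((3, 4)), (0, 0.0, 0)),
        (np.eye(4), (0, 1.0, 1)),
        (np.array([[1.0, 1.0], [1.0, 0.0]]), (1, 1.5, 2)),
    ])
    def test_hand_computed_traces(self, matrix, expected):
        lat = LatentMatrix(ids=[f"m{i}" for i in range(matrix.shape[0])],
                           vectors=matrix, source_temperature=0.05)
        s = dimension_population(lat)
        assert (s.always_nonzero, s.mean_nonzero, s.max_nonzero) == expected
        assert s.dimensionality == matrix.shape[1]

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 12), st.integers(1, 12), st.integers(0, 10 ** 6))
    def test_ordering_invariant(self, n, d, seed):
        rng = np.random.default_rng(seed)
        v = rng.random((n, d)) * (rng.random((n, d)) > 0.4)
        s = dimension_population(LatentMatrix(
            ids=[f"m{i}" for i in range(n)], vectors=v,
            source_temperature=0.05))
        assert 0 <= s.always_nonzero <= s.mean_nonzero
        assert s.mean_nonzero <= s.max_nonzero <= s.dimensionality

    def test_epsilon_threshold(self):
        lat = LatentMatrix(ids=["a"], vectors=np.array([[0.05, 0.5]]),
                           source_temperature=0.05)
        assert dimension_population(lat, epsilon=0.1).mean_nonzero == 1.0


class TestDimensionHistogram:
    def test_counts_sum_to_n(self):
        lat = random_latents(40, 6, seed=5)
        counts, _, _ = dimension_histogram(lat, [], dim=2, n_bins=7)
        assert counts.sum() == 40

    def test_constant_column_single_bin(self):
        v = np.ones((10, 3))
        lat = LatentMatrix(ids=[f"m{i}" for i in range(10)], vectors=v,
                           source_temperature=0.05)
        counts, _, _ = dimension_histogram(lat, [], dim=1, n_bins=5)
        assert (counts > 0).sum() == 1
        assert counts.sum() == 10

    def test_hand_placed_two_bins_with_representatives(self):
        v = np.array([[0.0], [0.1], [0.9], [1.0]])
        lat = LatentMatrix(ids=["a", "b", "c", "d"], vectors=v,
                           source_temperature=0.05)
        counts, edges, reps = dimension_histogram(lat, [], dim=0, n_bins=2,
                                                  representatives_per_bin=2)
        assert list(counts) == [2, 2]
        assert set(reps[0]) == {"a", "b"}
        assert set(reps[1]) == {"c", "d"}

    def test_dim_out_of_range(self):
        lat = random_latents(5, 3, seed=0)
        with pytest.raises(ValueError):
            dimension_histogram(lat, [], dim=3)


class TestMap2d:
    def _clustered_latents(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0, 0, 0], [10, 10, 0, 0], [0, 10, 10, 0]],
                           dtype=float)
        vecs, ids = [], []
        for c, center in enumerate(centers):
            for j in range(10):
                vecs.append(center + rng.normal(scale=0.3, size=4))
                ids.append(f"c{c}_{j}")
        return LatentMatrix(ids=ids, vectors=np.abs(np.array(vecs)),
                            source_temperature=0.05)

    def test_tsne_shape_and_determinism(self):
        lat = self._clustered_latents()
        c1 = map_2d(lat, "tsne", seed=4)
        c2 = map_2d(lat, "tsne", seed=4)
        assert c1.shape == (30, 2)
        np.testing.assert_allclose(c1, c2)

    def test_tsne_preserves_cluster_neighborhoods(self):
        lat = self._clustered_latents()
        coords = map_2d(lat, "tsne", seed=4)
        cluster = np.repeat(np.arange(3), 10)
        good = 0
        for i in range(30):
            d = np.linalg.norm(coords - coords[i], axis=1)
            nn = np.argsort(d)[1:6]
            if (cluster[nn] == cluster[i]).sum() >= 3:
                good += 1
        assert good >= 27  # majority of 5-NN share the cluster

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            map_2d(random_latents(4, 3, 0), "tsne", seed=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            map_2d(random_latents(8, 3, 0), "pca", seed=0)
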