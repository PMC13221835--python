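"""Variant preparation, k-mer embedding, silhouette scoring."""
import numpy as np
import pytest

from toxprotkit.embedding_eval import (
    EmbeddingMatrix,
    KmerEmbedder,
    SilhouetteError,
    Variant,
    compare_variants,
    mock_embed,
    prepare_variant,
    silhouette_by_family,
)
from toxprotkit.swissprot_io import Dataset, Feature, FeatureKind

from conftest import make_entry

SEQ100 = "ACDEFGHIKLMNPQRSTVWY" * 5


def _dataset():
    plain = make_entry(accession="P00001", sequence=SEQ100)
    signed = make_entry(
        accession="P00002", sequence=SEQ100,
        features=[Feature(FeatureKind.SIGNAL, 1, 20),
                  Feature(FeatureKind.PROPEP, 21, 35)],
    )
    frag = make_entry(
        accession="P00003", sequence=SEQ100, is_fragment=True,
        features=[Feature(FeatureKind.SIGNAL, 1, 20)],
    )
    return Dataset(entries=[plain, signed, frag])


class TestPrepareVariant:
    def test_signal_excised(self):
        pairs = dict(prepare_variant(_dataset(), Variant.SIGNAL_REMOVED))
        assert len(pairs["P00002"]) == 80
        assert pairs["P00002"] == SEQ100[20:]

    def test_signal_and_propep_excised(self):
        pairs = dict(prepare_variant(_dataset(), Variant.SIGNAL_PROPEP_REMOVED))
        assert len(pairs["P00002"]) == 65

    def test_fragment_present_then_absent(self):
        with_frag = dict(prepare_variant(_dataset(), Variant.SIGNAL_REMOVED))
        without = dict(prepare_variant(_dataset(), Variant.SIGNAL_REMOVED_NOFRAG))
        assert "P00003" in with_frag
        assert "P00003" not in without

    def test_featureless_entry_identical_under_all_variants(self):
        for variant in Variant:
            pairs = dict(prepare_variant(_dataset(), variant))
            assert pairs["P00001"] == SEQ100

    def test_empty_result_dropped_with_warning(self, caplog):
        e = make_entry(accession="P00009", sequence="A" * 30,
                       features=[Feature(FeatureKind.SIGNAL, 1, 30)])
        with caplog.at_level("WARNING"):
            pairs = prepare_variant(Dataset(entries=[e]), Variant.SIGNAL_REMOVED)
        assert pairs == []
        assert "P00009" in caplog.text


class TestMockEmbed:
    def test_k1_homopolymer_is_unit_weight(self):
        m = mock_embed([("x", "AAAA")], k=1)
        assert m.dim == 20
        assert m.vectors[0, 0] == 1.0  # alphabet starts with A
        assert m.vectors[0, 1:].sum() == 0.0

    def test_identical_sequences_identical_vectors(self):
        m = mock_embed([("a", SEQ100), ("b", SEQ100)], k=2)
        assert np.array_equal(m.vectors[0], m.vectors[1])

    def test_deterministic_bit_identical(self):
        pairs = [("a", SEQ100), ("b", SEQ100[::-1])]
        m1, m2 = mock_embed(pairs, k=2), mock_embed(pairs, k=2)
        assert np.array_equal(m1.vectors, m2.vectors)

    def test_short_sequence_zero_vector_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m = mock_embed([("short", "AB")], k=3)
        assert m.vectors.sum() == 0.0
        assert "short" in caplog.text

    def test_frequencies_sum_to_one(self):
        m = mock_embed([("a", SEQ100)], k=2)
        assert m.vectors[0].sum() == pytest.approx(1.0)


def _matrix(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"P{i}" for i in range(len(points))]
    return EmbeddingMatrix(ids=tuple(ids), vectors=points)


def _brute_silhouette(points, labels):
    """Exhaustive pairwise-distance silhouette."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        a = np.mean([dist[i, j] for j in same])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestSilhouette:
    def test_coincident_families_at_distinct_locations_score_one(self):
        m = _matrix([[0, 0], [0, 0], [5, 5], [5, 5]])
        labels = {"P0": "X", "P1": "X", "P2": "Y", "P3": "Y"}
        r = silhouette_by_family(m, labels, top_n=5)
        assert r.mean_silhouette == pytest.approx(1.0)
        assert r.n_families == 2 and r.n_proteins == 4

    def test_four_point_configuration_matches_brute_force(self):
        points = [[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [9.0, 2.0]]
        labels_list = ["X", "X", "Y", "Y"]
        m = _matrix(points)
        labels = {f"P{i}": fam for i, fam in enumerate(labels_list)}
        r = silhouette_by_family(m, labels, top_n=5)
        assert r.mean_silhouette == pytest.approx(
            _brute_silhouette(points, labels_list), abs=1e-12
        )

    def test_larger_configuration_matches_brute_force(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(12, 3))
        labels_list = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        m = _matrix(points)
        labels = {f"P{i}": fam for i, fam in enumerate(labels_list)}
        r = silhouette_by_family(m, labels, top_n=5)
        assert r.mean_silhouette == pytest.approx(
            _brute_silhouette(points, labels_list), abs=1e-12
        )

    def test_single_family_is_error(self):
        m = _matrix([[0, 0], [1, 1]])
        with pytest.raises(SilhouetteError):
            silhouette_by_family(m, {"P0": "X", "P1": "X"}, top_n=5)

    def test_singleton_families_excluded(self):
        m = _matrix([[0, 0], [1, 1], [2, 2]])
        labels = {"P0": "X", "P1": "Y", "P2": "Z"}
        with pytest.raises(SilhouetteError):
            silhouette_by_family(m, labels, top_n=5)

    def test_unassigned_entries_excluded(self):
        m = _matrix([[0, 0], [0, 0], [5, 5], [5, 5], [99, 99]])
        labels = {"P0": "X", "P1": "X", "P2": "Y", "P3": "Y", "P4": "Unassigned"}
        r = silhouette_by_family(m, labels, top_n=5)
        assert r.n_proteins == 4

    def test_degenerate_identical_points_score_zero(self, caplog):
        m = _matrix([[1, 1]] * 4)
        labels = {"P0": "X", "P1": "X", "P2": "Y", "P3": "Y"}
        with caplog.at_level("WARNING"):
            r = silhouette_by_family(m, labels, top_n=5)
        assert r.mean_silhouette == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        points = rng.normal(size=(10, 4))
        labels_list = ["A"] * 5 + ["B"] * 5
        labels = {f"P{i}": fam for i, fam in enumerate(labels_list)}
        base = silhouette_by_family(_matrix(points), labels, top_n=5)
        perm = rng.permutation(10)
        shuffled = _matrix(points[perm], ids=[f"P{i}" for i in perm])
        assert silhouette_by_family(
            shuffled, labels, top_n=5
        ).mean_silhouette == pytest.approx(base.mean_silhouette, abs=1e-12)

    def test_range_bounds(self, small_records):
        dataset = Dataset(entries=[r.entry for r in small_records])
        labels = {r.accession: r.family for r in small_records}
        reports = compare_variants(dataset, labels, KmerEmbedder(k=2), top_n=10)
        for r in reports:
            assert -1.0 <= r.mean_silhouette <= 1.0


class TestCompareVariants:
    def test_reports_in_canonical_order(self, small_records):
        dataset = Dataset(entries=[r.entry for r in small_records])
        labels = {r.accession: r.family for r in small_records}
        reports = compare_variants(dataset, labels, KmerEmbedder(k=2), top_n=10)
        assert [r.variant for r in reports] == list(Variant)
        assert sum(r.selected for r in reports) == 1

    def test_planted_structure_signal_removal_improves_separation(
        self, small_records
    ):
        """Family motifs live in the mature core; signal peptides are
        noise, so removing them must sharpen family separation."""
        dataset = Dataset(entries=[r.entry for r in small_records])
        labels = {r.accession: r.family for r in small_records}
        reports = {
            r.variant: r.mean_silhouette
            for r in compare_variants(dataset, labels, KmerEmbedder(k=2), top_n=10)
        }
        assert reports[Variant.SIGNAL_REMOVED] > reports[Variant.FULL]

    def test_provider_failure_carries_variant_context(self, small_records):
        dataset = Dataset(entries=[r.entry for r in small_records[:10]])
        labels = {r.accession: r.family for r in small_records[:10]}

        def broken(pairs):
            raise OSError("backend down")

        with pytest.raises(RuntimeError, match="full"):
            compare_variants(dataset, labels, broken, top_n=10)
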