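import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from creglink.genomics_io import CountMatrix, FragmentSet, GenomicInterval
from creglink.matrices import (
    bin_genome_counts,
    feature_matrix,
    filter_top_features,
    lognormalize,
    lsi_reduce,
    pca_reduce,
    pseudobulk_mean,
    scale_features,
    select_variable_features,
    tfidf,
)

from conftest import frag


def make_matrix(arr, layer="raw", sparse=True):
    arr = np.asarray(arr)
    values = sp.csr_matrix(arr) if sparse else arr.astype(float)
    return CountMatrix(
        values,
        [f"f{i}" for i in range(arr.shape[0])],
        [f"c{j}" for j in range(arr.shape[1])],
        layer,
    )


class TestLognormalize:
    def test_zero_stays_zero(self, small_counts):
        out = lognormalize(small_counts)
        assert out.get("g1", "c2") == 0.0

    def test_closed_form(self):
        m = make_matrix([[9]])
        out = lognormalize(m)
        assert out.get("f0", "c0") == pytest.approx(np.log(10001), rel=1e-9)

    def test_equal_column_values_stay_equal(self):
        out = lognormalize(make_matrix([[2], [2], [2]]))
        col = out.dense()[:, 0]
        assert np.allclose(col, col[0])

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValueError, match="c1"):
            lognormalize(make_matrix([[1, 0], [2, 0]]))

    def test_wrong_layer(self, small_counts):
        with pytest.raises(ValueError):
            lognormalize(lognormalize(small_counts))

    @settings(max_examples=50, deadline=None)
    @given(v1=st.integers(0, 100), v2=st.integers(0, 100), total=st.integers(201, 400))
    def test_strictly_monotone_at_fixed_total(self, v1, v2, total):
        """For cells with equal totals, larger count -> larger value."""
        m = make_matrix([[v1, v2], [total - v1, total - v2]])
        out = lognormalize(m)
        a, b = out.get("f0", "c0"), out.get("f0", "c1")
        if v1 < v2:
            assert a < b
        elif v1 == v2:
            assert a == b
        else:
            assert a > b


class TestVariableFeatures:
    def test_ranking(self):
        # variances across cells: rows engineered as [3-ish, tiny, middle]
        m = make_matrix([[0, 6, 0, 6], [1, 1, 1, 2], [0, 3, 0, 3]], layer="raw")
        log = lognormalize(m)
        top2 = select_variable_features(log, 2)
        var = np.var(log.dense(), axis=1)
        expected = [log.feature_ids[i] for i in np.argsort(-var, kind="stable")[:2]]
        assert top2 == expected

    def test_constant_feature_last(self):
        m = make_matrix([[5, 5, 5], [1, 9, 1]])
        log = lognormalize(m)
        assert select_variable_features(log, 2)[-1] != "f1"

    def test_all_features(self, small_counts):
        log = lognormalize(small_counts)
        assert set(select_variable_features(log, 3)) == {"g1", "g2", "g3"}

    def test_bad_n(self, small_counts):
        log = lognormalize(small_counts)
        with pytest.raises(ValueError):
            select_variable_features(log, 0)
        with pytest.raises(ValueError):
            select_variable_features(log, 4)


class TestScaleFeatures:
    def test_hand_standardization(self):
        m = make_matrix([[1, 2, 3]], layer="lognorm")
        out = scale_features(m).dense()[0]
        assert out.mean() == pytest.approx(0)
        assert out.std() == pytest.approx(1)
        np.testing.assert_allclose(out, [-1.22474487, 0, 1.22474487], rtol=1e-6)

    def test_constant_row_zeros(self):
        m = make_matrix([[4, 4, 4]], layer="lognorm")
        assert np.all(scale_features(m).dense() == 0)

    def test_idempotent(self, rng):
        m = make_matrix(rng.poisson(5, (6, 10)), layer="lognorm")
        once = scale_features(m)
        twice = scale_features(
            CountMatrix(once.values, once.feature_ids, once.cell_barcodes, "lognorm")
        )
        np.testing.assert_allclose(once.dense(), twice.dense(), atol=1e-12)


class TestPca:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=10)
        data = np.outer(base, rng.normal(size=30))
        m = make_matrix(data, layer="lognorm", sparse=False)
        red = pca_reduce(scale_features(m), k=5)
        total = (red.singular_values**2).sum()
        assert red.singular_values[0] ** 2 / total > 0.999

    def test_matches_dense_eigendecomposition(self, rng):
        data = rng.normal(size=(10, 10))
        scaled = scale_features(make_matrix(data, layer="lognorm", sparse=False))
        red = pca_reduce(scaled, k=10)
        x = scaled.dense().T  # cells x features, feature-centered
        eigvals = np.linalg.eigvalsh(x.T @ x)[::-1]
        np.testing.assert_allclose(red.singular_values**2, eigvals[:10], rtol=1e-8, atol=1e-8)

    def test_reconstruction_error_decreases(self, rng):
        data = rng.normal(size=(20, 40))
        scaled = scale_features(make_matrix(data, layer="lognorm", sparse=False))
        x = scaled.dense().T
        errors = []
        red = pca_reduce(scaled, k=10)
        u = red.embedding / red.singular_values[None, :]
        for k in (2, 5, 10):
            approx = (u[:, :k] * red.singular_values[:k]) @ (
                np.linalg.pinv(u[:, :k] * red.singular_values[:k]) @ x
            )
            errors.append(np.linalg.norm(x - approx))
        assert errors[0] > errors[1] > errors[2]


class TestFeatureMatrix:
    peaks = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)]

    def test_overlap_counted(self):
        frags = FragmentSet.from_records([frag("chr1", 10, 110, "c1", 2)])
        m = feature_matrix(frags, self.peaks, ["c1"])
        assert m.dense()[0, 0] == 2

    def test_bookended_not_counted(self):
        frags = FragmentSet.from_records([frag("chr1", 10, 100, "c1")])
        m = feature_matrix(frags, self.peaks, ["c1"])
        assert m.dense().sum() == 0

    def test_spanning_fragment_counted_in_both(self):
        frags = FragmentSet.from_records([frag("chr1", 150, 350, "c1")])
        m = feature_matrix(frags, self.peaks, ["c1"])
        np.testing.assert_array_equal(m.dense()[:, 0], [1, 1])

    def test_brute_force_oracle(self, rng):
        # non-overlapping random peaks
        starts = np.cumsum(rng.integers(50, 300, size=30))
        peaks = [
            GenomicInterval("chr1", int(s), int(s + rng.integers(20, 200)))
            for s in starts
        ]
        peaks = [p for i, p in enumerate(peaks) if i == 0 or p.start >= peaks[i - 1].end]
        cells = [f"c{j}" for j in range(5)]
        records = []
        for _ in range(200):
            s = int(rng.integers(0, 8000))
            records.append(
                frag(
                    "chr1",
                    s,
                    s + int(rng.integers(1, 400)),
                    str(rng.choice(cells)),
                    int(rng.integers(1, 4)),
                )
            )
        frags = FragmentSet.from_records(records)
        m = feature_matrix(frags, peaks, cells).dense()
        oracle = np.zeros_like(m)
        for r in records:
            j = cells.index(r.barcode)
            for i, p in enumerate(peaks):
                if r.interval.overlaps(p):
                    oracle[i, j] += r.count
        np.testing.assert_array_equal(m, oracle)


class TestFilterTopFeatures:
    def test_threshold_semantics(self):
        m = make_matrix([[2, 2], [2, 3], [1, 3]])
        out = filter_top_features(m, min_cutoff=5)
        assert out.feature_ids == ["f1"]  # total 4 dropped, total 5 kept

    def test_empty(self):
        m = make_matrix(np.zeros((0, 3), dtype=int))
        assert filter_top_features(m).feature_ids == []


class TestTfidf:
    def test_closed_form_single_entry(self):
        m = make_matrix([[4]])
        out = tfidf(m)
        assert out.get("f0", "c0") == pytest.approx(np.log(1 + 2500), rel=1e-9)

    def test_zero_count_zero(self):
        m = make_matrix([[4, 0], [1, 5]])
        assert tfidf(m).get("f0", "c1") == 0.0

    def test_identical_cells_identical_columns(self):
        m = make_matrix([[3, 3], [1, 1]])
        d = tfidf(m).dense()
        np.testing.assert_allclose(d[:, 0], d[:, 1])


class TestLsi:
    def test_component_count_and_ordering(self, rng):
        m = make_matrix(rng.poisson(3, (8, 6)))
        red = lsi_reduce(tfidf(m), k=4)
        assert red.embedding.shape == (6, 4)
        assert np.all(np.diff(red.singular_values) <= 1e-9)
        assert red.component_range == (2, 4)

    def test_matches_dense_svd(self, rng):
        m = make_matrix(rng.poisson(3, (8, 6)))
        t = tfidf(m)
        red = lsi_reduce(t, k=6)
        s = np.linalg.svd(t.dense().T, compute_uv=False)
        np.testing.assert_allclose(red.singular_values, s[:6], rtol=1e-9)


class TestPseudobulk:
    def test_single_cell_group(self):
        log = lognormalize(make_matrix([[2, 8], [0, 1]]))
        (pb,) = pseudobulk_mean(log, {"c0": "g"})
        np.testing.assert_allclose(pb.values, log.dense()[:, 0])
        assert pb.n_cells == 1

    def test_two_cell_mean(self):
        m = CountMatrix(
            np.array([[0.0, 2.0]]), ["f0"], ["c0", "c1"], "lognorm"
        )
        (pb,) = pseudobulk_mean(m, {"c0": "g", "c1": "g"})
        assert pb.values[0] == pytest.approx(1.0)

    def test_loop_oracle_random(self, rng):
        log = lognormalize(make_matrix(rng.poisson(4, (20, 30)) + 1))
        groups = {f"c{j}": f"grp{j % 3}" for j in range(30)}
        pbs = {p.group_id: p for p in pseudobulk_mean(log, groups)}
        dense = log.dense()
        for g in ("grp0", "grp1", "grp2"):
            cols = [j for j in range(30) if groups[f"c{j}"] == g]
            np.testing.assert_allclose(pbs[g].values, dense[:, cols].mean(axis=1))

    def test_permutation_invariance(self, rng):
        m = make_matrix(rng.poisson(4, (10, 12)) + 1)
        log = lognormalize(m)
        groups = {f"c{j}": "g0" if j % 2 else "g1" for j in range(12)}
        perm = rng.permutation(12)
        permuted = log.subset_cells([f"c{j}" for j in perm])
        a = {p.group_id: p.values for p in pseudobulk_mean(log, groups)}
        b = {p.group_id: p.values for p in pseudobulk_mean(permuted, groups)}
        for g in a:
            np.testing.assert_allclose(a[g], b[g])


class TestBinGenomeCounts:
    sizes = {"chr1": 250_000}

    def test_boundary_spanning_fragment(self):
        frags = FragmentSet.from_records([frag("chr1", 99_950, 100_050)])
        labels, counts = bin_genome_counts(frags, self.sizes)
        assert counts.tolist() == [1, 1, 0]

    def test_single_bin_fragment(self):
        frags = FragmentSet.from_records([frag("chr1", 0, 100)])
        _, counts = bin_genome_counts(frags, self.sizes)
        assert counts.tolist() == [1, 0, 0]

    def test_total_contribution_brute_force(self, rng):
        records = [
            frag(
                "chr1",
                int(s := rng.integers(0, 240_000)),
                int(s + rng.integers(1, 20_000)),
                "b",
                int(rng.integers(1, 5)),
            )
            for _ in range(100)
        ]
        frags = FragmentSet.from_records(records)
        _, counts = bin_genome_counts(frags, self.sizes)
        expected = 0
        for r in records:
            bins = [
                b
                for b in range(3)
                if r.interval.start < (b + 1) * 100_000 and r.interval.end > b * 100_000
            ]
            expected += r.count * len(bins)
        assert counts.sum() == expected
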