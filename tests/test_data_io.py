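import numpy as np
import pytest

from spatialcut import data_io
from spatialcut.data_io import (
    CoordinateParseError,
    DuplicateCoordinateError,
    InputTooSmallError,
    SpatialExpressionMatrix,
)


def test_load_tsv_with_coordinate_labels(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("spot\tg1\tg2\n1x1\t1\t0\n1x2\t2\t3\n2x1\t4\t5\n")
    m = data_io.load_expression(p, "tsv")
    assert m.n_spots == 3 and m.n_genes == 2
    np.testing.assert_array_equal(m.coords, [[1, 1], [1, 2], [2, 1]])
    np.testing.assert_array_equal(m.counts, [[1, 0], [2, 3], [4, 5]])


def test_malformed_coordinate_label_names_the_row(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("spot\tg1\n1x1\t1\nnotacoord\t2\n2x1\t3\n")
    with pytest.raises(CoordinateParseError, match="notacoord"):
        data_io.load_expression(p, "tsv")


def test_too_few_spots_rejected(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("spot\tg1\n1x1\t1\n1x2\t2\n")
    with pytest.raises(InputTooSmallError):
        data_io.load_expression(p, "tsv")


def test_duplicate_coordinates_rejected_with_offenders():
    with pytest.raises(DuplicateCoordinateError, match="a.*c"):
        SpatialExpressionMatrix(
            coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]]),
            counts=np.zeros((3, 1)),
            gene_ids=["g"],
            spot_ids=["a", "b", "c"],
        )


@pytest.mark.parametrize("fmt", ["tsv", "csv", "mtx"])
def test_write_load_round_trip(tiny_matrix, tmp_path, fmt):
    path = tmp_path / f"m.{fmt}"
    data_io.write_expression(tiny_matrix, path, fmt)
    back = data_io.load_expression(path, fmt)
    np.testing.assert_allclose(back.coords, tiny_matrix.coords)
    np.testing.assert_allclose(back.counts, tiny_matrix.counts)
    assert back.gene_ids == tiny_matrix.gene_ids
    assert back.spot_ids == tiny_matrix.spot_ids


def test_mtx_preserves_nonzero_count(tmp_path):
    rng = np.random.default_rng(0)
    n, g, nnz = 262, 100, 500
    counts = np.zeros((n, g))
    flat = rng.choice(n * g, size=nnz, replace=False)
    counts.ravel()[flat] = rng.integers(1, 50, nnz)
    m = SpatialExpressionMatrix(
        coords=np.column_stack([np.arange(n) % 20 + rng.random(n) * 0.1,
                                np.arange(n) // 20 + rng.random(n) * 0.1]),
        counts=counts,
        gene_ids=[f"g{i}" for i in range(g)],
        spot_ids=[f"s{i}" for i in range(n)],
    )
    path = tmp_path / "m.mtx"
    data_io.write_expression(m, path, "mtx")
    back = data_io.load_expression(path, "mtx")
    assert np.count_nonzero(back.counts) == nnz


def test_normalize_counts_scale_factors():
    # per-spot totals 10, 20, 40 -> median 20 -> factors 2, 1, 0.5
    m = SpatialExpressionMatrix(
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        counts=np.array([[4.0, 6.0], [5.0, 15.0], [10.0, 30.0]]),
        gene_ids=["g1", "g2"],
        spot_ids=["a", "b", "c"],
    )
    out = data_io.normalize_counts(m)
    np.testing.assert_allclose(out.counts, [[8, 12], [5, 15], [5, 15]])
    assert out.normalized


def test_normalize_counts_zero_total_spot_untouched():
    m = SpatialExpressionMatrix(
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        counts=np.array([[0.0, 0.0], [5.0, 15.0], [10.0, 30.0]]),
        gene_ids=["g1", "g2"],
        spot_ids=["a", "b", "c"],
    )
    out = data_io.normalize_counts(m)
    np.testing.assert_array_equal(out.counts[0], [0, 0])


def test_normalize_counts_idempotent_with_warning(tiny_matrix):
    once = data_io.normalize_counts(tiny_matrix)
    with pytest.warns(UserWarning, match="already normalized"):
        twice = data_io.normalize_counts(once)
    np.testing.assert_array_equal(once.counts, twice.counts)


def test_normalize_preserves_within_spot_proportions():
    rng = np.random.default_rng(3)
    m = SpatialExpressionMatrix(
        coords=rng.random((10, 2)) * 10,
        counts=rng.integers(1, 100, size=(10, 5)).astype(float),
        gene_ids=[f"g{i}" for i in range(5)],
        spot_ids=[f"s{i}" for i in range(10)],
    )
    out = data_io.normalize_counts(m)
    before = m.counts / m.counts.sum(axis=1, keepdims=True)
    after = out.counts / out.counts.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(before, after)
    # the median per-spot total is invariant
    assert np.isclose(
        np.median(out.counts.sum(axis=1)), np.median(m.counts.sum(axis=1)), atol=1e-9
    )


@pytest.mark.parametrize(
    "x,expected", [(0.0, 0.0), (3.0, 2.0), (7.0, 3.0)]
)
def test_log_transform_values(x, expected):
    m = SpatialExpressionMatrix(
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        counts=np.full((3, 1), x),
        gene_ids=["g"],
        spot_ids=["a", "b", "c"],
    )
    out = data_io.log_transform(m, pseudocount=1.0)
    np.testing.assert_allclose(out.counts, expected)
    assert out.log_transformed


def test_filter_genes_threshold_counting():
    # 10 genes nonzero in 1..10 spots; min_spots=5 keeps 6 genes
    n = 10
    counts = np.zeros((n, 10))
    for j in range(10):
        counts[: j + 1, j] = 1.0
    rng = np.random.default_rng(0)
    m = SpatialExpressionMatrix(
        coords=rng.random((n, 2)) * 10,
        counts=counts,
        gene_ids=[f"g{j}" for j in range(10)],
        spot_ids=[f"s{i}" for i in range(n)],
    )
    out = data_io.filter_genes(m, min_spots=5)
    assert out.gene_ids == [f"g{j}" for j in range(4, 10)]
    identity = data_io.filter_genes(m, min_spots=0)
    assert identity.gene_ids == m.gene_ids
    with pytest.raises(ValueError, match="every gene"):
        data_io.filter_genes(m, min_spots=n + 1)


def test_results_round_trip(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {
            "gene": ["a", "b"],
            "p_value": [0.01, 0.5],
            "q_value": [0.02, 0.5],
            "smooth_factor": [10.0, 20.0],
            "n_segments": [3, 1],
        }
    )
    path = tmp_path / "res.tsv"
    data_io.write_results(df, path)
    back = data_io.read_results(path)
    assert list(back.columns[:5]) == ["gene", "p_value", "q_value", "smooth_factor", "n_segments"]
    np.testing.assert_allclose(back.p_value, df.p_value)
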