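import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dacl.schema import (ColumnSpec, DataTable, FeatureSchema, SchemaError,
                         ValidationError, decode_matrix, encode_table,
                         load_table, stratified_split, write_table)


def test_load_flags_missing_cells(small_schema, tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("bmi,hypertension,work_type,stroke\n"
                 "2.0,0,Private,0\n"
                 ",1,Govt_job,1\n"
                 "6.0,NA,children,0\n")
    t = load_table(p, small_schema)
    assert t.missing_mask.sum() == 2
    assert t.missing_mask[1, 0] and t.missing_mask[2, 1]


def test_load_rejects_unknown_level(small_schema, tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("bmi,hypertension,work_type,stroke\n2.0,0,Unknown,0\n")
    with pytest.raises(ValidationError, match="work_type"):
        load_table(p, small_schema)


def test_load_rejects_wrong_header(small_schema, tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("bmi,hypertension,stroke\n2.0,0,0\n")
    with pytest.raises(SchemaError):
        load_table(p, small_schema)


def test_missing_label_rejected(small_schema, tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("bmi,hypertension,work_type,stroke\n2.0,0,Private,\n")
    with pytest.raises(ValidationError, match="label"):
        load_table(p, small_schema)


def test_write_load_round_trip(small_schema, small_table, tmp_path):
    small_table.missing_mask[0, 0] = True
    p = tmp_path / "rt.csv"
    write_table(small_table, p)
    back = load_table(p, small_schema)
    assert np.array_equal(back.missing_mask, small_table.missing_mask)
    obs = ~small_table.missing_mask
    for j, col in enumerate(small_schema.columns):
        a = small_table.values[col.name].to_numpy()
        b = back.values[col.name].to_numpy()
        for i in range(3):
            if obs[i, j]:
                if col.kind == "numeric":
                    assert float(a[i]) == float(b[i])
                else:
                    assert str(a[i]) == str(b[i])


def test_encode_minmax_onehot_binary(small_table):
    enc = encode_table(small_table)
    np.testing.assert_allclose(enc.matrix[:, 0], [0.0, 0.5, 1.0])   # bmi scaled
    np.testing.assert_allclose(enc.matrix[:, 1], [0.0, 1.0, 0.0])   # binary as-is
    onehot = enc.matrix[:, 2:5]
    np.testing.assert_allclose(onehot.sum(axis=1), 1.0)
    assert enc.matrix.shape == (3, 5)
    np.testing.assert_array_equal(enc.label_vector, [0, 1, 0])


def test_encode_constant_column_warns(small_schema):
    values = pd.DataFrame({
        "bmi": [3.0, 3.0], "hypertension": ["0", "1"],
        "work_type": ["Private", "Govt_job"], "stroke": ["0", "1"],
    }, columns=small_schema.names)
    t = DataTable(small_schema, values, np.zeros((2, 4), dtype=bool))
    with pytest.warns(UserWarning, match="zero observed range"):
        enc = encode_table(t)
    np.testing.assert_allclose(enc.matrix[:, 0], 0.5)


def test_encode_mask_expansion(small_table):
    small_table.missing_mask[0, 2] = True   # categorical with 3 levels
    enc = encode_table(small_table)
    assert enc.mask[0, 2:5].all()
    assert enc.mask.sum() == 3
    np.testing.assert_allclose(enc.matrix[0, 2:5], 0.0)  # placeholder


def test_decode_inverse(small_table):
    enc = encode_table(small_table)
    back = decode_matrix(enc, small_table.schema)
    for col in small_table.schema.columns:
        a = small_table.values[col.name].to_numpy()
        b = back.values[col.name].to_numpy()
        if col.kind == "numeric":
            np.testing.assert_allclose(a.astype(float), b.astype(float))
        else:
            assert list(map(str, a)) == list(map(str, b))


def test_decode_argmax_and_inverse_scale(small_table):
    enc = encode_table(small_table)
    enc.matrix[0, 2:5] = [0.1, 0.7, 0.2]
    enc.matrix[0, 0] = 0.5
    back = decode_matrix(enc, small_table.schema)
    assert back.values["work_type"][0] == "Govt_job"
    assert float(back.values["bmi"][0]) == pytest.approx(4.0)  # min 2, max 6


def test_decode_width_mismatch(small_table):
    enc = encode_table(small_table)
    enc.matrix = enc.matrix[:, :3]
    with pytest.raises(SchemaError):
        decode_matrix(enc, small_table.schema)


def _random_table(rng, n=30):
    schema = FeatureSchema(
        columns=(
            ColumnSpec("x", "numeric"),
            ColumnSpec("b", "binary", ("lo", "hi")),
            ColumnSpec("c", "categorical", ("p", "q", "r", "s")),
            ColumnSpec("y", "binary", ("0", "1")),
        ),
        label_column="y",
    )
    values = pd.DataFrame({
        "x": rng.normal(size=n).round(4),
        "b": rng.choice(["lo", "hi"], size=n),
        "c": rng.choice(["p", "q", "r", "s"], size=n),
        "y": rng.choice(["0", "1"], size=n),
    }, columns=schema.names)
    return DataTable(schema, values, np.zeros((n, 4), dtype=bool))


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_encode_decode_round_trip_property(seed):
    """encode/decode is exact on observed cells; encoded entries live in [0,1]."""
    table = _random_table(np.random.default_rng(seed))
    enc = encode_table(table)
    assert enc.matrix.min() >= 0.0 and enc.matrix.max() <= 1.0
    back = decode_matrix(enc, table.schema)
    for col in table.schema.columns:
        a, b = table.values[col.name].to_numpy(), back.values[col.name].to_numpy()
        if col.kind == "numeric":
            np.testing.assert_allclose(a.astype(float), b.astype(float), atol=1e-10)
        else:
            assert list(map(str, a)) == list(map(str, b))


@given(st.integers(0, 10_000), st.floats(0.05, 0.5))
@settings(max_examples=25, deadline=None)
def test_mask_cardinality_conserved(seed, rate):
    """Masked source cells expand to exactly their derived encoded columns."""
    rng = np.random.default_rng(seed)
    table = _random_table(rng)
    width = {"x": 1, "b": 1, "c": 4}
    for j, col in enumerate(table.schema.columns[:-1]):
        table.missing_mask[:, j] = rng.uniform(size=table.n_rows) < rate
    enc = encode_table(table)
    expected = sum(table.missing_mask[:, j].sum() * width[col.name]
                   for j, col in enumerate(table.schema.columns[:-1]))
    assert enc.mask.sum() == expected


def test_stratified_split_sizes_and_determinism(small_schema):
    rng = np.random.default_rng(0)
    n = 100
    values = pd.DataFrame({
        "bmi": rng.normal(size=n), "hypertension": rng.choice(["0", "1"], n),
        "work_type": rng.choice(["Private", "Govt_job", "children"], n),
        "stroke": ["1"] * 10 + ["0"] * 90,
    }, columns=small_schema.names)
    t = DataTable(small_schema, values, np.zeros((n, 4), dtype=bool))
    tr, te = stratified_split(t, 0.2, seed=5)
    assert len(tr) == 80 and len(te) == 20
    assert set(tr) | set(te) == set(range(n)) and not set(tr) & set(te)
    y = t.labels()
    assert y[te].sum() == 2      # 90/10 ratio -> 18 majority + 2 minority
    tr2, te2 = stratified_split(t, 0.2, seed=5)
    assert np.array_equal(tr, tr2) and np.array_equal(te, te2)


def test_stratified_split_rejects_tiny_class(small_schema):
    values = pd.DataFrame({
        "bmi": [1.0, 2.0, 3.0], "hypertension": ["0", "0", "0"],
        "work_type": ["Private"] * 3, "stroke": ["1", "0", "0"],
    }, columns=small_schema.names)
    t = DataTable(small_schema, values, np.zeros((3, 4), dtype=bool))
    with pytest.raises(ValueError):
        stratified_split(t, 0.3, seed=0)
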