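import numpy as np
import pandas as pd
import pytest

from dacl.schema import ColumnSpec, DataTable, FeatureSchema


@pytest.fixture
def small_schema():
    return FeatureSchema(
        columns=(
            ColumnSpec("bmi", "numeric"),
            ColumnSpec("hypertension", "binary", ("0", "1")),
            ColumnSpec("work_type", "categorical", ("Private", "Govt_job", "children")),
            ColumnSpec("stroke", "binary", ("0", "1")),
        ),
        label_column="stroke",
    )


@pytest.fixture
def small_table(small_schema):
    values = pd.DataFrame({
        "bmi": [2.0, 4.0, 6.0],
        "hypertension": ["0", "1", "0"],
        "work_type": ["Private", "Govt_job", "children"],
        "stroke": ["0", "1", "0"],
    }, columns=small_schema.names)
    mask = np.zeros((3, 4), dtype=bool)
    return DataTable(small_schema, values, mask)
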