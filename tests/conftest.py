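import numpy as np
import pandas as pd
import pytest

from claimscope.schema import ClaimsTable, FeatureSchema


@pytest.fixture
def tiny_schema():
    return FeatureSchema(
        entity_id_column="gp_id",
        categorical_columns=("spec", "code"),
        numerical_columns=("amount",),
    )


@pytest.fixture
def tiny_table(tiny_schema):
    df = pd.DataFrame(
        {
            "gp_id": ["a", "a", "a", "b", "b", "c"],
            "spec": ["GP", "GP", "GP", "GP", "ORT", "GP"],
            "code": ["X", "X", "Y", "Y", "Z", "X"],
            "amount": [1.0, 2.0, 3.0, 10.0, 20.0, 5.0],
        }
    )
    return ClaimsTable(df, tiny_schema)


def make_table(rows, schema):
    """Build a ClaimsTable from (entity, cat..., num...) tuples."""
    cols = [schema.entity_id_column, *schema.categorical_columns, *schema.numerical_columns]
    df = pd.DataFrame(rows, columns=cols)
    return ClaimsTable(df, schema)


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale labeled benchmark shared across detector/consensus tests."""
    from claimscope.synthetic import default_benchmark

    return default_benchmark(seed=11, n_entities=400)
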