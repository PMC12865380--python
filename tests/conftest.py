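import numpy as np
import pandas as pd
import pytest

from gfbart.data_model import CohortTable, CovariateSchema


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def simple_schema():
    return CovariateSchema(("bmi", "smoke"), ("continuous", "binary"))


def build_cohort_df(s_mat, r_mat, schema, rng, y_final_only=False,
                    with_treatment=True):
    """Long-format frame from survival/response matrices, values filled
    where observed."""
    n, T = np.asarray(s_mat).shape
    rows = []
    for i in range(n):
        for t in range(1, T + 1):
            s = int(s_mat[i][t - 1])
            r = int(r_mat[i][t - 1])
            obs = r == 1
            row = {"id": i, "t": t, "S": s, "R": r}
            for nm, ty in zip(schema.names, schema.types):
                if ty == "binary":
                    row[nm] = float(rng.integers(0, 2)) if obs else np.nan
                else:
                    row[nm] = rng.normal() if obs else np.nan
            if with_treatment:
                row["A"] = rng.normal(120, 15) if obs else np.nan
            y_obs = obs and (t == T if y_final_only else True)
            row["Y"] = rng.normal(50, 5) if y_obs else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def complete_cohort(simple_schema, rng):
    """2 subjects x 4 waves, everyone alive and observed."""
    s = [[1, 1, 1, 1]] * 2
    df = build_cohort_df(s, s, simple_schema, rng)
    return CohortTable(df, simple_schema)
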