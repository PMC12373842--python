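import numpy as np
import pandas as pd
import pytest

from morphoscreen import FeatureMatrix
from morphoscreen.layout import well_name


def make_feature_table(
    values_by_plate,
    roles_by_plate=None,
    n_cols: int = 24,
    feature: str = "median_colony_area",
    extra_features=None,
):
    """Build a small FeatureMatrix from per-plate value lists.

    ``values_by_plate``: {plate_id: [v0, v1, ...]} laid out row-major;
    ``roles_by_plate``: matching role lists (default all "compound").
    """
    rows = []
    for plate, values in values_by_plate.items():
        roles = (roles_by_plate or {}).get(plate, ["compound"] * len(values))
        for i, (v, role) in enumerate(zip(values, roles)):
            r, c = divmod(i, n_cols)
            rec = {
                "plate_id": plate,
                "well": well_name(r, c + 1),
                "role": role,
                "compound_id": f"X{i:03d}" if role == "compound" else None,
                "concentration_um": 1.0 if role == "compound" else np.nan,
                feature: float(v),
            }
            for name, vals in (extra_features or {}).items():
                rec[name] = float(vals[plate][i])
            rows.append(rec)
    return FeatureMatrix(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(3)


@pytest.fixture
def small_random_table(rng):
    """6 wells x 4 features of plain random numbers (one plate, one DMSO)."""
    X = rng.normal(10.0, 3.0, size=(6, 4))
    df = pd.DataFrame(X, columns=["f1", "f2", "f3", "f4"])
    df.insert(0, "plate_id", "P01")
    df.insert(1, "well", [well_name(0, c) for c in range(1, 7)])
    df.insert(2, "role", ["dmso"] + ["compound"] * 5)
    return FeatureMatrix(df)
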