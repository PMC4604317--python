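import numpy as np
import pandas as pd
import pytest


def build_table(
    n: int,
    cohort: str = "toy",
    seed: int = 0,
    sex: np.ndarray | None = None,
    menopause: np.ndarray | None = None,
    urate: np.ndarray | None = None,
    flags: list[str] | None = None,
    **columns,
) -> pd.DataFrame:
    """Hand-rolled cohort table for unit tests (no simulator involved)."""
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = np.where(rng.random(n) < 0.5, "female", "male")
    sex = np.asarray(sex)
    if menopause is None:
        menopause = np.where(sex == "male", "NA",
                             np.where(rng.random(n) < 0.5, "post", "pre"))
    if urate is None:
        urate = 0.3 + 0.05 * rng.standard_normal(n)
    table = pd.DataFrame(
        {
            "id": [f"{cohort}_{i:04d}" for i in range(n)],
            "cohort": cohort,
            "sex": sex,
            "age": columns.pop("age", rng.normal(50, 8, n)),
            "bmi": columns.pop("bmi", rng.normal(26, 4, n)),
            "menopause": menopause,
            "urate": urate,
            "pc1": columns.pop("pc1", rng.standard_normal(n)),
            "pc2": columns.pop("pc2", rng.standard_normal(n)),
            "flags": flags if flags is not None else [""] * n,
        }
    )
    for name, values in columns.items():
        table[name] = values
    table["group"] = np.where(table["sex"] == "male", "men", table["menopause"])
    return table


@pytest.fixture
def toy_table():
    return build_table
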