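import numpy as np
import pandas as pd
import pytest

from assistnet.instrument import SUBSTANCES, substance_items


def make_cohort(rows: list[dict[str, str]], default: str = "never") -> pd.DataFrame:
    """Build a full ASSIST item frame; each row dict maps '<sub>_<item>' to a level.

    Unspecified items default to "never"; a value of None marks a missing cell.
    """
    columns = [f"{s}_{it}" for s in SUBSTANCES for it in substance_items(s)]
    data = []
    for row in rows:
        full = {c: default for c in columns}
        full.update(row)
        data.append(full)
    df = pd.DataFrame(data, columns=columns)
    return df.where(df.notna(), np.nan)


@pytest.fixture
def cohort_builder():
    return make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
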