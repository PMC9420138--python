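import numpy as np
import pandas as pd
import pytest

from snapd import HarmonizationConfig
from snapd.io import RAW_COLUMNS


@pytest.fixture
def config() -> HarmonizationConfig:
    return HarmonizationConfig(rng_seed=1)


def make_raw(rows: list[dict]) -> pd.DataFrame:
    """Build a raw-schema frame from partial row dicts (missing fields -> NA)."""
    defaults = {
        "org_name_raw": "USGS",
        "st_abbr": "IL",
        "st_name": "Illinois",
        "orig_MLI": "S1",
        "orig_x": 1000.0,
        "orig_y": 2000.0,
        "date": "2001-06-15",
        "time": "10:00:00",
        "media": "Water",
        "activity_type": "Sample-Routine",
        "result_type": "Actual",
        "nutrient_handle": "Nitrate as N",
        "analytical_method": None,
        "sample_fraction_raw": "Filtered",
        "orig_conc": "1.0",
        "orig_conc_units": "mg/l",
        "DL_code": None,
        "DL_text": None,
        "orig_DL_val": None,
        "orig_DL_units": None,
        "provider": "NWIS",
    }
    full = []
    for row in rows:
        r = dict(defaults)
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full, columns=RAW_COLUMNS)
    df = df.where(pd.notna(df), np.nan)
    for col in ("orig_x", "orig_y", "orig_DL_val"):
        df[col] = pd.to_numeric(df[col])
    df.insert(0, "record_id", np.arange(len(df), dtype=np.int64))
    return df
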