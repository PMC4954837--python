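"""Date handling.

Internally every table carries integer day indices (day 0 = study
start), which keeps arithmetic on time lags trivial.  CSV files on disk
use ISO-8601 calendar dates; these helpers convert between the two given
the study base date recorded in the run configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_BASE_DATE = "2008-10-01"


def days_to_iso(days, base_date: str = DEFAULT_BASE_DATE) -> pd.Series:
    """Convert integer day offsets to ISO-8601 date strings."""
    base = np.datetime64(base_date, "D")
    arr = base + np.asarray(days, dtype="int64")
    return pd.Series(arr).dt.strftime("%Y-%m-%d")


def iso_to_days(dates, base_date: str = DEFAULT_BASE_DATE) -> np.ndarray:
    """Convert ISO-8601 date strings to integer day offsets."""
    base = np.datetime64(base_date, "D")
    arr = pd.to_datetime(pd.Series(dates)).values.astype("datetime64[D]")
    return (arr - base).astype("int64")
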