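"""Packaged reference data.

``load_toxicity_tables`` returns the published May-2024 field toxicity
results for the 26 white-backed planthopper populations (15 Hunan
destination sites, 11 Guangxi candidate sources): LC50 with 95% CI,
slope +/- SE and chi-square per site and insecticide, plus the letters
as printed.  ``load_sites`` returns the trap/sampling coordinates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

INSECTICIDES = ("pymetrozine", "nitenpyram")


def _read(name: str) -> pd.DataFrame:
    with resources.files("hoppertrace.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_toxicity_tables() -> pd.DataFrame:
    """Both insecticide tables concatenated (one row per site x insecticide)."""
    return pd.concat(
        [_read("toxicity_pymetrozine.csv"), _read("toxicity_nitenpyram.csv")],
        ignore_index=True,
    )


def load_sites() -> pd.DataFrame:
    """Monitoring/sampling site coordinates (site_id, region, lat, lon)."""
    return _read("sites.csv")
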