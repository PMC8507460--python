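"""Packaged reference tables from the 2013 and 2018 Swiss national surveys.

These are the published per-modality and per-CT-region summary values. They
serve three purposes: defaults for the synthetic generator, the prior-survey
baseline for trend comparison, and desk-scale reproduction of the published
headline figures.
"""
from __future__ import annotations

import io
from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    text = (resources.files(__name__) / name).read_text(encoding="utf-8")
    return pd.read_csv(io.StringIO(text))


def load_survey_reference(year: int = 2018) -> pd.DataFrame:
    """Published per-modality table for a survey year.

    2018 carries (modality, frequency_per_1000, dose_vector_msv); 2013 carries
    (modality, frequency_per_1000, dose_per_inhabitant_msv) as published.
    """
    if year == 2018:
        return _read("survey2018.csv")
    if year == 2013:
        return _read("survey2013.csv")
    raise ValueError(f"no packaged reference table for year {year}")


def load_ct_reference() -> pd.DataFrame:
    """Published 2018 per-CT-region frequencies and median effective doses."""
    return _read("ct_regions_2018.csv")


def load_verification_reference() -> pd.DataFrame:
    """Published billing-vs-RIS per-1000 frequencies used for verification."""
    return _read("verification_2018.csv")


#: Published 2018 CT dose-vector estimates computed from each practice stratum
#: alone (mSv); their spread drives the CT uncertainty estimate.
CT_STRATUM_VECTORS_2018: dict[str, float] = {
    "university": 6.73,
    "nonuniversity": 7.5,
}
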