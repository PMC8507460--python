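"""National examination frequencies from partially observed sources.

Billing counts cover only part of the population and are scaled up either by
the covered population fraction or by an activity ratio (imaging acts per
general medical act, assumed homogeneous nationally). Web-survey counts are
scaled by the per-modality response rate. Frequencies are reported per 1000
inhabitants.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from popdose import vocab
from popdose.config import CoverageModel
from popdose.errors import MissingResponseRateError


def _as_series(counts) -> pd.Series:
    s = pd.Series(counts, dtype="float64")
    if (s < 0).any():
        raise ValueError("counts must be non-negative")
    return s


def extrapolate_billing(observed_counts, coverage: CoverageModel) -> pd.Series:
    """Scale observed billing counts to the national level.

    national = observed / factor, with the factor selected by
    ``coverage.mode`` (covered population fraction or activity ratio).
    Accepts any mapping/Series keyed by modality or by (modality, region).
    """
    factor = coverage.factor
    if factor <= 0:
        raise ValueError("extrapolation factor must be positive")
    return _as_series(observed_counts) / factor


def extrapolation_sensitivity(observed_counts, coverage: CoverageModel) -> pd.DataFrame:
    """Both extrapolation modes side by side, for sensitivity reporting."""
    s = _as_series(observed_counts)
    return pd.DataFrame(
        {
            "observed": s,
            "population_scaling": s / coverage.population_covered_fraction,
            "activity_ratio": s / coverage.activity_ratio_factor,
        }
    )


def extrapolate_survey(responding_counts, rates: Mapping[str, float]) -> pd.Series:
    """Scale responding-facility counts by the per-modality response rate."""
    s = _as_series(responding_counts)
    missing = [m for m in s.index if m not in rates]
    if missing:
        raise MissingResponseRateError(missing[0])
    factors = pd.Series({m: rates[m] for m in s.index}, dtype="float64")
    if (factors <= 0).any() or (factors > 1).any():
        raise ValueError("response rates must lie in (0, 1]")
    return s / factors


def per_1000(
    national_counts,
    population_total: float,
    sources: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Frequency table per 1000 inhabitants, with a Total row.

    ``sources`` optionally annotates each modality with the authoritative
    source (billing / society_report / web_survey).
    """
    if population_total <= 0:
        raise ValueError("population_total must be positive")
    s = _as_series(national_counts)
    df = pd.DataFrame(
        {
            "modality": list(s.index),
            "national_count": s.to_numpy(),
            "frequency_per_1000": s.to_numpy() / population_total * 1000.0,
        }
    )
    df["source"] = (
        df["modality"].map(dict(sources)) if sources is not None else np.nan
    )
    total = pd.DataFrame(
        {
            "modality": [vocab.TOTAL],
            "national_count": [df["national_count"].sum()],
            "frequency_per_1000": [df["frequency_per_1000"].sum()],
            "source": [np.nan],
        }
    )
    return pd.concat([df, total], ignore_index=True)


def modality_frequencies(table: pd.DataFrame) -> dict[str, float]:
    """Modality → per-1000 frequency from a frequency table (Total dropped)."""
    body = table[table["modality"] != vocab.TOTAL]
    return dict(zip(body["modality"], body["frequency_per_1000"].astype(float)))
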