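"""CT dosimetry from dose-archive (DACS) DLP records.

The CT contribution to population dose is estimated from real dose indicators
rather than literature values: per anatomical region we take the median dose
length product (DLP, mGy·cm) over all archived acquisitions, convert it to an
effective dose with a region-specific coefficient k (mSv per mGy·cm), and form
the modality dose vector as the examination-frequency-weighted mean of the
per-region effective doses. Records are kept in two practice strata
(university vs non-university facilities); recomputing the vector from each
stratum alone yields a spread whose sample-sd/mean ratio is reported as the
relative uncertainty of the CT dose vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from popdose import vocab
from popdose.errors import MissingConversionFactorError, ModalityMismatchError

#: Illustrative adult DLP-to-effective-dose coefficients (mSv per mGy·cm),
#: keyed by CT region. National conversion coefficients are published
#: externally and are not re-derived here; replace these with locally
#: validated values for production use.
DEFAULT_CONVERSION_FACTORS: dict[str, float] = {
    "head": 0.0021,
    "face/sinus": 0.0021,
    "dental": 0.0021,
    "neck": 0.0051,
    "chest": 0.0145,
    "abdomen": 0.0153,
    vocab.CHEST_ABDOMEN: 0.0149,
    "pelvis": 0.0129,
    "spine": 0.0098,
    "shoulder": 0.0145,
    "elbow": 0.0080,
    "wrist/hand": 0.0080,
    "hip": 0.0129,
    "knee": 0.0080,
    "ankle/foot": 0.0008,
}


def summarize_dlp(
    records: pd.DataFrame,
    conversion_factors: Mapping[str, float] = DEFAULT_CONVERSION_FACTORS,
) -> pd.DataFrame:
    """Per-region DLP medians (pooled and per stratum) and effective doses.

    Parameters
    ----------
    records
        Dose records with columns ``region``, ``dlp_mgycm`` and ``stratum``
        (``university`` / ``nonuniversity``).
    conversion_factors
        Region-keyed k in mSv per mGy·cm; required for every region present.

    Returns
    -------
    One row per region with ``n_records``, pooled ``median_dlp_mgycm`` /
    ``effective_dose_msv`` and the per-stratum columns (NaN where a stratum has
    no records). Medians use the standard convention: mean of the two central
    order statistics for even counts.
    """
    if records.empty:
        raise ValueError("no dose records to summarize")
    unknown = set(records["region"]) - set(vocab.CT_REGIONS)
    if unknown:
        raise ValueError(f"unknown CT regions in dose records: {sorted(unknown)}")
    missing_k = set(records["region"]) - set(conversion_factors)
    if missing_k:
        raise MissingConversionFactorError(
            f"no conversion factor for regions: {sorted(missing_k)}"
        )
    bad = records["dlp_mgycm"]
    if not np.isfinite(bad).all() or (bad < 0).any():
        raise ValueError("DLP values must be finite and non-negative")

    pooled = records.groupby("region", sort=True)["dlp_mgycm"].agg(["size", "median"])
    pooled.columns = ["n_records", "median_dlp_mgycm"]
    by_stratum = records.pivot_table(
        index="region", columns="stratum", values="dlp_mgycm", aggfunc="median"
    )
    out = pooled.reset_index()
    k = out["region"].map(conversion_factors)
    out["effective_dose_msv"] = k * out["median_dlp_mgycm"]
    for stratum in vocab.DOSE_STRATA:
        if stratum in by_stratum:
            out[f"median_dlp_{stratum}_mgycm"] = out["region"].map(by_stratum[stratum])
        else:
            out[f"median_dlp_{stratum}_mgycm"] = np.nan
        out[f"effective_dose_{stratum}_msv"] = k * out[f"median_dlp_{stratum}_mgycm"]
    return out


@dataclass
class CtDoseVector:
    """Frequency-weighted CT effective dose with its per-region decomposition.

    ``value`` is Σ_r share(r) · E(r) in mSv; ``stratum_values`` are the same
    quantity recomputed with stratum-specific E(r) (pooled fallback where a
    stratum lacks records); ``relative_uncertainty`` is sample-sd/mean of the
    stratum values (None with fewer than two strata).
    """

    regions: pd.DataFrame
    value: float
    stratum_values: dict[str, float] = field(default_factory=dict)
    relative_uncertainty: float | None = None


def _region_doses(summaries) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Normalize summaries into pooled and per-stratum region→E mappings."""
    if isinstance(summaries, pd.DataFrame):
        pooled = dict(zip(summaries["region"], summaries["effective_dose_msv"]))
        strata: dict[str, dict[str, float]] = {}
        for stratum in vocab.DOSE_STRATA:
            col = f"effective_dose_{stratum}_msv"
            if col in summaries:
                vals = dict(zip(summaries["region"], summaries[col]))
                strata[stratum] = {
                    r: (v if np.isfinite(v) else pooled[r]) for r, v in vals.items()
                }
        return pooled, strata
    return dict(summaries), {}


def ct_dose_vector(
    summaries,
    frequencies: Mapping[str, float],
    stratum_doses: Mapping[str, Mapping[str, float]] | None = None,
) -> CtDoseVector:
    """Combine per-region effective doses with CT examination frequencies.

    Parameters
    ----------
    summaries
        Either the DataFrame returned by :func:`summarize_dlp` or a plain
        region → effective dose (mSv) mapping.
    frequencies
        Region → examination frequency (any common unit; only shares matter,
        per-1000-inhabitant values are conventional).
    stratum_doses
        Optional stratum → (region → E) mappings overriding those extracted
        from `summaries`.
    """
    pooled, strata = _region_doses(summaries)
    if stratum_doses is not None:
        strata = {s: dict(m) for s, m in stratum_doses.items()}
    freqs = {r: float(f) for r, f in frequencies.items() if f > 0}
    if not freqs:
        raise ValueError("no CT frequencies with positive weight")
    missing = set(freqs) - set(pooled)
    if missing:
        raise ModalityMismatchError(
            f"CT regions with frequency but no dose summary: {sorted(missing)}"
        )
    total = sum(freqs.values())
    rows = []
    for region in sorted(freqs, key=list(vocab.CT_REGIONS).index):
        share = freqs[region] / total
        e = pooled[region]
        rows.append(
            {
                "region": region,
                "frequency_per_1000": freqs[region],
                "share": share,
                "effective_dose_msv": e,
                "dose_contribution_msv": share * e,
            }
        )
    regions = pd.DataFrame(rows)
    value = float(regions["dose_contribution_msv"].sum())
    stratum_values = {
        s: float(sum(freqs[r] / total * doses[r] for r in freqs))
        for s, doses in strata.items()
        if all(r in doses for r in freqs)
    }
    return CtDoseVector(
        regions=regions,
        value=value,
        stratum_values=stratum_values,
        relative_uncertainty=stratum_uncertainty(stratum_values.values()),
    )


def stratum_uncertainty(values: Iterable[float]) -> float | None:
    """Sample-sd (n−1) over mean of per-stratum dose-vector estimates.

    Returns None when fewer than two strata are available, mirroring the
    survey convention of leaving the uncertainty unreported in that case.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2 or not np.isfinite(vals).all():
        return None
    mean = float(np.mean(vals))
    if mean == 0:
        return None
    return float(np.std(vals, ddof=1) / mean)
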