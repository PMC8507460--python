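"""Headline survey outputs and between-survey trend comparison.

The per-inhabitant annual effective dose is Σ_m frequency_m × vector_m / 1000
(frequency per 1000 inhabitants, vector in mSv). Contribution shares use the
nuclear-medicine-inclusive totals as denominator; dental frequency is reported
pooled with CBCT for the headline share. Trend changes are
(new − old)/old × 100 anchored on the earlier survey. All rounding happens at
render time; internal values keep full precision.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from popdose import vocab
from popdose.ct_dose import CtDoseVector
from popdose.errors import ModalityMismatchError

RESULT_COLUMNS = [
    "modality",
    "frequency_per_1000",
    "dose_vector_msv",
    "dose_per_inhabitant_msv",
    "frequency_share_pct",
    "dose_share_pct",
]


@dataclass
class SurveyResult:
    """Per-modality frequencies, dose vectors and per-inhabitant doses."""

    year: int
    table: pd.DataFrame
    total_frequency_with_nm: float
    total_frequency_without_nm: float
    total_dose_with_nm: float
    total_dose_without_nm: float

    @property
    def exams_per_inhabitant(self) -> float:
        return self.total_frequency_with_nm / 1000.0

    @property
    def dental_frequency_share_pct(self) -> float:
        """Dental imaging share (plain dental + CBCT pooled), in %."""
        dental = self.table.loc[
            self.table["modality"].isin(vocab.DENTAL_MODALITIES),
            "frequency_per_1000",
        ].sum()
        return float(dental / self.total_frequency_with_nm * 100.0)

    def share(self, modality: str, of: str = "dose") -> float:
        col = "dose_share_pct" if of == "dose" else "frequency_share_pct"
        row = self.table.loc[self.table["modality"] == modality, col]
        if row.empty:
            raise KeyError(modality)
        return float(row.iloc[0])


def _finish_result(df: pd.DataFrame, year: int) -> SurveyResult:
    has_nm = df["modality"] == vocab.NUCLEAR_MEDICINE
    tot_f = float(df["frequency_per_1000"].sum())
    tot_d = float(df["dose_per_inhabitant_msv"].sum())
    df = df.assign(
        frequency_share_pct=df["frequency_per_1000"] / tot_f * 100.0,
        dose_share_pct=df["dose_per_inhabitant_msv"] / tot_d * 100.0,
    )
    return SurveyResult(
        year=year,
        table=df[RESULT_COLUMNS].reset_index(drop=True),
        total_frequency_with_nm=tot_f,
        total_frequency_without_nm=tot_f - float(df.loc[has_nm, "frequency_per_1000"].sum()),
        total_dose_with_nm=tot_d,
        total_dose_without_nm=tot_d - float(df.loc[has_nm, "dose_per_inhabitant_msv"].sum()),
    )


def build_result(freq_table, dose_table, year: int = 2018) -> SurveyResult:
    """Combine a frequency table with per-modality dose vectors.

    Parameters
    ----------
    freq_table
        DataFrame with ``modality`` and ``frequency_per_1000`` (a Total row is
        ignored), or a plain modality → per-1000 frequency mapping.
    dose_table
        DataFrame with ``modality`` and ``dose_vector_msv``, or a mapping.
        Every modality present in the frequency table must have a vector.
    """
    if isinstance(freq_table, pd.DataFrame):
        body = freq_table[freq_table["modality"] != vocab.TOTAL]
        freqs = dict(zip(body["modality"], body["frequency_per_1000"].astype(float)))
    else:
        freqs = {m: float(f) for m, f in freq_table.items()}
    if isinstance(dose_table, pd.DataFrame):
        doses: Mapping[str, float] = dict(
            zip(dose_table["modality"], dose_table["dose_vector_msv"].astype(float))
        )
    else:
        doses = {m: float(v) for m, v in dose_table.items()}
    missing = set(freqs) - set(doses)
    if missing:
        raise ModalityMismatchError(
            f"modalities without a dose vector: {sorted(missing)}"
        )
    order = {m: i for i, m in enumerate(vocab.MODALITIES)}
    modalities = sorted(freqs, key=lambda m: order.get(m, len(order)))
    df = pd.DataFrame(
        {
            "modality": modalities,
            "frequency_per_1000": [freqs[m] for m in modalities],
            "dose_vector_msv": [doses[m] for m in modalities],
        }
    )
    df["dose_per_inhabitant_msv"] = (
        df["frequency_per_1000"] * df["dose_vector_msv"] / 1000.0
    )
    return _finish_result(df, year)


def survey_result_from_reference(table: pd.DataFrame, year: int) -> SurveyResult:
    """Build a SurveyResult from a published per-modality summary table.

    Accepts either a ``dose_vector_msv`` or a ``dose_per_inhabitant_msv``
    column (the other is derived), as prior surveys publish one or the other.
    """
    df = table.copy()
    df = df[df["modality"] != vocab.TOTAL]
    if "dose_vector_msv" in df and "dose_per_inhabitant_msv" not in df:
        df["dose_per_inhabitant_msv"] = (
            df["frequency_per_1000"] * df["dose_vector_msv"] / 1000.0
        )
    elif "dose_per_inhabitant_msv" in df and "dose_vector_msv" not in df:
        df["dose_vector_msv"] = (
            df["dose_per_inhabitant_msv"] / df["frequency_per_1000"] * 1000.0
        )
    return _finish_result(
        df[["modality", "frequency_per_1000", "dose_vector_msv",
            "dose_per_inhabitant_msv"]],
        year,
    )


@dataclass
class TrendComparison:
    """Percentage changes between two surveys (earlier survey as base)."""

    base_year: int
    new_year: int
    table: pd.DataFrame
    overall_frequency_change_pct: float
    overall_dose_change_pct: float


def _pct_change(new: float, old: float) -> float:
    if old == 0 or not np.isfinite(old) or not np.isfinite(new):
        return np.nan
    return (new - old) / old * 100.0


def compare_surveys(old: SurveyResult, new: SurveyResult) -> TrendComparison:
    """Per-modality and overall changes in frequency, dose per inhabitant and
    dose per examination. Modalities present in only one survey are kept with
    NaN changes rather than dropped. Overall changes use the without-NM totals
    (the trend table's scope)."""
    o = old.table.set_index("modality")
    n = new.table.set_index("modality")
    rows = []
    order = {m: i for i, m in enumerate(vocab.MODALITIES)}
    for m in sorted(set(o.index) | set(n.index), key=lambda m: order.get(m, len(order))):
        of = o["frequency_per_1000"].get(m, np.nan)
        nf = n["frequency_per_1000"].get(m, np.nan)
        od = o["dose_per_inhabitant_msv"].get(m, np.nan)
        nd = n["dose_per_inhabitant_msv"].get(m, np.nan)
        ope = od / of * 1000.0 if of and np.isfinite(of) else np.nan
        npe = nd / nf * 1000.0 if nf and np.isfinite(nf) else np.nan
        rows.append(
            {
                "modality": m,
                "frequency_change_pct": _pct_change(nf, of),
                "dose_per_inhabitant_change_pct": _pct_change(nd, od),
                "dose_per_exam_change_pct": _pct_change(npe, ope),
            }
        )
    return TrendComparison(
        base_year=old.year,
        new_year=new.year,
        table=pd.DataFrame(rows),
        overall_frequency_change_pct=_pct_change(
            new.total_frequency_without_nm, old.total_frequency_without_nm
        ),
        overall_dose_change_pct=_pct_change(
            new.total_dose_without_nm, old.total_dose_without_nm
        ),
    )


def _rounded_result_table(result: SurveyResult) -> pd.DataFrame:
    body = result.table.copy()
    body["frequency_per_1000"] = body["frequency_per_1000"].round(1)
    body["dose_vector_msv"] = body["dose_vector_msv"].round(2)
    body["dose_per_inhabitant_msv"] = body["dose_per_inhabitant_msv"].round(3)
    body["frequency_share_pct"] = body["frequency_share_pct"].round(2)
    body["dose_share_pct"] = body["dose_share_pct"].round(1)
    totals = pd.DataFrame(
        [
            {
                "modality": vocab.TOTAL_WITHOUT_NM,
                "frequency_per_1000": round(result.total_frequency_without_nm, 1),
                "dose_per_inhabitant_msv": round(result.total_dose_without_nm, 3),
            },
            {
                "modality": vocab.TOTAL_WITH_NM,
                "frequency_per_1000": round(result.total_frequency_with_nm, 1),
                "dose_per_inhabitant_msv": round(result.total_dose_with_nm, 3),
            },
        ]
    )
    return pd.concat([body, totals], ignore_index=True)


def render_report(
    result: SurveyResult,
    outdir,
    comparison: TrendComparison | None = None,
    ct_vector: CtDoseVector | None = None,
    verification: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the survey tables, a JSON summary and a contribution chart.

    Numeric rounding is applied here only; omits the trend section when no
    comparison is given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["survey_table"] = outdir / "survey_table.csv"
    _rounded_result_table(result).to_csv(paths["survey_table"], index=False)

    if comparison is not None:
        paths["trend_table"] = outdir / "trend_table.csv"
        trend = comparison.table.copy()
        for col in trend.columns[1:]:
            trend[col] = trend[col].round(0)
        trend.to_csv(paths["trend_table"], index=False)

    if ct_vector is not None:
        paths["ct_regions"] = outdir / "ct_regions.csv"
        ct = ct_vector.regions.copy()
        ct["share"] = (ct["share"] * 100).round(1)
        ct = ct.rename(columns={"share": "frequency_share_pct"})
        ct.to_csv(paths["ct_regions"], index=False)

    if verification is not None:
        paths["verification"] = outdir / "verification.csv"
        verification.to_csv(paths["verification"], index=False)

    summary = {
        "year": result.year,
        "exams_per_inhabitant": round(result.exams_per_inhabitant, 3),
        "dose_per_inhabitant_msv": round(result.total_dose_with_nm, 3),
        "dose_per_inhabitant_without_nm_msv": round(result.total_dose_without_nm, 3),
        "dental_frequency_share_pct": round(result.dental_frequency_share_pct, 2),
    }
    if ct_vector is not None:
        summary["ct_dose_vector_msv"] = round(ct_vector.value, 2)
        if ct_vector.relative_uncertainty is not None:
            summary["ct_relative_uncertainty_pct"] = round(
                ct_vector.relative_uncertainty * 100, 1
            )
    if comparison is not None:
        summary["overall_frequency_change_pct"] = round(
            comparison.overall_frequency_change_pct, 1
        )
        summary["overall_dose_change_pct"] = round(
            comparison.overall_dose_change_pct, 1
        )
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2))

    paths["chart"] = outdir / "contributions.svg"
    _contribution_chart(result, paths["chart"])
    return paths


def _contribution_chart(result: SurveyResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    body = result.table
    x = np.arange(len(body))
    fig, ax = plt.subplots(figsize=(10, 5))
    ax.bar(x - 0.2, body["frequency_share_pct"], width=0.4, label="frequency share")
    ax.bar(x + 0.2, body["dose_share_pct"], width=0.4, label="dose share")
    ax.set_xticks(x)
    ax.set_xticklabels(body["modality"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("share (%)")
    ax.set_title(f"Frequency and dose contributions, {result.year}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
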