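"""End-to-end orchestration: bundle of raw tables → survey result.

Stages: invoice lines → examinations (with CT merging) → per-modality and
per-CT-region counts → extrapolation to national counts (coverage factor for
billing sources, response rates for surveyed sources) → frequency table →
CT dose vector from DACS records → assembled dose vectors → survey result,
plus the billing-vs-RIS verification table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from popdose import vocab
from popdose.config import CoverageModel, DEFAULT_RESPONSE_RATES
from popdose.ct_dose import (
    DEFAULT_CONVERSION_FACTORS,
    CtDoseVector,
    ct_dose_vector,
    summarize_dlp,
)
from popdose.dose_vectors import (
    DEFAULT_NM_PROCEDURES,
    NmProcedure,
    assemble_dose_tables,
    nm_effective_dose,
)
from popdose.examinations import (
    DEFAULT_MERGE_RULES,
    MergeRule,
    build_examinations,
    verify_against_ris,
)
from popdose.frequency import extrapolate_billing, extrapolate_survey, per_1000
from popdose.report import SurveyResult, build_result
from popdose.synthetic import SyntheticBundle

BILLING = "billing"
WEB_SURVEY = "web_survey"
SOCIETY = "society_report"


@dataclass
class AnalysisConfig:
    """Everything the analysis needs besides the raw tables."""

    population_total: int
    coverage: CoverageModel
    code_map: Mapping[str, tuple[str, str]]
    sources: Mapping[str, str]  # modality -> billing | web_survey | society_report
    merge_rules: tuple[MergeRule, ...] = DEFAULT_MERGE_RULES
    response_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_RATES)
    )
    conversion_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONVERSION_FACTORS)
    )
    modality_dose_vectors: Mapping[str, tuple[float, str]] | None = None
    nm_procedures: tuple[NmProcedure, ...] = DEFAULT_NM_PROCEDURES
    year: int = 2018

    @classmethod
    def from_bundle(cls, bundle: SyntheticBundle,
                    mode: str = "population_scaling") -> "AnalysisConfig":
        """Analysis settings matching a synthetic bundle's generating truth.

        The coverage fraction is the bundle's *realized* covered volume share
        (what a real analyst would establish from the covered facilities);
        the activity-ratio factor is set equal to it, since the synthetic
        world has no separate general-medical activity data.
        """
        truth = bundle.truth
        covered = bundle.covered_volume_fraction
        sources = {}
        for m in truth.modality_frequencies:
            if m in truth.billing_modalities:
                sources[m] = BILLING
            elif truth.response_rates.get(m, 1.0) < 1.0:
                sources[m] = WEB_SURVEY
            else:
                sources[m] = SOCIETY
        rates = {
            m: truth.response_rates.get(m, 1.0)
            for m, s in sources.items()
            if s in (WEB_SURVEY, SOCIETY)
        }
        return cls(
            population_total=truth.population_size,
            coverage=CoverageModel(
                population_total=truth.population_size,
                population_covered_fraction=covered,
                activity_ratio_factor=covered,
                mode=mode,
            ),
            code_map=bundle.code_map,
            sources=sources,
            response_rates=rates,
            year=truth.year,
        )


@dataclass
class PipelineResult:
    """All intermediate and final products of one analysis run."""

    examinations: pd.DataFrame
    frequency_table: pd.DataFrame
    ct_region_frequencies: dict[str, float]
    ct_summaries: pd.DataFrame
    ct_vector: CtDoseVector
    dose_table: pd.DataFrame
    verification: pd.DataFrame
    result: SurveyResult


def analyze_bundle(bundle: SyntheticBundle,
                   config: AnalysisConfig | None = None) -> PipelineResult:
    """Run the full survey analysis on a data bundle."""
    cfg = config if config is not None else AnalysisConfig.from_bundle(bundle)

    exams = build_examinations(bundle.invoices, cfg.code_map, cfg.merge_rules)

    # national counts: billing channel
    billing_mods = [m for m, s in cfg.sources.items() if s == BILLING]
    observed = exams.groupby("modality").size() if len(exams) else pd.Series(dtype=int)
    observed = observed.reindex(billing_mods, fill_value=0)
    national = dict(extrapolate_billing(observed, cfg.coverage))

    # national counts: surveyed channels (web survey and society reports)
    surveyed = [m for m, s in cfg.sources.items() if s in (WEB_SURVEY, SOCIETY)]
    if surveyed:
        responded = bundle.survey[bundle.survey["responded"]]
        counts = responded.groupby("modality")["count"].sum()
        counts = counts.reindex(surveyed, fill_value=0)
        rates = {m: cfg.response_rates.get(m, 1.0) for m in surveyed}
        national.update(dict(extrapolate_survey(counts, rates)))

    freq_table = per_1000(national, cfg.population_total, cfg.sources)

    # CT dose vector from dose-archive records
    ct_exams = exams[exams["modality"] == vocab.CT]
    region_counts = ct_exams.groupby("region").size()
    region_national = extrapolate_billing(region_counts, cfg.coverage)
    region_freqs = dict(region_national / cfg.population_total * 1000.0)
    summaries = summarize_dlp(bundle.dacs, cfg.conversion_factors)
    ct_vec = ct_dose_vector(summaries, region_freqs)

    dose_table = assemble_dose_tables(
        ct_vec, cfg.modality_dose_vectors, nm_effective_dose(cfg.nm_procedures)
    )
    result = build_result(freq_table, dose_table, cfg.year)
    verification = verify_against_ris(exams, bundle.ris)
    return PipelineResult(
        examinations=exams,
        frequency_table=freq_table,
        ct_region_frequencies=region_freqs,
        ct_summaries=summaries,
        ct_vector=ct_vec,
        dose_table=dose_table,
        verification=verification,
        result=result,
    )
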