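"""Generator: determinism, marginal recovery, DLP medians, IO round-trip."""
import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import helpers
from popdose import (
    GeneratorConfig,
    build_examinations,
    generate,
    read_bundle,
    write_bundle,
)
from popdose import vocab

TABLES = ("invoices", "ris", "dacs", "survey", "facilities")


def test_same_seed_gives_byte_identical_bundles():
    cfg = GeneratorConfig(seed=42, population_size=20_000)
    a, b = generate(cfg), generate(cfg)
    for name in TABLES:
        assert getattr(a, name).to_csv(index=False) == getattr(b, name).to_csv(
            index=False
        )
    assert a.code_map == b.code_map


def test_different_seeds_differ():
    a = generate(GeneratorConfig(seed=1, population_size=20_000))
    b = generate(GeneratorConfig(seed=2, population_size=20_000))
    assert not a.invoices.equals(b.invoices)


def test_zero_discrepancy_ris_equals_invoice_derived_exams():
    cfg = GeneratorConfig(seed=5, population_size=20_000, ris_discrepancy_rate=0.0)
    bundle = generate(cfg)
    exams = build_examinations(bundle.invoices, bundle.code_map)
    exam_rows = sorted(
        map(tuple, exams[["patient_id", "facility_id", "date", "modality",
                          "region"]].itertuples(index=False))
    )
    ris_rows = sorted(map(tuple, bundle.ris.itertuples(index=False)))
    assert exam_rows == ris_rows


def test_marginal_recovery_ct_frequency(ct_only_bundle, ct_only_config):
    """Full coverage, CT at 135/1000: count within 3 Poisson sd of the mean."""
    cfg = ct_only_config
    expected = 135.0 * cfg.population_size / 1000.0
    exams = build_examinations(ct_only_bundle.invoices, ct_only_bundle.code_map)
    assert abs(len(exams) - expected) < 3 * np.sqrt(expected)


def test_combined_ct_sessions_bill_two_component_codes(ct_only_bundle):
    """The chest+abdomen share of CT sessions matches the configured rate and
    appears on invoices as separate chest and abdomen codes."""
    bundle = ct_only_bundle
    exams = build_examinations(bundle.invoices, bundle.code_map)
    n = len(exams)
    n_combined = (exams["region"] == vocab.CHEST_ABDOMEN).sum()
    rate = bundle.truth.combined_ct_rate
    assert abs(n_combined / n - rate) < 3 * np.sqrt(rate * (1 - rate) / n)
    # invoices never carry a combined-region code directly
    billed_regions = {bundle.code_map[c][1] for c in bundle.invoices["billing_code"]}
    assert vocab.CHEST_ABDOMEN not in billed_regions


def test_dlp_median_recovery(ct_only_bundle, ct_only_config):
    """Empirical per-(region, stratum) median within 5% of configured median
    wherever the archive holds at least 2000 records."""
    dacs = ct_only_bundle.dacs
    models = ct_only_config.dlp_models
    checked = 0
    for (region, stratum), grp in dacs.groupby(["region", "stratum"]):
        if len(grp) < 2000:
            continue
        med = grp["dlp_mgycm"].median()
        target = models[region][stratum].median_mgycm
        assert med == pytest.approx(target, rel=0.05), (region, stratum)
        checked += 1
    assert checked >= 4


def test_survey_counts_match_generated_sessions(default_bundle):
    """Per-facility survey counts sum to the true number of sessions."""
    total = default_bundle.survey["count"].sum()
    truth = default_bundle.truth
    expected = (
        sum(truth.modality_frequencies.values()) * truth.population_size / 1000.0
    )
    assert abs(total - expected) < 4 * np.sqrt(expected)


def test_write_read_round_trip(tmp_path):
    cfg = GeneratorConfig(seed=9, population_size=5_000)
    bundle = generate(cfg)
    write_bundle(bundle, tmp_path)
    back = read_bundle(tmp_path)
    for name in TABLES:
        pd.testing.assert_frame_equal(
            getattr(bundle, name), getattr(back, name), check_dtype=False
        )
    assert back.code_map == bundle.code_map
    assert back.truth == bundle.truth


def test_invoice_csv_row_count(tmp_path):
    bundle = generate(GeneratorConfig(seed=9, population_size=5_000))
    paths = write_bundle(bundle, tmp_path)
    lines = paths["invoices"].read_text().strip().splitlines()
    assert len(lines) == len(bundle.invoices) + 1  # header


def test_empty_bundle_writes_headers_only(tmp_path):
    cfg = GeneratorConfig(seed=0, population_size=1, modality_frequencies={})
    bundle = generate(cfg)
    assert bundle.invoices.empty and bundle.dacs.empty and bundle.ris.empty
    paths = write_bundle(bundle, tmp_path)
    header = paths["invoices"].read_text().strip().splitlines()
    assert header == ["patient_id,facility_id,date,billing_code"]


@pytest.mark.parametrize(
    "overrides, field",
    [
        ({"modality_frequencies": {"CT": -1.0}}, "modality_frequencies"),
        ({"region_mix": {"CT": {"head": 0.7, "chest": 0.2}}}, "region_mix"),
        ({"coverage_fraction": 0.0}, "coverage_fraction"),
        ({"ris_discrepancy_rate": 1.5}, "ris_discrepancy_rate"),
        ({"modality_frequencies": {"Ultrasound": 10.0}}, "modalities"),
    ],
)
def test_invalid_config_rejected_with_field_named(overrides, field):
    with pytest.raises(ValidationError) as err:
        GeneratorConfig(**overrides)
    assert field.split("_")[0] in str(err.value)


def test_realized_coverage_near_target(default_bundle):
    truth = default_bundle.truth
    assert default_bundle.covered_volume_fraction == pytest.approx(
        truth.coverage_fraction, abs=0.05
    )


def test_recovered_frequencies_within_design_error(default_bundle):
    """Round-trip: generator → pipeline recovers every configured per-1000
    frequency within 3 design standard errors."""
    from popdose.frequency import modality_frequencies
    from popdose.pipeline import AnalysisConfig, analyze_bundle

    cfg = AnalysisConfig.from_bundle(default_bundle)
    res = analyze_bundle(default_bundle, cfg)
    recovered = modality_frequencies(res.frequency_table)
    truth = default_bundle.truth
    for m, f in truth.modality_frequencies.items():
        se = np.sqrt(
            helpers.frequency_variance_per_1000(
                truth, default_bundle.facilities, m, cfg.sources[m]
            )
        )
        assert abs(recovered[m] - f) < 3 * se, m
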