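"""Independent oracles and analytic variance formulas used by the tests.

Everything here is deliberately written without reusing the package's own
grouping/estimation code paths: the examination oracle is a plain-Python
enumeration, and the expected values / standard errors are closed-form
derivations from the generator's configuration.
"""
from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from popdose import vocab
from popdose.ct_dose import DEFAULT_CONVERSION_FACTORS
from popdose.dose_vectors import default_modality_dose_vectors, nm_effective_dose


def oracle_build_examinations(invoices, code_map, merge_rules):
    """Exhaustive grouping + merging oracle on a list of invoice dicts.

    Returns sorted (patient, facility, date, modality, region, n_source) tuples.
    Assumes non-overlapping merge rules.
    """
    groups = Counter()
    for inv in invoices:
        if inv["billing_code"] not in code_map:
            continue
        m, r = code_map[inv["billing_code"]]
        groups[(inv["patient_id"], inv["facility_id"], inv["date"], m, r)] += 1
    sessions: dict = {}
    for (p, f, d, m, r), n in groups.items():
        sessions.setdefault((p, f, d), {})[(m, r)] = n
    out = []
    for (p, f, d), items in sessions.items():
        ct_regions = {r: n for (m, r), n in items.items() if m == vocab.CT}
        merged_items = dict(items)
        for rule in merge_rules:
            if not set(rule.components) <= set(ct_regions):
                continue
            n = sum(merged_items.pop((vocab.CT, c)) for c in rule.components)
            n += merged_items.pop((vocab.CT, rule.merged), 0)
            merged_items[(vocab.CT, rule.merged)] = n
        for (m, r), n in merged_items.items():
            out.append((p, f, d, m, r, n))
    return sorted(out)


def exams_as_tuples(exams_df):
    return sorted(
        (r.patient_id, r.facility_id, r.date, r.modality, r.region,
         int(r.n_source_codes))
        for r in exams_df.itertuples()
    )


# ---------------------------------------------------------------------------
# expected values and design variances from generator truth


def university_volume_share(truth) -> float:
    return sum(
        s.volume_share for s in truth.facility_strata if s.label == vocab.UNIVERSITY
    )


def mixture_median(m_uni: float, m_non: float, sigma: float, w_uni: float) -> float:
    """Median of a two-component log-normal mixture (equal log-sd)."""
    if m_uni == m_non:
        return m_uni

    def cdf(x):
        return (
            w_uni * norm.cdf(np.log(x / m_uni) / sigma)
            + (1 - w_uni) * norm.cdf(np.log(x / m_non) / sigma)
            - 0.5
        )

    lo, hi = min(m_uni, m_non) / 2, max(m_uni, m_non) * 2
    return brentq(cdf, lo, hi)


def expected_region_doses(truth) -> dict[str, float]:
    """Region → true effective dose implied by the configured DLP models."""
    w = university_volume_share(truth)
    doses = {}
    for region, models in truth.dlp_models.items():
        mu = models[vocab.UNIVERSITY]
        mn = models[vocab.NONUNIVERSITY]
        med = mixture_median(mu.median_mgycm, mn.median_mgycm, mu.sigma_log, w)
        doses[region] = DEFAULT_CONVERSION_FACTORS[region] * med
    return doses


def expected_ct_weights(truth) -> dict[str, float]:
    mix = truth.region_mix[vocab.CT]
    c = truth.combined_ct_rate
    weights = {r: (1 - c) * s for r, s in mix.items()}
    if c > 0:
        weights[vocab.CHEST_ABDOMEN] = weights.get(vocab.CHEST_ABDOMEN, 0.0) + c
    return weights


def expected_ct_vector(truth) -> float:
    doses = expected_region_doses(truth)
    return sum(w * doses[r] for r, w in expected_ct_weights(truth).items())


def expected_modality_vectors(truth) -> dict[str, float]:
    vectors = {m: v for m, (v, _) in default_modality_dose_vectors().items()}
    vectors[vocab.CT] = expected_ct_vector(truth)
    vectors[vocab.NUCLEAR_MEDICINE] = nm_effective_dose()
    return vectors


def expected_dose_per_inhabitant(truth) -> float:
    vectors = expected_modality_vectors(truth)
    return sum(
        f * vectors[m] / 1000.0 for m, f in truth.modality_frequencies.items()
    )


def frequency_variance_per_1000(truth, facilities, modality, source) -> float:
    """Design variance of the per-1000 national frequency estimator.

    Billing: Poisson counts scaled by the realized coverage. Surveyed:
    Poisson facility counts thinned by Bernoulli response and scaled by the
    response rate — with few large facilities the response term dominates.
    """
    pop = truth.population_size
    f = truth.modality_frequencies[modality]
    if source == "billing":
        c = float(facilities.loc[facilities["covered"], "volume_share"].sum())
        return 1000.0 * f / (pop * c)
    from popdose.synthetic import modality_facility_shares

    p = truth.response_rates.get(modality, 1.0)
    lam = f * pop / 1000.0 * modality_facility_shares(truth, facilities, modality)
    var_n = np.sum((lam**2 + lam) / p - lam**2)
    return (1000.0 / pop) ** 2 * var_n


def ct_vector_variance(truth, n_ct_records: float) -> float:
    """Variance of the estimated CT dose vector (median noise + weight noise)."""
    doses = expected_region_doses(truth)
    weights = expected_ct_weights(truth)
    var_med = 0.0
    for region, w in weights.items():
        if w == 0:
            continue
        model = truth.dlp_models[region][vocab.UNIVERSITY]
        n_r = max(w * n_ct_records, 1.0)
        sd_med = doses[region] * 1.2533 * model.sigma_log / np.sqrt(n_r)
        var_med += (w * sd_med) ** 2
    mean_e = sum(w * doses[r] for r, w in weights.items())
    var_e = sum(w * (doses[r] - mean_e) ** 2 for r, w in weights.items())
    return var_med + var_e / max(n_ct_records, 1.0)


def dose_se(truth, facilities, sources) -> float:
    """Standard error of the per-inhabitant dose estimator."""
    vectors = expected_modality_vectors(truth)
    pop = truth.population_size
    var = 0.0
    for m, f in truth.modality_frequencies.items():
        var += (vectors[m] / 1000.0) ** 2 * frequency_variance_per_1000(
            truth, facilities, m, sources[m]
        )
    f_ct = truth.modality_frequencies.get(vocab.CT, 0.0)
    n_ct = f_ct * pop / 1000.0
    var += (f_ct / 1000.0) ** 2 * ct_vector_variance(truth, n_ct)
    return float(np.sqrt(var))
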