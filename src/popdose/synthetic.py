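"""Synthetic invoice / RIS / DACS / survey-response data with known truth.

The generator emulates the data landscape a national exposure survey draws
on, with the statistical structure the downstream analysis assumes:

* examination counts are Poisson per facility, with expectation
  frequency × population/1000 allocated by facility volume share;
* a configurable share of CT sessions are combined chest+abdomen sessions,
  billed as two separate codes on the same patient/facility/day (the
  examination builder merges them back);
* invoice records exist only for facilities inside the billing-coverage
  panel; RIS rows mirror the covered examinations up to a controlled
  discrepancy rate (deletions/duplications);
* every CT session leaves a log-normal DLP record in the dose archive,
  stratified into university vs non-university practice;
* each facility answers the web survey per modality with the configured
  response probability, reporting its true examination count.

Everything is reproducible bit-for-bit from (config, seed): a single
SeedSequence spawns one deterministic sub-stream per table.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from popdose import vocab
from popdose.config import GeneratorConfig

INVOICE_COLUMNS = ["patient_id", "facility_id", "date", "billing_code"]
RIS_COLUMNS = ["patient_id", "facility_id", "date", "modality", "region"]
DACS_COLUMNS = ["exam_id", "region", "dlp_mgycm", "stratum"]
SURVEY_COLUMNS = ["facility_id", "modality", "count", "responded"]
FACILITY_COLUMNS = ["facility_id", "stratum", "volume_share", "covered"]


@dataclass
class SyntheticBundle:
    """One generated survey landscape plus the truth that produced it."""

    invoices: pd.DataFrame
    ris: pd.DataFrame
    dacs: pd.DataFrame
    survey: pd.DataFrame
    facilities: pd.DataFrame
    code_map: dict[str, tuple[str, str]]
    truth: GeneratorConfig

    @property
    def covered_volume_fraction(self) -> float:
        """Realized share of national volume inside the billing panel."""
        cov = self.facilities.loc[self.facilities["covered"], "volume_share"]
        return float(cov.sum())


def build_code_map(config: GeneratorConfig) -> dict[str, tuple[str, str]]:
    """Deterministic synthetic billing-code table for a configuration.

    One code per (modality, region) pair that can appear on an invoice;
    non-CT modalities bill under a single unresolved-region code.
    """
    pairs: list[tuple[str, str]] = []
    for modality in config.modality_frequencies:
        if modality in config.region_mix:
            regions = sorted(config.region_mix[modality])
            if modality == vocab.CT:
                # combined sessions bill their components
                regions = sorted(set(regions) | {"chest", "abdomen"})
            pairs.extend((modality, r) for r in regions)
        else:
            pairs.append((modality, vocab.UNSPECIFIED_REGION))
    return {f"T{idx:03d}": pair for idx, pair in enumerate(sorted(set(pairs)))}


def _build_facilities(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for stratum in config.facility_strata:
        share = stratum.volume_share / stratum.n_facilities
        for _ in range(stratum.n_facilities):
            rows.append((f"F{i:03d}", stratum.label, share))
            i += 1
    df = pd.DataFrame(rows, columns=["facility_id", "stratum", "volume_share"])
    # greedy coverage: add facilities (largest first) while it brings the
    # covered volume closer to the target fraction
    target = config.coverage_fraction
    order = df.sort_values(
        ["volume_share", "facility_id"], ascending=[False, True]
    ).index
    covered = np.zeros(len(df), dtype=bool)
    cum = 0.0
    for idx in order:
        v = df.loc[idx, "volume_share"]
        if abs(cum + v - target) < abs(cum - target):
            covered[idx] = True
            cum += v
    df["covered"] = covered
    return df


def modality_facility_shares(config: GeneratorConfig,
                             facilities: pd.DataFrame,
                             modality: str) -> np.ndarray:
    """Per-facility share of a modality's national volume.

    Modalities with a stratum profile split the profiled stratum share
    equally across that stratum's facilities; others follow the global
    facility volume shares.
    """
    profile = config.modality_stratum_shares.get(modality)
    if profile is None:
        return facilities["volume_share"].to_numpy(dtype=float)
    counts = facilities["stratum"].value_counts()
    per_fac = facilities["stratum"].map(
        lambda s: profile.get(s, 0.0) / counts[s]
    )
    return per_fac.to_numpy(dtype=float)


def _draw_sessions(config: GeneratorConfig, facilities: pd.DataFrame,
                   rng_counts: np.random.Generator,
                   rng_attrs: np.random.Generator) -> pd.DataFrame:
    pop = config.population_size
    fac_ids = facilities["facility_id"].to_numpy()
    frames = []
    for modality in sorted(config.modality_frequencies):
        freq = config.modality_frequencies[modality]
        lam = freq * pop / 1000.0 * modality_facility_shares(
            config, facilities, modality
        )
        counts = rng_counts.poisson(lam)
        n = int(counts.sum())
        if n == 0:
            continue
        facility = np.repeat(fac_ids, counts)
        patient = rng_attrs.integers(0, pop, n)
        day = rng_attrs.integers(0, 365, n)
        date = (
            np.datetime64(f"{config.year}-01-01") + day.astype("timedelta64[D]")
        ).astype(str)
        if modality in config.region_mix:
            mix = config.region_mix[modality]
            labels = np.array(sorted(mix))
            probs = np.array([mix[r] for r in labels])
            region = labels[rng_attrs.choice(len(labels), size=n, p=probs)]
            if modality == vocab.CT and config.combined_ct_rate > 0:
                combined = rng_attrs.random(n) < config.combined_ct_rate
                region = np.where(combined, vocab.CHEST_ABDOMEN, region)
        else:
            region = np.full(n, vocab.UNSPECIFIED_REGION)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient,
                    "facility_id": facility,
                    "date": date,
                    "modality": modality,
                    "region": region,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=RIS_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _emit_invoices(sessions: pd.DataFrame,
                   code_map: dict[str, tuple[str, str]]) -> pd.DataFrame:
    if sessions.empty:
        return pd.DataFrame(columns=INVOICE_COLUMNS)
    inverse = {pair: code for code, pair in code_map.items()}
    combined = (sessions["modality"] == vocab.CT) & (
        sessions["region"] == vocab.CHEST_ABDOMEN
    )
    plain = sessions[~combined].copy()
    plain["billing_code"] = [
        inverse[(m, r)] for m, r in zip(plain["modality"], plain["region"])
    ]
    parts = [plain[INVOICE_COLUMNS]]
    comb = sessions[combined]
    for component in ("chest", "abdomen"):
        rows = comb[["patient_id", "facility_id", "date"]].copy()
        rows["billing_code"] = inverse[(vocab.CT, component)]
        parts.append(rows)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(INVOICE_COLUMNS, kind="mergesort").reset_index(drop=True)


def _inject_ris_discrepancies(ris: pd.DataFrame, config: GeneratorConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    if ris.empty or config.ris_discrepancy_rate == 0:
        return ris.sort_values(RIS_COLUMNS, kind="mergesort").reset_index(drop=True)
    u = rng.random(len(ris))
    delete_below = config.ris_discrepancy_rate * config.ris_deletion_share
    keep = ris[u >= delete_below]
    duplicated = ris[(u >= delete_below) & (u < config.ris_discrepancy_rate)]
    out = pd.concat([keep, duplicated], ignore_index=True)
    return out.sort_values(RIS_COLUMNS, kind="mergesort").reset_index(drop=True)


def _draw_dacs(sessions: pd.DataFrame, facilities: pd.DataFrame,
               config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    ct = sessions[sessions["modality"] == vocab.CT]
    if ct.empty:
        return pd.DataFrame(columns=DACS_COLUMNS)
    stratum_of = dict(zip(facilities["facility_id"], facilities["stratum"]))
    ct = ct.assign(
        stratum=[vocab.dose_stratum(stratum_of[f]) for f in ct["facility_id"]]
    )
    ct = ct.sort_values(["region", "stratum"], kind="mergesort").reset_index(drop=True)
    dlp = np.empty(len(ct))
    for region in sorted(ct["region"].unique()):
        for stratum in vocab.DOSE_STRATA:
            mask = (ct["region"] == region) & (ct["stratum"] == stratum)
            n = int(mask.sum())
            if n == 0:
                continue
            try:
                model = config.dlp_models[region][stratum]
            except KeyError:
                raise ValueError(
                    f"no DLP model configured for region {region!r}, stratum {stratum!r}"
                ) from None
            dlp[mask.to_numpy()] = rng.lognormal(
                mean=np.log(model.median_mgycm), sigma=model.sigma_log, size=n
            )
    return pd.DataFrame(
        {
            "exam_id": [f"E{i:07d}" for i in range(len(ct))],
            "region": ct["region"],
            "dlp_mgycm": dlp,
            "stratum": ct["stratum"],
        }
    )


def _draw_survey(sessions: pd.DataFrame, facilities: pd.DataFrame,
                 config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    modalities = sorted(config.modality_frequencies)
    fac_ids = list(facilities["facility_id"])
    if sessions.empty:
        counts = {}
    else:
        counts = sessions.groupby(["facility_id", "modality"]).size().to_dict()
    rows = []
    for facility in fac_ids:
        for modality in modalities:
            rate = config.response_rates.get(modality, 1.0)
            rows.append(
                (
                    facility,
                    modality,
                    int(counts.get((facility, modality), 0)),
                    bool(rng.random() < rate),
                )
            )
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate one reproducible survey landscape from a configuration."""
    names = ("counts", "attrs", "ris", "dacs", "survey")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    rng = {n: np.random.default_rng(c) for n, c in zip(names, children)}

    facilities = _build_facilities(config)
    code_map = build_code_map(config)
    sessions = _draw_sessions(config, facilities, rng["counts"], rng["attrs"])

    covered = set(facilities.loc[facilities["covered"], "facility_id"])
    observable = sessions[
        sessions["facility_id"].isin(covered)
        & sessions["modality"].isin(config.billing_modalities)
    ]
    invoices = _emit_invoices(observable, code_map)
    ris = _inject_ris_discrepancies(observable[RIS_COLUMNS], config, rng["ris"])
    dacs = _draw_dacs(sessions, facilities, config, rng["dacs"])
    survey = _draw_survey(sessions, facilities, config, rng["survey"])
    return SyntheticBundle(
        invoices=invoices,
        ris=ris,
        dacs=dacs,
        survey=survey,
        facilities=facilities,
        code_map=code_map,
        truth=config,
    )


def write_bundle(bundle: SyntheticBundle, directory) -> dict[str, Path]:
    """Write a bundle as plain CSV tables plus a config echo; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "invoices": bundle.invoices,
        "ris": bundle.ris,
        "dacs": bundle.dacs,
        "survey": bundle.survey,
        "facilities": bundle.facilities,
    }
    for name, df in tables.items():
        paths[name] = directory / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    code_map = pd.DataFrame(
        [(c, m, r) for c, (m, r) in sorted(bundle.code_map.items())],
        columns=["billing_code", "modality", "region"],
    )
    paths["code_map"] = directory / "code_map.csv"
    code_map.to_csv(paths["code_map"], index=False)
    paths["config"] = directory / "config.json"
    paths["config"].write_text(
        json.dumps(bundle.truth.model_dump(mode="json"), indent=2, sort_keys=True)
    )
    return paths


def read_bundle(directory) -> SyntheticBundle:
    """Read back a bundle written by :func:`write_bundle`."""
    directory = Path(directory)

    def _read(name, columns, dtypes):
        df = pd.read_csv(directory / f"{name}.csv", dtype=dtypes)
        return df[columns]

    invoices = _read("invoices", INVOICE_COLUMNS,
                     {"patient_id": "int64", "facility_id": str,
                      "date": str, "billing_code": str})
    ris = _read("ris", RIS_COLUMNS,
                {"patient_id": "int64", "facility_id": str, "date": str,
                 "modality": str, "region": str})
    dacs = _read("dacs", DACS_COLUMNS,
                 {"exam_id": str, "region": str, "dlp_mgycm": "float64",
                  "stratum": str})
    survey = _read("survey", SURVEY_COLUMNS,
                   {"facility_id": str, "modality": str, "count": "int64",
                    "responded": "bool"})
    facilities = _read("facilities", FACILITY_COLUMNS,
                       {"facility_id": str, "stratum": str,
                        "volume_share": "float64", "covered": "bool"})
    cm = pd.read_csv(directory / "code_map.csv", dtype=str)
    code_map = {
        row.billing_code: (row.modality, row.region) for row in cm.itertuples()
    }
    truth = GeneratorConfig.model_validate(
        json.loads((directory / "config.json").read_text())
    )
    return SyntheticBundle(
        invoices=invoices,
        ris=ris,
        dacs=dacs,
        survey=survey,
        facilities=facilities,
        code_map=code_map,
        truth=truth,
    )
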