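"""From invoice lines to examinations, and verification against the RIS.

The counting unit of the survey is the *examination*: one or more exposures of
an anatomical region with a single modality during a single visit (taken as
one calendar day at one facility). Invoice lines are therefore grouped by
(patient, facility, date, modality, region); repeated identical codes collapse
into one examination. Within a CT session, co-billed component regions that
match a merge rule (by default chest + abdomen) are replaced by one combined
examination, so that combined-trunk CTs are counted — and dosed — once.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from popdose import vocab
from popdose.errors import AmbiguousMergeError, MappingError

EXAM_KEYS = ["patient_id", "facility_id", "date", "modality", "region"]


@dataclass(frozen=True)
class MergeRule:
    """Replace co-occurring component regions by one combined region."""

    components: frozenset[str]
    merged: str

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValueError("a merge rule needs at least two component regions")
        if self.merged in self.components:
            raise ValueError("merged label must not be one of the components")


DEFAULT_MERGE_RULES: tuple[MergeRule, ...] = (
    MergeRule(frozenset({"chest", "abdomen"}), vocab.CHEST_ABDOMEN),
)


def build_examinations(
    invoices: pd.DataFrame,
    code_map: Mapping[str, tuple[str, str]],
    merge_rules: Iterable[MergeRule] = DEFAULT_MERGE_RULES,
    strict: bool = True,
) -> pd.DataFrame:
    """Group invoice lines into examinations and apply CT merge rules.

    Parameters
    ----------
    invoices
        Columns ``patient_id``, ``facility_id``, ``date``, ``billing_code``.
    code_map
        billing code → (modality, region); must be total over the observed
        codes in strict mode, otherwise unmapped lines are dropped with a
        warning.
    merge_rules
        Applied within CT sessions only; each rule fires when *all* its
        component regions are present in the session, absorbing the component
        examinations (and any pre-existing examination already carrying the
        merged label) into one combined examination. Two applicable rules
        sharing a component raise :class:`AmbiguousMergeError`.

    Returns
    -------
    One row per examination, sorted by the grouping keys, with
    ``n_source_codes`` = number of invoice lines absorbed.
    """
    merge_rules = tuple(merge_rules)
    if invoices.empty:
        return pd.DataFrame(columns=EXAM_KEYS + ["n_source_codes"])
    mapped = invoices["billing_code"].map(code_map)
    if mapped.isna().any():
        bad = invoices.loc[mapped.isna(), "billing_code"].unique()
        if strict:
            raise MappingError(bad)
        warnings.warn(f"dropping {mapped.isna().sum()} invoice lines with "
                      f"unmapped codes: {sorted(map(str, bad))}")
    df = invoices.loc[mapped.notna(), ["patient_id", "facility_id", "date"]].copy()
    pairs = mapped.dropna()
    df["modality"] = [p[0] for p in pairs]
    df["region"] = [p[1] for p in pairs]
    exams = (
        df.groupby(EXAM_KEYS, as_index=False, sort=False)
        .size()
        .rename(columns={"size": "n_source_codes"})
    )
    if merge_rules:
        exams = _apply_merge_rules(exams, merge_rules)
    return exams.sort_values(EXAM_KEYS, kind="mergesort").reset_index(drop=True)


def _apply_merge_rules(exams: pd.DataFrame,
                       rules: tuple[MergeRule, ...]) -> pd.DataFrame:
    ct = exams[exams["modality"] == vocab.CT]
    if ct.empty:
        return exams
    session_keys = ["patient_id", "facility_id", "date"]
    sizes = ct.groupby(session_keys)["region"].transform("size")
    multi = ct[sizes > 1]
    if multi.empty:
        return exams
    drop: list = []
    new_rows: list[dict] = []
    for key, group in multi.groupby(session_keys, sort=False):
        present = set(group["region"])
        applicable = [r for r in rules if r.components <= present]
        if not applicable:
            continue
        for i, a in enumerate(applicable):
            for b in applicable[i + 1:]:
                if a.components & b.components:
                    raise AmbiguousMergeError(
                        f"rules for {sorted(a.components)} and "
                        f"{sorted(b.components)} overlap in session {key}"
                    )
        for rule in applicable:
            absorb = group[
                group["region"].isin(rule.components)
                | (group["region"] == rule.merged)
            ]
            drop.extend(absorb.index)
            new_rows.append(
                {
                    "patient_id": key[0],
                    "facility_id": key[1],
                    "date": key[2],
                    "modality": vocab.CT,
                    "region": rule.merged,
                    "n_source_codes": int(absorb["n_source_codes"].sum()),
                }
            )
    if not new_rows:
        return exams
    return pd.concat(
        [exams.drop(index=drop), pd.DataFrame(new_rows)], ignore_index=True
    )


def verification_table(
    invoice_freq: Mapping[str, float], ris_freq: Mapping[str, float]
) -> pd.DataFrame:
    """Relative billing-vs-RIS differences per modality plus a Total row.

    difference (%) = (billing − RIS) / billing × 100, reported to two
    decimals; the Total row is computed on the summed frequencies, not on the
    rounded parts. A modality absent from the billing side gets a NaN
    difference rather than an error.
    """
    modalities = sorted(set(invoice_freq) | set(ris_freq))
    rows = []
    for m in modalities + [vocab.TOTAL]:
        if m == vocab.TOTAL:
            inv = float(sum(invoice_freq.values()))
            ris = float(sum(ris_freq.values()))
        else:
            inv = float(invoice_freq.get(m, 0.0))
            ris = float(ris_freq.get(m, 0.0))
        diff = (inv - ris) / inv * 100 if inv > 0 else np.nan
        rows.append((m, inv, ris, round(diff, 2) if np.isfinite(diff) else np.nan))
    return pd.DataFrame(
        rows,
        columns=["modality", "invoice_frequency", "ris_frequency", "difference_pct"],
    )


def verify_against_ris(
    exams: pd.DataFrame, ris: pd.DataFrame, population: float | None = None
) -> pd.DataFrame:
    """Compare invoice-derived examination counts with the RIS registry.

    Both inputs must cover the same facilities and period. With `population`
    given, frequencies are expressed per 1000 inhabitants; relative
    differences are identical either way.
    """
    scale = 1000.0 / population if population else 1.0
    inv = (exams.groupby("modality").size() * scale).to_dict() if len(exams) else {}
    reg = (ris.groupby("modality").size() * scale).to_dict() if len(ris) else {}
    return verification_table(inv, reg)
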