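"""WHO-ASSIST 3.0 scoring, dichotomisation and substance-group classification.

The ASSIST screens ten substance categories.  For each substance, Q2 records
frequency of use in the past 3 months and Q3-Q7 record five harm domains
(urge to use; health/social/legal/financial problems; failure to meet normal
expectations; concern expressed by others; failed attempts to cut down).
The weighted item sum is the substance-specific involvement (risk) score.

All operations are vectorised over a cohort table: one row per participant,
columns ``<substance>_q2`` ... ``<substance>_q7`` holding canonical level
strings (empty/NaN = missing).  Q5 is never administered for tobacco.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: The ten ASSIST substance categories, in instrument order.
SUBSTANCES: tuple[str, ...] = (
    "tobacco",
    "alcohol",
    "cannabis",
    "cocaine",
    "ats",
    "inhalants",
    "sedatives",
    "hallucinogens",
    "opioids",
    "other",
)

#: Categories counted as illicit substances.
ILLICIT: frozenset[str] = frozenset({"ats", "cannabis", "cocaine", "hallucinogens", "opioids"})

ITEMS: tuple[str, ...] = ("q2", "q3", "q4", "q5", "q6", "q7")

FREQUENCY_LEVELS: tuple[str, ...] = (
    "never",
    "once_or_twice",
    "monthly",
    "weekly",
    "daily_or_almost_daily",
)
RECENCY_LEVELS: tuple[str, ...] = ("never", "yes_not_past_3_months", "yes_past_3_months")

#: Harm item -> short indicator name used in dichotomised output columns.
HARM_NAMES: Mapping[str, str] = {
    "q3": "urge",
    "q4": "problems",
    "q5": "failed_expectations",
    "q6": "concerns",
    "q7": "failed_cutdown",
}

#: Group labels for the high-centrality substance classification.
GROUP_LEVELS: tuple[str, ...] = ("none", "alcohol_tobacco_other", "cannabis_no_ats", "ats")

POLY_LEVELS: tuple[str, ...] = ("none", "one_only", "polydrug")


class AssistValidationError(ValueError):
    """Raised when a response level is not legal for its item."""


def load_weight_table(path: str | None = None) -> dict[str, dict[str, dict[str, int]]]:
    """Load the item-weight configuration, expanded to substance x item x level.

    Parameters
    ----------
    path
        Optional path to a YAML weight file; defaults to the bundled
        WHO-ASSIST v3.0 table.
    """
    if path is None:
        src = importlib.resources.files("assistnet.data").joinpath("assist_weights.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    excluded = {s: set(v) for s, v in (raw.get("excluded_items") or {}).items()}
    overrides = raw.get("overrides") or {}
    table: dict[str, dict[str, dict[str, int]]] = {}
    for sub in SUBSTANCES:
        table[sub] = {}
        for item in ITEMS:
            if item in excluded.get(sub, set()):
                continue
            weights = dict(raw["weights"][item])
            weights.update(overrides.get(sub, {}).get(item, {}))
            table[sub][item] = {str(k): int(v) for k, v in weights.items()}
    return table


def substance_items(substance: str) -> tuple[str, ...]:
    """Items contributing to a substance's involvement score (no Q5 for tobacco)."""
    if substance == "tobacco":
        return ("q2", "q3", "q4", "q6", "q7")
    return ITEMS


def _validate_levels(col: pd.Series, legal: Iterable[str], substance: str, item: str) -> None:
    bad = col.dropna()[~col.dropna().isin(list(legal))]
    if len(bad):
        raise AssistValidationError(
            f"illegal level {bad.iloc[0]!r} for {substance}_{item} "
            f"(participant index {bad.index[0]})"
        )


def score_involvement(
    cohort: pd.DataFrame,
    weights: Mapping[str, Mapping[str, Mapping[str, int]]] | None = None,
) -> pd.DataFrame:
    """Compute per-substance involvement scores and their log transform.

    Returns a frame with columns ``<substance>_score`` (weighted item sum;
    NaN when any contributing item is missing) and ``<substance>_logscore``
    (``ln(score + 1)``).  A substance whose columns are absent from the input
    is skipped entirely.
    """
    if weights is None:
        weights = load_weight_table()
    out = pd.DataFrame(index=cohort.index)
    for sub in SUBSTANCES:
        items = [it for it in substance_items(sub) if f"{sub}_{it}" in cohort.columns]
        if not items:
            continue
        total = np.zeros(len(cohort))
        missing = np.zeros(len(cohort), dtype=bool)
        for item in items:
            col = cohort[f"{sub}_{item}"]
            legal = weights[sub][item]
            _validate_levels(col, legal.keys(), sub, item)
            w = col.map(legal)
            missing |= w.isna().to_numpy()
            total = total + w.fillna(0).to_numpy(dtype=float)
        total[missing] = np.nan
        out[f"{sub}_score"] = total
        out[f"{sub}_logscore"] = np.log1p(total)
    return out


def dichotomize_items(cohort: pd.DataFrame) -> pd.DataFrame:
    """Dichotomise ASSIST items to past-3-month use/harm indicators.

    Per substance: ``<sub>_used`` is true when Q2 is any level other than
    "never"; harm flags (``urge``, ``problems``, ``failed_expectations``,
    ``concerns``, ``failed_cutdown``) are true when the harm occurred within
    the past 3 months.  For Q6/Q7 only the "yes, in the past 3 months" level
    counts.  Missing answers propagate to missing flags (nullable booleans).
    Any-substance aggregate columns ``any_<harm>`` and ``any_used`` are true
    if the flag is true for at least one substance, missing only when no
    substance answered.  ``<sub>_harm_without_use`` QC columns flag harm
    reports without corresponding 3-month use.
    """
    out = pd.DataFrame(index=cohort.index)
    for sub in SUBSTANCES:
        q2 = f"{sub}_q2"
        if q2 in cohort.columns:
            _validate_levels(cohort[q2], FREQUENCY_LEVELS, sub, "q2")
            used = (cohort[q2] != "never").astype("boolean")
            used[cohort[q2].isna()] = pd.NA
            out[f"{sub}_used"] = used
        for item, name in HARM_NAMES.items():
            col = f"{sub}_{item}"
            if col not in cohort.columns:
                continue
            if item in ("q6", "q7"):
                _validate_levels(cohort[col], RECENCY_LEVELS, sub, item)
                flag = (cohort[col] == "yes_past_3_months").astype("boolean")
            else:
                _validate_levels(cohort[col], FREQUENCY_LEVELS, sub, item)
                flag = (cohort[col] != "never").astype("boolean")
            flag[cohort[col].isna()] = pd.NA
            out[f"{sub}_{name}"] = flag
    # aggregates: true if any substance true; NA only if nothing observed
    for name in list(HARM_NAMES.values()) + ["used"]:
        cols = [c for c in out.columns if c.endswith(f"_{name}") and not c.startswith("any")]
        if cols:
            block = out[cols]
            any_true = block.fillna(False).any(axis=1)
            all_na = block.isna().all(axis=1)
            agg = any_true.astype("boolean")
            agg[all_na] = pd.NA
            out[f"any_{name}"] = agg
    # QC: harm endorsed with no 3-month use
    for sub in SUBSTANCES:
        used = out.get(f"{sub}_used")
        if used is None:
            continue
        harm_cols = [f"{sub}_{n}" for n in HARM_NAMES.values() if f"{sub}_{n}" in out.columns]
        if harm_cols:
            any_harm = out[harm_cols].fillna(False).any(axis=1)
            out[f"{sub}_harm_without_use"] = (any_harm & (used == False)).astype(bool)  # noqa: E712
    return out


def classify_polysubstance(
    indicators: pd.DataFrame, include_tobacco_alcohol: bool = True
) -> pd.Series:
    """Classify participants as none / one_only / polydrug by count of substances used.

    With ``include_tobacco_alcohol=False`` tobacco and alcohol are not counted
    (the "excluding tobacco and alcohol" variant).  The category is missing
    when every counted use flag is missing.
    """
    subs = [s for s in SUBSTANCES if include_tobacco_alcohol or s not in ("tobacco", "alcohol")]
    cols = [f"{s}_used" for s in subs if f"{s}_used" in indicators.columns]
    block = indicators[cols]
    count = block.fillna(False).sum(axis=1).astype(int)
    labels = pd.Series(
        pd.Categorical(
            np.where(count == 0, "none", np.where(count == 1, "one_only", "polydrug")),
            categories=POLY_LEVELS,
        ),
        index=indicators.index,
    )
    labels[block.isna().all(axis=1)] = np.nan
    return labels


def assign_group(indicators: pd.DataFrame) -> pd.Series:
    """Assign the four-group classification by high-centrality substance use.

    Priority: any ATS use -> ``ats``; else cannabis use -> ``cannabis_no_ats``;
    else any other substance -> ``alcohol_tobacco_other``; else ``none``.
    The group is missing when the flags needed to decide are missing (e.g. the
    ATS answer is missing and no higher-priority flag overrides it).
    """
    used = {
        s: indicators[f"{s}_used"]
        for s in SUBSTANCES
        if f"{s}_used" in indicators.columns
    }
    n = len(indicators)
    result = pd.Series(
        pd.Categorical([None] * n, categories=GROUP_LEVELS), index=indicators.index
    )
    ats = used.get("ats", pd.Series(pd.NA, index=indicators.index, dtype="boolean"))
    cannabis = used.get("cannabis", pd.Series(pd.NA, index=indicators.index, dtype="boolean"))
    others = [u for s, u in used.items() if s not in ("ats", "cannabis")]
    other_any = (
        pd.concat(others, axis=1).fillna(False).any(axis=1)
        if others
        else pd.Series(False, index=indicators.index)
    )
    other_all_known = (
        pd.concat(others, axis=1).notna().all(axis=1)
        if others
        else pd.Series(True, index=indicators.index)
    )
    result[ats == True] = "ats"  # noqa: E712
    undecided = result.isna() & (ats == False)
    result[undecided & (cannabis == True)] = "cannabis_no_ats"  # noqa: E712
    undecided = result.isna() & (ats == False) & (cannabis == False)
    result[undecided & other_any] = "alcohol_tobacco_other"
    result[undecided & ~other_any & other_all_known] = "none"
    return result
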