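"""Descriptive statistics recomputed from the reference cohort's summary counts.

The motivating cohort's raw records are not publicly released, but its
printed summary counts (per-variable numerators and missing-data counts)
are.  This module re-derives the headline descriptive percentages from
those counts — each prevalence is ``100 * count / (N - missing)`` — so they
can be checked against the published figures and used as calibration
anchors for the synthetic generator.
"""

from __future__ import annotations

import importlib.resources

import yaml

__all__ = ["reference_counts", "headline_descriptives"]


def reference_counts() -> dict:
    """The bundled published summary counts (see data/reference_counts.yaml)."""
    src = importlib.resources.files("assistnet.data").joinpath("reference_counts.yaml")
    return yaml.safe_load(src.read_text())


def _prevalence(entry: dict, n_total: int) -> tuple[float, int]:
    denom = n_total - entry.get("missing", 0)
    return 100.0 * entry["count"] / denom, denom


def headline_descriptives() -> dict[str, dict[str, float]]:
    """Headline percentages, each as ``{"value": pct, "n": denominator}``.

    Includes any-substance / per-substance / harm prevalences, the polydrug
    share, the cannabis share within the ATS group, and the share of daily
    tobacco smokers who also use cannabis.
    """
    raw = reference_counts()
    n_total = raw["cohort"]["n_total"]
    out: dict[str, dict[str, float]] = {}

    poly = raw["polysubstance_including_tobacco_alcohol"]
    denom = n_total - poly["missing"]
    used = poly["one_only"] + poly["polydrug"]
    out["any_substance_prevalence"] = {"value": 100.0 * used / denom, "n": denom}
    out["polydrug_share"] = {"value": 100.0 * poly["polydrug"] / denom, "n": denom}

    for sub in ("alcohol", "tobacco", "illicit", "cocaine"):
        value, d = _prevalence(raw["use_prevalence"][sub], n_total)
        out[f"{sub}_prevalence"] = {"value": value, "n": d}

    value, d = _prevalence(raw["harm_prevalence"]["urge"], n_total)
    out["urge_prevalence"] = {"value": value, "n": d}

    cross = raw["group_cross_use"]["cannabis_in_ats_group"]
    out["cannabis_share_in_ats_group"] = {
        "value": 100.0 * cross["count"] / cross["of"], "n": cross["of"],
    }
    daily = raw["daily_tobacco_smokers"]["cannabis_co_use"]
    out["daily_smoker_cannabis_share"] = {
        "value": 100.0 * daily["count"] / daily["of"], "n": daily["of"],
    }
    return out
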