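"""End-to-end analysis pipeline.

Stages run in a fixed order — instrument scoring, descriptive tables,
zero-order network, partial-correlation GGM, centrality, grouping,
regression — behind a single configuration; any subset can be toggled.
Every stage draws its randomness from a seed derived from the single root
seed and the stage's fixed position, so disabling one stage never perturbs
another's output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, centrality, ggm, instrument, io, synthetic, zero_order

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]

STAGES = (
    "instrument",
    "descriptives",
    "zero_order",
    "ggm",
    "centrality",
    "grouping",
    "regression",
)

#: Harm indicators included as zero-order network nodes (per substance).
DEFAULT_NODE_HARMS = ("urge", "problems", "failed_expectations", "concerns")


@dataclass
class RunConfig:
    """Pipeline configuration: input, seed, stage toggles and parameters."""

    input_csv: str | None = None  # mutually exclusive with preset
    preset: str | None = "paper_like"
    n: int = 1107
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    edge_alpha: float = 0.05  # zero-order display threshold
    node_harms: tuple[str, ...] = DEFAULT_NODE_HARMS
    include_q7_harm: bool = False
    gamma: float = 0.0
    gamma_path: float = 0.5
    n_lambdas: int = 100
    m_imputations: int = 20
    mice_iter: int = 10
    out_dir: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.input_csv is None and self.preset not in ("paper_like",):
            raise ValueError(f"unknown preset {self.preset!r}")
        if not 0 < self.edge_alpha < 1:
            raise ValueError("edge_alpha must lie in (0, 1)")
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be at least 2")


@dataclass
class ReportBundle:
    config_hash: str
    seed: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    objects: dict[str, object] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "stages_completed": sorted(self.tables.keys() | self.objects.keys()),
            "errors": self.errors,
            "qc": self.qc,
        }


def _stage_seed(root_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % 2**31)


def _descriptive_rows(
    frame: pd.DataFrame, variables: list[str], grouping: str
) -> pd.DataFrame:
    rows = []
    for var in variables:
        comp = associations.compare_groups(frame, var, grouping)
        if comp.test == "kruskal_wallis":
            for g, r in comp.summary.iterrows():
                rows.append(
                    {
                        "variable": var, "group": g,
                        "value": f"{r['median']:g} ({r['q1']:g}, {r['q3']:g})",
                        "n": int(r["n"]), "test": comp.test,
                        "statistic": comp.statistic, "p": comp.p,
                    }
                )
        else:
            totals = comp.summary.sum(axis=0)
            for level in comp.summary.index:
                for g in comp.summary.columns:
                    cnt = int(comp.summary.loc[level, g])
                    pct = 100 * cnt / totals[g] if totals[g] else np.nan
                    rows.append(
                        {
                            "variable": f"{var}={level}", "group": g,
                            "value": f"{cnt} ({pct:.0f}%)", "n": cnt,
                            "test": comp.test, "statistic": comp.statistic,
                            "p": comp.p,
                        }
                    )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages; returns (and optionally writes) a bundle.

    A stage failure is recorded in the bundle's error manifest and dependent
    stages are skipped; earlier outputs are kept.
    """
    config.validate()
    hashed = dataclasses.asdict(config)
    # the hash covers what determines each file's content: stage toggles and
    # the output directory select *which* files exist, never their bytes
    hashed.pop("out_dir")
    hashed.pop("stages")
    chash = io.config_hash(hashed)
    bundle = ReportBundle(config_hash=chash, seed=config.seed)

    if config.input_csv is not None:
        cohort = pd.read_csv(config.input_csv, comment="#")
    else:
        gen_cfg = synthetic.paper_like_config(
            n=config.n, seed=_stage_seed(config.seed, "instrument")
        )
        cohort = synthetic.generate_cohort(gen_cfg)
    bundle.tables["cohort"] = cohort

    scores = indicators = group = None
    harms = config.node_harms + (("failed_cutdown",) if config.include_q7_harm else ())

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    # --- instrument ---------------------------------------------------
    if stage_enabled("instrument"):
        try:
            scores = instrument.score_involvement(cohort)
            indicators = instrument.dichotomize_items(cohort)
            group = instrument.assign_group(indicators)
            poly_incl = instrument.classify_polysubstance(indicators, True)
            poly_excl = instrument.classify_polysubstance(indicators, False)
            bundle.tables["scores"] = scores
            bundle.tables["indicators"] = indicators
            bundle.tables["groups"] = pd.DataFrame(
                {
                    "group": group.astype(object),
                    "polysubstance_incl": poly_incl.astype(object),
                    "polysubstance_excl": poly_excl.astype(object),
                }
            )
            qc_cols = [c for c in indicators.columns if c.endswith("harm_without_use")]
            bundle.qc["harm_without_use_total"] = int(
                indicators[qc_cols].sum().sum()
            )
            bundle.qc["missing_per_variable"] = {
                c: int(cohort[c].isna().sum()) for c in cohort.columns
            }
            bundle.qc["group_sizes"] = {
                str(k): int(v) for k, v in group.value_counts(dropna=False).items()
            }
        except Exception as exc:  # pragma: no cover - defensive
            bundle.errors["instrument"] = str(exc)

    # --- descriptives --------------------------------------------------
    if stage_enabled("descriptives") and indicators is not None:
        try:
            frame = cohort.copy()
            for col in ("any_used", "any_urge", "any_problems",
                        "any_failed_expectations", "any_concerns"):
                if col in indicators.columns:
                    frame[col] = indicators[col].astype(object)
            frame["age_band"] = np.where(frame["age"] <= 17, "12-17", "18-25")
            variables = [
                c for c in (
                    "any_used", "any_urge", "any_problems",
                    "any_failed_expectations", "any_concerns",
                )
                if c in frame.columns
            ]
            bundle.tables["descriptives_by_age"] = _descriptive_rows(
                frame, variables, "age_band"
            )
            if group is not None:
                frame["group"] = group.astype(object)
                use_vars = [
                    f"{s}_used" for s in instrument.SUBSTANCES
                    if f"{s}_used" in indicators.columns
                ]
                for v in use_vars:
                    frame[v] = indicators[v].astype(object)
                sub_frame = frame[frame["group"].notna() & (frame["group"] != "none")]
                bundle.tables["descriptives_by_group"] = _descriptive_rows(
                    sub_frame, use_vars + variables, "group"
                )
        except Exception as exc:
            bundle.errors["descriptives"] = str(exc)

    # --- zero-order network -------------------------------------------
    if stage_enabled("zero_order") and indicators is not None:
        try:
            cols = [
                f"{s}_{name}"
                for s in instrument.SUBSTANCES
                for name in ("used",) + harms
                if f"{s}_{name}" in indicators.columns
            ]
            net0 = zero_order.build_zero_order_network(
                indicators[cols], alpha=config.edge_alpha
            )
            layout = zero_order.mds_layout(net0, seed=_stage_seed(config.seed, "zero_order"))
            bundle.objects["zero_order_network"] = net0
            bundle.objects["zero_order_layout"] = layout
            bundle.tables["zero_order_edges"] = net0.to_edge_frame()
            bundle.tables["zero_order_layout"] = pd.DataFrame(
                {"node": layout.labels,
                 "x": layout.coords[:, 0], "y": layout.coords[:, 1]}
            )
            bundle.qc["zero_order_mean_rt"] = net0.mean_weight
            bundle.qc["zero_order_stress"] = layout.stress
        except Exception as exc:
            bundle.errors["zero_order"] = str(exc)

    # --- GGM ------------------------------------------------------------
    model = net_p = None
    if stage_enabled("ggm") and scores is not None:
        try:
            logcols = [f"{s}_logscore" for s in instrument.SUBSTANCES
                       if f"{s}_logscore" in scores.columns]
            logs = scores[logcols].rename(
                columns=lambda c: c.replace("_logscore", "")
            )
            model, net_p = ggm.fit_ggm(
                logs, gamma=config.gamma, gamma_path=config.gamma_path,
                n_lambdas=config.n_lambdas,
            )
            bundle.objects["ggm_model"] = model
            bundle.objects["ggm_network"] = net_p
            bundle.tables["ggm_edges"] = net_p.to_edge_frame()
        except Exception as exc:
            bundle.errors["ggm"] = str(exc)

    # --- centrality ------------------------------------------------------
    if stage_enabled("centrality") and net_p is not None:
        try:
            profile = centrality.centrality_indices(net_p)
            ranks = centrality.rank_substances(profile)
            bundle.objects["centrality_profile"] = profile
            long_rows = []
            for idx in centrality.INDICES:
                for node in profile.table.index:
                    long_rows.append(
                        {
                            "node": node, "index": idx,
                            "raw": profile.table.loc[node, idx],
                            "z": profile.table.loc[node, f"{idx}_z"],
                        }
                    )
            bundle.tables["centrality"] = pd.DataFrame(long_rows)
            bundle.qc["centrality_ranking"] = {
                k: v for k, v in ranks["ranking"].items()
            }
            bundle.qc["top_on_majority"] = ranks["top_on_majority"]
        except Exception as exc:
            bundle.errors["centrality"] = str(exc)

    # --- grouping summary -------------------------------------------------
    if stage_enabled("grouping") and group is not None:
        try:
            sizes = group.value_counts(dropna=False)
            bundle.tables["group_sizes"] = pd.DataFrame(
                {
                    "group": [str(k) for k in sizes.index],
                    "n": sizes.to_numpy(),
                }
            )
        except Exception as exc:
            bundle.errors["grouping"] = str(exc)

    # --- regression -------------------------------------------------------
    if stage_enabled("regression") and group is not None:
        try:
            analysis = associations.build_analysis_table(cohort, group)
            bundle.tables["regression"] = associations.pooled_regression(
                analysis,
                m=config.m_imputations,
                seed=_stage_seed(config.seed, "regression"),
                n_iter=config.mice_iter,
            )
        except Exception as exc:
            bundle.errors["regression"] = str(exc)

    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: ReportBundle, config: RunConfig) -> None:
    out = Path(config.out_dir)
    chash, seed = bundle.config_hash, bundle.seed
    for name, df in bundle.tables.items():
        io.write_csv(df, out / f"{name}.csv", chash, seed)
    if "zero_order_network" in bundle.objects:
        io.write_graphml(
            bundle.objects["zero_order_network"], out / "zero_order.graphml",
            chash, seed, layout=bundle.objects.get("zero_order_layout"),
        )
    if "ggm_network" in bundle.objects:
        io.write_graphml(
            bundle.objects["ggm_network"], out / "ggm.graphml", chash, seed
        )
    if "ggm_model" in bundle.objects:
        model = bundle.objects["ggm_model"]
        io.write_json(
            {
                "edge_set": sorted(model.edge_set),
                "bic": model.bic,
                "log_likelihood": model.log_likelihood,
                "gamma": model.gamma,
                "meta": {k: v for k, v in model.meta.items() if k != "ebic_trace"},
                "ebic_trace": model.meta.get("ebic_trace", []),
            },
            out / "ggm_model.json", chash, seed,
        )
    io.write_json(bundle.manifest(), out / "manifest.json", chash, seed)
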