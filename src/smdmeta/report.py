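"""Pipeline orchestration and table rendering.

`run_pipeline` drives ingest -> effect sizes -> pooling -> subgroups ->
meta-regression -> publication bias for every requested outcome and returns
an in-memory bundle; `write_bundle` serializes it to CSV tables plus a
machine-readable JSON summary. Report surfaces round SMD/CI to 2 decimals,
I-squared to integer percent, and p-values to 3 decimals with a "<0.001"
floor.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from smdmeta import __version__ as _version
from smdmeta.effect_size import EffectSize, effect_from_record
from smdmeta.errors import DomainError, SchemaError
from smdmeta.ingest import (
    ComparisonRecord,
    MODERATORS,
    read_comparisons,
    validate_records,
    write_comparisons,
)
from smdmeta.meta_regression import MetaRegResult, fit_meta_regression
from smdmeta.pooling import (
    Heterogeneity,
    PooledResult,
    SubgroupTable,
    fixed_effect_pool,
    heterogeneity,
    random_effects_pool,
    subgroup_analysis,
)
from smdmeta.publication_bias import BiasResult, assess_robustness
from smdmeta.synthetic import SimulationConfig, simulate_ensemble

logger = logging.getLogger("smdmeta")

__all__ = [
    "OutcomeReport",
    "ReportBundle",
    "run_pipeline",
    "write_bundle",
    "render_forest_table",
    "render_subgroup_table",
    "render_metareg_table",
    "render_bias_table",
    "fmt_p",
]


def fmt_p(p: float) -> str:
    """Report-surface p-value: 3 decimals with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class OutcomeReport:
    outcome: str
    k: int
    pooled: PooledResult | None
    het: Heterogeneity | None
    bias: BiasResult | None
    forest: pd.DataFrame | None
    subgroups: dict[str, SubgroupTable] = field(default_factory=dict)
    metareg: dict[str, MetaRegResult] = field(default_factory=dict)


@dataclass
class ReportBundle:
    outcomes: dict[str, OutcomeReport]
    records: list[ComparisonRecord]
    metadata: dict


def render_forest_table(
    effects: Sequence[EffectSize], pooled: PooledResult, tau2: float = 0.0
) -> pd.DataFrame:
    """Text forest representation: one row per comparison plus a summary row.

    Weights are the pooling model's (1/(var + tau2)), normalized to 100%.
    """
    if not effects:
        raise DomainError("forest table needs at least one effect")
    weights = [1.0 / (e.var + tau2) for e in effects]
    total_w = sum(weights)
    rows = []
    for e, w in zip(effects, weights):
        label = e.comparison.study_id if e.comparison is not None else ""
        half = 1.959963984540054 * e.se
        rows.append(
            {
                "label": label,
                "g": e.g,
                "ci_low": e.g - half,
                "ci_high": e.g + half,
                "weight_pct": 100.0 * w / total_w,
            }
        )
    rows.append(
        {
            "label": f"Pooled ({pooled.model})",
            "g": pooled.estimate,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


def render_subgroup_table(table: SubgroupTable) -> pd.DataFrame:
    """Subgroup table in the Subgroup|Dataset|SMD|CI|P|I2|P layout."""
    rows = []
    for lvl in table.levels:
        rows.append(
            {
                "moderator": table.moderator,
                "subgroup": lvl.level,
                "dataset": lvl.k,
                "SMD": round(lvl.pooled.estimate, 2),
                "ci_low": round(lvl.pooled.ci_low, 2),
                "ci_high": round(lvl.pooled.ci_high, 2),
                "p_value": fmt_p(lvl.pooled.p),
                "I2": "" if lvl.het is None else round(lvl.het.I2),
                "p_het": "" if lvl.het is None else fmt_p(lvl.het.p_Q),
            }
        )
    return pd.DataFrame(rows)


def render_metareg_table(results: Sequence[MetaRegResult]) -> pd.DataFrame:
    """Meta-regression table: Outcome, Moderator, k, SMD, QM, P, I2, R2.

    The SMD column is the inverse-variance weighted grand mean of the
    outcome's effects (labelled explicitly as such in the summary JSON).
    """
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome,
                "moderator": r.moderator,
                "k": r.k,
                "SMD_weighted_grand_mean": round(r.grand_mean, 2),
                "QM": round(r.QM, 2),
                "p_QM": fmt_p(r.p_QM),
                "I2_resid": round(r.I2_resid),
                "R2": round(r.R2),
            }
        )
    return pd.DataFrame(rows)


def render_bias_table(results: dict[str, BiasResult], pooled: dict[str, PooledResult]) -> pd.DataFrame:
    """Publication-bias table: Outcome, k, SMD, OS, TS, Nfs, n, 5n+10."""
    rows = []
    for outcome, b in results.items():
        pr = pooled.get(outcome)
        rows.append(
            {
                "outcome": outcome,
                "k": b.n_comparisons,
                "SMD": "" if pr is None else round(pr.estimate, 2),
                "OS": fmt_p(b.observed_significance),
                "TS": b.target_significance,
                "Nfs": b.Nfs,
                "n": b.n_comparisons,
                "threshold_5n_plus_10": b.threshold,
                "robust": b.robust,
            }
        )
    return pd.DataFrame(rows)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config: dict) -> ReportBundle:
    """Execute the full analysis described by a config mapping.

    Keys: ``input`` (CSV path) or ``simulate`` (SimulationConfig fields);
    ``outcomes`` (list or None = all observed); ``moderators`` (default all
    five); ``alpha``; ``model`` (random|fixed); ``tau2_method`` (DL|REML).
    """
    t0 = time.perf_counter()
    alpha = float(config.get("alpha", 0.05))
    model = config.get("model", "random")
    tau2_method = config.get("tau2_method", "DL")
    moderators = config.get("moderators") or list(MODERATORS)

    if config.get("input"):
        records = read_comparisons(config["input"])
        seed = None
    elif "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        if "seed" in config and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = config["seed"]
        # YAML gives lists where the dataclass wants tuples / keyed maps
        if "n_range" in sim_kwargs:
            sim_kwargs["n_range"] = tuple(sim_kwargs["n_range"])
        if "moderator_effects" in sim_kwargs:
            sim_kwargs["moderator_effects"] = {
                tuple(k.split(":", 1)) if isinstance(k, str) else tuple(k): v
                for k, v in sim_kwargs["moderator_effects"].items()
            }
        if "outcome_scales" in sim_kwargs:
            sim_kwargs["outcome_scales"] = {
                k: tuple(v) for k, v in sim_kwargs["outcome_scales"].items()
            }
        sim = SimulationConfig(**sim_kwargs)
        records, _ = simulate_ensemble(sim)
        seed = sim.seed
    else:
        raise SchemaError("config must provide 'input' or 'simulate'")

    violations = validate_records(records)
    if violations:
        raise SchemaError("invalid records: " + "; ".join(violations[:10]))
    logger.info("ingest: %d records (%.2fs)", len(records), time.perf_counter() - t0)

    requested = config.get("outcomes") or sorted({r.outcome for r in records})
    reports: dict[str, OutcomeReport] = {}
    for outcome in requested:
        t1 = time.perf_counter()
        subset = [r for r in records if r.outcome == outcome]
        if not subset:
            warnings.warn(f"outcome {outcome!r}: no records; skipped")
            continue
        effects = [effect_from_record(r) for r in subset]
        rep = OutcomeReport(
            outcome=outcome, k=len(effects), pooled=None, het=None, bias=None,
            forest=None,
        )
        if len(effects) < 2:
            warnings.warn(
                f"outcome {outcome!r}: only {len(effects)} comparison(s); "
                "no random-effects pool"
            )
            reports[outcome] = rep
            continue
        if model == "fixed":
            rep.pooled = fixed_effect_pool(effects, alpha)
            rep.het = heterogeneity(effects)
            tau2_for_weights = 0.0
        else:
            rep.pooled, rep.het = random_effects_pool(effects, alpha, tau2_method)
            tau2_for_weights = rep.het.tau2
        rep.forest = render_forest_table(effects, rep.pooled, tau2_for_weights)
        rep.bias = assess_robustness(effects, alpha)
        for moderator in moderators:
            try:
                rep.subgroups[moderator] = subgroup_analysis(
                    subset, moderator, alpha=alpha, tau2_method=tau2_method
                )
                rep.metareg[moderator] = fit_meta_regression(
                    subset, moderator, alpha=alpha, tau2_method=tau2_method
                )
            except DomainError as exc:
                warnings.warn(f"outcome {outcome!r}, moderator {moderator!r}: {exc}")
        reports[outcome] = rep
        logger.info("outcome %s: k=%d (%.2fs)", outcome, rep.k, time.perf_counter() - t1)

    metadata = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "version": _version,
        "alpha": alpha,
        "model": model,
        "tau2_method": tau2_method,
        "n_records": len(records),
    }
    return ReportBundle(outcomes=reports, records=records, metadata=metadata)


def _pooled_dict(p: PooledResult | None) -> dict | None:
    if p is None:
        return None
    return {
        "estimate": p.estimate,
        "ci_low": p.ci_low,
        "ci_high": p.ci_high,
        "z": p.z,
        "p": p.p,
        "k": p.k,
        "model": p.model,
    }


def _het_dict(h: Heterogeneity | None) -> dict | None:
    if h is None:
        return None
    return {"Q": h.Q, "df": h.df, "p_Q": h.p_Q, "I2": h.I2, "tau2": h.tau2}


def write_bundle(bundle: ReportBundle, outdir) -> Path:
    """Write all tables and a JSON summary under ``outdir``; returns the
    summary path. Numeric JSON values are unrounded (tables are rounded)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_comparisons(bundle.records, outdir / "normalized_input.csv")

    summary: dict = {"metadata": bundle.metadata, "outcomes": {}}
    metareg_rows = []
    bias_results, pooled_by_outcome = {}, {}
    for outcome, rep in bundle.outcomes.items():
        entry = {
            "k": rep.k,
            "pooled": _pooled_dict(rep.pooled),
            "heterogeneity": _het_dict(rep.het),
        }
        if rep.forest is not None:
            rep.forest.to_csv(outdir / f"forest_{outcome}.csv", index=False)
        if rep.subgroups:
            pd.concat(
                [render_subgroup_table(t) for t in rep.subgroups.values()],
                ignore_index=True,
            ).to_csv(outdir / f"subgroups_{outcome}.csv", index=False)
            entry["subgroups"] = {
                mod: [
                    {
                        "level": lvl.level,
                        "k": lvl.k,
                        "pooled": _pooled_dict(lvl.pooled),
                        "heterogeneity": _het_dict(lvl.het),
                    }
                    for lvl in table.levels
                ]
                for mod, table in rep.subgroups.items()
            }
        if rep.metareg:
            metareg_rows.extend(rep.metareg.values())
            entry["meta_regression"] = {
                mod: {
                    "k": r.k,
                    "QM": r.QM,
                    "df_M": r.df_M,
                    "p_QM": r.p_QM,
                    "tau2_resid": r.tau2_resid,
                    "tau2_total": r.tau2_total,
                    "I2_resid": r.I2_resid,
                    "R2": r.R2,
                    "weighted_grand_mean_SMD": r.grand_mean,
                    "coefficients": dict(
                        zip(r.coef_names, [float(b) for b in r.coefficients])
                    ),
                }
                for mod, r in rep.metareg.items()
            }
        if rep.bias is not None:
            bias_results[outcome] = rep.bias
            pooled_by_outcome[outcome] = rep.pooled
            entry["publication_bias"] = {
                "Nfs": rep.bias.Nfs,
                "n": rep.bias.n_comparisons,
                "threshold": rep.bias.threshold,
                "robust": rep.bias.robust,
                "observed_significance": rep.bias.observed_significance,
                "target_significance": rep.bias.target_significance,
            }
        summary["outcomes"][outcome] = entry

    if metareg_rows:
        render_metareg_table(metareg_rows).to_csv(
            outdir / "meta_regression.csv", index=False
        )
    if bias_results:
        render_bias_table(bias_results, pooled_by_outcome).to_csv(
            outdir / "publication_bias.csv", index=False
        )
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary_path
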