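"""End-to-end orchestration: simulate or load a cohort, call allelic
status, score gene sets, cross-tabulate clinical benefit and run the
association battery into a reproducible report."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .caller import classify_allelic_status
from .io import (
    calls_to_frame,
    read_clinical_tsv,
    read_expression_tsv,
    read_genomics_tsv,
    read_mutations_tsv,
    read_phasing_tsv,
    write_calls,
)
from .scoring import (
    GD13_SET_NAME,
    assemble_default_sets,
    read_gmt,
    rpm,
    score_sets,
    ward_cluster,
    zscore_rows,
)
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    ContingencyTable2x2,
    benjamini_hochberg,
    fisher_exact_2x2,
    lmm_random_intercepts,
    wilcoxon_rank_sum,
)

logger = logging.getLogger("b2mcall")

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    gene: str = "B2M"
    simulation: Optional[SimulationConfig] = None
    mutations_tsv: Optional[str] = None
    genomics_tsv: Optional[str] = None
    phasing_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None
    library_sizes_tsv: Optional[str] = None
    clinical_tsv: Optional[str] = None
    gmt_path: Optional[str] = None
    cluster_k: int = 2
    log_level: str = "INFO"


@dataclass
class CohortReport:
    calls: pd.DataFrame
    scores: pd.DataFrame
    cb_table: ContingencyTable2x2
    cb_rates: dict
    associations: list
    response_tabulation: dict
    metadata: dict = field(default_factory=dict)


def format_percent(value: float) -> str:
    """Integer percent, with one decimal below 10% (report convention)."""
    if np.isnan(value):
        return "NA"
    if value < 10.0:
        return f"{value:.1f}"
    return f"{value:.0f}"


def crosstab_cb(calls: pd.DataFrame, clinical: pd.DataFrame):
    """Cross-tabulate allelic status against clinical benefit.

    Returns ``(table, rates)`` where rates hold each arm's benefit
    percentage (NaN for an empty arm) plus the formatted strings.
    """
    merged = calls.merge(clinical, on="sample_id", how="left")
    missing = merged["clinical_benefit"].isna()
    if missing.any():
        dropped = merged.loc[missing, "sample_id"].tolist()
        warnings.warn(
            f"samples with a call but no outcome excluded: {dropped}",
            stacklevel=2,
        )
        merged = merged[~missing]
    bad = set(merged["clinical_benefit"]) - {"CB", "NCB"}
    if bad:
        raise ValueError(f"clinical_benefit must be CB/NCB, found {sorted(bad)}")
    mut = merged["b2m_status"] == "mutant"
    cb = merged["clinical_benefit"] == "CB"
    table = ContingencyTable2x2(
        a=int((mut & cb).sum()),
        b=int((mut & ~cb).sum()),
        c=int((~mut & cb).sum()),
        d=int((~mut & ~cb).sum()),
    )
    rates = {}
    for arm, benefit, total in (
        ("mutant", table.a, table.a + table.b),
        ("wildtype", table.c, table.c + table.d),
    ):
        pct = 100.0 * benefit / total if total else float("nan")
        rates[arm] = pct
        rates[f"{arm}_formatted"] = format_percent(pct)
    rates["n_excluded"] = int(missing.sum())
    return table, rates


def tabulate_response(clinical: pd.DataFrame, by_status: bool = True) -> dict:
    """Counts and percentages of RECIST best-overall-response categories.

    Percentages follow the report convention (nearest integer; one decimal
    below 10%).  When ``by_status`` the tabulation is per allelic-status
    arm, expecting a ``b2m_status`` column.
    """
    if "response" not in clinical.columns:
        raise ValueError("clinical table lacks a response column")
    observed = clinical[clinical["response"].notna()]
    unknown = set(observed["response"]) - set(RESPONSE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown response categories: {sorted(unknown)}")
    arms = (
        {arm: df for arm, df in observed.groupby("b2m_status")}
        if by_status and "b2m_status" in observed.columns
        else {"all": observed}
    )
    out = {}
    for arm, df in arms.items():
        n = len(df)
        counts = df["response"].value_counts()
        arm_result = {"n": n, "categories": {}}
        for cat in RESPONSE_CATEGORIES:
            count = int(counts.get(cat, 0))
            if count == 0:
                continue
            pct = 100.0 * count / n
            arm_result["categories"][cat] = {
                "count": count,
                "percent": pct,
                "percent_formatted": format_percent(pct),
            }
        out[arm] = arm_result
    return out


def _association_battery(scores, calls, clinical):
    """Wilcoxon per gene set (mutant vs wildtype) with BH correction, plus
    a mixed-model fit for the gamma-delta set when grouping data exist."""
    merged = calls.merge(clinical, on="sample_id")
    merged = merged.set_index("sample_id")
    common = [s for s in scores.columns if s in merged.index]
    merged = merged.loc[common]
    is_mut = (merged["b2m_status"] == "mutant").to_numpy()
    results = []
    raw_ps = []
    for set_name in scores.index:
        values = scores.loc[set_name, common].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        x = values[ok & is_mut]
        y = values[ok & ~is_mut]
        if len(x) == 0 or len(y) == 0:
            continue
        res = wilcoxon_rank_sum(x, y)
        res.details["gene_set"] = set_name
        res.details["mean_difference"] = float(np.mean(x) - np.mean(y))
        results.append(res)
        raw_ps.append(res.p_value)
    if raw_ps:
        adjusted = benjamini_hochberg(raw_ps)
        for res, q in zip(results, adjusted):
            res.details["fdr"] = float(q)
    if (
        GD13_SET_NAME in scores.index
        and {"tumour_type", "biopsy_site"} <= set(merged.columns)
        and is_mut.any()
        and (~is_mut).any()
    ):
        values = scores.loc[GD13_SET_NAME, common].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        res = lmm_random_intercepts(
            values[ok],
            is_mut[ok].astype(int),
            merged.loc[ok, ["tumour_type", "biopsy_site"]],
        )
        res.details["gene_set"] = GD13_SET_NAME
        results.append(res)
    return results


def run_pipeline(config: PipelineConfig) -> CohortReport:
    """Execute simulate/load -> call -> score -> associate and persist."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    stage = "input"
    try:
        if config.simulation is not None:
            stage = "simulate"
            sim_config = config.simulation
            cohort = simulate_cohort(sim_config)
            cohort.write(out / "inputs")
            mutations = cohort.mutations
            genomics = cohort.genomics
            phasing = cohort.phasing
            expression = cohort.expression
            library_sizes = cohort.library_sizes
            clinical = cohort.clinical
        else:
            stage = "load"
            mutations = (
                read_mutations_tsv(config.mutations_tsv)
                if config.mutations_tsv
                else {}
            )
            genomics = read_genomics_tsv(config.genomics_tsv)
            phasing = (
                read_phasing_tsv(config.phasing_tsv) if config.phasing_tsv else {}
            )
            expression, library_sizes = read_expression_tsv(
                config.expression_tsv, config.library_sizes_tsv
            )
            clinical = read_clinical_tsv(config.clinical_tsv)

        stage = "call"
        calls = []
        for sid, genome in sorted(genomics.items()):
            calls.append(
                classify_allelic_status(
                    mutations.get(sid, []),
                    genome,
                    phasing.get(sid, []),
                    gene=config.gene,
                )
            )
        calls_frame = calls_to_frame(calls)
        write_calls(calls, out / "calls.tsv", out / "calls_evidence.json")
        logger.info(
            "called %d samples (%d mutant)",
            len(calls),
            int((calls_frame["b2m_status"] == "mutant").sum()),
        )

        stage = "score"
        base_sets = read_gmt(config.gmt_path) if config.gmt_path else []
        sets = assemble_default_sets(list(expression.index), base_sets)
        rpm_matrix = rpm(expression, library_sizes)
        scores = score_sets(rpm_matrix, sets)
        scores.index.name = "gene_set"
        scores.to_csv(out / "scores.tsv", sep="\t")
        if config.cluster_k and scores.shape[1] >= config.cluster_k:
            clustered = zscore_rows(scores.dropna(axis=0, how="any"))
            labels, _ = ward_cluster(clustered, config.cluster_k)
            labels.rename("cluster").to_frame().rename_axis("sample_id").to_csv(
                out / "clusters.tsv", sep="\t"
            )

        stage = "crosstab"
        cb_table, cb_rates = crosstab_cb(calls_frame, clinical)
        fisher = fisher_exact_2x2(cb_table)
        response_tab = (
            tabulate_response(
                clinical.merge(
                    calls_frame[["sample_id", "b2m_status"]], on="sample_id"
                )
            )
            if "response" in clinical.columns
            else {}
        )

        stage = "associate"
        associations = [fisher] + _association_battery(
            scores, calls_frame, clinical
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    metadata = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "gene": config.gene,
        "config_hash": hashlib.sha256(
            repr(
                sorted(
                    (k, v)
                    for k, v in config.__dict__.items()
                    if k != "out_dir"  # location must not change the science
                )
            ).encode()
        ).hexdigest(),
    }
    report = CohortReport(
        calls=calls_frame,
        scores=scores,
        cb_table=cb_table,
        cb_rates=cb_rates,
        associations=associations,
        response_tabulation=response_tab,
        metadata=metadata,
    )
    _write_report_json(report, out / "report.json")
    return report


def _write_report_json(report: CohortReport, path) -> None:
    def clean(value):
        if isinstance(value, float) and np.isnan(value):
            return None
        if isinstance(value, (np.floating, np.integer)):
            return value.item()
        return value

    payload = {
        "metadata": report.metadata,
        "cb_table": {
            "mutant": [report.cb_table.a, report.cb_table.b],
            "wildtype": [report.cb_table.c, report.cb_table.d],
        },
        "cb_rates": {k: clean(v) for k, v in report.cb_rates.items()},
        "response_tabulation": report.response_tabulation,
        "associations": [
            {
                "test": res.test_name,
                "estimate": clean(res.estimate)
                if np.isfinite(res.estimate)
                else str(res.estimate),
                "p_value": clean(res.p_value),
                "n": res.n,
                "adjustment": list(res.adjustment),
                "details": {
                    k: clean(v)
                    for k, v in res.details.items()
                    if isinstance(v, (str, int, float, bool, list))
                },
            }
            for res in report.associations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
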