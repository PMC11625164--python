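"""End-to-end pipeline: measurements -> concentrations -> risk -> stats.

Writes the tidy output tables (TSV) plus a small JSON run log with the
config digest, seed (for synthetic runs) and package version. Display
rendering follows the survey-table convention: three significant figures,
scientific notation below 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concentrations import (
    apply_uniform_ww,
    flag_guideline_exceedance,
    replicate_wet_weights,
    summarize_concentrations,
)
from .config import AnalysisConfig
from .risk import RiskTable, build_risk_table
from .stats import pearson_matrix, seasonal_comparisons


def sig3(x: float | None) -> str:
    """Render at 3 significant figures; scientific notation below 0.01."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if x == 0:
        return "0"
    return f"{x:.2E}" if abs(x) < 0.01 else f"{float(f'{x:.3g}'):g}"


@dataclass(frozen=True)
class PipelineResult:
    """All tables computed by one run, at full precision."""

    seasonal: pd.DataFrame
    pooled: pd.DataFrame
    exceedance: pd.DataFrame
    risk: RiskTable
    correlation_r: pd.DataFrame
    correlation_rendered: pd.DataFrame
    comparisons: pd.DataFrame


def run_pipeline(measurements: pd.DataFrame, config: AnalysisConfig) -> PipelineResult:
    """Run the full analysis in memory. Raises on any validation failure."""
    replicate = replicate_wet_weights(measurements, config.species)
    seasonal = summarize_concentrations(measurements, config.species, "by_season")
    pooled = summarize_concentrations(measurements, config.species, "pooled")
    if config.as_uniform_ww is not None:
        seasonal = apply_uniform_ww(seasonal, "As", config.as_uniform_ww)
        pooled = apply_uniform_ww(pooled, "As", config.as_uniform_ww)
        # the stats stage sees the same substitution the summaries use
        replicate = replicate.copy()
        replicate.loc[replicate["metal"] == "As", "ww"] = config.as_uniform_ww

    exceedance = flag_guideline_exceedance(seasonal, config.guideline_limits_ww)
    risk = build_risk_table(pooled, list(config.scenarios.values()), config.tox)

    # inferential stage on replicate-level wet weights, metals as columns
    wide = replicate.sort_values(["species_id", "season"]).copy()
    wide["rep"] = wide.groupby(["species_id", "season", "metal"]).cumcount()
    corr_input = wide.pivot_table(
        index=["species_id", "season", "rep"], columns="metal", values="ww"
    )[list(config.metals)]
    corr = pearson_matrix(corr_input.reset_index(drop=True))
    comparisons = seasonal_comparisons(replicate)

    return PipelineResult(
        seasonal=seasonal,
        pooled=pooled,
        exceedance=exceedance,
        risk=risk,
        correlation_r=corr.r,
        correlation_rendered=corr.render(),
        comparisons=comparisons,
    )


def render_risk_tables(risk: RiskTable) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """EDI, THQ+HI and TR display tables at 3 significant figures."""
    pm = risk.per_metal
    edi_tbl = pm.pivot_table(
        index=["scenario", "species_id"], columns="metal", values="edi"
    ).map(sig3).reset_index()
    thq_tbl = pm.pivot_table(
        index=["scenario", "species_id"], columns="metal", values="thq"
    ).map(sig3).reset_index()
    hi = risk.hi.copy()
    hi["hi"] = hi["hi"].map(sig3)
    thq_hi = thq_tbl.merge(
        hi.rename(columns={"hi": "HI"}), on=["scenario", "species_id"]
    )
    tr_tbl = (
        pm.dropna(subset=["tr"])
        .pivot_table(index=["scenario", "species_id"], columns="metal", values="tr")
        .map(sig3)
        .reset_index()
    )
    return edi_tbl, thq_hi, tr_tbl


def write_outputs(
    result: PipelineResult,
    outdir: str | Path,
    config: AnalysisConfig,
    seed: int | None = None,
) -> list[Path]:
    """Write the output tables and run log; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    conc = result.seasonal.copy()
    pooled = result.pooled.copy()
    _write(pd.concat([conc, pooled], ignore_index=True), "concentrations.tsv")
    edi_tbl, thq_hi, tr_tbl = render_risk_tables(result.risk)
    _write(edi_tbl, "edi.tsv")
    _write(thq_hi, "thq_hi.tsv")
    _write(tr_tbl, "tr.tsv")
    _write(result.exceedance, "guideline_exceedance.tsv")
    _write(result.correlation_rendered, "correlations.tsv", index=True)
    _write(result.comparisons, "comparisons.tsv")

    log = {
        "package": "hmrisk",
        "version": __version__,
        "config": config.name,
        "config_digest": config.source_digest,
        "seed": seed,
        "tables": [p.name for p in written],
    }
    log_path = outdir / "run.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    written.append(log_path)
    return written
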