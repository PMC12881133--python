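"""End-to-end orchestration: counts -> DE -> sustained -> sets -> ORA.

Thin glue over the stage modules, shared by the command-line interface, the
examples and the tests. Each function returns plain DataFrames/dicts so the
stages stay independently exercisable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, de, io as sio, ora
from .containers import ALL_CONTRASTS, Contrast, CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and reporting knobs shared across stages."""

    lfc_threshold: float = 1.0
    alpha: float = 0.05
    top_k: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    sustained: dict[str, pd.DataFrame]
    classes: pd.DataFrame
    summary: dict[str, int]
    venn: dict[str, int]
    go_inputs: dict[str, list[str]]
    ora_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)


def run_de(
    cm: CountMatrix, config: PipelineConfig, contrasts: tuple[Contrast, ...] = ALL_CONTRASTS
) -> dict[str, pd.DataFrame]:
    """Run normalization, dispersion estimation and every Wald contrast."""
    for contrast in contrasts:
        if not cm.group_samples("control", contrast.timepoint):
            raise ValidationError(
                f"design lacks a control at {contrast.timepoint} h; "
                f"contrast {contrast.name} undefined"
            )
    size_factors = de.estimate_size_factors(cm)
    dispersions = de.estimate_dispersions(cm, size_factors)
    logger.info("DE engine: %s", de.SIMPLIFICATIONS_NOTICE)
    tables = {}
    for contrast in contrasts:
        res = de.wald_test(cm, size_factors, dispersions, contrast)
        tables[contrast.name] = de.call_degs(
            res, lfc_threshold=config.lfc_threshold, alpha=config.alpha
        )
    return tables


def run_classification(de_tables: dict[str, pd.DataFrame]) -> PipelineResult:
    """Sustained selection and responder classification from DEG calls."""
    sustained = {
        stim: classify.call_sustained(
            de_tables[f"{stim}_12h"], de_tables[f"{stim}_24h"], stim
        )
        for stim in ("LPS", "IL4")
    }
    classes = classify.classify_responders(sustained["LPS"], sustained["IL4"])
    summary = classify.summarize_sets(classes, sustained["LPS"], sustained["IL4"])
    venn = classify.venn_tallies(sustained["LPS"], sustained["IL4"])
    go_inputs = classify.build_go_inputs(classes)
    return PipelineResult(
        de_tables=de_tables,
        sustained=sustained,
        classes=classes,
        summary=summary,
        venn=venn,
        go_inputs=go_inputs,
    )


def run_ora(
    result: PipelineResult,
    annotations: list[ora.GeneSet],
    config: PipelineConfig,
    universe: list[str] | None = None,
) -> None:
    """Enrich the four GO input lists against the annotation.

    Default universe: all genes the DE stage tested (finite p in at least
    one contrast) — the only universe the pipeline can justify internally.
    """
    if universe is None:
        tested = None
        for table in result.de_tables.values():
            mask = table["p"].notna()
            tested = mask if tested is None else (tested | mask)
        universe = sorted(tested.index[tested].tolist())
    result.universe = list(universe)
    for name, genes in result.go_inputs.items():
        query = [g for g in genes if g in set(universe)]
        result.ora_tables[name] = ora.enrich(
            query, universe, annotations, alpha=config.alpha
        )


def run_pipeline(
    cm: CountMatrix,
    config: PipelineConfig | None = None,
    annotations: list[ora.GeneSet] | None = None,
) -> PipelineResult:
    """Full analysis from a count matrix: DE, classification, optional ORA."""
    config = config or PipelineConfig()
    de_tables = run_de(cm, config)
    result = run_classification(de_tables)
    if annotations is not None:
        run_ora(result, annotations, config)
    else:
        logger.warning("no gene-set annotation provided; skipping ORA")
    return result


def write_result_tree(
    result: PipelineResult, out_dir: str | Path, config: PipelineConfig
) -> None:
    """Emit the standard result files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in result.de_tables.items():
        sio.write_de_results(
            table, out / f"de_{name}.tsv", notice=de.SIMPLIFICATIONS_NOTICE
        )
    sio.write_sustained(list(result.sustained.values()), out / "sustained.tsv")
    sio.write_classes(result.classes, out / "responder_classes.tsv")
    sio.write_json(
        {**result.summary, "venn_tallies": result.venn}, out / "set_summary.json"
    )
    for name, genes in result.go_inputs.items():
        sio.write_gene_list(genes, out / f"go_input_{name}.txt")
    for name, table in result.ora_tables.items():
        table.to_csv(out / f"ora_{name}.tsv", sep="\t", index=False)
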