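"""Cross-dataset DEG concordance: overlap, quadrants, agreement, correlation.

Compares two thresholded DEG tables (e.g. the in-house sustained set against
an external primary-cell dataset analysed at the same thresholds): shared
gene count, the four directionality quadrants (up-up, down-down, up-down,
down-up), the percentage of shared DEGs with concordant direction, the
Spearman correlation of log2 fold changes over the shared genes, and the
overlap of the two datasets' top-K enriched terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


def make_deg_table(
    table: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Threshold a (gene_id, log2fc, padj) table into a DEG table.

    Keeps rows with ``padj < alpha`` and ``|log2fc| > lfc_threshold`` (both
    strict) and adds a ``direction`` column consistent with the sign of the
    fold change. Index must be unique gene ids.
    """
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in DEG table: {dupes[:5]}")
    keep = (table["padj"] < alpha) & (table["log2fc"].abs() > lfc_threshold)
    out = table.loc[keep, ["log2fc", "padj"]].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def overlap_degs(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Sizes of the two DEG sets and their shared gene ids."""
    for name, t in (("first", a), ("second", b)):
        if t.index.duplicated().any():
            raise ValueError(f"duplicate gene ids in {name} DEG table")
    shared = a.index.intersection(b.index)
    return {
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "n_shared": int(len(shared)),
        "shared_ids": sorted(shared.tolist()),
    }


def quadrant_analysis(a: pd.DataFrame, b: pd.DataFrame, shared_ids: list[str]) -> dict:
    """Directionality quadrants over the shared genes and % agreement.

    With no shared genes the agreement is undefined and reported as None
    (with a warning), never as 0. ``agreement_pct`` is rounded half-even to
    one decimal; ``agreement_pct_exact`` keeps full precision.
    """
    if not shared_ids:
        logger.warning("no shared DEGs; directional agreement undefined")
        return {
            "up_up": 0,
            "down_down": 0,
            "up_down": 0,
            "down_up": 0,
            "agreement_pct": None,
            "agreement_pct_exact": None,
        }
    da = a.loc[shared_ids, "direction"]
    db = b.loc[shared_ids, "direction"]
    up_up = int(((da == "up") & (db == "up")).sum())
    down_down = int(((da == "down") & (db == "down")).sum())
    up_down = int(((da == "up") & (db == "down")).sum())
    down_up = int(((da == "down") & (db == "up")).sum())
    exact = 100.0 * (up_up + down_down) / len(shared_ids)
    return {
        "up_up": up_up,
        "down_down": down_down,
        "up_down": up_down,
        "down_up": down_up,
        "agreement_pct": float(np.round(exact, 1)),
        "agreement_pct_exact": exact,
    }


def spearman_lfc(a: pd.DataFrame, b: pd.DataFrame, shared_ids: list[str]) -> float | None:
    """Spearman correlation of log2 fold changes over shared genes.

    Average ranks for ties (rank-then-Pearson). Undefined (None) for fewer
    than three shared genes or a constant vector.
    """
    if len(shared_ids) < 3:
        logger.warning("fewer than 3 shared DEGs; Spearman correlation undefined")
        return None
    x = a.loc[shared_ids, "log2fc"].to_numpy(dtype=float)
    y = b.loc[shared_ids, "log2fc"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant log2fc vector; Spearman correlation undefined")
        return None
    rs = spearmanr(x, y).statistic
    return float(rs)


def go_overlap(top_a: pd.DataFrame, top_b: pd.DataFrame, k: int = 50) -> dict:
    """Shared term ids within the two top-K enriched-term lists.

    If either list is shorter than ``k`` the comparison runs over the
    available prefix and the report is flagged as truncated.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    truncated = len(top_a) < k or len(top_b) < k
    ta = set(top_a["term_id"].head(k))
    tb = set(top_b["term_id"].head(k))
    shared = sorted(ta & tb)
    return {
        "k": k,
        "count": len(shared),
        "shared_terms": shared,
        "truncated": truncated,
    }


def compare(
    a: pd.DataFrame,
    b: pd.DataFrame,
    top_a: pd.DataFrame | None = None,
    top_b: pd.DataFrame | None = None,
    k: int = 50,
) -> dict:
    """Full concordance report between two DEG tables.

    ``a``/``b`` are thresholded DEG tables from :func:`make_deg_table`;
    ``top_a``/``top_b`` optional ranked enrichment results for the top-K
    term overlap.
    """
    ov = overlap_degs(a, b)
    quad = quadrant_analysis(a, b, ov["shared_ids"])
    report = {
        "n_a": ov["n_a"],
        "n_b": ov["n_b"],
        "n_shared": ov["n_shared"],
        "quadrants": {q: quad[q] for q in ("up_up", "down_down", "up_down", "down_up")},
        "agreement_pct": quad["agreement_pct"],
        "agreement_pct_exact": quad["agreement_pct_exact"],
        "spearman_rs": spearman_lfc(a, b, ov["shared_ids"]),
    }
    if top_a is not None and top_b is not None:
        report["go_overlap"] = go_overlap(top_a, top_b, k=k)
    return report


def quadrant_scatter_table(
    a: pd.DataFrame, b: pd.DataFrame, shared_ids: list[str]
) -> pd.DataFrame:
    """Per-gene quadrant assignment for scatter-style reporting."""
    da = a.loc[shared_ids]
    db = b.loc[shared_ids]
    quad = da["direction"].str.cat(db["direction"], sep="_")
    return pd.DataFrame(
        {"lfc_a": da["log2fc"], "lfc_b": db["log2fc"], "quadrant": quad},
        index=pd.Index(shared_ids, name="gene_id"),
    )
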