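"""Hypergeometric over-representation analysis against GMT gene sets.

One-sided upper-tail test per term: with a universe of ``N`` genes, ``K`` of
them annotated to the term, and a query of ``n`` genes of which ``k`` hit the
term, ``p = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``. P-values are
BH-adjusted across all terms tested in a run; the gene ratio ``k/n`` is the
conventional dot-plot x-axis. Annotation members outside the universe are
dropped before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from collections.abc import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .de import adjust_bh


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: term, description, then member ids, tab-separated.

    Blank lines are skipped; duplicated members within a line are stored
    once; a line with fewer than three fields is a parse error naming the
    line number.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                    f"(term, description, members), got {len(fields)}"
                )
            term_id, term_name, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: term {term_id!r} has no members")
            if term_id in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            sets.append(GeneSet(term_id, term_name, frozenset(members)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    annotations: Sequence[GeneSet],
    alpha: float = 0.05,
    min_size: int = 1,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Test every annotation term for over-representation of ``query``.

    ``query`` must be a subset of ``universe``. Returns one row per term with
    ``K >= min_size`` after intersecting members with the universe, columns
    ``term_id, term_name, k, K, n, N, gene_ratio, p, padj, significant``,
    BH-adjusted across all tested terms.
    """
    query = set(query)
    universe = set(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(
            f"{len(stray)} query gene(s) outside the universe, e.g. {stray[:5]}"
        )
    n = len(query)
    N = len(universe)

    rows = []
    for gs in annotations:
        members = gs.members & universe
        K = len(members)
        if K < max(min_size, 1) or (max_size is not None and K > max_size):
            continue
        k = len(members & query)
        # upper tail P(X >= k); sf(k-1) == P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.term_id, gs.term_name, k, K, n, N, (k / n) if n else 0.0, p))

    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "K", "n", "N", "gene_ratio", "p"],
    )
    out["padj"] = adjust_bh(out["p"]) if len(out) else []
    out["significant"] = out["padj"] < alpha
    return out


def top_terms(results: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Top-k terms by adjusted p, ties broken by raw p then term id.

    The fully deterministic ordering makes top-k overlap counts between two
    enrichment runs reproducible.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ranked = results.sort_values(
        ["padj", "p", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return ranked.head(k)
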