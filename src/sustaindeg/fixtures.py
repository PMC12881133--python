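"""Synthetic membership fixtures built from published summary counts.

When only set sizes are known (sustained up/down per stimulus, common,
opposite, flip and ambiguous counts, or quadrant compositions), these
builders materialize a synthetic gene universe realizing exactly those
counts. They let the set-algebra and concordance stages be exercised against
printed totals without the underlying per-gene data, which is not public.
All outputs are synthetic stand-ins, not reconstructions of the real gene
lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def sustained_calls_from_marginals(
    sustained_lps_up: int,
    sustained_lps_down: int,
    sustained_il4_up: int,
    sustained_il4_down: int,
    common_up: int,
    common_down: int,
    opp_lps_up_il4_down: int,
    opp_il4_up_lps_down: int,
    n_lps_flip: int = 0,
    n_ambiguous_il4_down: int = 0,
    n_null: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build per-stimulus sustained-call tables realizing given marginals.

    ``sustained_*`` are the total sustained counts per stimulus and
    direction; common and opposite members are carved out of them.
    ``n_lps_flip`` adds genes direction-inconsistent under LPS and silent
    under IL-4; ``n_ambiguous_il4_down`` adds genes sustained-down under
    IL-4 but direction-inconsistent under LPS (counted inside
    ``sustained_il4_down``, excluded from both common and specific sets —
    the published single-gene exclusion case). Returns ``(lps, il4)``
    DataFrames indexed by gene id with ``stimulus``/``status`` columns.
    """
    lps_only_up = sustained_lps_up - common_up - opp_lps_up_il4_down
    lps_only_down = sustained_lps_down - common_down - opp_il4_up_lps_down
    il4_only_up = sustained_il4_up - common_up - opp_il4_up_lps_down
    il4_only_down = (
        sustained_il4_down - common_down - opp_lps_up_il4_down - n_ambiguous_il4_down
    )
    for name, v in (
        ("LPS-only up", lps_only_up),
        ("LPS-only down", lps_only_down),
        ("IL4-only up", il4_only_up),
        ("IL4-only down", il4_only_down),
    ):
        if v < 0:
            raise ValueError(f"marginals inconsistent: derived {name} count {v} < 0")

    # per-block (LPS status, IL4 status) patterns
    blocks = [
        ("lpsu", lps_only_up, "up", "not_sustained"),
        ("lpsd", lps_only_down, "down", "not_sustained"),
        ("il4u", il4_only_up, "not_sustained", "up"),
        ("il4d", il4_only_down, "not_sustained", "down"),
        ("comu", common_up, "up", "up"),
        ("comd", common_down, "down", "down"),
        ("opplu", opp_lps_up_il4_down, "up", "down"),
        ("oppiu", opp_il4_up_lps_down, "down", "up"),
        ("flipl", n_lps_flip, "inconsistent", "not_sustained"),
        ("ambig", n_ambiguous_il4_down, "inconsistent", "down"),
        ("null", n_null, "not_sustained", "not_sustained"),
    ]
    gene_ids: list[str] = []
    lps_status: list[str] = []
    il4_status: list[str] = []
    for tag, count, sl, si in blocks:
        for i in range(count):
            gene_ids.append(f"{tag}_{i + 1:05d}")
            lps_status.append(sl)
            il4_status.append(si)
    index = pd.Index(gene_ids, name="gene_id")
    lps = pd.DataFrame({"stimulus": "LPS", "status": lps_status}, index=index)
    il4 = pd.DataFrame({"stimulus": "IL4", "status": il4_status}, index=index)
    return lps, il4


def deg_tables_from_quadrants(
    up_up: int,
    down_down: int,
    up_down: int,
    down_up: int,
    n_a_only: int = 0,
    n_b_only: int = 0,
    seed: int = 0,
    lfc_scale: float = 2.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build two thresholded DEG tables realizing a quadrant composition.

    Shared genes populate the four directionality quadrants exactly;
    ``n_a_only``/``n_b_only`` add genes unique to each table. Fold-change
    magnitudes are drawn just above the |log2FC| > 1 threshold (seeded, for
    reproducible but non-degenerate ranks); padj is fixed nominal.
    """
    rng = np.random.default_rng(seed)
    quads = [
        ("uu", up_up, 1, 1),
        ("dd", down_down, -1, -1),
        ("ud", up_down, 1, -1),
        ("du", down_up, -1, 1),
    ]
    rows_a, rows_b = [], []
    for tag, count, sa, sb in quads:
        mags_a = 1.0 + lfc_scale * rng.random(count)
        mags_b = 1.0 + lfc_scale * rng.random(count)
        for i in range(count):
            gid = f"sh_{tag}_{i + 1:05d}"
            rows_a.append((gid, sa * mags_a[i]))
            rows_b.append((gid, sb * mags_b[i]))
    for i, m in enumerate(1.0 + lfc_scale * rng.random(n_a_only)):
        rows_a.append((f"aonly_{i + 1:05d}", (-1) ** i * m))
    for i, m in enumerate(1.0 + lfc_scale * rng.random(n_b_only)):
        rows_b.append((f"bonly_{i + 1:05d}", (-1) ** i * m))

    def _table(rows: list[tuple[str, float]]) -> pd.DataFrame:
        idx = pd.Index([r[0] for r in rows], name="gene_id")
        lfc = np.array([r[1] for r in rows])
        return pd.DataFrame(
            {
                "log2fc": lfc,
                "padj": np.full(len(rows), 1e-4),
                "direction": np.where(lfc > 0, "up", "down"),
            },
            index=idx,
        )

    return _table(rows_a), _table(rows_b)
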