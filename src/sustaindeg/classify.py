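"""Sustained-DEG selection and responder-set classification.

This is the analytical core of the pipeline. From per-timepoint DEG calls it

1. selects *sustained* genes — called in the same direction at both 12 h and
   24 h under a stimulus — while flagging direction-inconsistent genes
   (significant at both timepoints with opposite signs, the F5/Fabp3-like
   behaviour) separately;
2. partitions the gene universe into responder classes across the two
   stimuli: stimulus-specific (up/down), common (same direction under both),
   opposite (sustained under both with opposite signs), ambiguous, or none;
3. derives the published-style set views: specific-set sizes that INCLUDE
   opposite responders, per-direction Venn tallies in which a flip gene is
   counted in both directions, and the four GO input lists (common
   responders excluded, opposite responders allocated by direction under
   each stimulus).

The ambiguity rule: a gene sustained under one stimulus but
direction-inconsistent under the other is excluded from BOTH the common and
the specific sets. This is what makes a sustained-down set of 166 with 75
common members and one inconsistent-elsewhere gene yield 90 — not 91 —
specific genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUSTAINED_STATUSES = ("up", "down", "inconsistent", "not_sustained")

RESPONDER_LABELS = (
    "lps_specific_up",
    "lps_specific_down",
    "il4_specific_up",
    "il4_specific_down",
    "common_up",
    "common_down",
    "opposite_lps_up_il4_down",
    "opposite_il4_up_lps_down",
    "ambiguous",
    "none",
)


def _check_universe(a: pd.Index, b: pd.Index, what: str) -> None:
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise ValueError(
            f"gene universes differ between {what} "
            f"(first side only: {only_a}, second side only: {only_b})"
        )


def call_sustained(
    calls_12: pd.DataFrame, calls_24: pd.DataFrame, stimulus: str
) -> pd.DataFrame:
    """Combine 12 h and 24 h DEG calls into per-gene sustained status.

    Inputs are DataFrames indexed by gene id with a ``direction`` column in
    {up, down, ns}, covering the same gene universe. Status is ``up``/``down``
    when the gene is called in that direction at both timepoints,
    ``inconsistent`` when called at both timepoints with opposite directions,
    else ``not_sustained``.
    """
    _check_universe(calls_12.index, calls_24.index, f"12 h and 24 h calls ({stimulus})")
    d12 = calls_12["direction"]
    d24 = calls_24["direction"].reindex(d12.index)
    sig12 = d12.isin(("up", "down"))
    sig24 = d24.isin(("up", "down"))
    status = np.where(
        sig12 & sig24 & (d12 == d24),
        d12,
        np.where(sig12 & sig24, "inconsistent", "not_sustained"),
    )
    return pd.DataFrame(
        {"stimulus": stimulus, "status": status},
        index=d12.index.rename("gene_id"),
    )


def _responder_label(lps_status: str, il4_status: str) -> str:
    """Fine-grained responder label for one gene.

    Decision order: none; common; opposite; sustained + inconsistent →
    ambiguous; sustained + not_sustained → specific; any remaining
    inconsistency → ambiguous.
    """
    sus_l = lps_status in ("up", "down")
    sus_i = il4_status in ("up", "down")
    if lps_status == "not_sustained" and il4_status == "not_sustained":
        return "none"
    if sus_l and sus_i:
        if lps_status == il4_status:
            return f"common_{lps_status}"
        if lps_status == "up":
            return "opposite_lps_up_il4_down"
        return "opposite_il4_up_lps_down"
    if sus_l and il4_status == "inconsistent":
        return "ambiguous"
    if sus_i and lps_status == "inconsistent":
        return "ambiguous"
    if sus_l:
        return f"lps_specific_{lps_status}"
    if sus_i:
        return f"il4_specific_{il4_status}"
    # inconsistent under one or both stimuli, not sustained anywhere
    return "ambiguous"


def classify_responders(
    sustained_lps: pd.DataFrame, sustained_il4: pd.DataFrame
) -> pd.DataFrame:
    """Assign every gene exactly one responder-class label (a partition)."""
    _check_universe(
        sustained_lps.index, sustained_il4.index, "LPS and IL-4 sustained calls"
    )
    sl = sustained_lps["status"]
    si = sustained_il4["status"].reindex(sl.index)
    bad = sorted(
        (set(sl.unique()) | set(si.unique())) - set(SUSTAINED_STATUSES)
    )
    if bad:
        raise ValueError(f"unknown sustained status value(s): {bad}")
    labels = [_responder_label(a, b) for a, b in zip(sl, si)]
    return pd.DataFrame({"label": labels}, index=sl.index.rename("gene_id"))


def summarize_sets(
    classes: pd.DataFrame,
    sustained_lps: pd.DataFrame,
    sustained_il4: pd.DataFrame,
) -> dict[str, int]:
    """Count the published-style set views.

    ``*_specific_*`` counts include opposite responders allocated by their
    direction under that stimulus, so that
    ``specific_up(stim) = sustained_up(stim) - common_up - ambiguous_up(stim)``
    holds exactly (and symmetrically for down).
    """
    n = classes["label"].value_counts().to_dict()

    def c(label: str) -> int:
        return int(n.get(label, 0))

    opp_lps_up = c("opposite_lps_up_il4_down")
    opp_il4_up = c("opposite_il4_up_lps_down")
    summary = {
        "sustained_lps_up": int((sustained_lps["status"] == "up").sum()),
        "sustained_lps_down": int((sustained_lps["status"] == "down").sum()),
        "sustained_il4_up": int((sustained_il4["status"] == "up").sum()),
        "sustained_il4_down": int((sustained_il4["status"] == "down").sum()),
        "common_up": c("common_up"),
        "common_down": c("common_down"),
        "opposite_lps_up_il4_down": opp_lps_up,
        "opposite_il4_up_lps_down": opp_il4_up,
        "opposite_total": opp_lps_up + opp_il4_up,
        "lps_specific_up": c("lps_specific_up") + opp_lps_up,
        "lps_specific_down": c("lps_specific_down") + opp_il4_up,
        "il4_specific_up": c("il4_specific_up") + opp_il4_up,
        "il4_specific_down": c("il4_specific_down") + opp_lps_up,
        "ambiguous": c("ambiguous"),
        "none": c("none"),
        "n_genes": int(len(classes)),
    }
    return summary


def venn_tallies(
    sustained_lps: pd.DataFrame, sustained_il4: pd.DataFrame
) -> dict[str, int]:
    """Per-direction tallies of genes significant at both timepoints.

    A direction-flip gene is significant at both timepoints with one
    direction each, so it contributes to BOTH the up and down tally of its
    stimulus (e.g. 882 sustained-up + 4 flips = 886 up; 606 + 4 = 610 down).
    A separate report from the responder partition, where flips are never
    double-counted.
    """
    out = {}
    for stim, sus in (("lps", sustained_lps), ("il4", sustained_il4)):
        status = sus["status"]
        flips = int((status == "inconsistent").sum())
        out[f"{stim}_up"] = int((status == "up").sum()) + flips
        out[f"{stim}_down"] = int((status == "down").sum()) + flips
        out[f"{stim}_inconsistent"] = flips
    return out


def build_go_inputs(classes: pd.DataFrame) -> dict[str, list[str]]:
    """Four gene lists for over-representation analysis.

    Common responders are excluded; opposite responders are allocated by
    their direction under each stimulus (an LPS-up/IL-4-down gene appears in
    both the LPSup and the IL4down list). Ambiguous and none genes appear in
    no list. List sizes therefore equal the specific-set counts of
    :func:`summarize_sets`.
    """
    by_label: dict[str, list[str]] = {}
    for label, grp in classes.groupby("label"):
        by_label[label] = sorted(grp.index.tolist())

    def genes(*labels: str) -> list[str]:
        out: list[str] = []
        for label in labels:
            out.extend(by_label.get(label, []))
        return sorted(out)

    return {
        "LPSup": genes("lps_specific_up", "opposite_lps_up_il4_down"),
        "LPSdown": genes("lps_specific_down", "opposite_il4_up_lps_down"),
        "IL4up": genes("il4_specific_up", "opposite_il4_up_lps_down"),
        "IL4down": genes("il4_specific_down", "opposite_lps_up_il4_down"),
    }
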