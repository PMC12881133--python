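"""Readers and writers for every format the pipeline touches.

One dialect throughout: tab-separated, UTF-8, with headers. Gene identifiers
are opaque strings (gene symbols and lncRNA ids mix freely); no case
folding. Validation failures name the file, line/row and field. Every run
can be snapshotted with a ``manifest.json`` (config, seed, package version,
input digests, timestamp).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError
from .simulate import TRUTH_COLUMNS


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column ``gene_id``) and a sample table TSV.

    Every count cell must be a non-negative integer; the sample table must
    cover exactly the samples of the matrix with stimulus/timepoint values
    from the allowed vocabularies. Errors identify the offending cell.
    """
    raw = pd.read_csv(counts_path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise ValidationError(
            f"{counts_path}: first column must be 'gene_id', got {raw.columns[0]!r}"
        )
    genes = raw["gene_id"]
    if genes.duplicated().any():
        dupes = genes[genes.duplicated()].unique().tolist()
        raise ValidationError(f"{counts_path}: duplicate gene id(s): {dupes[:5]}")
    body = raw.drop(columns=["gene_id"])
    values = np.empty(body.shape, dtype=np.int64)
    for ci, col in enumerate(body.columns):
        numeric = pd.to_numeric(body[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric))
        if bad.any():
            ri = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{counts_path}: row {ri + 2}, column {col!r} "
                f"(gene {genes.iloc[ri]!r}): non-integer count {body[col].iloc[ri]!r}"
            )
        values[:, ci] = numeric.astype(np.int64)

    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in samples.columns:
        raise ValidationError(f"{samples_path}: missing 'sample_id' column")
    if samples["sample_id"].duplicated().any():
        raise ValidationError(f"{samples_path}: duplicate sample ids")
    samples = samples.set_index("sample_id")

    try:
        return CountMatrix(
            counts=pd.DataFrame(
                values, index=pd.Index(genes, name="gene_id"), columns=body.columns
            ),
            sample_table=samples,
        )
    except ValidationError as err:
        raise ValidationError(f"{counts_path} / {samples_path}: {err}") from err


def write_counts(
    cm: CountMatrix, counts_path: str | Path, samples_path: str | Path
) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.sample_table.rename_axis("sample_id").to_csv(samples_path, sep="\t")


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.loc[:, list(TRUTH_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "label": str})
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return truth


# ---------------------------------------------------------------------------
# DE results and DEG tables
# ---------------------------------------------------------------------------

def write_de_results(results: pd.DataFrame, path: str | Path, notice: str | None = None) -> None:
    """Write a per-contrast results TSV, optionally with a ``#`` header notice."""
    with open(path, "w", encoding="utf-8") as fh:
        if notice:
            fh.write(f"# {notice}\n")
        results.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_deg_table(
    path: str | Path, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Read an external (gene_id, log2fc, padj) TSV and threshold it.

    Returns the thresholded DEG table with directions computed at the run's
    thresholds. Duplicate genes and padj outside [0, 1] are errors.
    """
    from .concordance import make_deg_table

    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, comment="#")
    missing = [c for c in ("gene_id", "log2fc", "padj") if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if table["gene_id"].duplicated().any():
        dupes = table["gene_id"][table["gene_id"].duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    for col in ("log2fc", "padj"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            ri = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: row {ri + 2}, field {col!r}: "
                f"non-numeric value {table[col].iloc[ri]!r}"
            )
        table[col] = numeric
    out_of_range = (table["padj"] < 0) | (table["padj"] > 1)
    if out_of_range.any():
        ri = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {ri + 2}, field 'padj': value "
            f"{table['padj'].iloc[ri]} outside [0, 1]"
        )
    table = table.set_index("gene_id")
    return make_deg_table(table, lfc_threshold=lfc_threshold, alpha=alpha)


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, ["log2fc", "padj"]].rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# classification outputs
# ---------------------------------------------------------------------------

def write_sustained(sustained_tables: list[pd.DataFrame], path: str | Path) -> None:
    pd.concat(sustained_tables).rename_axis("gene_id").to_csv(path, sep="\t")


def write_classes(classes: pd.DataFrame, path: str | Path) -> None:
    classes.rename_axis("gene_id").to_csv(path, sep="\t")


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seed: int | None,
    inputs: dict[str, str | Path] | None = None,
) -> Path:
    from . import __version__
    from .de import SIMPLIFICATIONS_NOTICE

    manifest = {
        "package": "sustaindeg",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "de_engine": SIMPLIFICATIONS_NOTICE,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
            if Path(p).exists()
        },
    }
    path = Path(out_dir) / "manifest.json"
    write_json(manifest, path)
    return path
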