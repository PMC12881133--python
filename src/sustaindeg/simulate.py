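"""Synthetic bulk RNA-seq counts with planted stimulus-response programs.

The generator emulates the experimental design the analysis assumes: six
conditions (control, LPS, IL-4 at 12 h and 24 h) with independent replicates,
and a catalogue of planted gene programs — sustained stimulus-specific
responders, common and opposite responders, transient (single-timepoint)
responders and direction-flipping genes. Counts are negative-binomial,

    K_gj ~ NB(mean = s_j * mu_g * 2**delta_g(condition_j), dispersion alpha_g)

with per-sample depth factors ``s_j`` (log-normal), log-normal gene baselines
``mu_g`` and a mean-dependent dispersion trend ``alpha_g = a0/mu_g + a1`` —
the variance structure the downstream Wald engine assumes. Alongside the
count matrix the generator emits a truth table of planted labels and
per-condition true log2 fold changes, the oracle for recovery testing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, SimConfig, STIMULI, TIMEPOINTS

#: Planted gene classes and their signed effect patterns over
#: (LPS 12h, LPS 24h, IL4 12h, IL4 24h), in units of the configured effect.
#: Sustained classes act with one sign at both timepoints of a stimulus;
#: transient classes at exactly one timepoint; flip classes change sign
#: between 12 h and 24 h (the F5/Fabp3-like behaviour); ``none`` is null.
CLASS_PATTERNS: dict[str, tuple[int, int, int, int]] = {
    "none": (0, 0, 0, 0),
    "lps_up": (1, 1, 0, 0),
    "lps_down": (-1, -1, 0, 0),
    "il4_up": (0, 0, 1, 1),
    "il4_down": (0, 0, -1, -1),
    "common_up": (1, 1, 1, 1),
    "common_down": (-1, -1, -1, -1),
    "opp_lps_up_il4_down": (1, 1, -1, -1),
    "opp_il4_up_lps_down": (-1, -1, 1, 1),
    "transient_lps_12": (1, 0, 0, 0),
    "transient_lps_24": (0, 1, 0, 0),
    "transient_il4_12": (0, 0, 1, 0),
    "transient_il4_24": (0, 0, 0, 1),
    "flip_lps": (-1, 1, 0, 0),
    "flip_il4": (0, 0, 1, -1),
}

GENE_CLASSES = tuple(CLASS_PATTERNS)

#: Default class composition at n_genes = 2000, mirroring the study's
#: proportions: an LPS response larger than the IL-4 response, a few dozen
#: common and opposite responders, and a handful of flip genes.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "none": 1609,
    "lps_up": 80,
    "lps_down": 60,
    "il4_up": 40,
    "il4_down": 30,
    "common_up": 30,
    "common_down": 30,
    "opp_lps_up_il4_down": 24,
    "opp_il4_up_lps_down": 21,
    "transient_lps_12": 20,
    "transient_lps_24": 20,
    "transient_il4_12": 15,
    "transient_il4_24": 15,
    "flip_lps": 4,
    "flip_il4": 2,
}

TRUTH_COLUMNS = (
    "gene_id",
    "label",
    "baseline_mean",
    "dispersion",
    "lfc_lps_12",
    "lfc_lps_24",
    "lfc_il4_12",
    "lfc_il4_24",
)


def _resolve_class_counts(config: SimConfig) -> dict[str, int]:
    if config.class_counts is None:
        if config.n_genes == 2000:
            return dict(DEFAULT_CLASS_COUNTS)
        # scale the default composition, absorbing rounding into `none`
        scale = config.n_genes / 2000
        counts = {
            label: int(round(n * scale))
            for label, n in DEFAULT_CLASS_COUNTS.items()
            if label != "none"
        }
        rest = config.n_genes - sum(counts.values())
        if rest < 0:
            raise ValueError(
                f"n_genes={config.n_genes} too small for the default class mix; "
                "pass explicit class_counts"
            )
        counts["none"] = rest
        return counts
    counts = dict(config.class_counts)
    unknown = sorted(set(counts) - set(GENE_CLASSES))
    if unknown:
        raise ValueError(f"unknown gene class label(s): {unknown}")
    if any(n < 0 for n in counts.values()):
        raise ValueError("class_counts must be non-negative")
    total = sum(counts.values())
    if total != config.n_genes:
        raise ValueError(
            f"class_counts sum to {total}, but n_genes = {config.n_genes}"
        )
    return counts


def _condition_grid() -> list[tuple[str, int]]:
    return [(stim, tp) for tp in TIMEPOINTS for stim in STIMULI]


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one synthetic experiment.

    Returns the count matrix and the truth table (one row per gene:
    planted label, baseline mean, dispersion, and the four true log2 fold
    changes). Fully reproducible from ``config.seed``: sub-streams for gene
    parameters, class assignment, depth factors and count noise are spawned
    deterministically from one seed sequence.
    """
    class_counts = _resolve_class_counts(config)

    root = np.random.SeedSequence(config.seed)
    ss_genes, ss_assign, ss_depth, ss_counts = root.spawn(4)
    rng_genes = np.random.default_rng(ss_genes)
    rng_assign = np.random.default_rng(ss_assign)
    rng_depth = np.random.default_rng(ss_depth)
    rng_counts = np.random.default_rng(ss_counts)

    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"g{i + 1:0{width}d}" for i in range(n)])

    baseline = np.exp(
        rng_genes.normal(config.baseline_logmean_mu, config.baseline_logmean_sigma, n)
    )
    alpha = config.dispersion_a0 / baseline + config.dispersion_a1
    if np.any(alpha <= 0):
        raise ValueError("dispersion trend produced alpha <= 0")

    # assign labels to shuffled gene indices so class membership is not
    # positionally confounded with the baseline draw order
    labels = np.repeat(
        [label for label in GENE_CLASSES if class_counts.get(label, 0) > 0],
        [class_counts[label] for label in GENE_CLASSES if class_counts.get(label, 0) > 0],
    ).astype(object)
    perm = rng_assign.permutation(n)
    assigned = np.empty(n, dtype=object)
    assigned[perm] = labels

    e = config.effect_lfc
    patterns = np.array([CLASS_PATTERNS[label] for label in assigned], dtype=float) * e
    # columns: lfc_lps_12, lfc_lps_24, lfc_il4_12, lfc_il4_24
    lfc_by_cell = {
        ("LPS", 12): patterns[:, 0],
        ("LPS", 24): patterns[:, 1],
        ("IL4", 12): patterns[:, 2],
        ("IL4", 24): patterns[:, 3],
        ("control", 12): np.zeros(n),
        ("control", 24): np.zeros(n),
    }

    sample_rows = []
    for stim, tp in _condition_grid():
        for rep in range(1, config.replicates + 1):
            sample_rows.append((f"{stim}_{tp}h_r{rep}", stim, tp, rep))
    sample_ids = [r[0] for r in sample_rows]
    m = len(sample_ids)

    depth = np.exp(rng_depth.normal(0.0, config.libsize_sigma, m))

    counts = np.empty((n, m), dtype=np.int64)
    r = 1.0 / alpha  # NB size parameter per gene
    for j, (sid, stim, tp, rep) in enumerate(sample_rows):
        mean_j = depth[j] * baseline * np.exp2(lfc_by_cell[(stim, tp)])
        # gamma-Poisson mixture == NB(mean, alpha); robust for tiny alpha
        lam = rng_counts.gamma(shape=r, scale=mean_j / r)
        counts[:, j] = rng_counts.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
        ),
        sample_table=pd.DataFrame(
            {
                "stimulus": [r[1] for r in sample_rows],
                "timepoint": [r[2] for r in sample_rows],
                "replicate": [r[3] for r in sample_rows],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": assigned,
            "baseline_mean": baseline,
            "dispersion": alpha,
            "lfc_lps_12": patterns[:, 0],
            "lfc_lps_24": patterns[:, 1],
            "lfc_il4_12": patterns[:, 2],
            "lfc_il4_24": patterns[:, 3],
        }
    )
    return cm, truth


def write_fixture(cm: CountMatrix, truth: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write counts/samples/truth TSVs for a simulated experiment.

    Files round-trip losslessly through :mod:`sustaindeg.io`; regenerating
    from the same seed yields byte-identical files.
    """
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_path = out / "counts.tsv"
    samples_path = out / "samples.tsv"
    truth_path = out / "truth.tsv"
    sio.write_counts(cm, counts_path, samples_path)
    sio.write_truth(truth, truth_path)
    return {"counts": counts_path, "samples": samples_path, "truth": truth_path}
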