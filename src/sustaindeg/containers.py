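"""Core data containers for the sustained-response pipeline.

The pipeline's entry point is a :class:`CountMatrix`: a gene x sample table of
raw integer read counts together with a sample annotation table describing the
two-stimulus, two-timepoint design (control / LPS / IL-4 at 12 h and 24 h).
Everything downstream — size factors, dispersions, Wald contrasts, sustained
calls — consumes this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed stimulus vocabulary for the sample table.
STIMULI = ("control", "LPS", "IL4")

#: Treated arms (everything tested against the matched-timepoint control).
TREATMENTS = ("LPS", "IL4")

#: Allowed timepoints, in hours post-stimulation.
TIMEPOINTS = (12, 24)

SAMPLE_TABLE_COLUMNS = ("stimulus", "timepoint", "replicate")


@dataclass(frozen=True)
class Contrast:
    """A treated-vs-control comparison at a single timepoint.

    Contrasts never mix timepoints: each stimulus x timepoint group is tested
    against the untreated control collected at the same timepoint.
    """

    stimulus: str
    timepoint: int

    def __post_init__(self) -> None:
        if self.stimulus not in TREATMENTS:
            raise ValueError(
                f"contrast stimulus must be one of {TREATMENTS}, got {self.stimulus!r}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"contrast timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )

    @property
    def name(self) -> str:
        return f"{self.stimulus}_{self.timepoint}h"


#: The four contrasts of the full design, in pipeline order.
ALL_CONTRASTS = (
    Contrast("LPS", 12),
    Contrast("LPS", 24),
    Contrast("IL4", 12),
    Contrast("IL4", 24),
)


class ValidationError(ValueError):
    """Raised when an input object or file fails structural validation."""


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with sample annotations.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index = gene ids (unique),
        columns = sample ids (unique).
    sample_table
        DataFrame indexed by sample id with columns ``stimulus``
        (control/LPS/IL4), ``timepoint`` (12 or 24) and ``replicate``.
        Must cover exactly the samples of ``counts``.
    """

    counts: pd.DataFrame
    sample_table: pd.DataFrame

    def __post_init__(self) -> None:
        c, st = self.counts, self.sample_table
        if c.shape[0] == 0:
            raise ValidationError("count matrix has no genes")
        if c.shape[1] == 0:
            raise ValidationError("count matrix has no samples")
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if c.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        if not np.issubdtype(np.asarray(c.values).dtype, np.integer):
            # allow float storage only if every value is integral
            vals = np.asarray(c.values)
            if not np.all(np.isfinite(vals)) or not np.all(vals == np.floor(vals)):
                raise ValidationError("counts must be integers")
            self.counts = c = c.astype(np.int64)
        if (c.values < 0).any():
            raise ValidationError("counts must be non-negative")

        missing = [col for col in SAMPLE_TABLE_COLUMNS if col not in st.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        if set(st.index) != set(c.columns):
            only_counts = sorted(set(c.columns) - set(st.index))
            only_table = sorted(set(st.index) - set(c.columns))
            raise ValidationError(
                "sample ids differ between counts and sample table "
                f"(counts only: {only_counts[:5]}, table only: {only_table[:5]})"
            )
        # align sample table to the column order of the matrix
        self.sample_table = st = st.loc[c.columns].copy()
        bad_stim = sorted(set(st["stimulus"]) - set(STIMULI))
        if bad_stim:
            raise ValidationError(
                f"unknown stimulus value(s) {bad_stim}; allowed: {list(STIMULI)}"
            )
        st["timepoint"] = pd.to_numeric(st["timepoint"], errors="coerce")
        bad_tp = sorted(set(st["timepoint"].dropna()) - set(TIMEPOINTS)) or st[
            "timepoint"
        ].isna().any()
        if bad_tp:
            raise ValidationError(
                f"timepoint values must be in {list(TIMEPOINTS)}; "
                f"got {sorted(st['timepoint'].unique().tolist())}"
            )
        st["timepoint"] = st["timepoint"].astype(int)

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def condition_labels(self) -> pd.Series:
        """Per-sample design group label, e.g. ``'LPS_12h'`` / ``'control_24h'``."""
        st = self.sample_table
        return st["stimulus"].str.cat(st["timepoint"].astype(str) + "h", sep="_")

    def group_samples(self, stimulus: str, timepoint: int) -> list[str]:
        st = self.sample_table
        mask = (st["stimulus"] == stimulus) & (st["timepoint"] == timepoint)
        return list(st.index[mask])

    def validate_full_design(self) -> None:
        """Require at least one sample in every (stimulus, timepoint) cell."""
        for stim in STIMULI:
            for tp in TIMEPOINTS:
                if not self.group_samples(stim, tp):
                    raise ValidationError(
                        f"design cell ({stim}, {tp} h) has no samples"
                    )


@dataclass
class SimConfig:
    """Configuration of the synthetic count generator.

    Defaults emulate the study design: six conditions (control/LPS/IL-4 at
    12 h and 24 h) with five independent replicates each, planted responder
    programs at |log2FC| = 2, and negative-binomial counts with a
    mean-dependent dispersion trend ``alpha = a0/mu + a1``.
    """

    n_genes: int = 2000
    replicates: int = 5
    class_counts: dict[str, int] | None = None
    effect_lfc: float = 2.0
    baseline_logmean_mu: float = 4.0
    baseline_logmean_sigma: float = 2.0
    dispersion_a0: float = 3.0
    dispersion_a1: float = 0.05
    libsize_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (DE needs within-group variance)")
        if self.effect_lfc <= 0:
            raise ValueError("effect_lfc must be positive")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion trend coefficients must be non-negative")
        if self.dispersion_a0 == 0 and self.dispersion_a1 == 0:
            raise ValueError("dispersion trend yields alpha <= 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be non-negative")
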